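"""Rule-based differential diagnosis and the end-to-end pipeline.

Evidence strands:

* ``D`` — significant density deficit: paired-cube p < alpha and median
  mdd > 0 (the discoloured area is the less dense one);
* ``R`` — gradient reversal: the lesion profile's gradient is reversed
  while the normal profile's is increasing;
* ``C`` — elemental contamination: any staining element flagged by XRF;
* ``S`` — surface-confined deficit: deficit ~ 0 below the dissolution
  boundary depth and substantial above it.

Ordered decision table::

    D and R and C      -> hypomineralised_with_postmortem_uptake
    D and R and not C  -> hypomineralised
    not D and C        -> taphonomic_stain
    D and not R and S  -> acid_dissolution_suspect
    not D and not C    -> sound
    otherwise          -> indeterminate
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import phantom as ph
from .densitometry import (
    DEFAULT_CUBE_EDGE_UM,
    MddTable,
    paired_cube_analysis,
    write_mdd_csv,
)
from .profiles import (
    ProfileComparison,
    compare_profiles,
    profile_from_lines,
    write_comparison_csv,
)
from .volume_core import extract_transect, load_volume, read_landmarks
from .xrf import summarize_xrf, read_xrf_csv

__all__ = [
    "LABELS",
    "Thresholds",
    "EvidenceBundle",
    "DiagnosticResult",
    "classify_tooth",
    "run_pipeline",
]

LABELS = (
    "sound",
    "hypomineralised",
    "hypomineralised_with_postmortem_uptake",
    "taphonomic_stain",
    "acid_dissolution_suspect",
    "indeterminate",
)

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class Thresholds:
    alpha: float = 0.05
    shell_boundary_u: float = 0.7  # inner/outer split for the dissolution check
    shell_inner_tol: float = 0.02  # "deficit ~ 0" tolerance below the boundary
    shell_outer_min: float = 0.05  # "substantial" deficit above the boundary


@dataclass
class EvidenceBundle:
    tooth_id: str
    density_test: MddTable
    profile_cmp: ProfileComparison
    xrf_flags: dict | None = None  # element -> ElementFlag, optional strand
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density_test is None or self.profile_cmp is None:
            raise ValueError("density and profile evidence are both required")


@dataclass
class DiagnosticResult:
    label: str
    rule_trace: list[str]
    evidence: dict

    def to_dict(self) -> dict:
        return {"label": self.label, "rule_trace": list(self.rule_trace), "evidence": self.evidence}


def classify_tooth(
    evidence: EvidenceBundle, thresholds: Thresholds = Thresholds()
) -> DiagnosticResult:
    """Apply the ordered decision table to an evidence bundle.

    The label and trace are a pure function of the evidence and thresholds.
    """
    density = evidence.density_test
    cmp = evidence.profile_cmp
    trace: list[str] = []

    p = density.p_value
    median_mdd = density.median_mdd
    d_flag = p is not None and p < thresholds.alpha and median_mdd > 0
    trace.append(
        f"D={d_flag} (p={'none' if p is None else format(p, '.6g')}, "
        f"alpha={thresholds.alpha:g}, median_mdd={median_mdd:.6g})"
    )

    r_flag = (
        cmp.gradient_lesion.label == "reversed"
        and cmp.gradient_normal.label == "increasing"
    )
    trace.append(
        f"R={r_flag} (lesion={cmp.gradient_lesion.label}, normal={cmp.gradient_normal.label})"
    )

    if evidence.xrf_flags is None:
        c_flag = False
        trace.append("C=False (no XRF evidence provided)")
    else:
        flagged = sorted(el for el, f in evidence.xrf_flags.items() if f.flagged)
        c_flag = bool(flagged)
        trace.append(f"C={c_flag} (flagged={flagged})")

    inner = cmp.deficit_curve[cmp.positions <= thresholds.shell_boundary_u]
    outer = cmp.deficit_curve[cmp.positions > thresholds.shell_boundary_u]
    s_flag = (
        inner.size > 0
        and outer.size > 0
        and float(np.mean(np.abs(inner))) < thresholds.shell_inner_tol
        and float(np.mean(outer)) >= thresholds.shell_outer_min
    )
    trace.append(
        f"S={s_flag} (inner_mean_abs={float(np.mean(np.abs(inner))):.6g}, "
        f"outer_mean={float(np.mean(outer)):.6g}, boundary_u={thresholds.shell_boundary_u:g})"
    )

    if d_flag and r_flag and c_flag:
        label = "hypomineralised_with_postmortem_uptake"
        trace.append("rule: D and R and C")
    elif d_flag and r_flag:
        label = "hypomineralised"
        trace.append("rule: D and R and not C")
    elif not d_flag and c_flag:
        label = "taphonomic_stain"
        trace.append("rule: not D and C")
    elif d_flag and not r_flag and s_flag:
        label = "acid_dissolution_suspect"
        trace.append("rule: D and not R and S")
    elif not d_flag and not c_flag:
        label = "sound"
        trace.append("rule: not D and not C")
    else:
        label = "indeterminate"
        trace.append("rule: fallthrough (conflicting evidence)")

    summary = {
        "tooth_id": evidence.tooth_id,
        "p_value": None if p is None else float(p),
        "median_mdd": float(median_mdd),
        "mid_deficit": float(cmp.mid_deficit),
        "max_deficit": float(cmp.max_deficit),
        "gradient_normal": cmp.gradient_normal.label,
        "gradient_lesion": cmp.gradient_lesion.label,
        "xrf_flagged": sorted(
            el for el, f in (evidence.xrf_flags or {}).items() if f.flagged
        ),
        "thresholds": asdict(thresholds),
    }
    return DiagnosticResult(label=label, rule_trace=trace, evidence=summary)


# ---------------------------------------------------------------------------
# End-to-end pipeline


def run_pipeline(
    config: dict | str | Path,
    seed: int | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Execute phantom/data → densitometry → profiles → XRF → classification.

    ``config`` is a YAML path or an equivalent dict with either a
    ``phantom`` section (synthetic mode) or a ``volume`` section (data
    mode).  Returns the JSON-serialisable report; when ``output_dir`` is
    given, writes ``report.json``, ``mdd.csv``, ``profiles.csv``,
    ``xrf_summary.csv`` and ``profile_plot.png``.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    if "phantom" not in config and "volume" not in config:
        raise ValueError("config must define a 'phantom' (synthetic) or 'volume' (data) input section")
    if seed is None:
        seed = int(config.get("seed", 0))
    thresholds = Thresholds(**config.get("thresholds", {}))
    edge = float(config.get("cube_edge_um", DEFAULT_CUBE_EDGE_UM))
    method = str(config.get("test_method", "normal_approx"))

    if "phantom" in config:
        bundle, extras = _synthetic_evidence(config, seed, edge, method)
    else:
        bundle, extras = _data_evidence(config, edge, method)

    try:
        result = classify_tooth(bundle, thresholds)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "tooth_id": bundle.tooth_id,
        "label": result.label,
        "rule_trace": result.rule_trace,
        "evidence": result.evidence,
        "mdd": [float(v) for v in bundle.density_test.mdd],
        "density_p_value": (
            None
            if bundle.density_test.p_value is None
            else float(bundle.density_test.p_value)
        ),
        "density_label": bundle.density_test.label,
        "test_method": method,
        "cube_edge_um": edge,
        "thresholds": asdict(thresholds),
    }
    report.update(extras)

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        write_mdd_csv(bundle.density_test, output_dir / "mdd.csv")
        write_comparison_csv(bundle.profile_cmp, output_dir / "profiles.csv")
        if extras.get("_xrf_summary_obj") is not None:
            from .xrf import write_xrf_summary_csv

            write_xrf_summary_csv(extras["_xrf_summary_obj"], output_dir / "xrf_summary.csv")
        from .profiles import plot_comparison

        plot_comparison(bundle.profile_cmp, output_dir / "profile_plot.png")
        (output_dir / "report.json").write_text(_dump_report(report))

    report.pop("_xrf_summary_obj", None)
    return report


def _dump_report(report: dict) -> str:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, sort_keys=True, indent=2) + "\n"


def _synthetic_evidence(config: dict, seed: int, edge: float, method: str):
    cfg = dict(config["phantom"])
    cfg["seed"] = seed
    try:
        spec = ph.PhantomSpec(**cfg)
        vol, truth = ph.generate_phantom(spec)
    except Exception as exc:
        raise RuntimeError(f"stage 'phantom' failed: {exc}") from exc

    nz, ny, nx = spec.resolved_shape()
    round_x = config.get("round_x_indices", [nx // 3, (2 * nx) // 3])
    if len(round_x) != 2:
        raise RuntimeError("stage 'densitometry' failed: need exactly 2 round x positions")

    try:
        normal_ts, lesion_ts = [], []
        for x in round_x:
            s, d = ph.line_endpoints(spec, "normal", int(x))
            normal_ts.append(extract_transect(vol, s, d))
            s, d = ph.line_endpoints(spec, "lesion", int(x))
            lesion_ts.append(extract_transect(vol, s, d))
        density = paired_cube_analysis(
            vol, normal_ts, lesion_ts, edge=edge, method=method, tooth_id="phantom"
        )
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'densitometry' failed: {exc}") from exc

    try:
        n_lines = int(config.get("profile_lines", 15))
        half = n_lines // 2
        xs = [min(max(x, 0), nx - 1) for x in range(nx // 2 - half, nx // 2 - half + n_lines)]
        normal_lines = [ph.line_endpoints(spec, "normal", x) for x in xs]
        lesion_lines = [ph.line_endpoints(spec, "lesion", x) for x in xs]
        prof_normal = profile_from_lines(vol, normal_lines)
        prof_lesion = profile_from_lines(vol, lesion_lines)
        cmp = compare_profiles(prof_normal, prof_lesion)
    except Exception as exc:
        raise RuntimeError(f"stage 'profiles' failed: {exc}") from exc

    xrf_cfg = config.get("xrf", {})
    xrf_flags = None
    extras: dict = {"mode": "synthetic", "truth_class": truth.class_label, "xrf": None}
    if xrf_cfg is not None:
        try:
            table = ph.simulate_xrf(
                truth,
                baseline=xrf_cfg.get("baseline"),
                cv=float(xrf_cfg.get("cv", 0.25)),
                n_repeats=int(xrf_cfg.get("n_repeats", 2)),
                seed=seed + 1,
                tooth_id="phantom",
            )
            summary = summarize_xrf(table, "phantom")
            xrf_flags = summary.flags
            extras["xrf"] = {
                "p_value": float(summary.p_value),
                "flagged": list(summary.flagged_elements),
                "fold_changes": {
                    el: (None if np.isinf(f.fold_change) else float(f.fold_change))
                    for el, f in summary.flags.items()
                },
            }
            extras["_xrf_summary_obj"] = summary
        except Exception as exc:
            raise RuntimeError(f"stage 'xrf' failed: {exc}") from exc

    bundle = EvidenceBundle(
        tooth_id="phantom",
        density_test=density,
        profile_cmp=cmp,
        xrf_flags=xrf_flags,
        provenance={"mode": "synthetic", "seed": seed},
    )
    return bundle, extras


def _data_evidence(config: dict, edge: float, method: str):
    for key in ("volume", "landmarks"):
        if key not in config:
            raise ValueError(f"data-mode config missing '{key}'")
    tooth_id = str(config.get("tooth_id", "tooth"))
    try:
        vol = load_volume(config["volume"])
        marks = read_landmarks(config["landmarks"])
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    def _mark(label: str):
        if label not in marks:
            raise RuntimeError(f"stage 'landmarks' failed: missing landmark {label!r}")
        return marks[label]

    try:
        normal_ts = [
            extract_transect(vol, _mark(f"normal_surface_{r}"), _mark(f"normal_dej_{r}"))
            for r in (1, 2)
        ]
        lesion_ts = [
            extract_transect(vol, _mark(f"disc_surface_{r}"), _mark(f"disc_dej_{r}"))
            for r in (1, 2)
        ]
        density = paired_cube_analysis(
            vol, normal_ts, lesion_ts, edge=edge, method=method, tooth_id=tooth_id
        )
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'densitometry' failed: {exc}") from exc

    try:
        prof_normal = profile_from_lines(
            vol, [(_mark("profile_normal_surface"), _mark("profile_normal_dej"))]
        )
        prof_lesion = profile_from_lines(
            vol, [(_mark("profile_disc_surface"), _mark("profile_disc_dej"))]
        )
        cmp = compare_profiles(prof_normal, prof_lesion)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'profiles' failed: {exc}") from exc

    xrf_flags = None
    extras: dict = {"mode": "data", "xrf": None}
    if "xrf_csv" in config:
        try:
            table = read_xrf_csv(config["xrf_csv"])
            summary = summarize_xrf(table, tooth_id)
            xrf_flags = summary.flags
            extras["xrf"] = {
                "p_value": float(summary.p_value),
                "flagged": list(summary.flagged_elements),
            }
            extras["_xrf_summary_obj"] = summary
        except Exception as exc:
            raise RuntimeError(f"stage 'xrf' failed: {exc}") from exc

    bundle = EvidenceBundle(
        tooth_id=tooth_id,
        density_test=density,
        profile_cmp=cmp,
        xrf_flags=xrf_flags,
        provenance={"mode": "data", "volume": str(config["volume"])},
    )
    return bundle, extras
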