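import json

import numpy as np
import pytest

from paleoenamel.densitometry import MddTable
from paleoenamel.diagnosis import (
    EvidenceBundle,
    Thresholds,
    classify_tooth,
    run_pipeline,
)
from paleoenamel.profiles import DensityProfile, N_PROFILE_POINTS, compare_profiles
from paleoenamel.xrf import ElementFlag


def make_mdd(mdd_values, p_value):
    mdd = np.asarray(mdd_values, dtype=float)
    normal = np.linspace(30000, 31000, 10).reshape(2, 5)
    return MddTable(
        tooth_id="t",
        normal_means=normal,
        discoloured_means=normal - mdd.reshape(2, 5),
        mdd=mdd,
        p_value=p_value,
        method="normal_approx",
        label="tested" if p_value is not None else "no difference",
    )


def linear_profile(a, b):
    return DensityProfile(values=np.linspace(a, b, N_PROFILE_POINTS))


def make_cmp(lesion_kind="reversed"):
    normal = linear_profile(30000, 31500)
    if lesion_kind == "reversed":
        lesion = linear_profile(29000, 26000)
    elif lesion_kind == "increasing":
        lesion = linear_profile(29500, 31000)
    elif lesion_kind == "surface_shell":
        vals = np.linspace(30000, 31500, N_PROFILE_POINTS)
        u = np.linspace(0, 1, N_PROFILE_POINTS)
        vals = vals * np.where(u > 0.7, 0.8, 1.0)
        lesion = DensityProfile(values=vals)
    else:
        lesion = normal
    return compare_profiles(normal, lesion)


def flags(**flagged):
    out = {}
    for el in ("Mn", "Fe", "Cu", "Pb"):
        f = flagged.get(el, False)
        out[el] = ElementFlag(
            element=el,
            fold_change=10.0 if f else 1.0,
            flagged=f,
            dc_values=(1.0, 1.1),
            no_values=(0.1, 0.11) if f else (1.0, 1.1),
        )
    return out


SIG = make_mdd(np.full(10, 2000.0), 0.005)
NSIG = make_mdd(np.random.default_rng(0).normal(0, 300, 10), 0.4)


class TestClassifyTooth:
    def test_hypomineralised_with_uptake(self):
        ev = EvidenceBundle("t", SIG, make_cmp("reversed"), flags(Fe=True))
        res = classify_tooth(ev)
        assert res.label == "hypomineralised_with_postmortem_uptake"
        assert any("D and R and C" in r for r in res.rule_trace)

    def test_hypomineralised(self):
        ev = EvidenceBundle("t", SIG, make_cmp("reversed"), flags())
        assert classify_tooth(ev).label == "hypomineralised"

    def test_hypomineralised_without_xrf_evidence(self):
        ev = EvidenceBundle("t", SIG, make_cmp("reversed"), None)
        assert classify_tooth(ev).label == "hypomineralised"

    def test_taphonomic_stain(self):
        ev = EvidenceBundle("t", NSIG, make_cmp("increasing"), flags(Mn=True))
        assert classify_tooth(ev).label == "taphonomic_stain"

    def test_sound(self):
        ev = EvidenceBundle("t", NSIG, make_cmp("increasing"), flags())
        assert classify_tooth(ev).label == "sound"

    def test_acid_dissolution_suspect(self):
        ev = EvidenceBundle("t", SIG, make_cmp("surface_shell"), flags())
        res = classify_tooth(ev)
        assert res.label == "acid_dissolution_suspect"

    def test_conflicting_evidence_is_indeterminate(self):
        # significant deficit but increasing lesion gradient and no shell
        ev = EvidenceBundle("t", SIG, make_cmp("increasing"), flags())
        assert classify_tooth(ev).label == "indeterminate"

    def test_negative_mdd_blocks_density_criterion(self):
        neg = make_mdd(np.full(10, -2000.0), 0.005)
        ev = EvidenceBundle("t", neg, make_cmp("increasing"), flags())
        assert classify_tooth(ev).label == "sound"

    def test_no_difference_result_counts_as_not_significant(self):
        nd = make_mdd(np.zeros(10), None)
        ev = EvidenceBundle("t", nd, make_cmp("identical"), flags())
        assert classify_tooth(ev).label == "sound"

    def test_missing_evidence_errors(self):
        with pytest.raises(ValueError, match="required"):
            EvidenceBundle("t", None, make_cmp("reversed"))

    def test_trace_is_pure_function_of_evidence(self):
        ev = EvidenceBundle("t", SIG, make_cmp("reversed"), flags(Fe=True))
        a = classify_tooth(ev)
        b = classify_tooth(ev)
        assert a.label == b.label
        assert a.rule_trace == b.rule_trace

    def test_removing_xrf_moves_within_antemortem_pair(self):
        with_xrf = classify_tooth(EvidenceBundle("t", SIG, make_cmp("reversed"), flags(Fe=True)))
        without = classify_tooth(EvidenceBundle("t", SIG, make_cmp("reversed"), None))
        assert with_xrf.label == "hypomineralised_with_postmortem_uptake"
        assert without.label == "hypomineralised"

    def test_removing_xrf_moves_within_postmortem_pair(self):
        with_xrf = classify_tooth(EvidenceBundle("t", NSIG, make_cmp("increasing"), flags(Mn=True)))
        without = classify_tooth(EvidenceBundle("t", NSIG, make_cmp("increasing"), None))
        assert with_xrf.label == "taphonomic_stain"
        assert without.label == "sound"

    def test_threshold_alpha_exposed(self):
        borderline = make_mdd(np.full(10, 2000.0), 0.04)
        ev = EvidenceBundle("t", borderline, make_cmp("reversed"), None)
        assert classify_tooth(ev, Thresholds(alpha=0.05)).label == "hypomineralised"
        # tighter alpha: not D and not C falls through to sound
        assert classify_tooth(ev, Thresholds(alpha=0.01)).label == "sound"


class TestRunPipeline:
    def test_synthetic_hypomineralised_recovers_truth(self):
        cfg = {
            "phantom": {"lesion_class": "hypomineralised", "deficit_mid": 0.10, "noise_sd": 300.0},
            "seed": 11,
        }
        report = run_pipeline(cfg)
        assert report["label"] == "hypomineralised"
        assert report["truth_class"] == "hypomineralised"

    def test_missing_input_section_errors(self):
        with pytest.raises(ValueError, match="phantom.*volume|volume.*phantom"):
            run_pipeline({"seed": 1})

    def test_same_config_and_seed_byte_identical_report(self, tmp_path):
        cfg = {
            "phantom": {"lesion_class": "taphonomic_stain", "noise_sd": 400.0},
            "seed": 5,
        }
        r1 = run_pipeline(cfg, output_dir=tmp_path / "a")
        r2 = run_pipeline(cfg, output_dir=tmp_path / "b")
        j1 = (tmp_path / "a" / "report.json").read_bytes()
        j2 = (tmp_path / "b" / "report.json").read_bytes()
        assert j1 == j2
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_output_files_written(self, tmp_path):
        cfg = {
            "phantom": {"lesion_class": "hypomineralised_with_uptake", "deficit_mid": 0.10,
                        "noise_sd": 300.0},
            "seed": 2,
        }
        report = run_pipeline(cfg, output_dir=tmp_path)
        for name in ("report.json", "mdd.csv", "profiles.csv", "xrf_summary.csv", "profile_plot.png"):
            assert (tmp_path / name).exists(), name
        assert report["label"] == "hypomineralised_with_postmortem_uptake"
        assert report["xrf"]["flagged"] == ["Fe"]

    def test_yaml_config_and_seed_override(self, tmp_path):
        cfg_path = tmp_path / "config.yaml"
        cfg_path.write_text(
            "phantom:\n  lesion_class: sound\n  noise_sd: 300.0\nseed: 1\n"
        )
        report = run_pipeline(cfg_path, seed=99)
        assert report["seed"] == 99
        assert report["label"] == "sound"

    def test_data_mode_roundtrip(self, tmp_path):
        # write a hypomineralised phantom to disk, then run in data mode
        import pandas as pd

        from paleoenamel import phantom as ph
        from paleoenamel.volume_core import save_volume

        spec = ph.PhantomSpec(lesion_class="hypomineralised", deficit_mid=0.10, noise_sd=0.0)
        vol, truth = ph.generate_phantom(spec)
        tiff = save_volume(vol, tmp_path / "tooth.tiff")

        rows = []

        def add(label, pt):
            z, y, x = pt
            rows.append({"label": label, "x_um": x, "y_um": y, "z_um": z})

        for r, x in enumerate((13, 26), start=1):
            s, d = ph.line_endpoints(spec, "normal", x)
            add(f"normal_surface_{r}", s)
            add(f"normal_dej_{r}", d)
            s, d = ph.line_endpoints(spec, "lesion", x)
            add(f"disc_surface_{r}", s)
            add(f"disc_dej_{r}", d)
        s, d = ph.line_endpoints(spec, "normal", 20)
        add("profile_normal_surface", s)
        add("profile_normal_dej", d)
        s, d = ph.line_endpoints(spec, "lesion", 20)
        add("profile_disc_surface", s)
        add("profile_disc_dej", d)
        marks = tmp_path / "landmarks.csv"
        pd.DataFrame(rows).to_csv(marks, index=False)

        report = run_pipeline(
            {"volume": str(tiff), "landmarks": str(marks), "tooth_id": "T16"}
        )
        assert report["mode"] == "data"
        assert report["tooth_id"] == "T16"
        # no XRF provided: D and R hold, so the label stays ante-mortem
        assert report["label"] == "hypomineralised"

    def test_partial_stage_failure_names_stage(self, tmp_path):
        cfg = {"volume": str(tmp_path / "missing.tiff"), "landmarks": str(tmp_path / "none.csv")}
        with pytest.raises(RuntimeError, match="stage 'load'"):
            run_pipeline(cfg)
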