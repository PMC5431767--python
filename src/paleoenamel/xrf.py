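"""Paired XRF elemental screening of stained (DC) vs normal (NO) enamel.

Input tables are tidy frames with columns ``tooth, element, condition,
repeat, value`` holding relative concentrations (oxide form) of the four
staining-relevant elements Mn, Fe, Cu, Pb.  Extra elements (e.g. Sn, Zn, Sr
or the P/Ca condition-1 measurements) may be present; they are retained in
summaries but excluded from the staining screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .npstats import WilcoxonResult, wilcoxon_signed_rank

__all__ = [
    "STAIN_ELEMENTS",
    "DEFAULT_FOLD_THRESHOLD",
    "ElementFlag",
    "XRFSummary",
    "validate_xrf_table",
    "read_xrf_csv",
    "xrf_paired_test",
    "element_enrichment",
    "summarize_xrf",
    "write_xrf_summary_csv",
]

STAIN_ELEMENTS = ("Mn", "Fe", "Cu", "Pb")
DEFAULT_FOLD_THRESHOLD = 3.0
_COLUMNS = ("tooth", "element", "condition", "repeat", "value")


@dataclass(frozen=True)
class ElementFlag:
    element: str
    fold_change: float  # mean_DC / mean_NO (inf when mean_NO == 0)
    flagged: bool
    dc_values: tuple[float, ...]
    no_values: tuple[float, ...]


@dataclass
class XRFSummary:
    tooth_id: str
    stats: pd.DataFrame  # per (element, condition): mean, sd (n-1 denominator)
    p_value: float
    test: WilcoxonResult
    flags: dict[str, ElementFlag] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def flagged_elements(self) -> tuple[str, ...]:
        return tuple(el for el, f in self.flags.items() if f.flagged)


def validate_xrf_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"XRF table missing columns: {sorted(missing)}")
    bad_cond = set(table["condition"].unique()) - {"DC", "NO"}
    if bad_cond:
        raise ValueError(f"unknown condition labels {sorted(bad_cond)}; expected DC/NO")
    if (table["value"] < 0).any():
        raise ValueError("relative concentrations must be non-negative")
    counts = table.groupby(["tooth", "element", "condition"])["repeat"].count()
    if counts.groupby(["tooth", "element"]).nunique().gt(1).any():
        raise ValueError("each (tooth, element) must have equal repeat counts in DC and NO")
    return table


def read_xrf_csv(path: str | Path) -> pd.DataFrame:
    return validate_xrf_table(pd.read_csv(path))


def _paired_values(
    table: pd.DataFrame, tooth_id: str, element: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = table[(table["tooth"] == tooth_id) & (table["element"] == element)]
    out = []
    for cond in ("DC", "NO"):
        vals = sub[sub["condition"] == cond].sort_values("repeat")["value"].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"missing condition {cond} for element {element} of tooth {tooth_id}")
        out.append(vals)
    dc, no = out
    if dc.size != no.size:
        raise ValueError(
            f"unbalanced repeats for element {element} of tooth {tooth_id}: "
            f"{dc.size} DC vs {no.size} NO"
        )
    return dc, no


def xrf_paired_test(
    table: pd.DataFrame,
    tooth_id: str,
    method: str = "normal_approx",
    elements=STAIN_ELEMENTS,
) -> WilcoxonResult:
    """Two-sided signed-rank test of DC - NO differences paired by
    (element, repeat index) over the four staining-relevant elements
    (8 pairs at the default two repeats)."""
    validate_xrf_table(table)
    diffs = []
    for el in elements:
        dc, no = _paired_values(table, tooth_id, el)
        diffs.extend(dc - no)
    return wilcoxon_signed_rank(diffs, method=method)


def element_enrichment(
    table: pd.DataFrame,
    tooth_id: str,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    elements=STAIN_ELEMENTS,
) -> dict[str, ElementFlag]:
    """Per-element contamination flags.

    An element is flagged when its DC/NO fold change reaches the threshold
    AND every DC repeat exceeds every NO repeat (non-overlapping repeats).
    With mean_NO == 0 the fold change is infinite and the flag reduces to
    all DC repeats being positive.
    """
    validate_xrf_table(table)
    flags: dict[str, ElementFlag] = {}
    for el in elements:
        dc, no = _paired_values(table, tooth_id, el)
        mean_no = float(no.mean())
        if mean_no > 0:
            fold = float(dc.mean() / mean_no)
        else:
            fold = float("inf")
        flagged = fold >= fold_threshold and float(dc.min()) > float(no.max())
        flags[el] = ElementFlag(
            element=el,
            fold_change=fold,
            flagged=bool(flagged),
            dc_values=tuple(float(v) for v in dc),
            no_values=tuple(float(v) for v in no),
        )
    return flags


def summarize_xrf(
    table: pd.DataFrame,
    tooth_id: str,
    method: str = "normal_approx",
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> XRFSummary:
    """Per-condition means/SDs, the paired test and the enrichment flags
    for one tooth."""
    validate_xrf_table(table)
    sub = table[table["tooth"] == tooth_id]
    if sub.empty:
        raise ValueError(f"no XRF rows for tooth {tooth_id}")
    stats = (
        sub.groupby(["element", "condition"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    test = xrf_paired_test(table, tooth_id, method=method)
    flags = element_enrichment(table, tooth_id, fold_threshold=fold_threshold)
    return XRFSummary(
        tooth_id=tooth_id,
        stats=stats,
        p_value=test.p_two_sided,
        test=test,
        flags=flags,
    )


def write_xrf_summary_csv(summary: XRFSummary, path: str | Path) -> Path:
    """Wide layout mirroring the element-columns x DC/NO table: one mean row
    and one SD row, plus the rounded p-value and significance star."""
    cols: dict[str, list] = {"tooth": [summary.tooth_id, summary.tooth_id], "stat": ["mean", "sd"]}
    st = summary.stats.set_index(["element", "condition"])
    for el in STAIN_ELEMENTS:
        for cond in ("DC", "NO"):
            key = f"{el}_{cond}"
            if (el, cond) in st.index:
                cols[key] = [st.loc[(el, cond), "mean"], st.loc[(el, cond), "sd"]]
            else:
                cols[key] = [np.nan, np.nan]
    p = round(summary.p_value, 3)
    cols["p_value"] = [p, ""]
    cols["significant"] = ["*" if summary.significant else "", ""]
    path = Path(path)
    pd.DataFrame(cols).to_csv(path, index=False)
    return path
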