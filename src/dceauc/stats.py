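"""Cohort statistics: group comparisons, collagen correlations, box-plot summaries.

Conventions follow the source study design: values are reported as
mean ± SEM; group differences use the unpaired two-tailed Student's t-test
with pooled (equal) variance, degrees of freedom n_a + n_b − 2 (Welch is
available behind a flag); associations between imaging biomarkers and
tissue collagen (hydroxyproline) use Pearson correlation with a
least-squares line; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from dceauc.io import AssayTable

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "compare_groups",
    "correlate",
    "boxplot_stats",
    "cohort_report",
]

BIOMARKERS = ["auc_5_55", "auc_0_55", "enh5", "enh_last", "perf_vf"]


@dataclass(frozen=True)
class GroupComparison:
    name_a: str
    name_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    biomarker: str
    assay: str
    n: int
    r: float
    slope: float
    intercept: float


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    name_a: str = "a",
    name_b: str = "b",
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups (pooled variance by default).

    Degenerate case: if both groups have zero variance and equal means the
    test is uninformative and (t, p) = (0, 1) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("group values must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        name_a=name_a,
        name_b=name_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=_sem(a),
        sem_b=_sem(b),
        t=float(t),
        p=float(p),
    )


def correlate(
    biomarker: Sequence[float],
    assay: Sequence[float],
    biomarker_name: str = "biomarker",
    assay_name: str = "assay",
) -> CorrelationResult:
    """Pearson correlation and least-squares line between paired measurements."""
    x = np.asarray(assay, dtype=float)
    y = np.asarray(biomarker, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("biomarker and assay must be paired 1D sequences")
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("correlation inputs must be finite")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance in correlation input")
    r = float(sps.pearsonr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(
        biomarker=biomarker_name,
        assay=assay_name,
        n=len(x),
        r=r,
        slope=float(slope),
        intercept=float(intercept),
    )


def boxplot_stats(values: Sequence[float]) -> dict[str, float]:
    """Whiskers at the 0/100 percentiles, box at 25/75, median bar."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return {"min": q[0], "q25": q[1], "median": q[2], "q75": q[3], "max": q[4]}


def cohort_report(
    summaries: pd.DataFrame,
    assays: AssayTable,
    correlation_arm: str = "targeted",
) -> dict[str, pd.DataFrame | list[str]]:
    """Join per-specimen imaging summaries to assay values and tabulate the cohort.

    ``summaries`` needs columns specimen_id, tissue, probe plus the imaging
    biomarkers.  Emits group comparisons (AUC_5–55 by probe arm and tissue,
    simulated/measured Gd by arm, hydroxyproline by tissue), Pearson
    correlations of each biomarker against hydroxyproline within the
    targeted arm, and box-plot summaries.  Specimens that fail the join are
    listed, never dropped silently.
    """
    req = {"specimen_id", "tissue", "probe", *BIOMARKERS}
    missing = req - set(summaries.columns)
    if missing:
        raise ValueError(f"summary table missing columns {sorted(missing)}")
    joined = summaries.merge(assays.table, on="specimen_id", how="left", validate="m:1")
    unmatched = sorted(joined.loc[joined["hydroxyproline_ug_g"].isna(), "specimen_id"].unique())
    joined = joined.sort_values(["specimen_id", "tissue"]).reset_index(drop=True)

    def _grp(tissue: str, probe: str, col: str) -> np.ndarray:
        sel = (joined["tissue"] == tissue) & (joined["probe"] == probe)
        return joined.loc[sel, col].dropna().to_numpy()

    comparisons = []
    pairs = [
        ("auc_5_55", ("tumour", "targeted"), ("tumour", "control")),
        ("auc_5_55", ("tumour", "targeted"), ("pancreas", "targeted")),
        ("gadolinium_nmol_g", ("tumour", "targeted"), ("tumour", "control")),
        ("gadolinium_nmol_g", ("tumour", "targeted"), ("pancreas", "targeted")),
        ("hydroxyproline_ug_g", ("tumour", "targeted"), ("pancreas", "targeted")),
    ]
    for col, (tis_a, prb_a), (tis_b, prb_b) in pairs:
        a, b = _grp(tis_a, prb_a, col), _grp(tis_b, prb_b, col)
        if len(a) >= 2 and len(b) >= 2:
            cmp_ = compare_groups(a, b, f"{tis_a}/{prb_a}", f"{tis_b}/{prb_b}")
            comparisons.append({"quantity": col, **asdict(cmp_)})

    arm = joined[joined["probe"] == correlation_arm].dropna(subset=["hydroxyproline_ug_g"])
    correlations = []
    if len(arm) >= 3:
        for bm in BIOMARKERS:
            sub = arm.dropna(subset=[bm])
            if len(sub) >= 3 and sub[bm].var() > 0 and sub["hydroxyproline_ug_g"].var() > 0:
                res = correlate(
                    sub[bm], sub["hydroxyproline_ug_g"], bm, "hydroxyproline_ug_g"
                )
                correlations.append(asdict(res))

    boxes = []
    for (tissue, probe), grp in joined.groupby(["tissue", "probe"]):
        for bm in BIOMARKERS:
            vals = grp[bm].dropna()
            if len(vals):
                boxes.append(
                    {"tissue": tissue, "probe": probe, "biomarker": bm,
                     "n": len(vals), **boxplot_stats(vals)}
                )

    return {
        "joined": joined,
        "comparisons": pd.DataFrame(comparisons),
        "correlations": pd.DataFrame(correlations),
        "boxplots": pd.DataFrame(boxes),
        "unmatched": unmatched,
    }
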