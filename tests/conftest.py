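import numpy as np
import pandas as pd
import pytest

from dceauc.io import DynamicSeries, RoiSet
from dceauc.pipeline import analyze_cohort, assays_from_truth, simulate_cohort
from dceauc.stats import cohort_report

CANONICAL_TIMES = np.array([0.0, 5.0, 20.0, 35.0, 45.0, 55.0])


def make_series(rng, shape=(6, 6, 3), times=CANONICAL_TIMES, specimen_id="test"):
    """A random positive dynamic series on the canonical schedule."""
    data = rng.uniform(1.0, 10.0, (*shape, len(times)))
    return DynamicSeries(data=data, sample_times=times, specimen_id=specimen_id)


def make_rois(shape=(6, 6, 3)):
    """Tumour ROI in the top half, muscle in the bottom slab."""
    labels = np.zeros(shape, dtype=np.int16)
    labels[:, shape[1] // 2 :, :] = 1
    labels[:, : shape[1] // 4, :] = 2
    return RoiSet(labels=labels, names={"tumour": 1, "muscle": 2})


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_series(rng):
    return make_series(rng)


@pytest.fixture
def small_rois():
    return make_rois()


@pytest.fixture(scope="session")
def default_cohort():
    """The default three-arm synthetic cohort, analysed end to end once.

    Arm sizes mirror the study design (8 targeted tumours, 7 control
    tumours, 3 targeted healthy-pancreas shams).
    """
    studies = simulate_cohort(seed=1)
    summaries, threshold, curves = analyze_cohort(studies)
    assays = assays_from_truth(studies)
    report = cohort_report(summaries, assays)
    return {
        "studies": studies,
        "summaries": summaries,
        "threshold": threshold,
        "curves": curves,
        "assays": assays,
        "report": report,
    }


def arm_mean(summaries: pd.DataFrame, tissue: str, probe: str, col: str) -> float:
    sel = (summaries["tissue"] == tissue) & (summaries["probe"] == probe)
    return float(summaries.loc[sel, col].mean())
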