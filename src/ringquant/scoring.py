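"""Cell classification and core/patient scoring.

Implements the scoring chain of the perinuclear-staining assay: a per-cell
positivity call (mean DAB OD inside the perinuclear ring, thresholded and
optionally compared against the cytoplasm mean to reject diffuse staining),
a random-forest tumor/stroma classifier over morphology + stain features,
per-core percent-positive scores with a minimum-tumor-cell QC gate,
replicate averaging to patient level, and median dichotomization with
optional cut-point transfer between cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cells import FEATURE_COLUMNS

__all__ = [
    "CoreScore",
    "PatientScore",
    "classify_pn_positive",
    "TumorStromaClassifier",
    "train_tumor_stroma_classifier",
    "score_core",
    "aggregate_patient",
    "dichotomize",
    "plot_ring_od_histogram",
]

logger = logging.getLogger(__name__)


@dataclass
class CoreScore:
    """Percent perinuclear-positive tumor cells for one TMA core.

    ``percent_positive`` is 100 * positives / tumor cells, NaN when the core
    has no tumor cells. ``qc_pass`` is True iff the core has at least the
    minimum tumor-cell count (cores below it are excluded from analysis).
    """

    core_id: str
    patient_id: str
    n_tumor_cells: int
    n_pn_positive: int
    percent_positive: float
    qc_pass: bool


@dataclass
class PatientScore:
    """Patient-level percent positive: mean over QC-passing replicate cores."""

    patient_id: str
    percent_positive: float
    n_cores: int
    group: str | None = None


def classify_pn_positive(
    cells: pd.DataFrame,
    ring_od_threshold: float = 0.3,
    ring_to_cytoplasm_ratio: float = 1.0,
) -> pd.Series:
    """Call each cell perinuclear-positive or negative.

    A cell is positive iff its ring mean DAB OD reaches ``ring_od_threshold``
    AND is at least ``ring_to_cytoplasm_ratio`` times its cytoplasm mean DAB
    OD. The ratio term separates intense perinuclear staining from diffuse
    cytoplasmic staining (which carries no perinuclear enrichment); set it
    to 0 to recover a pure intensity threshold. Cells with an empty ring are
    negative.
    """
    if ring_od_threshold <= 0:
        raise ValueError("ring_od_threshold must be > 0")
    if ring_to_cytoplasm_ratio < 0:
        raise ValueError("ring_to_cytoplasm_ratio must be >= 0")
    ring = cells["dab_od_ring"].to_numpy(dtype=float)
    cyto = cells["dab_od_cytoplasm"].to_numpy(dtype=float)
    positive = (ring >= ring_od_threshold) & (ring >= ring_to_cytoplasm_ratio * cyto)
    if "empty_ring" in cells:
        positive &= ~cells["empty_ring"].to_numpy(dtype=bool)
    return pd.Series(positive, index=cells.index, name="pn_positive")


class TumorStromaClassifier:
    """Random forest over cell morphology + stain features.

    Thin wrapper fixing the feature column order and exposing an
    out-of-bag accuracy estimate; deterministic for a fixed seed.
    """

    def __init__(self, model: RandomForestClassifier, features: list[str]):
        self._model = model
        self.features = features

    @property
    def oob_accuracy(self) -> float:
        return float(self._model.oob_score_)

    def predict(self, cells: pd.DataFrame) -> pd.Series:
        pred = self._model.predict(cells[self.features].to_numpy(dtype=float))
        return pd.Series(pred, index=cells.index, name="compartment_class")


def train_tumor_stroma_classifier(
    training: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_trees: int = 100,
    seed: int = 0,
    features: list[str] | None = None,
) -> TumorStromaClassifier:
    """Train the tumor/stroma random forest from annotated cells.

    ``labels`` holds ``"tumor"`` / ``"stroma"`` per training row. Training
    with fewer than 10 annotations in a class emits a warning (the working
    minimum for acceptable classifiers); a single-class set is an error.
    """
    features = FEATURE_COLUMNS if features is None else features
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"training set contains a single class: {classes.tolist()}")
    for cls, cnt in zip(classes, counts):
        if cnt < 10:
            warnings.warn(
                f"only {cnt} annotations for class {cls!r}; at least 10 per class "
                "is recommended before accepting a classifier",
                stacklevel=2,
            )
    model = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        oob_score=True,
        bootstrap=True,
    )
    with warnings.catch_warnings():
        # tiny training sets can leave some rows never out-of-bag
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB scores")
        model.fit(training[features].to_numpy(dtype=float), y)
    return TumorStromaClassifier(model, features)


def score_core(
    cells: pd.DataFrame,
    core_id: str,
    patient_id: str = "",
    min_tumor_cells: int = 100,
) -> CoreScore:
    """Score one core: percent positive among tumor cells only.

    Stromal cells enter neither numerator nor denominator. QC passes iff
    the core holds at least ``min_tumor_cells`` tumor cells (the boundary is
    inclusive: exactly 100 cells passes under the default). A core with no
    tumor cells gets percent NaN and fails QC.
    """
    tumor = cells[cells["compartment_class"] == "tumor"]
    n_tumor = len(tumor)
    n_pos = int(tumor["pn_positive"].sum())
    percent = 100.0 * n_pos / n_tumor if n_tumor > 0 else float("nan")
    return CoreScore(
        core_id=str(core_id),
        patient_id=str(patient_id),
        n_tumor_cells=n_tumor,
        n_pn_positive=n_pos,
        percent_positive=percent,
        qc_pass=n_tumor >= min_tumor_cells,
    )


def aggregate_patient(core_scores: list[CoreScore]) -> PatientScore | None:
    """Average percent positive over QC-passing replicate cores.

    Cores failing QC are dropped before averaging. Returns None (with a
    logged reason) when no core passes, i.e. the patient is excluded.
    """
    if not core_scores:
        raise ValueError("no core scores supplied")
    patient_id = core_scores[0].patient_id
    passing = [c for c in core_scores if c.qc_pass]
    if not passing:
        logger.info(
            "patient %s excluded: none of %d cores passed QC",
            patient_id,
            len(core_scores),
        )
        return None
    mean = float(np.mean([c.percent_positive for c in passing]))
    return PatientScore(patient_id=patient_id, percent_positive=mean, n_cores=len(passing))


def dichotomize(
    values,
    cutpoint: float | None = None,
) -> tuple[np.ndarray, float]:
    """Split values into ``high`` (> cut-point) and ``low`` (<= cut-point).

    The cut-point defaults to the within-cohort median — the unbiased
    choice — with values exactly at the median assigned low (strict ">").
    Passing ``cutpoint`` transfers an external cut-point (e.g. a discovery
    cohort's median) onto a second cohort. Returns (labels, cutpoint used).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    if not np.isfinite(arr).all():
        raise ValueError("values must be finite")
    if cutpoint is None:
        cutpoint = float(np.median(arr))
    if np.all(arr == arr[0]):
        warnings.warn("all values identical; every sample labelled low", stacklevel=2)
    labels = np.where(arr > cutpoint, "high", "low")
    return labels, float(cutpoint)


def plot_ring_od_histogram(cells: pd.DataFrame, bins: int = 50, ax=None):
    """Histogram of ring mean DAB ODs, to support manual threshold setting."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(cells["dab_od_ring"].to_numpy(dtype=float), bins=bins)
    ax.set_xlabel("ring mean DAB OD")
    ax.set_ylabel("cells")
    return ax
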