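"""End-to-end core analysis: RGB image -> classified, scored cells.

Chains stain separation, nucleus detection, compartment expansion,
measurement and per-cell classification. Also provides the detected-cell /
ground-truth matcher used when evaluating the pipeline against synthetic
cores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cells import detect_nuclei, expand_compartments, measure_cells
from .scoring import TumorStromaClassifier, classify_pn_positive
from .stains import ODImage, RGBImage, StainBasis, rgb_to_od, separate_stains

__all__ = ["analyze_core_image", "match_to_truth"]


def analyze_core_image(
    image: RGBImage,
    *,
    basis: StainBasis | None = None,
    background_intensity: int = 255,
    ring_width_um: float = 1.0,
    cytoplasm_um: float = 5.0,
    ring_od_threshold: float = 0.3,
    ring_to_cytoplasm_ratio: float = 1.0,
    classifier: TumorStromaClassifier | None = None,
    detection_params: dict | None = None,
) -> pd.DataFrame:
    """Run the full per-cell pipeline on one core image.

    Returns the measured cell table with ``compartment_class`` (from the
    random-forest classifier, or ``"tumor"`` for every cell when none is
    given) and the boolean ``pn_positive`` call appended.
    """
    od = rgb_to_od(image, background_intensity=background_intensity)
    stains = separate_stains(od, basis)
    hema = ODImage(
        stains.channel("hematoxylin"), ("hematoxylin",), pixel_size_um=stains.pixel_size_um
    )
    nuclei = detect_nuclei(hema, **(detection_params or {}))
    compartments = expand_compartments(
        nuclei, ring_width_um=ring_width_um, cytoplasm_um=cytoplasm_um
    )
    cells = measure_cells(compartments, stains)
    if len(cells) == 0:
        cells["compartment_class"] = pd.Series(dtype=object)
        cells["pn_positive"] = pd.Series(dtype=bool)
        return cells
    if classifier is not None:
        cells["compartment_class"] = classifier.predict(cells)
    else:
        cells["compartment_class"] = "tumor"
    cells["pn_positive"] = classify_pn_positive(
        cells,
        ring_od_threshold=ring_od_threshold,
        ring_to_cytoplasm_ratio=ring_to_cytoplasm_ratio,
    )
    return cells


def match_to_truth(
    cells: pd.DataFrame,
    truth: pd.DataFrame,
    max_distance_px: float = 8.0,
) -> pd.DataFrame:
    """Match detected cells to planted ground-truth cells by centroid.

    One-to-one assignment minimizing total centroid distance (Hungarian
    algorithm), discarding pairs farther apart than ``max_distance_px``.
    Returns the matched subset of ``cells`` with the truth columns
    (suffixed ``_true``) joined on.
    """
    if len(cells) == 0 or len(truth) == 0:
        return pd.DataFrame()
    det = cells[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    tru = truth[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    dist = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    cost = np.where(dist <= max_distance_px, dist, 1e6)
    ri, ci = linear_sum_assignment(cost)
    keep = dist[ri, ci] <= max_distance_px
    ri, ci = ri[keep], ci[keep]
    matched = cells.iloc[ri].reset_index(drop=True)
    truth_cols = truth.drop(columns=["centroid_row", "centroid_col"]).iloc[ci]
    truth_cols = truth_cols.add_suffix("_true").reset_index(drop=True)
    return pd.concat([matched, truth_cols], axis=1)
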