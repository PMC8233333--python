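"""Reading and writing the pipeline's file formats.

Images are TIFF or PNG RGB (tifffile / Pillow); tabular interchange is
tab-separated text throughout. Per-cell tables use one row per cell with
the documented column order; expression matrices are features x samples
with a header row of sample ids.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .scoring import CoreScore, PatientScore
from .stains import RGBImage

__all__ = [
    "read_image",
    "write_image",
    "write_cells_tsv",
    "read_cells_tsv",
    "read_expression_tsv",
    "read_clinical_tsv",
    "write_core_scores_tsv",
    "write_patient_scores_tsv",
    "write_label_png",
]

#: documented column order of the per-cell TSV
CELL_COLUMNS = [
    "cell",
    "centroid_row",
    "centroid_col",
    "nucleus_area_um2",
    "hema_od_nucleus",
    "dab_od_nucleus",
    "dab_od_ring",
    "dab_od_cytoplasm",
    "eccentricity",
    "solidity",
    "nucleus_cell_ratio",
    "empty_ring",
]


def read_image(path: str | Path, pixel_size_um: float | None = None) -> RGBImage:
    """Read a TIFF or PNG RGB image.

    ``pixel_size_um`` overrides any resolution metadata; TIFF X-resolution
    tags (in pixels/cm or pixels/inch) are used when present and no
    override is given. PNG carries no physical scale, so the argument is
    required there.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            if pixel_size_um is None:
                pixel_size_um = _tiff_pixel_size(page)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if pixel_size_um is None:
        raise ValueError("pixel size unavailable; pass pixel_size_um explicitly")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RGBImage(arr, pixel_size_um=pixel_size_um)


def _tiff_pixel_size(page) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    ppu = xres[0] / xres[1]
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
    if unit_um is None or ppu <= 0:
        return None
    return unit_um / ppu


def write_image(path: str | Path, image: RGBImage) -> None:
    """Write an RGB image as TIFF (with resolution tags) or PNG."""
    path = Path(path)
    px = image.pixels.astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        ppcm = 10000.0 / image.pixel_size_um
        tifffile.imwrite(path, px, resolution=(ppcm, ppcm), resolutionunit="CENTIMETER")
    else:
        Image.fromarray(px).save(path)


def write_cells_tsv(path: str | Path, cells: pd.DataFrame) -> None:
    cols = [c for c in CELL_COLUMNS if c in cells.columns]
    extra = [c for c in cells.columns if c not in cols]
    cells[cols + extra].to_csv(path, sep="\t", index=False)


def read_cells_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (first column = feature ids).

    GCT-like files (``#1.2`` header plus a dimension line) are detected and
    their two leading header lines skipped, with any Description column
    dropped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        if "Description" in df.columns:
            df = df.drop(columns="Description")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clinical table (patient_id, time, event, covariates...)."""
    df = pd.read_csv(path, sep="\t")
    if "event" in df:
        df["event"] = df["event"].astype(bool)
    return df


def write_core_scores_tsv(path: str | Path, scores: list[CoreScore]) -> None:
    pd.DataFrame([vars(s) for s in scores]).to_csv(path, sep="\t", index=False)


def write_patient_scores_tsv(path: str | Path, scores: list[PatientScore]) -> None:
    pd.DataFrame([vars(s) for s in scores]).to_csv(path, sep="\t", index=False)


def write_label_png(path: str | Path, labels: np.ndarray) -> None:
    """Export a label map as an 8-bit PNG for visual QC (labels mod 255)."""
    vis = (labels.astype(np.int64) % 255).astype(np.uint8)
    vis[labels == 0] = 0
    Image.fromarray(vis).save(path)
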