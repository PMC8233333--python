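"""Optical-density transform and H-DAB stain unmixing for brightfield IHC.

Brightfield chromogens obey Beer-Lambert absorption: stain amounts are
additive in optical density (OD = -log10(I / I0)) but not in raw intensity.
An RGB pixel is therefore converted to a 3-vector of per-channel ODs and
decomposed onto known stain vectors (hematoxylin, DAB and an orthogonal
residual) by least squares, giving per-pixel stain concentrations.

The default basis uses the widely published H-DAB unmixing vectors; both the
basis and the background intensity are configurable because scanner white
points and stain lots vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGBImage",
    "ODImage",
    "StainBasis",
    "default_hdab_basis",
    "rgb_to_od",
    "od_to_rgb",
    "separate_stains",
    "compose_stains",
]


class SingularBasisError(ValueError):
    """Raised when stain vectors are collinear and cannot be unmixed."""


@dataclass
class RGBImage:
    """An H x W x 3 brightfield image with a known physical pixel size.

    ``pixels`` holds integer intensities in [0, 255]; ``pixel_size_um`` is
    the edge length of one pixel in micrometers (0.25 um/px is typical of a
    x40 scan).
    """

    pixels: np.ndarray
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected an H x W x 3 image, got shape {self.pixels.shape}"
            )
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class ODImage:
    """Per-pixel optical density, H x W x C, with named channels.

    Channels are either raw RGB ODs (``("r", "g", "b")``) or unmixed stain
    concentrations (``("hematoxylin", "dab", "residual")``). ODs are
    clamped nonnegative.
    """

    od: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim == 2:
            self.od = self.od[:, :, None]
        if self.od.shape[2] != len(self.channel_names):
            raise ValueError("channel_names must match the last axis")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as an H x W array."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}")
        return self.od[:, :, idx]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain vector cannot be zero")
    return v / n


@dataclass
class StainBasis:
    """Unit stain vectors in RGB-OD space.

    ``residual`` defaults to the normalized cross product of the two stain
    vectors, capturing any OD component outside their span.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    residual: np.ndarray | None = None
    _matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        cross = np.cross(h, d)
        if np.linalg.norm(cross) < 1e-6:
            raise SingularBasisError("hematoxylin and DAB vectors are collinear")
        r = _unit(cross) if self.residual is None else _unit(self.residual)
        self.hematoxylin, self.dab, self.residual = h, d, r
        m = np.column_stack([h, d, r])
        if abs(np.linalg.det(m)) < 1e-6:
            raise SingularBasisError("stain basis is singular")
        self._matrix = m

    @property
    def matrix(self) -> np.ndarray:
        """3 x 3 matrix whose columns are the stain vectors."""
        return self._matrix

    @property
    def stain_names(self) -> tuple[str, str, str]:
        return ("hematoxylin", "dab", "residual")


def default_hdab_basis() -> StainBasis:
    """The canonical H-DAB unmixing vectors (Ruifrok-Johnston constants)."""
    return StainBasis(hematoxylin=(0.65, 0.70, 0.29), dab=(0.27, 0.57, 0.78))


def rgb_to_od(image: RGBImage, background_intensity: int = 255) -> ODImage:
    """Convert an RGB image to per-channel optical density.

    ``od_c = -log10(max(i_c, 1) / I0)``: intensities are floored at 1 to
    avoid infinite OD, and any pixel brighter than the background clamps to
    OD 0. The background itself maps to 0 in every channel.
    """
    if not 1 <= background_intensity <= 255:
        raise ValueError("background_intensity must lie in [1, 255]")
    px = np.maximum(image.pixels.astype(float), 1.0)
    od = -np.log10(px / float(background_intensity))
    od = np.clip(od, 0.0, None)
    return ODImage(od, ("r", "g", "b"), pixel_size_um=image.pixel_size_um)


def od_to_rgb(od: ODImage, background_intensity: int = 255) -> RGBImage:
    """Invert :func:`rgb_to_od`, quantizing to 8-bit intensities."""
    if od.od.shape[2] != 3:
        raise ValueError("od_to_rgb needs a 3-channel OD image")
    intensity = background_intensity * np.power(10.0, -od.od)
    px = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return RGBImage(px, pixel_size_um=od.pixel_size_um)


def separate_stains(od: ODImage, basis: StainBasis | None = None) -> ODImage:
    """Unmix a 3-channel OD image into per-stain concentrations.

    Solves ``basis.matrix @ c = od`` per pixel and clamps negative
    concentrations to zero (physical nonnegativity).
    """
    if basis is None:
        basis = default_hdab_basis()
    if od.od.shape[2] != 3:
        raise ValueError("separate_stains needs a 3-channel OD image")
    flat = od.od.reshape(-1, 3)
    conc = np.linalg.solve(basis.matrix, flat.T).T
    conc = np.clip(conc, 0.0, None)
    return ODImage(
        conc.reshape(od.od.shape),
        basis.stain_names,
        pixel_size_um=od.pixel_size_um,
    )


def compose_stains(
    concentrations: np.ndarray,
    basis: StainBasis | None = None,
    pixel_size_um: float = 0.25,
) -> ODImage:
    """Compose per-stain concentrations (H x W x 3) into an RGB-OD image."""
    if basis is None:
        basis = default_hdab_basis()
    conc = np.asarray(concentrations, dtype=float)
    if conc.ndim == 3 and conc.shape[2] == 2:
        conc = np.concatenate([conc, np.zeros_like(conc[:, :, :1])], axis=2)
    if conc.ndim != 3 or conc.shape[2] != 3:
        raise ValueError("concentrations must be H x W x 2 or H x W x 3")
    od = conc.reshape(-1, 3) @ basis.matrix.T
    od = np.clip(od, 0.0, None)
    return ODImage(od.reshape(conc.shape), ("r", "g", "b"), pixel_size_um=pixel_size_um)
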