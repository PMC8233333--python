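"""Ground-truthed synthetic IHC cores and expression + survival cohorts.

Two generators make the full pipeline testable without patient data:

* :func:`generate_ihc_core` renders an H-DAB brightfield core: elliptical
  hematoxylin nuclei (round for tumor cells, elongated for stromal cells)
  placed by rejection sampling, with DAB painted either as an intense
  ~1 um perinuclear annulus (activated pattern), as diffuse cytoplasmic
  staining that builds up away from the nuclear envelope, or not at all.
  The image is composed through the same Beer-Lambert stain model the
  pipeline unmixes with and quantized to 8-bit RGB; an exact per-cell truth
  table accompanies it.

* :func:`generate_cohort` draws an expression matrix with a latent
  two-group structure (signature genes shifted upward in the poor-prognosis
  group) plus proportional-hazards exponential survival with independent
  uniform censoring calibrated to a target rate.

Both are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .stains import ODImage, RGBImage, StainBasis, compose_stains, default_hdab_basis, od_to_rgb

__all__ = [
    "SyntheticCoreSpec",
    "SyntheticCohortSpec",
    "generate_ihc_core",
    "generate_cohort",
]


@dataclass
class SyntheticCoreSpec:
    """Parameters of one synthetic TMA core.

    Fractions are of tumor cells: ``fraction_pn_positive`` get the
    perinuclear annulus, ``fraction_diffuse`` get diffuse cytoplasmic DAB,
    the remainder are unstained. OD levels are stain concentrations in the
    composition basis; ``noise_sd`` is additive Gaussian noise on the
    concentration maps before quantization.
    """

    n_tumor_cells: int = 200
    n_stromal_cells: int = 50
    fraction_pn_positive: float = 0.4
    fraction_diffuse: float = 0.3
    nucleus_radius_um: tuple[float, float] = (3.0, 4.5)
    ring_od: float = 0.8
    diffuse_od: float = 0.5
    hema_od: float = 0.7
    noise_sd: float = 0.02
    pixel_size_um: float = 0.5
    seed: int = 0
    touching_pairs: int = 0
    basis: StainBasis = field(default_factory=default_hdab_basis)

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_pn_positive <= 1 or not 0 <= self.fraction_diffuse <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_pn_positive + self.fraction_diffuse > 1 + 1e-12:
            raise ValueError("fractions must sum to <= 1")
        if min(self.ring_od, self.diffuse_od, self.hema_od) < 0 or self.noise_sd < 0:
            raise ValueError("OD levels and noise sd must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")


def _place_centers(
    rng: np.random.Generator,
    n: int,
    canvas: int,
    margin: float,
    min_spacing: float,
    max_attempts_per_cell: int = 400,
) -> np.ndarray:
    """Rejection-sample n centers with a minimum pairwise spacing."""
    centers = np.empty((n, 2))
    placed = 0
    attempts = 0
    budget = max_attempts_per_cell * max(n, 1)
    while placed < n:
        if attempts > budget:
            raise ValueError(
                f"cannot place {n} cells on a {canvas}x{canvas} canvas "
                f"with spacing {min_spacing:.1f} px"
            )
        attempts += 1
        cand = rng.uniform(margin, canvas - margin, size=2)
        d2 = np.sum((centers[:placed] - cand) ** 2, axis=1)
        if placed == 0 or d2.min() >= min_spacing**2:
            centers[placed] = cand
            placed += 1
    return centers


def _cell_window(canvas: int, center, reach_px: float):
    """Slices plus local pixel-coordinate grids around one cell."""
    r0 = max(int(np.floor(center[0] - reach_px)), 0)
    r1 = min(int(np.ceil(center[0] + reach_px)) + 1, canvas)
    c0 = max(int(np.floor(center[1] - reach_px)), 0)
    c1 = min(int(np.ceil(center[1] + reach_px)) + 1, canvas)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return (slice(r0, r1), slice(c0, c1)), rr, cc


def generate_ihc_core(spec: SyntheticCoreSpec) -> tuple[RGBImage, pd.DataFrame]:
    """Render a synthetic H-DAB core plus its exact cell truth table.

    Tumor nuclei are near-circular (eccentricity < 0.6), stromal nuclei
    elongated (eccentricity > 0.85). Perinuclear-positive cells receive a
    DAB annulus of ~1 um just outside the nucleus at ``ring_od`` over a
    faint cytoplasmic background; diffuse cells receive cytoplasmic DAB
    ramping from zero at the nuclear boundary to ``diffuse_od`` at 2 um out
    (diffuse staining carries no perinuclear accumulation). The truth table
    columns are cell, centroid_row, centroid_col, cell_class
    (tumor/stroma), pattern (perinuclear/diffuse/negative), pn_positive.
    """
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size_um
    r_max_px = spec.nucleus_radius_um[1] / ps
    spacing = 2 * r_max_px + 5.0 / ps + 4  # nuclei + cytoplasm halos stay disjoint
    n_total = spec.n_tumor_cells + spec.n_stromal_cells
    canvas = int(np.ceil(np.sqrt(max(n_total, 1)) * spacing * 1.45)) + int(2 * spacing)
    margin = spacing / 2 + 2

    centers = _place_centers(rng, n_total, canvas, margin, spacing)
    shape = (canvas, canvas)

    hema = np.zeros(shape)
    dab = np.zeros(shape)

    n_pos = int(round(spec.fraction_pn_positive * spec.n_tumor_cells))
    n_diff = int(round(spec.fraction_diffuse * spec.n_tumor_cells))
    patterns = ["perinuclear"] * n_pos + ["diffuse"] * n_diff
    patterns += ["negative"] * (spec.n_tumor_cells - len(patterns))
    rng.shuffle(patterns)

    rows = []
    reach_um = 6.0  # cytoplasm halo extent
    for k in range(n_total):
        center = centers[k]
        is_tumor = k < spec.n_tumor_cells
        radius_um = rng.uniform(*spec.nucleus_radius_um)
        angle = rng.uniform(0, np.pi)
        if is_tumor:
            ratio = rng.uniform(0.85, 1.0)  # eccentricity <= 0.53
            pattern = patterns[k]
        else:
            ratio = rng.uniform(0.30, 0.45)  # eccentricity >= 0.89
            pattern = "negative"
        a_px = radius_um / np.sqrt(ratio) / ps  # preserve area pi*r^2
        b_px = a_px * ratio
        reach_px = a_px + reach_um / ps + 2
        win, rr, cc = _cell_window(canvas, center, reach_px)

        dr = rr - center[0]
        dc = cc - center[1]
        ca, sa = np.cos(angle), np.sin(angle)
        u = dr * ca + dc * sa
        v = -dr * sa + dc * ca
        # elliptical radial scale: 1.0 on the nucleus boundary
        scale = np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)
        nucleus = scale <= 1.0
        hview = hema[win]
        dview = dab[win]
        hview[nucleus] = spec.hema_od

        # approximate outward distance (um) from the boundary, minor-axis scaled
        dist_out_um = (scale - 1.0) * b_px * ps

        if pattern == "perinuclear":
            annulus = (~nucleus) & (dist_out_um <= 1.0)
            halo = (dist_out_um > 1.0) & (dist_out_um <= 4.0)
            np.maximum(dview, np.where(annulus, spec.ring_od, 0.0), out=dview)
            np.maximum(dview, np.where(halo, 0.15 * spec.ring_od, 0.0), out=dview)
        elif pattern == "diffuse":
            shell = (~nucleus) & (dist_out_um <= 5.0)
            ramp = np.clip(dist_out_um / 2.0, 0.0, 1.0)
            np.maximum(dview, np.where(shell, spec.diffuse_od * ramp, 0.0), out=dview)

        rows.append(
            {
                "cell": k + 1,
                "centroid_row": center[0],
                "centroid_col": center[1],
                "cell_class": "tumor" if is_tumor else "stroma",
                "pattern": pattern,
                "pn_positive": pattern == "perinuclear",
            }
        )

    # optional touching pairs: plant a hematoxylin-only companion nucleus
    # overlapping the first few tumor cells to exercise the watershed split
    for j in range(min(spec.touching_pairs, spec.n_tumor_cells)):
        center = centers[j]
        radius_um = np.mean(spec.nucleus_radius_um)
        r_px = radius_um / ps
        offset = 1.4 * r_px
        companion = (center[0] + offset, center[1])
        win, rr, cc = _cell_window(canvas, companion, r_px + 2)
        mask = (rr - companion[0]) ** 2 + (cc - companion[1]) ** 2 <= r_px**2
        hview = hema[win]
        hview[mask] = spec.hema_od
        rows.append(
            {
                "cell": n_total + j + 1,
                "centroid_row": companion[0],
                "centroid_col": companion[1],
                "cell_class": "tumor",
                "pattern": "negative",
                "pn_positive": False,
            }
        )

    if spec.noise_sd > 0:
        hema = np.clip(hema + rng.normal(0, spec.noise_sd, shape), 0, None)
        dab = np.clip(dab + rng.normal(0, spec.noise_sd, shape), 0, None)

    conc = np.stack([hema, dab, np.zeros(shape)], axis=2)
    od = compose_stains(conc, spec.basis, pixel_size_um=ps)
    image = od_to_rgb(od)
    truth = pd.DataFrame(rows)
    return image, truth


@dataclass
class SyntheticCohortSpec:
    """Parameters of a synthetic expression + survival cohort.

    Half the patients form a latent poor-prognosis group whose
    ``signature_size`` signature genes are shifted upward by
    ``effect_size`` (in sd units); all other expression is standard normal.
    Survival is exponential under proportional hazards: the poor-prognosis
    (elevated-gene, low-score) group has ``baseline_hazard`` events/month
    and the other group ``hazard_ratio`` times that, so ``hazard_ratio`` is
    the high-score : low-score hazard ratio. Censoring is independent
    uniform, calibrated to ``censoring_rate``.
    """

    n_patients: int = 300
    n_genes: int = 200
    signature_size: int = 25
    effect_size: float = 1.0
    hazard_ratio: float = 0.4
    baseline_hazard: float = 0.02
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hazard_ratio > 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size cannot exceed n_genes")
        if not self.baseline_hazard > 0:
            raise ValueError("baseline_hazard must be positive")


def _uniform_censor_tau(rates: np.ndarray, target: float) -> float:
    """Solve for tau so P(U(0,tau) < Exp(rate)) averages to target."""

    def censored_fraction(tau: float) -> float:
        lt = rates * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > target and hi < 1e9:
        hi *= 2.0
    return brentq(lambda t: censored_fraction(t) - target, lo, hi)


def generate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw an expression matrix, a clinical table and the latent truth.

    Returns ``(expr, clinical, truth)``: ``expr`` is genes x samples
    (g0001.. x s0001..), ``clinical`` has patient_id, time (months), event,
    plus covariates age_category / t_stage / n_status drawn independently
    of outcome, and ``truth`` records the planted signature genes and each
    patient's latent group ("low" = elevated signature genes = low
    signature score = poor prognosis).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    genes = [f"g{i + 1:04d}" for i in range(spec.n_genes)]
    samples = [f"s{i + 1:04d}" for i in range(n)]
    signature = genes[: spec.signature_size]

    latent_low = np.zeros(n, dtype=bool)
    latent_low[: n // 2] = True
    rng.shuffle(latent_low)

    x = rng.normal(0.0, 1.0, size=(spec.n_genes, n))
    x[: spec.signature_size, latent_low] += spec.effect_size
    expr = pd.DataFrame(x, index=genes, columns=samples)

    rates = np.where(latent_low, spec.baseline_hazard, spec.baseline_hazard * spec.hazard_ratio)
    t_event = rng.exponential(1.0 / rates)
    if spec.censoring_rate > 0:
        tau = _uniform_censor_tau(rates, spec.censoring_rate)
        t_censor = rng.uniform(0.0, tau, size=n)
        time = np.minimum(t_event, t_censor)
        event = t_event <= t_censor
    else:
        time, event = t_event, np.ones(n, dtype=bool)
    time = np.maximum(time, 1e-6)

    clinical = pd.DataFrame(
        {
            "patient_id": samples,
            "time": time,
            "event": event,
            "age_category": rng.choice(["<40", "40-49", "50-59", ">60"], size=n),
            "t_stage": rng.choice([1, 2, 3, 4], size=n),
            "n_status": rng.choice(["negative", "positive"], size=n),
        }
    )
    truth = {
        "signature_genes": signature,
        "latent_group": pd.Series(
            np.where(latent_low, "low", "high"), index=samples, name="latent_group"
        ),
    }
    return expr, clinical, truth
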