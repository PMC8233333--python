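"""Gene-signature derivation and negative-sum scoring.

Given a gene-level expression matrix and a two-group labelling of samples
(e.g. the IHC-defined high/low perinuclear-staining groups), genes are
ranked by how strongly they are upregulated in the low group, the top k
(default 25) form the signature, and every sample is scored by the
*negative sum* of its signature-gene expression — so tumors with elevated
signature genes get low scores. Scores are dichotomized at the
within-dataset median; absolute scores are platform-dependent and are never
compared across datasets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .scoring import dichotomize

__all__ = [
    "summarize_to_genes",
    "rank_genes",
    "derive_signature",
    "score_signature",
]

logger = logging.getLogger(__name__)

_SUMMARIZE = {"mean": "mean", "median": "median", "max": "max"}


def _check_matrix(expr: pd.DataFrame) -> None:
    if expr.columns.duplicated().any():
        raise ValueError("duplicated sample ids in expression matrix")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")


def summarize_to_genes(
    expr: pd.DataFrame,
    probe_map: pd.Series | dict,
    policy: str = "mean",
) -> pd.DataFrame:
    """Collapse a probe-level matrix (probes x samples) to gene level.

    ``probe_map`` maps probe id -> gene symbol. Probes without a mapping
    are dropped (count logged); multiple probes per gene are combined by
    ``policy`` (mean, median or max).
    """
    if policy not in _SUMMARIZE:
        raise ValueError(f"unknown policy {policy!r}; choose from {sorted(_SUMMARIZE)}")
    mapping = pd.Series(probe_map)
    if mapping.empty:
        raise ValueError("probe map is empty")
    _check_matrix(expr)
    mapped = expr.index.intersection(mapping.index)
    dropped = len(expr.index) - len(mapped)
    if dropped:
        logger.info("dropping %d unmapped probes of %d", dropped, len(expr.index))
    if len(mapped) == 0:
        raise ValueError("probe map covers none of the matrix features")
    sub = expr.loc[mapped]
    genes = mapping.loc[mapped]
    return sub.groupby(genes.to_numpy()).agg(_SUMMARIZE[policy]).sort_index()


def _floored_sd(x: np.ndarray) -> np.ndarray:
    """Per-gene sd with the canonical signal-to-noise variance floors."""
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    return np.maximum(sd, np.maximum(0.2 * np.abs(mean), 0.2))


def rank_genes(
    expr: pd.DataFrame,
    groups: pd.Series,
    metric: str = "s2n",
) -> pd.DataFrame:
    """Rank genes by upregulation in the ``low`` group.

    ``groups`` maps sample id -> "low"/"high". The default metric is the
    signal-to-noise ratio (mean_low - mean_high) / (sd_low + sd_high) with
    per-group sd floors of max(0.2*|mean|, 0.2); ``metric="t"`` uses the
    two-sample Welch t statistic instead. Genes are returned in descending
    score order, ties broken by gene id, so the head of the ranking is the
    genes most elevated in low-group samples.
    """
    groups = pd.Series(groups)
    low_ids = groups.index[groups == "low"]
    high_ids = groups.index[groups == "high"]
    if len(low_ids) == 0 or len(high_ids) == 0:
        raise ValueError("both groups must be non-empty")
    if len(low_ids) < 2 or len(high_ids) < 2:
        raise ValueError("need >= 2 samples per group to estimate an sd")
    _check_matrix(expr)
    lo = expr[low_ids].to_numpy(dtype=float)
    hi = expr[high_ids].to_numpy(dtype=float)
    diff = lo.mean(axis=1) - hi.mean(axis=1)
    if metric == "s2n":
        score = diff / (_floored_sd(lo) + _floored_sd(hi))
    elif metric == "t":
        se = np.sqrt(
            lo.var(axis=1, ddof=1) / lo.shape[1] + hi.var(axis=1, ddof=1) / hi.shape[1]
        )
        score = np.divide(diff, se, out=np.zeros_like(diff), where=se > 0)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose 's2n' or 't'")
    ranked = pd.DataFrame({"gene": expr.index, "score": score})
    ranked = ranked.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    )
    return ranked.reset_index(drop=True)


def derive_signature(ranked: pd.DataFrame, k: int = 25) -> list[str]:
    """Take the top-k ranked genes as the signature, order preserved."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the {len(ranked)} ranked genes")
    return ranked["gene"].head(k).tolist()


def score_signature(
    expr: pd.DataFrame,
    signature: list[str],
    missing: str = "error",
    cutpoint: float | None = None,
) -> pd.DataFrame:
    """Score samples by the negative sum of signature-gene expression.

    ``score_s = -sum_g expr[g, s]`` over the signature genes, so higher
    signature-gene expression gives a strictly lower score. Samples are
    labelled high/low by median split of the scores within this dataset
    (or at an externally supplied ``cutpoint``). Missing signature genes
    raise by default; ``missing="drop"`` drops them with a warning.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    _check_matrix(expr)
    present = [g for g in signature if g in expr.index]
    absent = [g for g in signature if g not in expr.index]
    if absent:
        if missing == "drop":
            logger.warning("dropping %d signature genes absent from matrix", len(absent))
        else:
            raise KeyError(f"signature genes absent from matrix: {absent}")
    if not present:
        raise ValueError("no signature genes present in the matrix")
    scores = -expr.loc[present].sum(axis=0).astype(float)
    labels, cut = dichotomize(scores.to_numpy(), cutpoint=cutpoint)
    out = pd.DataFrame(
        {"sample": expr.columns, "score": scores.to_numpy(), "group": labels}
    )
    out.attrs["cutpoint"] = cut
    return out
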