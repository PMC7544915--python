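"""All-sample pairwise Pearson coexpression network.

Correlations are computed on log2(CPM + 1) values across every sample.
Nominal two-sided p-values come from the Fisher z-transform normal
approximation; edges are multiplicity-adjusted with Benjamini-Hochberg over
all tested pairs and the headline network keeps pairs with |r| > 0.98 and
FDR < 0.02 (both strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "standardize_rows",
    "correlation_matrix",
    "pairwise_correlation",
    "correlation_pvalue",
    "significant_edges",
    "network_edges",
    "efdr_network",
]

_TINY_P = np.finfo(float).tiny


def standardize_rows(values: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale each row to unit variance.

    Returns (Z, ok) where ``ok`` marks rows with nonzero variance; rows with
    zero variance are returned as all-zeros.
    """
    x = np.asarray(values, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    sd = np.sqrt((xc**2).sum(axis=1, keepdims=True) / (x.shape[1] - ddof))
    ok = sd[:, 0] > 0
    sd[~ok, 0] = 1.0
    return xc / sd, ok


def correlation_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of every row pair; rows with zero variance get
    NaN against everything. Returns (R, ok_mask)."""
    n = values.shape[1]
    z, ok = standardize_rows(values)
    r = (z @ z.T) / (n - 1)
    np.clip(r, -1.0, 1.0, out=r)
    r[~ok, :] = np.nan
    r[:, ~ok] = np.nan
    return r, ok


def pairwise_correlation(
    em: ExpressionMatrix, features: list[str] | None = None
) -> pd.DataFrame:
    """Pearson r for every unordered feature pair across all samples.

    Zero-variance features are excluded (logged). Returns an edge table with
    columns feature_a, feature_b (a < b lexicographically), r.
    """
    sub = em if features is None else em.subset_features(features)
    if len(sub.sample_ids) < 3:
        raise ValueError("need at least 3 samples for pairwise correlation")
    ids = np.array(sub.feature_ids)
    order = np.argsort(ids)
    ids = ids[order]
    vals = sub.values.to_numpy()[order]
    r, ok = correlation_matrix(vals)
    if not ok.all():
        logger.info("excluding %d zero-variance features", int((~ok).sum()))
        ids, r = ids[ok], r[np.ix_(ok, ok)]
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame({"feature_a": ids[iu], "feature_b": ids[ju], "r": r[iu, ju]})


def correlation_pvalue(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p for a Pearson correlation via the Fisher z normal
    approximation: z = atanh(r) * sqrt(n - 3), p = 2 * (1 - Phi(|z|)).

    |r| = 1 returns the smallest positive representable p.
    """
    if n < 4:
        raise ValueError("need n >= 4 for the normal approximation")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1):
        raise ValueError("|r| must be <= 1")
    with np.errstate(divide="ignore"):
        z = np.abs(np.arctanh(np.clip(r_arr, -1, 1))) * np.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(z)
    p = np.clip(p, _TINY_P, 1.0)
    return float(p) if np.isscalar(r) or p.ndim == 0 else p


def significant_edges(
    edges: pd.DataFrame,
    n_samples: int,
    r_threshold: float = 0.98,
    fdr_threshold: float = 0.02,
) -> pd.DataFrame:
    """Attach nominal p and Benjamini-Hochberg FDR (over all tested pairs),
    then keep edges with |r| > r_threshold and FDR < fdr_threshold (strict).

    Returns the retained edge table with columns r, p, fdr, sign.
    """
    edges = edges.copy()
    if edges.empty:
        return edges.assign(p=[], fdr=[], sign=[])
    edges["p"] = correlation_pvalue(edges["r"].to_numpy(), n_samples)
    edges["fdr"] = multipletests(edges["p"].to_numpy(), method="fdr_bh")[1]
    keep = (edges["r"].abs() > r_threshold) & (edges["fdr"] < fdr_threshold)
    out = edges.loc[keep].reset_index(drop=True)
    out["sign"] = np.where(out["r"] > 0, "+", "-")
    n_pos = int((out["sign"] == "+").sum())
    logger.info(
        "significant edges: %d retained (%d positive, %d negative)",
        len(out), n_pos, len(out) - n_pos,
    )
    return out


def network_edges(
    em: ExpressionMatrix,
    r_threshold: float = 0.98,
    fdr_threshold: float = 0.02,
) -> pd.DataFrame:
    """All-sample network in one step: correlate every pair, then keep the
    significant edges."""
    edges = pairwise_correlation(em)
    return significant_edges(edges, len(em.sample_ids), r_threshold, fdr_threshold)


def efdr_network(
    em: ExpressionMatrix,
    r_threshold: float = 0.98,
    n_randomizations: int = 1000,
    seed: int | None = None,
):
    """Empirical alternative to the analytic FDR for the all-sample network
    (off by default): each feature's values are permuted independently
    across samples, destroying every pairwise association while preserving
    marginals, and exceedances of the |r| threshold are counted."""
    from .rewiring import EFDRResult

    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    rng = np.random.default_rng(seed)
    vals = em.values.to_numpy()
    r, ok = correlation_matrix(vals)
    iu, ju = np.triu_indices(vals.shape[0], k=1)
    observed = int((np.abs(r[iu, ju]) > r_threshold).sum())
    scrambled = np.zeros(n_randomizations)
    for b in range(n_randomizations):
        shuffled = rng.permuted(vals, axis=1)
        rb, _ = correlation_matrix(shuffled)
        scrambled[b] = (np.abs(rb[iu, ju]) > r_threshold).sum()
    return EFDRResult.from_counts(observed, scrambled)
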