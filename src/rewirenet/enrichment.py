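"""Length-bias-aware gene-set over-representation testing.

Longer transcripts accumulate more reads, so length-correlated selection
(e.g. of differentially expressed genes) inflates naive hypergeometric
enrichment. A probability weighting function (PWF) — the per-gene chance of
being selected as a monotone non-decreasing function of transcript length —
is estimated by quantile-binned isotonic pooling, and the enrichment null
draws gene sets of the observed size *without replacement with probability
proportional to the PWF*. The Monte-Carlo upper-tail p is

    p_over = (1 + #{samplings with in-term count >= observed}) / (n + 1)

and terms are adjusted with Benjamini-Yekutieli (FDR valid under arbitrary
dependency); the conventional reporting threshold is FDR < 0.10.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "fit_pwf",
    "weighted_sample_counts",
    "sampling_enrichment_test",
    "fdr_by",
    "run_enrichment",
]


def fit_pwf(
    lengths: pd.Series,
    selected: pd.Series,
    n_bins: int = 20,
    eps: float = 1e-6,
) -> pd.Series:
    """Per-gene selection weight as a monotone function of length.

    Background genes are split into ``n_bins`` length-quantile bins, the
    selected fraction is computed per bin and pooled isotonically (weighted
    by bin size) so weights never decrease with length; every weight is
    floored at ``eps``. With all or no genes selected the weights are flat.
    """
    if len(lengths) < 20:
        raise ValueError("need at least 20 background genes to fit a PWF")
    sel = selected.loc[lengths.index].astype(bool)
    if sel.all() or not sel.any():
        logger.warning("degenerate selection (all or none); flat weights")
        return pd.Series(1.0, index=lengths.index, name="weight")
    n_bins = max(1, min(n_bins, len(lengths)))
    order = lengths.sort_values(kind="mergesort").index
    bins = np.array_split(np.arange(len(order)), n_bins)
    bin_len = np.array([lengths.loc[order[b]].mean() for b in bins])
    bin_frac = np.array([sel.loc[order[b]].mean() for b in bins])
    bin_n = np.array([len(b) for b in bins], dtype=float)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    pooled = iso.fit_transform(bin_len, bin_frac, sample_weight=bin_n)
    w = pd.Series(0.0, index=lengths.index, name="weight")
    for b, frac in zip(bins, pooled):
        w.loc[order[b]] = frac
    return w.clip(lower=eps)


def weighted_sample_counts(
    in_term: np.ndarray,
    weights: np.ndarray,
    k: int,
    n_samplings: int,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """In-term counts of ``n_samplings`` draws of ``k`` background genes
    without replacement with probability proportional to ``weights``
    (Gumbel-top-k sampling)."""
    if k == 0:
        return np.zeros(n_samplings, dtype=np.int64)
    logw = np.log(weights)
    counts = np.empty(n_samplings, dtype=np.int64)
    done = 0
    while done < n_samplings:
        m = min(chunk, n_samplings - done)
        keys = logw[None, :] + rng.gumbel(size=(m, len(weights)))
        top = np.argpartition(-keys, k - 1, axis=1)[:, :k]
        counts[done : done + m] = in_term[top].sum(axis=1)
        done += m
    return counts


def sampling_enrichment_test(
    term_genes: set | list,
    selected: set | list,
    background: list,
    weights: pd.Series,
    n_samplings: int = 10000,
    seed: int | None = None,
) -> tuple[float, int, float]:
    """Monte-Carlo over-representation p for one term.

    Returns (p_over, observed in-term count, expected in-term count under
    the weighted null). Terms with no background members are skipped by the
    caller; here they raise.
    """
    if n_samplings < 1:
        raise ValueError("need at least one sampling")
    bg = list(background)
    term = set(term_genes) & set(bg)
    if not term:
        raise ValueError("term has no genes in the background")
    sel = set(selected) & set(bg)
    k = len(sel)
    observed = len(sel & term)
    in_term = np.array([g in term for g in bg])
    w = weights.loc[bg].to_numpy()
    rng = np.random.default_rng(seed)
    counts = weighted_sample_counts(in_term, w, k, n_samplings, rng)
    p_over = (1 + int((counts >= observed).sum())) / (n_samplings + 1)
    return p_over, observed, float(counts.mean())


def fdr_by(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (valid under dependency)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


def run_enrichment(
    gene_sets: pd.DataFrame,
    selected: list,
    background: list,
    lengths: pd.Series,
    n_samplings: int = 10000,
    n_bins: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test every term (two-column table term_id, gene_id) against the
    selected set with the length-aware sampling null; returns one row per
    term with p_over and BY FDR. Terms with < 2 background members drop."""
    bg = list(background)
    w = fit_pwf(lengths.loc[bg], pd.Series([g in set(selected) for g in bg], index=bg), n_bins)
    rng = np.random.default_rng(seed)
    rows = []
    for term_id, grp in gene_sets.groupby("term_id"):
        members = set(grp["gene_id"]) & set(bg)
        if len(members) < 2:
            continue
        p_over, obs, exp = sampling_enrichment_test(
            members, selected, bg, w, n_samplings, rng.integers(2**31)
        )
        rows.append(
            {
                "term_id": term_id,
                "n_term": len(members),
                "n_selected_in_term": obs,
                "expected": exp,
                "p_over": p_over,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr_by"] = fdr_by(out["p_over"].to_numpy())
    return out


def read_gene_sets(path) -> pd.DataFrame:
    """Read gene sets as a two-column TSV (term_id, gene_id) or GMT
    (term, description, members...). Returns the long-format table."""
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() == ".gmt":
        rows = []
        for line in path.read_text().splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            rows += [{"term_id": parts[0], "gene_id": g} for g in parts[2:] if g]
        return pd.DataFrame(rows)
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"term_id", "gene_id"} <= set(df.columns):
        raise ValueError("gene-set TSV needs term_id and gene_id columns")
    return df[["term_id", "gene_id"]]
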