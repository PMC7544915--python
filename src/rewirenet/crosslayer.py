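"""Cross-layer coexpression of circulating miRNAs with PWBC mRNAs.

Both layers are profiled from the same animals, so each (miRNA, gene) pair
has a Pearson r across all samples. Significance of the all-sample selection
(|r| > 0.85 by default) is an empirical FDR obtained by shuffling the animal
identities of the mRNA matrix (the miRNA layer fixed), which breaks the
common source of the two RNA types while leaving each layer's within-layer
structure untouched. Differential cross-layer coexpression reuses the
rewiring rule engine with the non-pregnant group focal, and known
miRNA-target interactions can be overlaid from a two-column table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .coexpression import standardize_rows
from .io import ExpressionMatrix, Outcome, SampleTable
from .rewiring import (
    EFDRResult,
    RewireClass,
    RewireThresholds,
    consensus_classes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "cross_correlation_matrix",
    "cross_correlation",
    "efdr_cross_layer",
    "cross_layer_rewiring",
    "overlay_interactions",
]


def _aligned_values(
    em_mirna: ExpressionMatrix, em_mrna: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a, b = set(em_mirna.sample_ids), set(em_mrna.sample_ids)
    if a != b:
        raise ValueError(f"sample mismatch between layers: {sorted(a ^ b)}")
    order = sorted(a)
    mi = em_mirna.values[order].to_numpy()
    mg = em_mrna.values[order].to_numpy()
    return mi, mg, np.array(em_mirna.feature_ids), np.array(em_mrna.feature_ids)


def cross_correlation_matrix(
    mirna_vals: np.ndarray, mrna_vals: np.ndarray
) -> np.ndarray:
    """Pearson r between every miRNA row and every mRNA row (columns are the
    same samples in the same order). Zero-variance rows give NaN."""
    n = mirna_vals.shape[1]
    zm, ok_m = standardize_rows(mirna_vals)
    zg, ok_g = standardize_rows(mrna_vals)
    r = (zm @ zg.T) / (n - 1)
    np.clip(r, -1.0, 1.0, out=r)
    r[~ok_m, :] = np.nan
    r[:, ~ok_g] = np.nan
    return r


def cross_correlation(
    em_mirna: ExpressionMatrix,
    em_mrna: ExpressionMatrix,
    r_threshold: float = 0.85,
) -> pd.DataFrame:
    """All-sample r for every (miRNA, gene) pair, with a ``selected`` flag
    for |r| > r_threshold (strict)."""
    mi, mg, mi_ids, mg_ids = _aligned_values(em_mirna, em_mrna)
    r = cross_correlation_matrix(mi, mg)
    ii, jj = np.nonzero(~np.isnan(r))
    df = pd.DataFrame(
        {"mirna_id": mi_ids[ii], "gene_id": mg_ids[jj], "r_all": r[ii, jj]}
    )
    df["selected"] = df["r_all"].abs() > r_threshold
    logger.info(
        "cross-layer: %d pairs, %d with |r| > %s",
        len(df), int(df["selected"].sum()), r_threshold,
    )
    return df


def efdr_cross_layer(
    em_mirna: ExpressionMatrix,
    em_mrna: ExpressionMatrix,
    r_threshold: float = 0.85,
    n_randomizations: int = 5000,
    seed: int | None = None,
) -> EFDRResult:
    """Identity-shuffle eFDR of the |r| > threshold selection.

    Per randomization the mRNA matrix's sample identities are permuted (the
    miRNA layer fixed), all cross-layer correlations recomputed and
    exceedances of the threshold counted.
    """
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    rng = np.random.default_rng(seed)
    mi, mg, _, _ = _aligned_values(em_mirna, em_mrna)
    n = mi.shape[1]
    zm, ok_m = standardize_rows(mi)
    zg, ok_g = standardize_rows(mg)
    zm, zg = zm[ok_m], zg[ok_g]
    r_obs = (zm @ zg.T) / (n - 1)
    observed = int((np.abs(r_obs) > r_threshold).sum())
    scrambled = np.zeros(n_randomizations)
    for b in range(n_randomizations):
        perm = rng.permutation(n)
        r_b = (zm @ zg[:, perm].T) / (n - 1)
        scrambled[b] = (np.abs(r_b) > r_threshold).sum()
    return EFDRResult.from_counts(observed, scrambled)


def cross_layer_rewiring(
    em_mirna: ExpressionMatrix,
    em_mrna: ExpressionMatrix,
    samples: SampleTable,
    th: RewireThresholds = RewireThresholds(),
    focal: str = Outcome.NON_PREG.value,
    references: tuple[str, str] = (Outcome.AI_PREG.value, Outcome.NB_PREG.value),
) -> pd.DataFrame:
    """Consensus rewiring classes for (miRNA, gene) pairs, focal group
    non-pregnant, using the same rule engine as the within-layer network."""
    mi, mg, mi_ids, mg_ids = _aligned_values(em_mirna, em_mrna)
    order = sorted(set(em_mirna.sample_ids))
    outcomes = samples.outcomes(order).to_numpy()
    corr = {}
    for g in {focal, *references}:
        idx = np.flatnonzero(outcomes == g)
        if len(idx) < 3:
            raise ValueError(f"group {g} has {len(idx)} samples; need >= 3")
        corr[g] = cross_correlation_matrix(mi[:, idx], mg[:, idx])
    cls, disc = consensus_classes(corr, th, focal, references)
    valid = np.ones_like(cls, dtype=bool)
    for r in corr.values():
        valid &= ~np.isnan(r)
    sel = valid & ((cls != RewireClass.NONE) | disc)
    ii, jj = np.nonzero(sel)
    short = {"AI_PREG": "r_ai", "NB_PREG": "r_nb", "NON_PREG": "r_np"}
    df = pd.DataFrame(
        {
            "mirna_id": mi_ids[ii],
            "gene_id": mg_ids[jj],
            "rewire_class": [RewireClass(c).name for c in cls[ii, jj]],
            "discordant": disc[ii, jj],
        }
    )
    for g, r in corr.items():
        df[short.get(g, f"r_{g.lower()}")] = r[ii, jj]
    return df


def overlay_interactions(edges: pd.DataFrame, interactions: pd.DataFrame) -> pd.DataFrame:
    """Flag pairs present in a known miRNA-target interaction table
    (columns mirna_id, gene_id; duplicates ignored)."""
    known = set(
        zip(interactions["mirna_id"].astype(str), interactions["gene_id"].astype(str))
    )
    out = edges.copy()
    out["known_interaction"] = [
        (m, g) in known for m, g in zip(out["mirna_id"].astype(str), out["gene_id"].astype(str))
    ]
    return out
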