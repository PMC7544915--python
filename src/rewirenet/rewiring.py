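"""Differential (rewired) coexpression between pregnancy-outcome groups.

Within-group Pearson correlations are compared between a focal group
(non-pregnant by default) and each reference group (AI-pregnant,
NB-pregnant). An edge is

* ``INVERTED``          if |r_focal - r_reference| > 1.95;
* ``GAINED_POSITIVE``/``GAINED_NEGATIVE`` (by the sign of r_focal)
                        if |r_focal| > 0.99 and -0.1 < r_reference < 0.1;
* ``LOST_POSITIVE``/``LOST_NEGATIVE`` (by the sign of r_reference)
                        if |r_reference| > 0.99 and -0.1 < r_focal < 0.1;
* ``NONE``              otherwise.

All inequalities are strict. Under the default thresholds the gained/lost
regions cannot overlap the inverted region (|r1| > 0.99 and |r2| < 0.1 imply
|r1 - r2| < 1.09 < 1.95).

A *consensus* rewired edge must receive the same non-NONE class against both
reference groups. Significance is an empirical FDR: outcome labels are
permuted across samples (group sizes preserved), the consensus count is
recomputed per randomization, and eFDR = mean scrambled count / observed
count, clipped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from .coexpression import correlation_matrix
from .io import ExpressionMatrix, Outcome, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "RewireClass",
    "RewireThresholds",
    "GroupCorrelationTable",
    "EFDRResult",
    "groupwise_correlation",
    "classify_edge",
    "classify_matrix",
    "consensus_classes",
    "consensus_rewired_edges",
    "efdr_rewiring",
]


class RewireClass(IntEnum):
    NONE = 0
    GAINED_POSITIVE = 1
    GAINED_NEGATIVE = 2
    LOST_POSITIVE = 3
    LOST_NEGATIVE = 4
    INVERTED = 5


@dataclass(frozen=True)
class RewireThresholds:
    """Constants of the rewiring rules (all compared strictly)."""

    inverted_gap: float = 1.95
    present_abs_r: float = 0.99
    absent_band: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.inverted_gap <= 2):
            raise ValueError("inverted_gap must be in (0, 2]")
        if not (0 < self.absent_band < self.present_abs_r <= 1):
            raise ValueError("need 0 < absent_band < present_abs_r <= 1")


@dataclass
class GroupCorrelationTable:
    """Within-group correlation matrices over a common feature order."""

    feature_ids: np.ndarray
    corr: dict[str, np.ndarray]  # outcome value -> features x features r
    group_sizes: dict[str, int]
    # pairs with zero within-group variance anywhere are NaN in `corr`
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            v = np.ones((len(self.feature_ids),) * 2, dtype=bool)
            for r in self.corr.values():
                v &= ~np.isnan(r)
            self.valid = v

    def to_frame(self) -> pd.DataFrame:
        """Per-pair table (upper triangle, defined in all groups)."""
        iu, ju = np.triu_indices(len(self.feature_ids), k=1)
        ok = self.valid[iu, ju]
        iu, ju = iu[ok], ju[ok]
        data = {
            "feature_a": self.feature_ids[iu],
            "feature_b": self.feature_ids[ju],
        }
        short = {"AI_PREG": "r_ai", "NB_PREG": "r_nb", "NON_PREG": "r_np"}
        for g, r in self.corr.items():
            data[short.get(g, f"r_{g.lower()}")] = r[iu, ju]
        return pd.DataFrame(data)


def _group_columns(em: ExpressionMatrix, samples: SampleTable) -> dict[str, np.ndarray]:
    missing = set(em.sample_ids) - set(samples.sample_ids)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    out = {}
    outcomes = samples.outcomes(em.sample_ids).to_numpy()
    for g in Outcome:
        cols = np.flatnonzero(outcomes == g.value)
        out[g.value] = cols
    return out


def groupwise_correlation(
    em: ExpressionMatrix, samples: SampleTable, min_group: int = 3
) -> GroupCorrelationTable:
    """Pearson r per feature pair within each outcome group.

    Each group's r uses only that group's columns. Groups with fewer than
    ``min_group`` samples are an error; pairs undefined (zero variance) in
    any group are flagged invalid and excluded from downstream tables.
    """
    ids = np.array(em.feature_ids)
    order = np.argsort(ids)
    ids = ids[order]
    vals = em.values.to_numpy()[order]
    cols = _group_columns(em, samples)
    corr, sizes = {}, {}
    for g, idx in cols.items():
        if len(idx) < min_group:
            raise ValueError(f"group {g} has {len(idx)} samples; need >= {min_group}")
        r, _ = correlation_matrix(vals[:, idx])
        corr[g] = r
        sizes[g] = len(idx)
    gct = GroupCorrelationTable(ids, corr, sizes)
    n_bad = int((~gct.valid[np.triu_indices(len(ids), k=1)]).sum())
    if n_bad:
        logger.info("%d pairs undefined within at least one group; excluded", n_bad)
    return gct


def classify_matrix(
    r_focal: np.ndarray, r_reference: np.ndarray, th: RewireThresholds
) -> np.ndarray:
    """Vectorized rewiring rule; NaN anywhere yields NONE."""
    rf = np.asarray(r_focal, dtype=float)
    rr = np.asarray(r_reference, dtype=float)
    out = np.zeros(np.broadcast(rf, rr).shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        inverted = np.abs(rf - rr) > th.inverted_gap
        in_band_r = np.abs(rr) < th.absent_band
        in_band_f = np.abs(rf) < th.absent_band
        gained = (np.abs(rf) > th.present_abs_r) & in_band_r
        lost = (np.abs(rr) > th.present_abs_r) & in_band_f
        out[inverted] = RewireClass.INVERTED
        out[gained & (rf > 0)] = RewireClass.GAINED_POSITIVE
        out[gained & (rf < 0)] = RewireClass.GAINED_NEGATIVE
        out[lost & (rr > 0)] = RewireClass.LOST_POSITIVE
        out[lost & (rr < 0)] = RewireClass.LOST_NEGATIVE
    out[np.isnan(rf) | np.isnan(rr)] = RewireClass.NONE
    return out


def classify_edge(
    r_focal: float, r_reference: float, th: RewireThresholds = RewireThresholds()
) -> RewireClass:
    """Rewiring class of one edge from its two within-group correlations."""
    return RewireClass(int(classify_matrix(np.array(r_focal), np.array(r_reference), th)))


def consensus_classes(
    gct_corr: dict[str, np.ndarray],
    th: RewireThresholds,
    focal: str = Outcome.NON_PREG.value,
    references: tuple[str, str] = (Outcome.AI_PREG.value, Outcome.NB_PREG.value),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair consensus class matrix and a discordance mask.

    Consensus requires the SAME non-NONE class against both references;
    pairs with two different non-NONE classes are discordant (excluded from
    headline sets, reported separately).
    """
    rf = gct_corr[focal]
    c1 = classify_matrix(rf, gct_corr[references[0]], th)
    c2 = classify_matrix(rf, gct_corr[references[1]], th)
    consensus = np.where((c1 == c2) & (c1 != RewireClass.NONE), c1, RewireClass.NONE)
    discordant = (c1 != c2) & (c1 != RewireClass.NONE) & (c2 != RewireClass.NONE)
    return consensus.astype(np.int8), discordant


def consensus_rewired_edges(
    gct: GroupCorrelationTable,
    th: RewireThresholds = RewireThresholds(),
    focal: str = Outcome.NON_PREG.value,
    references: tuple[str, str] = (Outcome.AI_PREG.value, Outcome.NB_PREG.value),
) -> pd.DataFrame:
    """Edges receiving the same non-NONE class in both focal-vs-reference
    contrasts. Returns one row per edge with the class, all three r values
    and a ``discordant`` column for mixed-class pairs."""
    cls, disc = consensus_classes(gct.corr, th, focal, references)
    iu, ju = np.triu_indices(len(gct.feature_ids), k=1)
    ok = gct.valid[iu, ju]
    report = (cls[iu, ju] != RewireClass.NONE) | disc[iu, ju]
    sel = ok & report
    iu, ju = iu[sel], ju[sel]
    short = {"AI_PREG": "r_ai", "NB_PREG": "r_nb", "NON_PREG": "r_np"}
    df = pd.DataFrame(
        {
            "feature_a": gct.feature_ids[iu],
            "feature_b": gct.feature_ids[ju],
            "rewire_class": [RewireClass(c).name for c in cls[iu, ju]],
            "discordant": disc[iu, ju],
        }
    )
    for g, r in gct.corr.items():
        df[short.get(g, f"r_{g.lower()}")] = r[iu, ju]
    return df


@dataclass
class EFDRResult:
    """Empirical FDR of a selection rule under label permutation."""

    observed: int
    mean_scrambled: float
    n_randomizations: int
    efdr: float
    per_class: dict[str, "EFDRResult"] | None = None

    @staticmethod
    def from_counts(observed: int, scrambled: np.ndarray) -> "EFDRResult":
        mean_s = float(np.mean(scrambled)) if len(scrambled) else 0.0
        if observed > 0:
            efdr = min(1.0, mean_s / observed)
        else:
            logger.warning("no observed selections; eFDR undefined, reporting 1")
            efdr = 1.0
        return EFDRResult(observed, mean_s, len(scrambled), efdr)


def _count_consensus(
    vals: np.ndarray,
    group_cols: dict[str, np.ndarray],
    th: RewireThresholds,
    valid: np.ndarray,
    focal: str,
    references: tuple[str, str],
) -> np.ndarray:
    """Upper-triangle consensus counts per class (index = RewireClass)."""
    corr = {}
    for g, idx in group_cols.items():
        r, _ = correlation_matrix(vals[:, idx])
        corr[g] = r
    cls, _ = consensus_classes(corr, th, focal, references)
    iu, ju = np.triu_indices(vals.shape[0], k=1)
    c = cls[iu, ju][valid[iu, ju]]
    return np.bincount(c, minlength=len(RewireClass))


def efdr_rewiring(
    em: ExpressionMatrix,
    samples: SampleTable,
    th: RewireThresholds = RewireThresholds(),
    n_randomizations: int = 5000,
    seed: int | None = None,
    focal: str = Outcome.NON_PREG.value,
    references: tuple[str, str] = (Outcome.AI_PREG.value, Outcome.NB_PREG.value),
) -> EFDRResult:
    """Permutation eFDR of the consensus rewiring rule.

    Outcome labels are permuted over all samples preserving group sizes;
    group-wise correlations and the consensus count are recomputed each
    randomization. The pooled eFDR is reported along with per-class eFDRs
    (the estimator restricted to each rewiring class).
    """
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    rng = np.random.default_rng(seed)
    ids = np.array(em.feature_ids)
    order = np.argsort(ids)
    vals = em.values.to_numpy()[order]
    cols = _group_columns(em, samples)
    gct = groupwise_correlation(em, samples)
    obs_counts = _count_consensus(vals, cols, th, gct.valid, focal, references)

    n = vals.shape[1]
    group_names = list(cols)
    sizes = [len(cols[g]) for g in group_names]
    scr = np.zeros((n_randomizations, len(RewireClass)), dtype=float)
    for b in range(n_randomizations):
        perm = rng.permutation(n)
        bounds = np.cumsum([0] + sizes)
        pcols = {
            g: perm[bounds[k] : bounds[k + 1]] for k, g in enumerate(group_names)
        }
        scr[b] = _count_consensus(vals, pcols, th, gct.valid, focal, references)

    pooled_obs = int(obs_counts[1:].sum())
    pooled = EFDRResult.from_counts(pooled_obs, scr[:, 1:].sum(axis=1))
    pooled.per_class = {
        RewireClass(k).name: EFDRResult.from_counts(int(obs_counts[k]), scr[:, k])
        for k in range(1, len(RewireClass))
        if obs_counts[k] > 0 or scr[:, k].sum() > 0
    }
    return pooled
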