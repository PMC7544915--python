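"""Consensus negative-binomial differential expression.

A gene is called differentially expressed between two outcome groups only if
TWO independent count-based tests both give nominal p <= 0.03:

* an exact conditional test on group pseudo-sums (library sizes equalized to
  a common size), which with dispersion 0 reduces to the binomial-conditional
  Poisson exact test; and
* a Wald test from a negative-binomial log-linear model fit by IRLS, which
  also accommodates a cohort-year fixed effect.

The consensus set is then assessed by an empirical FDR (sample labels
reshuffled, consensus counts recomputed; eFDR = mean scrambled / observed)
and finally by leave-one-out retention: a call is kept only if the consensus
holds in every round that omits one sample.

Both tests sit behind a pluggable contract (any callable mapping
(counts, design) -> per-gene p) so external engines can be swapped in;
normalization is TMM or DESeq-style median-of-ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import CountMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "NormMethod",
    "normalization_factors",
    "normalized_counts",
    "equalize_libraries",
    "nb_dispersion",
    "nb_exact_test",
    "exact_test_table",
    "nb_wald_test",
    "nb_wald_glm",
    "consensus_de",
    "run_de",
    "efdr_de",
    "loo_validation",
]


class NormMethod(str, Enum):
    TMM = "TMM"
    MEDIAN_OF_RATIOS = "MEDIAN_OF_RATIOS"


# ---------------------------------------------------------------------------
# normalization


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """Trimmed mean of M-values of one sample against the reference.

    Genes with zero counts in either sample are excluded; the doubly trimmed
    (30% on M, 5% on A) weighted mean of log ratios gives the factor, with
    inverse asymptotic-variance (delta-method binomial) weights.
    """
    ok = (obs > 0) & (ref > 0)
    if ok.sum() < 1:
        return 1.0
    o, r = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = 1.0 / (
        (n_obs - obs[ok]) / (n_obs * obs[ok]) + (n_ref - ref[ok]) / (n_ref * ref[ok])
    )
    if np.allclose(m, 0, atol=1e-10):
        return 1.0
    lo_m, hi_m = np.quantile(m, [0.30, 0.70])
    lo_a, hi_a = np.quantile(a, [0.05, 0.95])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if keep.sum() == 0:
        keep = np.ones_like(m, dtype=bool)
    return float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def normalization_factors(
    cm: CountMatrix, method: NormMethod | str = NormMethod.TMM
) -> pd.Series:
    """Per-sample scale factors with geometric mean 1."""
    method = NormMethod(method)
    y = cm.counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero library size")
    if method is NormMethod.TMM:
        # reference: sample whose upper-quartile fraction is closest to the mean
        uq = np.array([np.quantile(y[:, s][y[:, s] > 0] / lib[s], 0.75) if (y[:, s] > 0).any() else 0 for s in range(y.shape[1])])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        f = np.array(
            [_tmm_pair(y[:, s], y[:, ref], lib[s], lib[ref]) for s in range(y.shape[1])]
        )
    else:
        log_y = np.full_like(y, np.nan)
        np.log(y, out=log_y, where=y > 0)
        all_pos = ~np.isnan(log_y).any(axis=1)
        if not all_pos.any():
            raise ValueError("no genes without zeros; cannot compute median-of-ratios")
        log_geo = log_y[all_pos].mean(axis=1)
        f = np.exp(np.median(log_y[all_pos] - log_geo[:, None], axis=0))
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=cm.sample_ids, name="factor")


def _effective_libs(cm: CountMatrix, factors: pd.Series) -> np.ndarray:
    return cm.library_sizes().to_numpy(dtype=float) * factors.loc[cm.sample_ids].to_numpy()


def normalized_counts(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts rescaled to the geometric-mean effective library size."""
    eff = _effective_libs(cm, factors)
    common = np.exp(np.mean(np.log(eff)))
    return cm.counts / eff * common


def equalize_libraries(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Integer pseudo-counts on a common library size (input to the exact
    test): normalized counts rounded to the nearest integer."""
    return normalized_counts(cm, factors).round().astype(np.int64)


# ---------------------------------------------------------------------------
# dispersion


_PHI_GRID = np.concatenate([[0.0], np.logspace(-5, 1, 55)])


def _apl_profile(pseudo: np.ndarray, glabels: np.ndarray, grid: np.ndarray = _PHI_GRID) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of each gene at each grid
    dispersion, on equal-library pseudo-counts with group means profiled."""
    y = pseudo.astype(float)
    apl = np.zeros((y.shape[0], len(grid)))
    group_idx = [np.flatnonzero(glabels == g) for g in pd.unique(glabels)]
    for j, phi in enumerate(grid):
        ll = np.zeros(y.shape[0])
        cr = np.zeros(y.shape[0])
        for idx in group_idx:
            yg = y[:, idx]
            mu = np.maximum(yg.mean(axis=1), 1e-8)[:, None]
            if phi == 0.0:
                ll += (yg * np.log(mu) - mu - gammaln(yg + 1)).sum(axis=1)
                cr += 0.5 * np.log(mu[:, 0] * len(idx))
            else:
                size = 1.0 / phi
                ll += (
                    gammaln(yg + size)
                    - gammaln(size)
                    - gammaln(yg + 1)
                    + size * np.log(size / (size + mu))
                    + yg * np.log(mu / (size + mu))
                ).sum(axis=1)
                cr += 0.5 * np.log(mu[:, 0] / (1 + phi * mu[:, 0]) * len(idx))
        apl[:, j] = ll - cr
    return apl


def nb_dispersion(
    cm: CountMatrix,
    groups: pd.Series,
    factors: pd.Series | None = None,
    shrink_weight: float = 0.5,
    n_bins: int = 20,
    floor_at_trend: bool = False,
) -> pd.Series:
    """Per-gene NB dispersion phi (variance = m + phi m^2).

    Raw estimates are method-of-moments on normalized counts, pooled across
    groups (weighted by within-group degrees of freedom) and floored at
    zero. They are then shrunk with the given weight toward a mean-
    dispersion trend estimated per mean-quantile bin by maximizing the
    bin-pooled Cox-Reid adjusted profile likelihood (far more stable than
    the raw per-gene values at these sample sizes). ``floor_at_trend``
    additionally never lets a gene drop below its trend value — the
    conservative default of the DE driver, since underestimated dispersions
    inflate both tests. Genes constant across all samples get phi 0.
    """
    if factors is None:
        factors = pd.Series(1.0, index=cm.sample_ids)
    z = normalized_counts(cm, factors).to_numpy()
    glabels = groups.loc[cm.sample_ids].to_numpy()
    if max(np.bincount(pd.factorize(glabels)[0])) < 2:
        raise ValueError("need at least one group with >= 2 samples")
    raw = _mom_dispersion(z, glabels)

    # trend: binned common dispersion by pooled adjusted profile likelihood
    pseudo = equalize_libraries(cm, factors).to_numpy()
    apl = _apl_profile(pseudo, glabels)
    mean_all = z.mean(axis=1)
    order = np.argsort(mean_all)
    n_bins = max(1, min(n_bins, len(raw)))
    bins = np.array_split(order, n_bins)
    bin_means = np.array([mean_all[b].mean() for b in bins])
    bin_phi = np.array([_PHI_GRID[np.argmax(apl[b].sum(axis=0))] for b in bins])
    trend = np.interp(mean_all, bin_means, bin_phi) if n_bins > 1 else np.full_like(raw, bin_phi[0])

    shrunk = shrink_weight * trend + (1 - shrink_weight) * raw
    if floor_at_trend:
        shrunk = np.maximum(shrunk, trend)
    constant = cm.counts.to_numpy().var(axis=1) == 0
    shrunk[constant] = 0.0
    out = pd.Series(shrunk, index=cm.feature_ids, name="dispersion")
    out.attrs["trend"] = trend
    return out


def _mom_dispersion(z: np.ndarray, glabels: np.ndarray) -> np.ndarray:
    """Pooled method-of-moments dispersion on normalized counts."""
    num = np.zeros(z.shape[0])
    den = 0.0
    for g in pd.unique(glabels):
        idx = np.flatnonzero(glabels == g)
        if len(idx) < 2:
            continue
        m = z[:, idx].mean(axis=1)
        v = z[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        num += (len(idx) - 1) * phi_g
        den += len(idx) - 1
    return np.maximum(num / den, 0.0)


# ---------------------------------------------------------------------------
# exact conditional test


def exact_test_table(
    total: int, n_a: int, n_b: int, dispersion: float
) -> np.ndarray:
    """Two-sided conditional exact p for every split k of ``total`` into
    group A (k) and group B (total - k), under equal per-sample NB means.

    p[k] sums the probabilities of all splits as or less likely than k,
    conditioned on the total. With dispersion 0 the group sums are Poisson
    and the conditional law is Binomial(total, n_a / (n_a + n_b)).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if total == 0:
        return np.ones(1)
    k = np.arange(total + 1)
    mu = total / (n_a + n_b)
    if dispersion < 1e-12:
        logj = stats.binom.logpmf(k, total, n_a / (n_a + n_b))
    else:
        size_a, size_b = n_a / dispersion, n_b / dispersion
        pa = size_a / (size_a + n_a * mu)
        pb = size_b / (size_b + n_b * mu)
        logj = stats.nbinom.logpmf(k, size_a, pa) + stats.nbinom.logpmf(
            total - k, size_b, pb
        )
    logj -= logj.max()
    joint = np.exp(logj)
    joint /= joint.sum()
    order = np.argsort(joint)
    csum = np.cumsum(joint[order])
    # rank of each k's probability among sorted values, tie-tolerant
    pos = np.searchsorted(joint[order], joint * (1 + 1e-10), side="right") - 1
    p = csum[np.clip(pos, 0, total)]
    return np.minimum(p, 1.0)


def nb_exact_test(
    counts_a: np.ndarray, counts_b: np.ndarray, dispersion: float
) -> float:
    """Exact conditional two-sided p for one gene from equalized-library
    pseudo-counts of the two groups."""
    s_a = int(round(float(np.sum(counts_a))))
    s_b = int(round(float(np.sum(counts_b))))
    table = exact_test_table(s_a + s_b, len(counts_a), len(counts_b), dispersion)
    return float(table[s_a])


# ---------------------------------------------------------------------------
# NB Wald GLM (vectorized IRLS across genes)


def nb_wald_glm(
    y: np.ndarray,
    design: np.ndarray,
    offset: np.ndarray,
    dispersion: np.ndarray,
    coef_idx: int = 1,
    max_iter: int = 100,
    tol: float = 1e-8,
    df: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit log-link NB GLMs for all genes at once by IRLS with fixed
    per-gene dispersion; Wald test on one coefficient.

    With ``df`` the Wald statistic is referred to a t distribution with
    that many degrees of freedom (the DE driver passes the residual df,
    n - p, a small-sample correction for estimated dispersions); otherwise
    the standard normal is used. Returns (coefficient, p_value, converged)
    per gene. Genes that fail to converge (or are all-zero) get p = 1 and
    converged = False.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n_genes, n_samples = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not full rank")
    phi = np.asarray(dispersion, dtype=float)[:, None]
    o = np.asarray(offset, dtype=float)[None, :]

    # init from least squares on log(y + 0.5) - offset
    z0 = np.log(y + 0.5) - o
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # genes x p
    converged = np.zeros(n_genes, dtype=bool)
    active = np.ones(n_genes, dtype=bool)
    A = np.zeros((n_genes, p, p))
    ridge = 1e-10 * np.eye(p)

    for _ in range(max_iter):
        eta = beta @ X.T  # genes x samples
        mu = np.exp(np.clip(eta + o, -30, 30))
        w = mu / (1.0 + phi * mu)
        z = eta + (y - mu) / mu
        A = np.einsum("gs,sp,sq->gpq", w, X, X) + ridge
        b = np.einsum("gs,sp->gp", w * z, X)
        new = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new - beta), axis=1)
        beta = np.where(active[:, None], new, beta)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.linalg.inv(A)
        se = np.sqrt(np.maximum(cov[:, coef_idx, coef_idx], 0.0))
        wald = np.where(se > 0, beta[:, coef_idx] / se, 0.0)
    if df is None:
        pvals = 2.0 * stats.norm.sf(np.abs(wald))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(wald), df=df)
    allzero = y.sum(axis=1) == 0
    ok = converged & ~allzero & np.isfinite(pvals)
    pvals = np.where(ok, pvals, 1.0)
    if (~ok).any():
        logger.info("%d genes non-converged or degenerate; p set to 1", int((~ok).sum()))
    return beta[:, coef_idx], pvals, ok


def _design(groups: np.ndarray, focal: str, years: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(len(groups)), (groups == focal).astype(float)]
    if years is not None:
        uniq = np.unique(years)
        for yv in uniq[1:]:
            cols.append((years == yv).astype(float))
    return np.column_stack(cols)


def nb_wald_test(
    cm: CountMatrix,
    samples: SampleTable,
    focal: str,
    reference: str,
    dispersion: pd.Series,
    factors: pd.Series | None = None,
    year_covariate: bool = False,
) -> pd.DataFrame:
    """NB Wald p per gene for the focal-vs-reference group coefficient,
    optionally adjusting for cohort year as a fixed effect."""
    if factors is None:
        factors = normalization_factors(cm)
    groups = samples.outcomes(cm.sample_ids).to_numpy()
    use = np.isin(groups, [focal, reference])
    ids = np.array(cm.sample_ids)[use]
    y = cm.counts.to_numpy(dtype=float)[:, use]
    eff = _effective_libs(cm, factors)[use]
    years = samples.years(ids).to_numpy() if year_covariate else None
    X = _design(groups[use], focal, years)
    coef, pvals, ok = nb_wald_glm(
        y, X, np.log(eff), dispersion.loc[cm.feature_ids].to_numpy(),
        df=X.shape[0] - X.shape[1],
    )
    return pd.DataFrame(
        {"coef": coef, "p_wald": pvals, "converged": ok}, index=cm.feature_ids
    )


# ---------------------------------------------------------------------------
# consensus / eFDR / leave-one-out


def consensus_de(p_a, p_b, p_cut: float = 0.03):
    """True iff both nominal p-values are <= p_cut (inclusive)."""
    return (np.asarray(p_a) <= p_cut) & (np.asarray(p_b) <= p_cut)


@dataclass
class _DEContext:
    """Precomputed state shared by run_de / efdr_de / loo_validation."""

    cm: CountMatrix  # restricted to the two groups
    groups: np.ndarray
    focal: str
    reference: str
    factors: pd.Series
    dispersion: pd.Series
    pseudo: np.ndarray  # equalized integer pseudo-counts
    tables: list[np.ndarray]  # exact-test p table per gene
    design: np.ndarray
    offset: np.ndarray
    trend: np.ndarray  # mean-dispersion trend (fixed across permutations)
    norm: np.ndarray  # normalized counts
    shrink_weight: float


def _build_context(
    cm: CountMatrix,
    samples: SampleTable,
    focal: str,
    reference: str,
    norm_method: NormMethod | str = NormMethod.TMM,
    shrink_weight: float = 0.5,
) -> _DEContext:
    groups_all = samples.outcomes(cm.sample_ids)
    use = groups_all.isin([focal, reference]).to_numpy()
    sub = cm.subset_samples(np.array(cm.sample_ids)[use])
    groups = groups_all.to_numpy()[use]
    factors = normalization_factors(sub, norm_method)
    disp = nb_dispersion(
        sub, samples.outcomes(sub.sample_ids), factors, shrink_weight,
        floor_at_trend=True,
    )
    pseudo = equalize_libraries(sub, factors).to_numpy()
    n_a = int((groups == focal).sum())
    n_b = int((groups == reference).sum())
    totals = pseudo.sum(axis=1)
    phi = disp.to_numpy()
    tables = [
        exact_test_table(int(t), n_a, n_b, float(ph)) for t, ph in zip(totals, phi)
    ]
    eff = _effective_libs(sub, factors)
    X = _design(groups, focal, None)
    return _DEContext(
        sub, groups, focal, reference, factors, disp, pseudo, tables, X,
        np.log(eff), disp.attrs["trend"], normalized_counts(sub, factors).to_numpy(),
        shrink_weight,
    )


def _exact_pvals(ctx: _DEContext, focal_mask: np.ndarray) -> np.ndarray:
    s_a = ctx.pseudo[:, focal_mask].sum(axis=1)
    return np.array([t[int(s)] for t, s in zip(ctx.tables, s_a)])


def run_de(
    cm: CountMatrix,
    samples: SampleTable,
    focal: str,
    reference: str,
    p_cut: float = 0.03,
    norm_method: NormMethod | str = NormMethod.TMM,
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-gene DE table: both test p-values, log2 fold change (focal over
    reference, normalized means with pseudocount 0.5), consensus flag and
    direction."""
    ctx = _build_context(cm, samples, focal, reference, norm_method, shrink_weight)
    focal_mask = ctx.groups == focal
    p_exact = _exact_pvals(ctx, focal_mask)
    _, p_wald, _ = nb_wald_glm(
        ctx.cm.counts.to_numpy(dtype=float),
        ctx.design,
        ctx.offset,
        ctx.dispersion.to_numpy(),
        df=ctx.design.shape[0] - ctx.design.shape[1],
    )
    norm = normalized_counts(ctx.cm, ctx.factors).to_numpy()
    m_f = norm[:, focal_mask].mean(axis=1)
    m_r = norm[:, ~focal_mask].mean(axis=1)
    lfc = np.log2((m_f + 0.5) / (m_r + 0.5))
    cons = consensus_de(p_exact, p_wald, p_cut)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_exact": p_exact,
            "p_wald": p_wald,
            "consensus": cons,
            "direction": np.where(lfc > 0, "UP", "DOWN"),
        },
        index=ctx.cm.feature_ids,
    )


from .rewiring import EFDRResult  # noqa: E402  (shared result type)


def _critical_bounds(total: int, n_a: int, n_b: int, phi: float, p_cut: float) -> tuple[int, int]:
    """Critical split values of the exact test: p(s_a) <= p_cut iff
    s_a <= k_lo or s_a >= k_hi (the two-sided p is monotone away from the
    conditional mode). Returns (-1, total + 1) when no split is critical."""
    table = exact_test_table(total, n_a, n_b, phi)
    flag = table <= p_cut
    if flag.all():
        return total, 0
    k_lo = -1
    i = 0
    while i < len(flag) and flag[i]:
        i += 1
    k_lo = i - 1
    j = len(flag) - 1
    while j >= 0 and flag[j]:
        j -= 1
    k_hi = j + 1
    return k_lo, k_hi


def efdr_de(
    cm: CountMatrix,
    samples: SampleTable,
    focal: str,
    reference: str,
    p_cut: float = 0.03,
    n_randomizations: int = 10000,
    seed: int | None = None,
    norm_method: NormMethod | str = NormMethod.TMM,
    n_total_grid: int = 9,
) -> EFDRResult:
    """Empirical FDR of the consensus rule under outcome-label reshuffling.

    Outcome labels are permuted across ALL samples of the matrix (all
    outcome groups, group sizes preserved), and each randomization's
    focal-vs-reference contrast is recomputed on the samples carrying the
    scrambled labels. Reshuffling over the full design rather than within
    the two contrast groups matters: with 5-6 animals per group a
    two-group-only shuffle reproduces or reverses the true grouping often
    enough that genuinely differential genes dominate the scrambled counts.

    Pseudo-counts are equalized once on the full matrix; per-gene Wald
    dispersions are re-estimated within each randomization and floored at
    the observed estimates (a permutation aligning with latent structure
    must not be awarded a smaller dispersion than the data support). The
    exact-test critical split values depend on the selected samples' total
    pseudo-count and are precomputed per gene on a grid of totals; each
    randomization's split is projected onto the nearest grid total.
    """
    if n_randomizations < 1:
        raise ValueError("need at least one randomization")
    rng = np.random.default_rng(seed)
    samples.check_covers(cm)
    outcomes = samples.outcomes(cm.sample_ids).to_numpy()
    for g in (focal, reference):
        if (outcomes == g).sum() < 2:
            raise ValueError(f"group {g} needs >= 2 samples")
    factors = normalization_factors(cm, norm_method)
    disp = nb_dispersion(
        cm, samples.outcomes(cm.sample_ids), factors, floor_at_trend=True
    )
    phi = disp.to_numpy()
    trend = disp.attrs["trend"]
    pseudo = equalize_libraries(cm, factors).to_numpy()
    norm = normalized_counts(cm, factors).to_numpy()
    y = cm.counts.to_numpy(dtype=float)
    offset = np.log(_effective_libs(cm, factors))

    n = len(outcomes)
    n_a = int((outcomes == focal).sum())
    n_b = int((outcomes == reference).sum())
    dof = n_a + n_b - 2

    def _contrast_stats(sel_a: np.ndarray, sel_b: np.ndarray, phi_w: np.ndarray):
        sel = np.concatenate([sel_a, sel_b])
        Xb = np.column_stack(
            [np.ones(len(sel)), np.r_[np.ones(len(sel_a)), np.zeros(len(sel_b))]]
        )
        _, pw, _ = nb_wald_glm(y[:, sel], Xb, offset[sel], phi_w, df=dof)
        s_a = pseudo[:, sel_a].sum(axis=1)
        t = pseudo[:, sel].sum(axis=1)
        return s_a, t, pw

    obs_a = np.flatnonzero(outcomes == focal)
    obs_b = np.flatnonzero(outcomes == reference)
    s_obs, t_obs, pw_obs = _contrast_stats(obs_a, obs_b, phi)

    # per-gene critical bounds on a grid of achievable totals (the observed
    # total is always a grid point, so the observed arm is exact)
    frac = (n_a + n_b) / n
    per_sample_var = pseudo.var(axis=1, ddof=1)
    sd_t = np.sqrt((n_a + n_b) * (1 - frac) * per_sample_var * n / (n - 1) + 1e-9)
    n_genes = cm.n_features
    pad = 2**62
    grid_t = np.full((n_genes, n_total_grid + 1), pad, dtype=np.int64)
    k_lo = np.full((n_genes, n_total_grid + 1), -1, dtype=np.int64)
    k_hi = np.full((n_genes, n_total_grid + 1), pad, dtype=np.int64)
    for g in range(n_genes):
        lo = max(0.0, frac * pseudo[g].sum() - 4 * sd_t[g])
        hi = frac * pseudo[g].sum() + 4 * sd_t[g]
        ts = np.unique(
            np.round(np.r_[np.linspace(lo, hi, n_total_grid), t_obs[g]]).astype(np.int64)
        )
        for j, t in enumerate(ts):
            lo_j, hi_j = _critical_bounds(int(t), n_a, n_b, float(phi[g]), p_cut)
            grid_t[g, j] = t
            k_lo[g, j] = lo_j
            k_hi[g, j] = hi_j

    def _exact_flags(s_a: np.ndarray, t: np.ndarray) -> np.ndarray:
        j = np.argmin(np.abs(grid_t - t[:, None]), axis=1)
        rows = np.arange(n_genes)
        tg = grid_t[rows, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            s_proj = np.where(t > 0, np.round(s_a * tg / np.maximum(t, 1)), 0).astype(np.int64)
        return (s_proj <= k_lo[rows, j]) | (s_proj >= k_hi[rows, j])

    observed = int((_exact_flags(s_obs, t_obs) & (pw_obs <= p_cut)).sum())

    scrambled = np.zeros(n_randomizations)
    for b in range(n_randomizations):
        perm = rng.permutation(n)
        sel_a, sel_b = perm[:n_a], perm[n_a : n_a + n_b]
        sel = np.concatenate([sel_a, sel_b])
        glab = np.r_[np.zeros(n_a), np.ones(n_b)]
        raw_b = _mom_dispersion(norm[:, sel], glab)
        phi_b = np.maximum(np.maximum(0.5 * trend + 0.5 * raw_b, trend), phi)
        s_a, t, pw = _contrast_stats(sel_a, sel_b, phi_b)
        scrambled[b] = int((_exact_flags(s_a, t) & (pw <= p_cut)).sum())
    return EFDRResult.from_counts(observed, scrambled)


def loo_validation(
    cm: CountMatrix,
    samples: SampleTable,
    focal: str,
    reference: str,
    p_cut: float = 0.03,
    genes: list[str] | None = None,
    norm_method: NormMethod | str = NormMethod.TMM,
) -> pd.Series:
    """Leave-one-out retention of consensus DE calls.

    Each sample of the two groups is omitted in turn and the consensus test
    recomputed on the remainder (dispersions held at the full-data
    estimates); a gene passes only if the consensus holds in every round.
    Rounds leaving a group with < 2 samples are skipped with a warning.
    """
    ctx = _build_context(cm, samples, focal, reference, norm_method)
    if genes is None:
        full = run_de(cm, samples, focal, reference, p_cut, norm_method)
        genes = list(full.index[full["consensus"]])
    gidx = [ctx.cm.feature_ids.index(g) for g in genes]
    phi_all = ctx.dispersion.to_numpy()
    passed = np.ones(len(genes), dtype=bool)
    sample_ids = np.array(ctx.cm.sample_ids)
    for drop in range(len(sample_ids)):
        keep = np.ones(len(sample_ids), dtype=bool)
        keep[drop] = False
        gk = ctx.groups[keep]
        if min((gk == ctx.focal).sum(), (gk == ctx.reference).sum()) < 2:
            logger.warning("leave-one-out round for %s skipped (group too small)", sample_ids[drop])
            continue
        sub_all = ctx.cm.subset_samples(sample_ids[keep])
        factors = normalization_factors(sub_all, norm_method)
        eff = _effective_libs(sub_all, factors)  # library over all features
        common = np.exp(np.mean(np.log(eff)))
        sub = sub_all.subset_features(genes)
        pseudo = np.round(sub.counts.to_numpy() / eff * common).astype(np.int64)
        n_a = int((gk == ctx.focal).sum())
        n_b = int((gk == ctx.reference).sum())
        phi = phi_all[gidx]
        fm = gk == ctx.focal
        p_e = np.array(
            [
                exact_test_table(int(row.sum()), n_a, n_b, float(ph))[int(row[fm].sum())]
                for row, ph in zip(pseudo, phi)
            ]
        )
        X = _design(gk, ctx.focal, None)
        _, p_w, _ = nb_wald_glm(
            sub.counts.to_numpy(dtype=float), X, np.log(eff), phi,
            df=X.shape[0] - X.shape[1],
        )
        passed &= consensus_de(p_e, p_w, p_cut)
        if not passed.any():
            break
    return pd.Series(passed, index=genes, name="loo_pass")


def calibrate_p_cut(
    cm: CountMatrix,
    samples: SampleTable,
    focal: str,
    reference: str,
    ladder: tuple[float, ...] = (0.03, 0.01, 0.003, 0.001),
    max_efdr: float = 0.05,
    n_randomizations: int = 300,
    seed: int | None = None,
    norm_method: NormMethod | str = NormMethod.TMM,
) -> tuple[float, dict[float, "EFDRResult"]]:
    """Choose the nominal consensus p cut-off against the empirical FDR.

    The consensus cut-off is a data-dependent choice: the largest ladder
    value whose consensus set has eFDR <= ``max_efdr`` is selected (the
    strictest ladder value if none qualifies). Returns the chosen cut and
    the eFDR result per ladder value evaluated (evaluation stops at the
    first qualifying cut).
    """
    results: dict[float, EFDRResult] = {}
    for cut in sorted(ladder, reverse=True):
        res = efdr_de(
            cm, samples, focal, reference, cut, n_randomizations, seed, norm_method
        )
        results[cut] = res
        if res.efdr <= max_efdr:
            return cut, results
    return min(ladder), results
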