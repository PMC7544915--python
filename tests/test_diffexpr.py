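import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

import rewirenet as rn
from rewirenet.diffexpr import (
    NormMethod,
    consensus_de,
    equalize_libraries,
    exact_test_table,
    nb_dispersion,
    nb_exact_test,
    nb_wald_glm,
    normalization_factors,
)
from rewirenet.io import CountMatrix, Layer, SampleTable
from rewirenet.simulate import (
    PlantedDEGene,
    SimulationSpec,
    simulate_dataset,
)
from tests.conftest import nb_counts


def _cm(arr, prefix="g"):
    df = pd.DataFrame(
        np.asarray(arr),
        index=[f"{prefix}{i}" for i in range(len(arr))],
        columns=[f"s{j}" for j in range(len(arr[0]))],
    )
    return CountMatrix(df, Layer.MRNA)


class TestNormalization:
    def test_identical_samples_give_unit_factors(self):
        cm = _cm(np.tile([[10], [20], [5]], (1, 3)))
        for method in NormMethod:
            f = normalization_factors(cm, method)
            np.testing.assert_allclose(f, 1.0, rtol=1e-12)

    def test_median_of_ratios_doubled_sample(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 1000, 50)
        cm = _cm(np.column_stack([base, 2 * base]))
        f = normalization_factors(cm, NormMethod.MEDIAN_OF_RATIOS)
        # after geometric-mean centering: {1/sqrt(2), sqrt(2)}
        np.testing.assert_allclose(f, [2**-0.5, 2**0.5], rtol=1e-9)

    def test_factors_invariant_to_gene_order(self):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 300, (80, 4))
        cm = _cm(arr)
        shuffled = cm.counts.sample(frac=1, random_state=2)
        cm2 = CountMatrix(shuffled, Layer.MRNA)
        for method in NormMethod:
            f1 = normalization_factors(cm, method)
            f2 = normalization_factors(cm2, method)
            np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_tmm_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        arr = rng.negative_binomial(5, 0.01, (200, 6))
        f = normalization_factors(_cm(arr), NormMethod.TMM)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, rel=1e-9)


class TestDispersion:
    def test_poisson_counts_near_zero(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(80, (2000, 12))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=[f"s{j}" for j in range(12)])
        d = nb_dispersion(_cm(arr), groups)
        assert d.median() < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        arr = nb_counts(rng, 200.0, 0.4, (5000, 12))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=[f"s{j}" for j in range(12)])
        d = nb_dispersion(_cm(arr), groups)
        assert abs(d.median() - 0.4) < 0.15

    def test_constant_gene_zero(self):
        arr = np.vstack([np.full(8, 50), np.arange(1, 9) * 10])
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=[f"s{j}" for j in range(8)])
        d = nb_dispersion(_cm(arr), groups)
        assert d.iloc[0] == 0.0


def enumeration_oracle(total, n_a, n_b, phi):
    """Independent brute-force conditional exact test: explicit NB pmf via
    gamma functions, full enumeration of all splits of the total."""
    if total == 0:
        return np.ones(1)
    mu = total / (n_a + n_b)

    def logpmf(k, size, mean):
        p = size / (size + mean)
        return (
            gammaln(k + size) - gammaln(size) - gammaln(k + 1)
            + size * np.log(p) + k * np.log1p(-p)
        )

    ks = np.arange(total + 1)
    if phi == 0:
        lp = stats.binom.logpmf(ks, total, n_a / (n_a + n_b))
    else:
        lp = logpmf(ks, n_a / phi, n_a * mu) + logpmf(total - ks, n_b / phi, n_b * mu)
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    return np.array(
        [probs[probs <= probs[k] * (1 + 1e-10)].sum() for k in ks]
    )


class TestExactTest:
    def test_binomial_limit(self):
        # dispersion 0, totals 10 vs 0 in two single-sample groups
        p = nb_exact_test(np.array([10]), np.array([0]), 0.0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_identical_group_sums_give_p_one(self):
        p = nb_exact_test(np.array([5, 5]), np.array([5, 5]), 0.1)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (6, 5), (3, 8)])
    def test_matches_enumeration_oracle_small_totals(self, phi, n_a, n_b):
        for total in range(0, 31):
            ours = exact_test_table(total, n_a, n_b, phi)
            theirs = enumeration_oracle(total, n_a, n_b, phi)
            np.testing.assert_allclose(ours, np.minimum(theirs, 1), atol=1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(np.array([1]), np.array([2]), -0.1)


@pytest.fixture(scope="module")
def null_fit():
    rng = np.random.default_rng(5)
    phi = 0.2
    y = nb_counts(rng, 100.0, phi, (2000, 11)).astype(float)
    X = np.column_stack([np.ones(11), np.r_[np.ones(6), np.zeros(5)]])
    coef, p, ok = nb_wald_glm(y, X, np.zeros(11), np.full(2000, phi))
    return y, X, coef, p, ok


class TestWaldGLM:

    def test_null_pvalues_uniform_with_known_dispersion(self, null_fit):
        _, _, _, p, ok = null_fit
        assert ok.mean() > 0.99
        # Kolmogorov-Smirnov at a generous level: the Wald normal
        # approximation at n=11 is close to but not exactly uniform
        assert stats.kstest(p[ok], "uniform").statistic < 0.05

    def test_matches_statsmodels_glm(self, null_fit):
        import statsmodels.api as sm

        y, X, coef, p, _ = null_fit
        for g in (0, 7, 42):
            m = sm.GLM(y[g], X, family=sm.families.NegativeBinomial(alpha=0.2)).fit()
            assert coef[g] == pytest.approx(m.params[1], rel=1e-5)
            assert p[g] == pytest.approx(m.pvalues[1], rel=1e-4)

    def test_power_for_planted_fold_change(self):
        rng = np.random.default_rng(6)
        phi = 0.1
        ya = nb_counts(rng, 400.0, phi, (1000, 6))
        yb = nb_counts(rng, 100.0, phi, (1000, 5))
        y = np.hstack([ya, yb]).astype(float)
        X = np.column_stack([np.ones(11), np.r_[np.ones(6), np.zeros(5)]])
        _, p, _ = nb_wald_glm(y, X, np.zeros(11), np.full(1000, phi))
        assert (p <= 0.03).mean() >= 0.9

    def test_year_confounded_null_with_covariate(self):
        # year shifts only; group coefficient must stay null-calibrated
        rng = np.random.default_rng(7)
        phi = 0.1
        year = np.r_[np.zeros(6), np.ones(6)]
        group = np.r_[np.ones(3), np.zeros(3), np.ones(3), np.zeros(3)]
        mean = 100 * np.exp(0.8 * year)
        y = nb_counts(rng, np.broadcast_to(mean, (2000, 12)), phi, (2000, 12)).astype(float)
        X = np.column_stack([np.ones(12), group, year])
        _, p, ok = nb_wald_glm(y, X, np.zeros(12), np.full(2000, phi))
        assert stats.kstest(p[ok], "uniform").statistic < 0.06

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError):
            nb_wald_glm(np.ones((2, 4)), X, np.zeros(4), np.array([0.1, 0.1]))


class TestConsensusRule:
    @pytest.mark.parametrize(
        "pa,pb,expected",
        [(0.02, 0.01, True), (0.02, 0.2, False), (0.03, 0.03, True)],
    )
    def test_inclusive_boundary(self, pa, pb, expected):
        assert bool(consensus_de(pa, pb, 0.03)) is expected


def _de_fixture(seed=4, n_de=30, lfc=2.4):
    de = [
        PlantedDEGene(f"g{i:05d}", lfc * (1 if i % 2 == 0 else -1), "NON_PREG")
        for i in range(n_de)
    ]
    spec = SimulationSpec(n_genes=300, n_mirna=5, planted_de=de, seed=seed)
    return simulate_dataset(spec), {d.gene_id for d in de}


class TestDEPipeline:
    def test_run_de_recovers_planted_genes(self):
        ds, planted = _de_fixture()
        tab = rn.run_de(ds.mrna, ds.samples, "NON_PREG", "AI_PREG")
        cons = set(tab.index[tab.consensus])
        assert len(planted & cons) >= 0.9 * len(planted)
        # false-positive rate among nulls controlled
        assert len(cons - planted) <= 0.05 * (300 - len(planted))

    def test_direction_agrees_with_fold_change(self):
        ds, _ = _de_fixture()
        tab = rn.run_de(ds.mrna, ds.samples, "NON_PREG", "AI_PREG")
        up = tab.direction == "UP"
        assert ((tab.log2_fold_change > 0) == up).all()

    def test_loo_implies_consensus_and_kills_outlier_genes(self):
        ds, planted = _de_fixture()
        cm = ds.mrna
        # corrupt one planted gene: its signal carried by a single sample
        gene = sorted(planted)[0]
        counts = cm.counts.copy()
        np_samples = ds.samples.group_samples("NON_PREG")
        base = counts.loc[gene, :].median()
        counts.loc[gene, :] = int(base)
        counts.loc[gene, np_samples[0]] = int(base * 60)
        cm2 = CountMatrix(counts, Layer.MRNA)
        tab = rn.run_de(cm2, ds.samples, "NON_PREG", "AI_PREG")
        cons = list(tab.index[tab.consensus])
        loo = rn.loo_validation(cm2, ds.samples, "NON_PREG", "AI_PREG", genes=cons)
        if gene in cons:  # single-outlier gene cannot survive every round
            assert not loo.loc[gene]
        strong = [g for g in cons if g in planted and g != gene]
        assert loo.loc[strong].mean() >= 0.9

    def test_efdr_de_seeded_reproducible(self):
        ds, _ = _de_fixture(n_de=10)
        a = rn.efdr_de(ds.mrna, ds.samples, "NON_PREG", "AI_PREG", n_randomizations=20, seed=3)
        b = rn.efdr_de(ds.mrna, ds.samples, "NON_PREG", "AI_PREG", n_randomizations=20, seed=3)
        assert a.efdr == b.efdr

    def test_efdr_arithmetic_example(self):
        from rewirenet.rewiring import EFDRResult

        res = EFDRResult.from_counts(100, np.full(10, 5.0))
        assert res.efdr == pytest.approx(0.05)


class TestAgainstDeseq2:
    def test_rank_agreement_with_pydeseq2(self):
        """Independent cross-check: on a planted fixture, gene ranking by
        our Wald p agrees with DESeq2's (different estimators, so only
        rank-level agreement is expected)."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        ds, planted = _de_fixture(seed=11, n_de=15)
        groups = ds.samples.outcomes(ds.mrna.sample_ids)
        use = groups.isin(["NON_PREG", "AI_PREG"]).to_numpy()
        cm = ds.mrna.subset_samples(np.array(ds.mrna.sample_ids)[use])
        meta = pd.DataFrame(
            {"condition": groups[use].to_numpy()}, index=cm.sample_ids
        )
        dds = DeseqDataSet(
            counts=cm.counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        stat = DeseqStats(
            dds, contrast=["condition", "NON_PREG", "AI_PREG"], quiet=True
        )
        stat.summary()
        theirs = stat.results_df["pvalue"]
        ours = rn.run_de(cm, ds.samples, "NON_PREG", "AI_PREG")["p_wald"]
        both = pd.concat([ours, theirs], axis=1, join="inner").dropna()
        rho = stats.spearmanr(both.iloc[:, 0], both.iloc[:, 1]).statistic
        assert rho > 0.8
        their_hits = set(theirs.index[theirs <= 0.03])
        assert len(their_hits & planted) >= 0.8 * len(planted & set(theirs.index))
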