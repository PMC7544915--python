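import numpy as np
import pandas as pd
import pytest

from rewirenet.io import Outcome
from rewirenet.prediction import (
    accuracy,
    accuracy_pvalue,
    default_registry,
    screen_algorithms,
    seed_sweep,
    select_panel,
    vst_transform,
)
from rewirenet.simulate import simulate_dataset, two_year_spec


@pytest.fixture(scope="module")
def fixture():
    return simulate_dataset(two_year_spec(n_genes=300, n_de=25, n_edges=5, n_cross=5, seed=7))


@pytest.fixture(scope="module")
def panel_and_splits(fixture):
    ds = fixture
    panel = select_panel(ds.mrna, ds.samples)
    keep = ds.samples.outcomes(ds.mrna.sample_ids).isin(["AI_PREG", "NON_PREG"])
    ids = pd.Index(ds.mrna.sample_ids)[keep.to_numpy()]
    years = ds.samples.years(ids)
    train_ids = list(ids[years == 1])
    test_ids = list(ids[years == 2])
    train = vst_transform(ds.mrna.subset_samples(train_ids), panel, fit=True)
    test = vst_transform(ds.mrna.subset_samples(test_ids), panel)
    labels = ds.samples.outcomes(ds.mrna.sample_ids)
    return ds, panel, train, test, labels


class TestPanelSelection:
    def test_panel_contains_planted_group_effects_not_year_effects(self, fixture):
        ds = fixture
        truth = ds.truth["de_genes"]
        ai_planted = set(truth.gene_id[truth.group == "AI_PREG"])
        panel = select_panel(ds.mrna, ds.samples)
        got = set(panel.genes)
        assert len(ai_planted & got) >= 0.9 * len(ai_planted)
        # edge/cross genes carry year-independent latent structure, no
        # group effect in this contrast; they must not flood the panel
        non_de = got - set(truth.gene_id)
        assert len(non_de) <= 0.1 * 300

    def test_selection_deterministic(self, fixture):
        a = select_panel(fixture.mrna, fixture.samples)
        b = select_panel(fixture.mrna, fixture.samples)
        assert a.genes == b.genes

    def test_empty_panel_raises(self, fixture):
        with pytest.raises(ValueError, match="threshold"):
            select_panel(fixture.mrna, fixture.samples, fdr_threshold=1e-12)


class TestVST:
    def test_train_parameters_reused_on_test(self, panel_and_splits):
        ds, panel, train, test, _ = panel_and_splits
        assert panel.mean is not None
        # training matrix is centered per gene; test matrix generally not
        np.testing.assert_allclose(train.mean(axis=0), 0, atol=1e-9)
        assert not np.allclose(test.mean(axis=0), 0, atol=1e-3)

    def test_sequencing_depth_invariance(self, fixture):
        # doubling one sample's counts (and hence its library) leaves its
        # transformed values essentially unchanged (up to the pseudocount)
        ds = fixture
        panel = select_panel(ds.mrna, ds.samples)
        cm = ds.mrna
        doubled = cm.counts.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        from rewirenet.io import CountMatrix

        cm2 = CountMatrix(doubled, cm.layer)
        a = vst_transform(cm, panel, fit=True)
        b = vst_transform(cm2, panel, fit=True)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=0.05)


class TestScreenAndSweep:
    def test_all_families_on_separable_panel(self, panel_and_splits):
        _, _, train, _, labels = panel_and_splits
        out = screen_algorithms(train, labels, k_folds=3, seed=0)
        assert set(out.algorithm) == set(default_registry())
        assert out.cv_accuracy.max() >= 0.9

    def test_label_permutation_baseline(self, panel_and_splits):
        _, _, train, _, labels = panel_and_splits
        rng = np.random.default_rng(0)
        shuffled = pd.Series(
            rng.permutation(labels.loc[train.index].to_numpy()), index=train.index
        )
        out = screen_algorithms(train, shuffled, k_folds=3, seed=0)
        assert out.cv_accuracy.mean() < 0.8

    def test_sweep_perfect_on_separated_fixture(self, panel_and_splits):
        _, _, train, test, labels = panel_and_splits
        runs, hist, importance = seed_sweep(train, test, labels, labels, n_runs=8, base_seed=1)
        assert all(r.accuracy == 1.0 for r in runs)
        assert hist.n_runs.sum() == 8
        assert (importance >= 0).all()
        assert importance.index.is_unique

    def test_sweep_deterministic_per_base_seed(self, panel_and_splits):
        _, _, train, test, labels = panel_and_splits
        r1, _, _ = seed_sweep(train, test, labels, labels, n_runs=1, base_seed=3)
        r2, _, _ = seed_sweep(train, test, labels, labels, n_runs=1, base_seed=3)
        assert (r1[0].predicted == r2[0].predicted).all()

    def test_importance_concentrates_on_informative_genes(self, panel_and_splits):
        ds, panel, train, test, labels = panel_and_splits
        truth = ds.truth["de_genes"]
        # genes shifted in either contrast group separate AI from non-pregnant
        informative = set(truth.gene_id) & set(panel.genes)
        if len(informative) < 3:
            pytest.skip("panel too small for importance check")
        _, _, importance = seed_sweep(train, test, labels, labels, n_runs=10, base_seed=2)
        top = set(importance.head(10).index)
        assert len(top & informative) >= 5


class TestAccuracy:
    def test_fraction_correct(self):
        assert accuracy(["a", "a", "b"], ["a", "b", "b"]) == pytest.approx(2 / 3)
        assert accuracy(list("aaa"), list("aaa")) == 1.0
        assert accuracy(list("aaa"), list("bbb")) == 0.0

    def test_ten_of_eleven(self):
        pred = ["A"] * 10 + ["B"]
        truth = ["A"] * 11
        assert accuracy(pred, truth) == pytest.approx(10 / 11)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy(["a"], ["a", "b"])

    def test_binomial_pvalue_against_majority(self):
        # 10/11 correct against a 6/11 majority-class rate
        p = accuracy_pvalue(10, 11, 6 / 11)
        from scipy import stats

        assert p == pytest.approx(stats.binom.sf(9, 11, 6 / 11))
        assert p < 0.05 < accuracy_pvalue(7, 11, 6 / 11)
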