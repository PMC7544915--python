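import numpy as np
import pandas as pd
import pytest

import rewirenet as rn
from rewirenet.io import ExpressionMatrix, Unit
from rewirenet.rewiring import (
    EFDRResult,
    RewireClass,
    RewireThresholds,
    classify_edge,
    classify_matrix,
    consensus_rewired_edges,
    groupwise_correlation,
)
from rewirenet.simulate import null_spec, planted_rewiring_spec, simulate_dataset

TH = RewireThresholds()


class TestClassifyEdge:
    @pytest.mark.parametrize(
        "rf,rr,expected",
        [
            (0.995, 0.05, RewireClass.GAINED_POSITIVE),
            (-0.995, 0.05, RewireClass.GAINED_NEGATIVE),
            (0.05, 0.995, RewireClass.LOST_POSITIVE),
            (0.05, -0.995, RewireClass.LOST_NEGATIVE),
            (0.98, -0.98, RewireClass.INVERTED),  # gap 1.96 > 1.95
            (0.5, 0.5, RewireClass.NONE),
            (0.99, 0.0, RewireClass.NONE),  # |r| must strictly exceed 0.99
            (0.995, 0.1, RewireClass.NONE),  # band is strict
            (0.975, -0.975, RewireClass.NONE),  # gap 1.95 not > 1.95
        ],
    )
    def test_rule_regions(self, rf, rr, expected):
        assert classify_edge(rf, rr, TH) is expected

    def test_antisymmetry_gained_lost(self):
        rng = np.random.default_rng(0)
        rf = rng.uniform(-1, 1, 2000)
        rr = rng.uniform(-1, 1, 2000)
        fwd = classify_matrix(rf, rr, TH)
        rev = classify_matrix(rr, rf, TH)
        swap = {
            int(RewireClass.GAINED_POSITIVE): int(RewireClass.LOST_POSITIVE),
            int(RewireClass.GAINED_NEGATIVE): int(RewireClass.LOST_NEGATIVE),
            int(RewireClass.LOST_POSITIVE): int(RewireClass.GAINED_POSITIVE),
            int(RewireClass.LOST_NEGATIVE): int(RewireClass.GAINED_NEGATIVE),
            int(RewireClass.INVERTED): int(RewireClass.INVERTED),
            int(RewireClass.NONE): int(RewireClass.NONE),
        }
        np.testing.assert_array_equal(rev, np.vectorize(swap.get)(fwd))

    def test_nan_yields_none(self):
        assert classify_edge(np.nan, 0.0, TH) is RewireClass.NONE

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            RewireThresholds(inverted_gap=2.5)
        with pytest.raises(ValueError):
            RewireThresholds(present_abs_r=0.05, absent_band=0.1)


class TestGroupwiseCorrelation:
    def _em_from_groups(self, per_group, samples):
        cols, vals = [], []
        for g in ("AI_PREG", "NB_PREG", "NON_PREG"):
            ids = samples.group_samples(g)
            cols += ids
            vals.append(per_group[g])
        arr = np.hstack(vals)
        return ExpressionMatrix(
            pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=cols),
            Unit.LOG2_CPM,
        )

    def test_collinear_everywhere(self, three_group_samples):
        rng = np.random.default_rng(1)
        per_group = {}
        for g, n in (("AI_PREG", 6), ("NB_PREG", 6), ("NON_PREG", 5)):
            x = rng.normal(size=n)
            per_group[g] = np.vstack([x, 2 * x + 1])
        gct = groupwise_correlation(self._em_from_groups(per_group, three_group_samples), three_group_samples)
        for g in gct.corr:
            assert gct.corr[g][0, 1] == pytest.approx(1.0)

    def test_group_specific_correlation(self, three_group_samples):
        rng = np.random.default_rng(2)
        per_group = {
            "AI_PREG": rng.normal(size=(2, 6)),
            "NB_PREG": rng.normal(size=(2, 6)),
        }
        x = rng.normal(size=5)
        per_group["NON_PREG"] = np.vstack([x, 3 * x])
        gct = groupwise_correlation(self._em_from_groups(per_group, three_group_samples), three_group_samples)
        assert gct.corr["NON_PREG"][0, 1] == pytest.approx(1.0)
        assert abs(gct.corr["AI_PREG"][0, 1]) < 1.0

    def test_zero_variance_pair_flagged(self, three_group_samples):
        rng = np.random.default_rng(3)
        per_group = {g: rng.normal(size=(2, n)) for g, n in
                     (("AI_PREG", 6), ("NB_PREG", 6), ("NON_PREG", 5))}
        per_group["NON_PREG"][0] = 7.0  # constant within one group
        gct = groupwise_correlation(self._em_from_groups(per_group, three_group_samples), three_group_samples)
        assert not gct.valid[0, 1]
        assert gct.to_frame().empty


class TestConsensusRule:
    def _gct(self, r_np, r_ai, r_nb):
        ids = np.array(["a", "b"])
        mk = lambda r: np.array([[1.0, r], [r, 1.0]])
        from rewirenet.rewiring import GroupCorrelationTable

        return GroupCorrelationTable(
            ids,
            {"AI_PREG": mk(r_ai), "NB_PREG": mk(r_nb), "NON_PREG": mk(r_np)},
            {"AI_PREG": 6, "NB_PREG": 6, "NON_PREG": 5},
        )

    @pytest.mark.parametrize(
        "r_np,r_ai,r_nb,expected",
        [
            (0.995, 0.02, -0.05, "GAINED_POSITIVE"),
            (-0.995, 0.0, 0.0, "GAINED_NEGATIVE"),
        ],
    )
    def test_same_class_in_both_contrasts(self, r_np, r_ai, r_nb, expected):
        out = consensus_rewired_edges(self._gct(r_np, r_ai, r_nb))
        assert len(out) == 1 and out.rewire_class.iloc[0] == expected

    def test_one_contrast_none_not_reported(self):
        out = consensus_rewired_edges(self._gct(0.995, 0.02, 0.5))
        assert out.empty or (out.rewire_class == "NONE").all()

    def test_discordant_flagged_and_separable(self):
        # gained vs one reference, inverted vs the other
        out = consensus_rewired_edges(self._gct(0.995, 0.05, -0.96))
        assert out.discordant.any()


class TestEFDR:
    def test_efdr_arithmetic(self):
        res = EFDRResult.from_counts(10, np.array([0, 1, 0, 1]))
        assert res.efdr == pytest.approx(0.05)
        assert EFDRResult.from_counts(5, np.zeros(3)).efdr == 0.0
        assert EFDRResult.from_counts(0, np.ones(3)).efdr == 1.0  # undefined ratio

    def test_reproducible_with_seed(self):
        ds = simulate_dataset(planted_rewiring_spec(n_edges=5, n_genes=60, seed=2))
        em = rn.log2_cpm(ds.mrna)
        a = rn.efdr_rewiring(em, ds.samples, n_randomizations=20, seed=5)
        b = rn.efdr_rewiring(em, ds.samples, n_randomizations=20, seed=5)
        assert a.efdr == b.efdr and a.mean_scrambled == b.mean_scrambled

    def test_null_data_efdr_large(self):
        # enough genes that observed and scrambled counts are both stable
        ds = simulate_dataset(null_spec(n_genes=600, n_mirna=5, seed=3))
        em = rn.log2_cpm(ds.mrna)
        res = rn.efdr_rewiring(em, ds.samples, n_randomizations=60, seed=7)
        # no group structure: scrambled counts comparable to observed
        assert res.efdr >= 0.5


class TestPlantedRecovery:
    def test_recovers_planted_consensus_edges(self):
        ds = simulate_dataset(planted_rewiring_spec(n_edges=30, n_genes=300, seed=3))
        em = rn.log2_cpm(ds.mrna)
        gct = groupwise_correlation(em, ds.samples)
        rew = consensus_rewired_edges(gct)
        truth = set(map(tuple, ds.truth["rewired_edges"][["feature_a", "feature_b"]].to_numpy()))
        found = set(map(tuple, rew.loc[~rew.discordant, ["feature_a", "feature_b"]].to_numpy()))
        assert len(truth & found) >= 0.9 * len(truth)

    def test_all_classes_recovered_with_correct_label(self):
        classes = ("GAINED_POSITIVE", "GAINED_NEGATIVE", "LOST_POSITIVE",
                   "LOST_NEGATIVE", "INVERTED")
        ds = simulate_dataset(
            planted_rewiring_spec(n_edges=15, n_genes=300, classes=classes, seed=5)
        )
        em = rn.log2_cpm(ds.mrna)
        rew = consensus_rewired_edges(groupwise_correlation(em, ds.samples))
        merged = ds.truth["rewired_edges"].merge(
            rew, on=["feature_a", "feature_b"], how="left", suffixes=("_true", "")
        )
        match = (merged.rewire_class_true == merged.rewire_class).mean()
        assert match >= 0.9
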