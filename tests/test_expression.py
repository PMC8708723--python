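"""CPM, filtering, TMM, DE thresholding, clustering, bound/DE overlap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regnet.expression import (
    DEParams,
    bound_de_overlap,
    call_de,
    cpm,
    filter_low_expression,
    nb_exact_test,
    tmm_factors,
    zscore_cluster,
)
from regnet.genome import ValidationError
from regnet.simulate import SimConfig, simulate_counts, simulate_tmm_fixture


class TestCpm:
    def test_direct_arithmetic(self):
        counts = pd.DataFrame({"s1": [10, 90]}, index=["g1", "g2"])
        out = cpm(counts)
        assert out["s1"].tolist() == [1e5, 9e5]

    def test_all_zero_gene_stays_zero(self):
        counts = pd.DataFrame({"s1": [0, 100], "s2": [0, 50]}, index=["g0", "g1"])
        assert (cpm(counts).loc["g0"] == 0).all()

    def test_matches_formula_on_random_matrix(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)),
                              columns=list("abcd"))
        factors = rng.uniform(0.5, 2.0, 4)
        out = cpm(counts, norm_factors=factors)
        lib = counts.sum(axis=0).to_numpy()
        expected = counts.to_numpy() / (lib * factors) * 1e6
        assert np.allclose(out.to_numpy(), expected)

    def test_columns_sum_to_a_million_at_unit_factors(self, rng):
        counts = pd.DataFrame(rng.integers(1, 500, size=(100, 3)))
        assert cpm(counts).sum(axis=0).to_numpy() == pytest.approx([1e6] * 3)

    def test_zero_library_is_an_error(self):
        counts = pd.DataFrame({"s1": [0, 0]})
        with pytest.raises(ValidationError):
            cpm(counts)


class TestFilter:
    def test_exactly_three_samples_retained(self):
        cpm_df = pd.DataFrame(
            [[2, 2, 2, 0, 0, 0, 0, 0]], index=["g"], columns=list("abcdefgh")
        )
        assert list(filter_low_expression(cpm_df)) == ["g"]

    def test_two_samples_removed(self):
        cpm_df = pd.DataFrame([[2, 2, 0.5, 0, 0]], index=["g"])
        with pytest.warns(UserWarning):
            assert list(filter_low_expression(cpm_df)) == []

    def test_all_below_threshold_warns(self):
        cpm_df = pd.DataFrame([[0.1, 0.1, 0.1]], index=["g"])
        with pytest.warns(UserWarning, match="every gene"):
            retained = filter_low_expression(cpm_df)
        assert len(retained) == 0


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(np.tile(np.arange(1, 201)[:, None], (1, 3)))
        assert tmm_factors(counts) == pytest.approx([1.0, 1.0, 1.0])

    def test_doubled_sample_closed_form(self, rng):
        # all M-values equal log2(2) against equal nominal library sizes,
        # so the factor ratio must be exactly 2 (trimming changes nothing)
        base = rng.integers(10, 1000, size=1000)
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        nominal = np.array([base.sum(), base.sum()])
        f = tmm_factors(counts, lib_sizes=nominal)
        assert f[1] / f[0] == pytest.approx(2.0, rel=0.01)

    def test_planted_factors_recovered_within_five_percent(self, rng):
        counts, nominal, true = simulate_tmm_fixture(rng, factors=(1.0, 1.5, 0.7))
        f = tmm_factors(counts, lib_sizes=nominal)
        assert np.max(np.abs(f / true - 1)) < 0.05

    def test_geometric_mean_is_one(self, rng):
        counts, nominal, _ = simulate_tmm_fixture(rng, factors=(0.5, 1.0, 2.0, 1.2))
        f = tmm_factors(counts, lib_sizes=nominal)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_no_shared_expression_is_an_error(self):
        counts = pd.DataFrame({"a": [5, 0, 3], "b": [0, 7, 0]})
        with pytest.raises(ValidationError, match="shares no expressed"):
            tmm_factors(counts, reference=0)


class TestZscoreCluster:
    def test_proportional_profiles_merge_first(self):
        cpm_df = pd.DataFrame(
            {
                "s1": [1.0, 10.0, 5.0],
                "s2": [2.0, 20.0, 1.0],
                "s3": [3.0, 30.0, 9.0],
            },
            index=["gA", "gB", "gC"],
        )
        out = zscore_cluster(cpm_df, ["gA", "gB", "gC"])
        # gA and gB have identical Z-profiles -> distance 0, first merge
        first_merge = out["gene_linkage"][0]
        assert first_merge[2] == pytest.approx(0.0)
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}

    def test_single_sample_is_an_error(self):
        cpm_df = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValidationError):
            zscore_cluster(cpm_df, ["a", "b"])

    def test_zero_variance_gene_dropped_with_warning(self):
        cpm_df = pd.DataFrame(
            {"s1": [1.0, 5.0, 2.0], "s2": [2.0, 5.0, 1.0], "s3": [3.0, 5.0, 3.0]},
            index=["a", "flat", "b"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            out = zscore_cluster(cpm_df, ["a", "flat", "b"])
        assert "flat" not in out["zscores"].index

    def test_planted_blocks_separate_at_k2(self, rng):
        n = 20
        up = rng.normal(0, 0.1, size=(n, 8)) + np.r_[np.zeros(4), np.ones(4)]
        down = rng.normal(0, 0.1, size=(n, 8)) + np.r_[np.ones(4), np.zeros(4)]
        cpm_df = pd.DataFrame(
            np.vstack([up, down]) + 5.0,
            index=[f"up{i}" for i in range(n)] + [f"dn{i}" for i in range(n)],
        )
        out = zscore_cluster(cpm_df, list(cpm_df.index))
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(out["gene_linkage"], 2, criterion="maxclust")
        genes = list(out["zscores"].index)
        up_labels = {l for g, l in zip(genes, labels) if g.startswith("up")}
        dn_labels = {l for g, l in zip(genes, labels) if g.startswith("dn")}
        assert up_labels.isdisjoint(dn_labels)
        assert len(up_labels) == len(dn_labels) == 1


class TestCallDe:
    TABLE = pd.DataFrame(
        {
            "gene": ["gUp", "gNsFdr", "gNsFc", "gDown"],
            "log2FC": [0.3, 3.0, -0.1, -0.5],
            "FDR": [0.04, 0.06, 0.01, 0.001],
        }
    )

    def test_threshold_examples(self):
        up, down = call_de(self.TABLE)
        assert up == {"gUp"}
        assert down == {"gDown"}

    def test_missing_column_is_a_schema_error(self):
        with pytest.raises(ValidationError, match="missing required column"):
            call_de(pd.DataFrame({"gene": ["a"], "log2FC": [1.0]}))

    def test_relaxing_fdr_never_shrinks_sets(self, rng):
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(200)],
                "log2FC": rng.normal(0, 1, 200),
                "FDR": rng.uniform(0, 1, 200),
            }
        )
        prev_up, prev_down = set(), set()
        for fdr in (0.01, 0.05, 0.2, 0.9):
            up, down = call_de(table, DEParams(fdr_max=fdr))
            assert prev_up <= up and prev_down <= down
            assert up.isdisjoint(down)
            prev_up, prev_down = up, down


class TestNbExactTest:
    def test_planted_de_detected_with_high_recall(self):
        cfg = SimConfig(seed=42, n_genes=400, de_fraction=0.2,
                        de_log2fc=2.0, low_expression_fraction=0.0)
        cd = simulate_counts(cfg)
        de = nb_exact_test(cd.counts, cd.groups)
        up, down = call_de(de)
        truth = cd.truth.set_index("gene")
        de_true = set(truth.index[truth.true_de != "ns"])
        called = up | down
        assert len(called & de_true) / len(de_true) >= 0.9

    def test_log2fc_sign_follows_treatment_group(self):
        cfg = SimConfig(seed=43, n_genes=300, de_fraction=0.2,
                        de_log2fc=2.0, low_expression_fraction=0.0)
        cd = simulate_counts(cfg)
        de = nb_exact_test(cd.counts, cd.groups).set_index("gene")
        truth = cd.truth.set_index("gene")
        up_true = truth.index[truth.true_de == "up"]
        assert (de.loc[up_true, "log2FC"] > 0).mean() > 0.95


class TestBoundDeOverlap:
    def test_disjoint_sets_fraction_zero(self):
        out = bound_de_overlap({"a", "b"}, set(), {"c"}, {"a", "b", "c", "d"})
        assert out["bound_down_fraction"] == 0.0

    def test_bound_subset_of_down_fraction_one(self):
        out = bound_de_overlap({"a", "b"}, set(), {"a", "b", "c"}, {"a", "b", "c", "d"})
        assert out["bound_down_fraction"] == 1.0

    def test_empty_bound_set_is_an_error(self):
        with pytest.raises(ValidationError):
            bound_de_overlap(set(), {"a"}, {"b"}, {"a", "b"})

    def test_planted_six_percent_fixture(self):
        universe = [f"g{i:04d}" for i in range(1000)]
        bound = set(universe[:100])
        down = set(universe[94:144])  # overlap of exactly 6 genes
        out = bound_de_overlap(bound, set(), down, universe)
        assert out["bound_down_fraction"] == pytest.approx(0.06)
        assert out["n_bound_down"] == 6

    def test_hypergeometric_matches_exact_enumeration(self, rng):
        # universes up to 30: compare against direct combinatorial enumeration
        for _ in range(30):
            M = int(rng.integers(5, 31))
            K = int(rng.integers(1, M + 1))
            n = int(rng.integers(1, M + 1))
            universe = [f"g{i}" for i in range(M)]
            down = set(rng.choice(universe, size=K, replace=False))
            bound = set(rng.choice(universe, size=n, replace=False))
            k = len(bound & down)
            out = bound_de_overlap(bound, set(), down, universe)
            exact = sum(
                math.comb(K, j) * math.comb(M - K, n - j) / math.comb(M, n)
                for j in range(k, min(K, n) + 1)
            )
            assert out["p_hypergeom_down"] == pytest.approx(exact, rel=1e-9)

    def test_contingency_table_margins(self):
        universe = [f"g{i}" for i in range(50)]
        bound = set(universe[:20])
        down = set(universe[10:25])
        out = bound_de_overlap(bound, set(), down, universe)
        table = out["table_down"]
        assert sum(map(sum, table)) == 50
        assert table[0][0] + table[0][1] == 20
        assert table[0][0] + table[1][0] == 15
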