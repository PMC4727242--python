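"""Transcription Correlation Score: oracle equivalence, null calibration,
threshold semantics and co-amplified-block recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from locuspipe import simulate as sim
from locuspipe import tcs


def ordered_expression(matrix: np.ndarray, chroms=None) -> tcs.OrderedExpression:
    genes = [f"g{i:03d}" for i in range(matrix.shape[0])]
    chroms = chroms or ["chr1"] * len(genes)
    pos = pd.DataFrame({"chrom": chroms,
                        "start": np.arange(len(genes)) * 1000,
                        "end": np.arange(len(genes)) * 1000 + 100,
                        "gene": genes})
    return tcs.OrderedExpression(
        matrix=pd.DataFrame(matrix, index=genes), positions=pos)


def naive_tcs(matrix: np.ndarray, n: int) -> np.ndarray:
    """Double-loop oracle built on scipy's spearmanr."""
    g = matrix.shape[0]
    out = np.zeros(g)
    for i in range(g):
        for j in range(max(0, i - n), min(g, i + n + 1)):
            if j != i:
                out[i] += stats.spearmanr(matrix[i], matrix[j]).statistic
    return out


class TestComputeTcs:
    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(25, 12))
        for n in (1, 3, 10):
            got = tcs.compute_tcs(ordered_expression(x), n=n).per_gene_tcs
            np.testing.assert_allclose(got.to_numpy(), naive_tcs(x, n),
                                       atol=1e-10)

    def test_three_gene_hand_case(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 1.0, 4.0, 3.0],
                      [4.0, 3.0, 2.0, 1.0]])
        res = tcs.compute_tcs(ordered_expression(x), n=1)
        # middle gene: rho with row0 = 0.6, with row2 = -0.6
        assert res.per_gene_tcs.iloc[1] == pytest.approx(0.0, abs=1e-12)
        assert res.per_gene_tcs.iloc[0] == pytest.approx(0.6, abs=1e-12)

    def test_perfectly_coherent_region_saturates(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        x = np.array([base + 1e-9 * rng.normal(size=30) for _ in range(21)])
        res = tcs.compute_tcs(ordered_expression(x), n=10)
        assert res.per_gene_tcs.iloc[10] == pytest.approx(20.0, abs=1e-6)
        assert res.neighbours_used.iloc[10] == 20

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1000, 50))
        res = tcs.compute_tcs(ordered_expression(x), n=10)
        assert abs(res.per_gene_tcs.mean()) < 0.5

    def test_chromosome_edges_truncate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 10))
        res = tcs.compute_tcs(ordered_expression(x), n=10)
        assert res.neighbours_used.iloc[0] == 10
        assert res.neighbours_used.iloc[15] == 20

    def test_single_gene_chromosome_flagged(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(5, 8))
        oe = ordered_expression(x, chroms=["chr1"] * 4 + ["chr2"])
        res = tcs.compute_tcs(oe, n=2)
        assert np.isnan(res.per_gene_tcs.iloc[4])
        assert res.neighbours_used.iloc[4] == 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            tcs.compute_tcs(ordered_expression(np.zeros((5, 2))), n=1)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(15, 20))
        a = tcs.compute_tcs(ordered_expression(x), n=3).per_gene_tcs
        b = tcs.compute_tcs(ordered_expression(np.exp(x)), n=3).per_gene_tcs
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_invariant_to_genome_reversal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(15, 20))
        fwd = tcs.compute_tcs(ordered_expression(x), n=3).per_gene_tcs
        rev = tcs.compute_tcs(ordered_expression(x[::-1]), n=3).per_gene_tcs
        np.testing.assert_allclose(fwd.to_numpy(), rev.to_numpy()[::-1],
                                   atol=1e-10)


class TestThreshold:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        oe = ordered_expression(rng.normal(size=(200, 10)))
        a = tcs.tcs_threshold(oe, n=5, p=0.01, n_randomizations=3, seed=42)
        b = tcs.tcs_threshold(oe, n=5, p=0.01, n_randomizations=3, seed=42)
        assert a == b

    def test_median_at_half(self):
        rng = np.random.default_rng(8)
        oe = ordered_expression(rng.normal(size=(300, 20)))
        thr = tcs.tcs_threshold(oe, n=5, p=0.5, n_randomizations=2, seed=0)
        res = tcs.compute_tcs(oe, n=5)
        frac = (res.per_gene_tcs > thr).mean()
        assert 0.35 <= frac <= 0.65

    def test_insufficient_null_size_rejected(self):
        rng = np.random.default_rng(9)
        oe = ordered_expression(rng.normal(size=(50, 10)))
        with pytest.raises(ValueError, match="1000"):
            tcs.tcs_threshold(oe, n=5, p=0.001, n_randomizations=1, seed=0)


class TestProbesetReduction:
    def matrix(self):
        return pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0],
             [5.0, 5.0, 5.0, 5.0],
             [2.0, 9.0, 1.0, 7.0]],
            index=["ps1", "ps2", "ps3"])

    def positions(self):
        return pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [100, 5000],
                             "end": [200, 5100], "gene": ["A", "B"]})

    def test_highest_iqr_probeset_kept(self):
        oe = tcs.reduce_to_one_probeset(
            self.matrix(), {"ps1": "A", "ps2": "A", "ps3": "B"},
            self.positions())
        assert list(oe.matrix.index) == ["A", "B"]
        np.testing.assert_allclose(oe.matrix.loc["A"], [1, 2, 3, 4])

    def test_iqr_tie_breaks_lexicographically(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["psB", "psA"])
        pos = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1],
                            "gene": ["G"]})
        oe = tcs.reduce_to_one_probeset(m, {"psA": "G", "psB": "G"}, pos)
        # both probesets have identical IQR; psA wins on id order
        np.testing.assert_allclose(oe.matrix.loc["G"], m.loc["psA"])

    def test_gene_without_position_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="without genomic position"):
            oe = tcs.reduce_to_one_probeset(
                self.matrix(), {"ps1": "A", "ps2": "A", "ps3": "C"},
                self.positions())
        assert list(oe.matrix.index) == ["A"]


class TestMapAndRecovery:
    def test_coamplified_block_forms_contiguous_run_lost_in_unchanged(self):
        spec = sim.CohortSpec(n_samples=200, n_genes=120, seed=21,
                              cnv_block=(50, 71, 0.25, 0.15, 2.0))
        data = sim.make_cohort(spec)
        oe = tcs.OrderedExpression(matrix=data["expression"],
                                   positions=data["positions"])
        thr = tcs.tcs_threshold(oe, n=10, p=0.005, n_randomizations=5, seed=21)
        table = tcs.tcs_map(tcs.compute_tcs(oe, n=10), data["positions"],
                            threshold=thr)
        above = table.loc[table["above_threshold"], "gene"]
        block_genes = {f"g{i:05d}" for i in range(50, 71)}
        # interior block genes dominate a single contiguous run
        assert block_genes & set(above)
        assert table.loc[table["above_threshold"], "peak_region"].nunique() == 1

        unchanged = data["labels"].index[data["labels"] == "unchanged"]
        oe_u = tcs.OrderedExpression(matrix=data["expression"][unchanged],
                                     positions=data["positions"])
        thr_u = tcs.tcs_threshold(oe_u, n=10, p=0.005, n_randomizations=5,
                                  seed=21)
        table_u = tcs.tcs_map(tcs.compute_tcs(oe_u, n=10), data["positions"],
                              threshold=thr_u)
        assert not (table_u.loc[table_u["above_threshold"], "gene"]
                    .isin(block_genes).any())

    def test_map_is_position_sorted_with_flags(self):
        rng = np.random.default_rng(10)
        oe = ordered_expression(rng.normal(size=(40, 10)))
        res = tcs.compute_tcs(oe, n=3)
        table = tcs.tcs_map(res, oe.positions, threshold=np.inf)
        assert (table["start"].diff().dropna() > 0).all()
        assert not table["above_threshold"].any()
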