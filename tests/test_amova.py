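import numpy as np
import pytest

from refugia.popgen import (
    DistanceSpec,
    GenotypeTable,
    PopulationPartition,
    SequenceAlignment,
    amova,
    diploid_fst,
    variance_components,
)
from tests.conftest import make_partition


def freq_fst_oracle(alleles: np.ndarray, groups: np.ndarray) -> float:
    """Frequency F_ST from allele-count sums of squares (independent path).

    Uses sum_{i,j in g} 1[a_i != a_j] = n_g^2 - sum_k c_gk^2 and the
    standard one-level variance-component algebra.
    """
    N = len(alleles)
    names = sorted(set(groups))
    G = len(names)
    total_counts = np.array([(alleles == a).sum() for a in set(alleles)])
    ss_total = (N - np.sum(total_counts**2) / N) / 2.0
    ss_within = 0.0
    sizes = []
    for g in names:
        sub = alleles[groups == g]
        n_g = len(sub)
        sizes.append(n_g)
        c = np.array([(sub == a).sum() for a in set(sub)])
        ss_within += (n_g - np.sum(c**2) / n_g) / 2.0
    sizes = np.array(sizes, dtype=float)
    sigma_w = ss_within / (N - G)
    n_prime = (N - np.sum(sizes**2) / N) / (G - 1)
    sigma_a = ((ss_total - ss_within) / (G - 1) - sigma_w) / n_prime
    return sigma_a / (sigma_a + sigma_w)


class TestAmova:
    def test_fixed_difference_phi_is_one(self):
        aln = SequenceAlignment(
            [f"s{i}" for i in range(6)],
            ["AAAA"] * 3 + ["TTTT"] * 3,
        )
        part = make_partition(["x"] * 3 + ["y"] * 3)
        res = amova(aln, part, DistanceSpec("identity"), n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.2

    def test_identity_equals_frequency_fst_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(8, 21))
            alleles = rng.integers(0, 4, size=n)
            groups = rng.permutation(
                np.array(["x"] * (n // 2) + ["y"] * (n - n // 2))
            )
            if len(set(alleles[groups == "x"])) == 0:
                continue
            seqs = ["ACGT"[a] * 4 for a in alleles]
            aln = SequenceAlignment([f"s{i}" for i in range(n)], seqs)
            part = make_partition(list(groups))
            res = amova(aln, part, DistanceSpec("identity"), n_perm=0)
            expected = freq_fst_oracle(alleles, groups)
            assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_panmictic_split_phi_near_zero(self):
        rng = np.random.default_rng(7)
        stats = []
        for rep in range(30):
            alleles = rng.integers(0, 6, size=24)
            codes = ["AA", "AC", "AG", "AT", "CA", "CC"]
            seqs = [codes[a] * 3 for a in alleles]
            aln = SequenceAlignment([f"s{i}" for i in range(24)], seqs)
            part = make_partition(["x"] * 12 + ["y"] * 12)
            res = amova(aln, part, DistanceSpec("identity"), n_perm=0)
            stats.append(res.statistic)
        assert abs(np.mean(stats)) < 0.05

    def test_single_group_rejected(self):
        aln = SequenceAlignment(["a", "b"], ["AA", "AT"])
        part = make_partition(["x", "x"])
        with pytest.raises(ValueError, match="two groups"):
            amova(aln, part, DistanceSpec("identity"), n_perm=0)

    def test_bad_matrix_rejected(self):
        part = make_partition(["x", "y", "x", "y"])
        asym = np.arange(16, dtype=float).reshape(4, 4)
        with pytest.raises(ValueError, match="symmetric"):
            amova(asym, part, DistanceSpec("identity"), n_perm=0)

    def test_pairwise_matrix_shape(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(12)]
        aln = SequenceAlignment([f"s{i}" for i in range(12)], seqs)
        part = make_partition(["x"] * 4 + ["y"] * 4 + ["z"] * 4)
        res = amova(aln, part, DistanceSpec("identity"), n_perm=19, seed=0)
        assert res.pairwise.shape == (3, 3)
        assert np.allclose(
            res.pairwise.to_numpy(float),
            res.pairwise.to_numpy(float).T,
            equal_nan=True,
        )

    def test_statistic_at_most_one(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            base = rng.choice(list("ACGT"), 40)
            seqs = []
            for _ in range(10):
                s = base.copy()
                for pos in rng.choice(40, size=3, replace=False):
                    s[pos] = rng.choice(list("ACGT"))
                seqs.append("".join(s))
            aln = SequenceAlignment([f"s{i}" for i in range(10)], seqs)
            part = make_partition(["x"] * 5 + ["y"] * 5)
            res = amova(aln, part, DistanceSpec("k2p-gamma", 0.42), n_perm=0)
            assert res.statistic <= 1.0 + 1e-12


class TestDiploidFst:
    def _table(self, genos, loci=("L1",)):
        ids = [f"s{i}" for i in range(len(genos))]
        calls = {
            l: np.array(
                [[str(g[li][0]), str(g[li][1])] for g in genos], dtype=object
            )
            for li, l in enumerate(loci)
        }
        return GenotypeTable(ids, calls)

    def test_fixed_demes_fst_one(self):
        genos = [[("a", "a")]] * 4 + [[("b", "b")]] * 4
        table = self._table(genos)
        part = make_partition(["x"] * 4 + ["y"] * 4)
        res = diploid_fst(table, part, n_perm=99, seed=1)
        assert res.statistic == pytest.approx(1.0)

    def test_identical_frequencies_nonpositive(self):
        genos = [[("a", "b")]] * 8
        table = self._table(genos)
        part = make_partition(["x"] * 4 + ["y"] * 4)
        res = diploid_fst(table, part, n_perm=0)
        assert res.statistic <= 0.0  # reported unclamped

    def test_all_monomorphic_rejected(self):
        genos = [[("a", "a")]] * 8
        table = self._table(genos)
        part = make_partition(["x"] * 4 + ["y"] * 4)
        with pytest.raises(ValueError, match="monomorphic"):
            diploid_fst(table, part, n_perm=0)

    def test_matches_identity_amova_on_gene_copies(self):
        # dual route: diploid counts path vs the distance-matrix AMOVA path
        rng = np.random.default_rng(5)
        n = 10
        genos = [[(rng.integers(0, 3), rng.integers(0, 3))] for _ in range(n)]
        table = self._table(genos)
        part = make_partition(["x"] * 5 + ["y"] * 5)
        res = diploid_fst(table, part, n_perm=0)
        # expand to gene copies and run sequence-identity AMOVA
        copies = []
        groups = []
        for i, g in enumerate(genos):
            for a in g[0]:
                copies.append("ACG"[int(a)] * 2)
                groups.append("x" if i < 5 else "y")
        aln = SequenceAlignment([f"c{i}" for i in range(2 * n)], copies)
        ref = amova(
            aln, make_partition(groups, prefix="c"), DistanceSpec("identity"),
            n_perm=0,
        )
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)

    def test_multilocus_missing_data(self):
        genos = [
            [("a", "a"), ("x", "y")],
            [("a", "b"), (".", ".")],
            [("b", "b"), ("x", "x")],
            [("a", "a"), ("y", "y")],
            [("b", "a"), ("x", "y")],
            [("b", "b"), ("y", "y")],
        ]
        table = self._table(genos, loci=("L1", "L2"))
        part = make_partition(["x"] * 3 + ["y"] * 3)
        res = diploid_fst(table, part, n_perm=19, seed=2)
        assert np.isfinite(res.statistic)
        assert 0 < res.p_value <= 1
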