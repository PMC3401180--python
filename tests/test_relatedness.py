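"""Queller-Goodnight relatedness estimator, matrix summaries, bootstrap."""

import numpy as np
import pytest

from nestkin import relatedness as rel
from nestkin import synthetic_data as sd
from nestkin.diversity import AlleleFrequencyTable
from nestkin.genotype_io import LocusDef

from .oracles import qg_direct


def _ref(freqs_per_locus):
    return [
        AlleleFrequencyTable(f"L{i}", f, 100) for i, f in enumerate(freqs_per_locus)
    ]


class TestEstimator:
    def test_identical_genotypes_give_unity(self):
        ref = _ref([{1: 0.5, 2: 0.3, 3: 0.2}] * 4)
        x = [(1, 2), (1, 1), (2, 3), (1, 3)]
        assert rel.qg_relatedness(x, x, ref) == pytest.approx(1.0)
        assert rel.qg_relatedness(x, x, ref, symmetric="pooled") == pytest.approx(1.0)

    def test_single_locus_matches_direct_transcription(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.dirichlet([1.0] * 4)
            freqs = {a + 1: float(p[a]) for a in range(4)}
            gx = tuple(sorted(rng.choice([1, 2, 3, 4], 2, p=p)))
            gy = tuple(sorted(rng.choice([1, 2, 3, 4], 2, p=p)))
            got = rel.qg_relatedness([gx], [gy], _ref([freqs]))
            assert got == pytest.approx(qg_direct(gx, gy, freqs), abs=1e-12)

    def test_unrelated_queens_average_near_zero(self):
        cfg = sd.SimConfig(n_colonies=200, n_loci=15, workers_per_colony=0, seed=9)
        _, truth = sd.simulate_population(cfg)
        queens = truth.queens
        ids = list(queens)
        loci = [LocusDef(f"L{i}", i + 1) for i in range(15)]
        ref = rel.reference_frequencies(queens, loci)
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(300):
            i, j = rng.choice(len(ids), 2, replace=False)
            vals.append(rel.qg_relatedness(queens[ids[i]], queens[ids[j]], ref))
        assert abs(np.mean(vals)) < 0.02

    def test_mother_daughter_pairs_average_half(self):
        """First-degree queen pairs: mean R ~ 0.5 over replicates."""
        vals = []
        for seed in range(250):
            cfg = sd.SimConfig(
                n_colonies=20, n_loci=15, workers_per_colony=0,
                scenario="mother-daughter", seed=seed,
            )
            _, truth = sd.simulate_population(cfg)
            loci = [LocusDef(f"L{i}", i + 1) for i in range(15)]
            ref = rel.reference_frequencies(truth.queens, loci)
            a, b, _ = truth.kin_pairs[0]
            vals.append(rel.qg_relatedness(truth.queens[a], truth.queens[b], ref))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


class TestMatrix:
    def test_two_identical_colonies(self):
        queens = {"a": [(1, 2), (3, 3)], "b": [(1, 2), (3, 3)], "c": [(2, 2), (3, 4)]}
        loci = [LocusDef("L1", 1), LocusDef("L2", 2)]
        m = rel.relatedness_matrix(queens, loci)
        assert m.pair("a", "b") == pytest.approx(1.0)
        assert m.values == pytest.approx(m.values.T)

    def test_permutation_invariance(self, reference_queens):
        loci, queens = reference_queens
        m1 = rel.relatedness_matrix(queens, loci)
        ids = list(queens)[::-1]
        m2 = rel.relatedness_matrix({i: queens[i] for i in ids}, loci)
        for x, y in [("3", "4"), ("19", "20"), ("1", "17")]:
            assert m1.pair(x, y) == pytest.approx(m2.pair(x, y))

    def test_mean_and_se_hand_example(self):
        m = rel.RelatednessMatrix(
            ids=["a", "b", "c"],
            values=np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]]),
            reference=[],
        )
        mean, se = rel.mean_relatedness(m)
        assert mean == pytest.approx((0.2 + 0.4 + 0.6) / 3)
        assert se == pytest.approx(np.std([0.2, 0.4, 0.6], ddof=1) / np.sqrt(3))

    def test_constant_matrix_zero_se(self):
        m = rel.RelatednessMatrix(
            ids=["a", "b", "c"], values=np.full((3, 3), 0.3), reference=[]
        )
        mean, se = rel.mean_relatedness(m)
        assert (mean, se) == (pytest.approx(0.3), pytest.approx(0.0))

    def test_mean_is_minus_one_over_n_minus_one(self, reference_queens):
        """Whole-sample reference frequencies force mean R = -1/(N-1)."""
        loci, queens = reference_queens
        m = rel.relatedness_matrix(queens, loci)
        mean, _ = rel.mean_relatedness(m)
        assert mean == pytest.approx(-1 / 19, abs=1e-9)


class TestBootstrap:
    def test_deterministic_given_seed(self, reference_queens):
        loci, queens = reference_queens
        ci1 = rel.bootstrap_ci(queens, loci, reps=150, seed=7)
        ci2 = rel.bootstrap_ci(queens, loci, reps=150, seed=7)
        assert ci1 == ci2

    def test_identical_loci_collapse(self):
        queens = {"a": [(1, 2)] * 4, "b": [(1, 3)] * 4, "c": [(2, 3)] * 4}
        loci = [LocusDef(f"L{i}", i + 1) for i in range(4)]
        lo, hi = rel.bootstrap_ci(queens, loci, reps=150, seed=1)
        m, _ = rel.mean_relatedness(rel.relatedness_matrix(queens, loci))
        assert lo == pytest.approx(m) and hi == pytest.approx(m)

    def test_brackets_point_estimate(self, reference_queens):
        loci, queens = reference_queens
        lo, hi = rel.bootstrap_ci(queens, loci, reps=199, seed=3)
        m, _ = rel.mean_relatedness(rel.relatedness_matrix(queens, loci))
        assert lo - 1e-9 <= m <= hi + 1e-9


class TestClassification:
    def test_reference_high_pairs(self, reference_queens):
        loci, queens = reference_queens
        m = rel.relatedness_matrix(queens, loci)
        df = rel.classify_pairs(m)
        sel = df["class"].isin(["half-sib-or-closer", "same-queen"])
        high = set(map(tuple, df.loc[sel, ["colony_i", "colony_j"]].to_numpy()))
        assert {("3", "4"), ("3", "5"), ("19", "20")} <= high

    def test_all_negative_matrix(self):
        m = rel.RelatednessMatrix(
            ids=["a", "b"], values=np.array([[1.0, -0.2], [-0.2, 1.0]]), reference=[]
        )
        df = rel.classify_pairs(m)
        assert list(df["class"]) == ["unrelated"]

    def test_matrix_writer(self, tmp_path, reference_queens):
        loci, queens = reference_queens
        m = rel.relatedness_matrix(queens, loci)
        rel.write_matrix_csv(m, tmp_path / "m.csv")
        lines = (tmp_path / "m.csv").read_text().splitlines()
        assert len(lines) == 21
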