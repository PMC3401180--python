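"""Per-locus queen/paternal inference and mating-system statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nestkin import queen_inference as qi
from nestkin import synthetic_data as sd
from nestkin.genotype_io import MISSING

from .oracles import infer_queen_locus_oracle


class TestInferQueenLocus:
    def test_all_homozygous_workers(self):
        res = qi.infer_queen_locus([(5, 5)] * 8)
        assert res.queen == (5, 5)
        assert res.paternal_counts == {5: 8}
        assert not res.flagged and res.dropped == []

    def test_documented_tie_break(self):
        # {(A,B) x10, (A,C) x10}: Q=(A,A) with drones B,C ties Q=(B,C) with
        # drone A at (1/2)^20; parsimony (fewest paternal alleles) picks (B,C)
        workers = [(1, 2)] * 10 + [(1, 3)] * 10
        res = qi.infer_queen_locus(workers)
        assert res.queen == (2, 3)
        assert res.paternal_counts == {1: 20}
        assert math.isclose(res.log_likelihood, 20 * math.log(0.5))

    def test_single_heterozygous_worker_deterministic(self):
        # 1 worker (A,B): several queens tie; homozygote-preference then
        # smallest pair resolves to (A,A) with paternal B
        res = qi.infer_queen_locus([(1, 2)])
        assert res.queen == (1, 1)
        assert res.paternal_counts == {2: 1}

    def test_missing_workers_ignored(self):
        res = qi.infer_queen_locus([(4, 4), MISSING, (4, 4)])
        assert res.paternal_counts == {4: 2}

    def test_error_fallback_drops_minimal_set(self):
        # three disjoint allele groups: no queen pair covers all workers;
        # the single (9,9) worker is the minimal drop
        workers = [(1, 1)] * 5 + [(2, 2)] * 5 + [(9, 9)]
        res = qi.infer_queen_locus(workers)
        assert res.flagged
        assert res.dropped == [10]
        assert res.n_workers == 10
        assert res.queen == (1, 2)
        with pytest.raises(qi.InferenceError):
            qi.infer_queen_locus(workers, allow_drop=False)

    def test_matches_em_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n = int(rng.integers(1, 7))
            workers = [tuple(sorted(rng.integers(0, 4, 2))) for _ in range(n)]
            res = qi.infer_queen_locus(workers)
            q_oracle, ll_oracle = infer_queen_locus_oracle(workers)
            assert res.queen == q_oracle, f"workers={workers}"
            assert res.log_likelihood == pytest.approx(ll_oracle, abs=1e-6)

    def test_simulated_truth_recovery_single_colony(self):
        rng = np.random.default_rng(3)
        queen = [(10, 12)]
        drones = [[10], [14], [16]]
        workers, _, _ = sd.simulate_colony(queen, drones, [1, 1, 1], 20, 0.0, rng)
        res = qi.infer_queen_locus([w[0] for w in workers])
        assert res.queen == (10, 12)


class TestEffectiveMatingNumber:
    @pytest.mark.parametrize(
        "counts,expected",
        [({1: 5, 2: 5, 3: 5}, 3.0), ({1: 10, 2: 5, 3: 5}, 8 / 3), ({1: 7}, 1.0)],
    )
    def test_closed_forms(self, counts, expected):
        assert qi.effective_mating_number(counts) == pytest.approx(expected)

    def test_corrected_variant(self):
        # all-distinct fathers: unbiased sum(q^2) estimate is 0 -> infinite
        assert qi.effective_mating_number({1: 1, 2: 1}, corrected=True) == math.inf
        # corrected exceeds the raw estimate for finite samples
        raw = qi.effective_mating_number({1: 6, 2: 4})
        corr = qi.effective_mating_number({1: 6, 2: 4}, corrected=True)
        assert corr > raw

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            qi.effective_mating_number({})


class TestIntracolonialRelatedness:
    def test_known_values(self):
        assert qi.intracolonial_relatedness(1.0) == 0.75
        assert qi.intracolonial_relatedness(16.0) == 0.28125
        assert qi.intracolonial_relatedness(1e12) == pytest.approx(0.25, abs=1e-9)

    def test_rejects_sub_unit_mating_number(self):
        with pytest.raises(ValueError):
            qi.intracolonial_relatedness(0.5)

    @given(st.floats(min_value=1.0, max_value=1e4), st.floats(min_value=1e-3, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing(self, me, delta):
        assert qi.intracolonial_relatedness(me + delta) < qi.intracolonial_relatedness(me)


class TestInferColony:
    def _colony(self, seed=0, n_workers=20):
        cfg = sd.SimConfig(n_colonies=1, n_loci=5, workers_per_colony=n_workers, seed=seed)
        ds, truth = sd.simulate_population(cfg)
        return ds, truth

    def test_aggregates_and_invariants(self):
        ds, truth = self._colony()
        ped = qi.infer_colony(ds.colonies[0], ds.loci)
        assert ped.me_mean >= 1.0
        assert 0.25 < ped.r <= 0.75
        for i, locus in enumerate(ped.loci):
            res = ped.per_locus[locus]
            assert sum(res.paternal_counts.values()) == res.n_workers
            q = res.queen
            for w in ds.colonies[0].workers:
                g = w[i]
                assert q[0] in g or q[1] in g

    def test_order_independence(self, reference_queens):
        ds, _ = self._colony(seed=1)
        ped1 = qi.infer_colony(ds.colonies[0], ds.loci)
        ped2 = qi.infer_colony(ds.colonies[0], ds.loci)
        assert ped1 == ped2

    def test_empty_colony_rejected(self):
        from nestkin.genotype_io import ColonyRecord, LocusDef

        with pytest.raises(qi.InferenceError):
            qi.infer_colony(ColonyRecord("x"), [LocusDef("L", 1)])

    def test_recovery_rate_nondecreasing_in_workers(self):
        """More workers -> no worse per-locus queen recovery (coarse grid)."""
        rates = []
        for n_workers in (4, 20):
            hits = tot = 0
            for seed in range(30):
                cfg = sd.SimConfig(
                    n_colonies=1, n_loci=8, workers_per_colony=n_workers, seed=seed
                )
                ds, truth = sd.simulate_population(cfg)
                ped = qi.infer_colony(ds.colonies[0], ds.loci)
                tq = truth.queens["1"]
                for i, l in enumerate(ped.loci):
                    hits += ped.per_locus[l].queen == tq[i]
                    tot += 1
            rates.append(hits / tot)
        assert rates[1] >= rates[0]

    def test_writers(self, tmp_path):
        ds, _ = self._colony(seed=2)
        ped = qi.infer_colony(ds.colonies[0], ds.loci)
        qi.write_pedigree_csv([ped], tmp_path / "p.csv")
        qi.write_colony_summary_csv([ped], tmp_path / "s.csv")
        lines = (tmp_path / "p.csv").read_text().splitlines()
        assert len(lines) == 1 + len(ped.loci)
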