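"""Fst, diploidization and hierarchical AMOVA against brute-force oracles."""

import numpy as np
import pytest

from nestkin import queen_inference as qi
from nestkin import structure as st
from nestkin import synthetic_data as sd
from nestkin.genotype_io import ColonyRecord, Dataset, LocusDef

from .oracles import amova_components_bruteforce


def _pop_from_freq(rng, p, n, loci=1):
    alleles = np.arange(1, len(p) + 1)
    return [
        [tuple(sorted(rng.choice(alleles, 2, p=p))) for _ in range(loci)]
        for _ in range(n)
    ]


class TestDiploidize:
    def _pedigree(self, counts):
        li = qi.LocusInference(queen=(1, 2), paternal_counts=counts,
                              log_likelihood=0.0, n_workers=sum(counts.values()))
        return qi.ColonyPedigree(
            colony_id="c", loci=["L"], per_locus={"L": li},
            me_per_locus={"L": 1.0}, me_mean=1.0, me_se=0.0, r=0.75,
        )

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({1: 10, 2: 10}, [(1, 1), (2, 2)]),
            ({7: 3}, [(7, 7)]),
            ({1: 2, 2: 1}, [(1, 1), (1, 1), (2, 2)]),
        ],
    )
    def test_weight_reduction(self, counts, expected):
        assert st.diploidize_paternal(self._pedigree(counts))["L"] == expected


class TestFst:
    def test_fixed_differences_give_unity(self):
        p1 = [[(1, 1)], [(1, 1)]]
        p2 = [[(2, 2)], [(2, 2)]]
        res = st.fst([p1, p2], permutations=0)
        assert res.mean_fst == pytest.approx(1.0)

    def test_identical_populations_give_zero(self):
        p = [[(1, 2)], [(1, 1)], [(2, 2)]]
        res = st.fst([p, list(p)], permutations=0)
        assert res.mean_fst == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_gst(self):
        # freqs (0.2, 0.8) vs (0.8, 0.2): Hs = 0.32, Ht = 0.5 -> Fst = 0.36
        p1 = [[(1, 1)]] * 1 + [[(1, 2)]] * 2 + [[(2, 2)]] * 7  # p(1) = 4/20 = 0.2
        p2 = [[(2, 2)]] * 1 + [[(1, 2)]] * 2 + [[(1, 1)]] * 7  # p(1) = 0.8
        res = st.fst([p1, p2], permutations=0)
        assert res.mean_fst == pytest.approx(0.36)

    def test_permutation_p_small_for_strong_structure(self):
        rng = np.random.default_rng(2)
        p1 = _pop_from_freq(rng, [0.95, 0.05], 30)
        p2 = _pop_from_freq(rng, [0.05, 0.95], 30)
        res = st.fst([p1, p2], permutations=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_wc_theta_close_to_gst_for_balanced_biallelic(self):
        rng = np.random.default_rng(8)
        p1 = _pop_from_freq(rng, [0.9, 0.1], 100, loci=3)
        p2 = _pop_from_freq(rng, [0.1, 0.9], 100, loci=3)
        gst = st.fst([p1, p2], permutations=0).mean_fst
        wc = st.fst([p1, p2], permutations=0, method="wc").mean_fst
        assert wc == pytest.approx(gst, abs=0.2)
        assert wc > 0.4

    def test_drift_monotonicity(self):
        """Stronger divergence in allele frequencies -> larger mean Fst."""
        rng = np.random.default_rng(4)
        means = []
        for d in (0.05, 0.2, 0.4):
            p1 = _pop_from_freq(rng, [0.5 + d, 0.5 - d], 60, loci=4)
            p2 = _pop_from_freq(rng, [0.5 - d, 0.5 + d], 60, loci=4)
            means.append(st.fst([p1, p2], permutations=0).mean_fst)
        assert means[0] < means[1] < means[2]


def _toy_dataset(colony_genos):
    loci = [LocusDef(f"L{i+1}", i + 1) for i in range(len(colony_genos[0][0]))]
    cols = [
        ColonyRecord(str(ci + 1), workers=[list(w) for w in col])
        for ci, col in enumerate(colony_genos)
    ]
    return Dataset(loci=loci, colonies=cols)


class TestAmova:
    def test_matches_bruteforce_on_toy(self):
        colonies = [
            [[(1, 2)], [(1, 1)]],
            [[(2, 2)], [(2, 3)]],
        ]
        ds = _toy_dataset(colonies)
        res = st.amova3(ds, permutations=0)
        sa, sb, sw = amova_components_bruteforce(colonies)
        assert res.components_raw["among_colonies"] == pytest.approx(sa, abs=1e-12)
        assert res.components_raw["among_workers_within"] == pytest.approx(sb, abs=1e-12)
        assert res.components_raw["within_workers"] == pytest.approx(sw, abs=1e-12)

    def test_matches_bruteforce_on_random_unbalanced(self):
        rng = np.random.default_rng(17)
        colonies = []
        for _ in range(4):
            n = int(rng.integers(2, 6))
            colonies.append(
                [[tuple(sorted(rng.integers(1, 5, 2))) for _ in range(3)] for _ in range(n)]
            )
        res = st.amova3(_toy_dataset(colonies), permutations=0)
        sa, sb, sw = amova_components_bruteforce(colonies)
        assert res.components_raw["among_colonies"] == pytest.approx(sa, abs=1e-9)
        assert res.components_raw["among_workers_within"] == pytest.approx(sb, abs=1e-9)
        assert res.components_raw["within_workers"] == pytest.approx(sw, abs=1e-9)

    def test_identical_colonies_no_among_component(self):
        col = [[(1, 2), (3, 4)], [(1, 1), (3, 3)], [(2, 2), (4, 4)]]
        ds = _toy_dataset([col, [list(w) for w in col]])
        res = st.amova3(ds, permutations=0)
        assert res.percentages["among_colonies"] == pytest.approx(0.0, abs=1e-9)

    def test_all_homozygous_no_within_individual_variance(self):
        colonies = [
            [[(1, 1)], [(2, 2)]],
            [[(3, 3)], [(1, 1)]],
        ]
        res = st.amova3(_toy_dataset(colonies), permutations=0)
        assert res.components_raw["within_workers"] == 0.0

    def test_percentages_sum_and_pvalue_for_structure(self):
        cfg = sd.SimConfig(n_colonies=6, n_loci=5, workers_per_colony=8, seed=5)
        ds, _ = sd.simulate_population(cfg)
        res = st.amova3(ds, permutations=99, seed=0)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=0.1)
        # colony structure (shared queen/drones) must be detected
        assert res.p_values["among_colonies"] <= 0.05

    def test_single_worker_colony_excluded(self):
        colonies = [
            [[(1, 2)], [(1, 1)]],
            [[(2, 2)], [(2, 3)]],
            [[(1, 3)]],
        ]
        with pytest.warns(UserWarning, match="single-worker"):
            res = st.amova3(_toy_dataset(colonies), permutations=0)
        assert res.excluded_colonies == ["3"]

    def test_fst_and_phi_rank_agreement(self):
        """Fst and the AMOVA among-colony Phi rank three divergence levels
        identically."""
        phis, fsts = [], []
        for conc, seed in [(50.0, 0), (2.0, 1), (0.3, 2)]:
            # smaller Dirichlet concentration -> more drift-like divergence
            rng = np.random.default_rng(seed)
            base = np.array([0.4, 0.3, 0.2, 0.1])
            pops = []
            colonies = []
            for _ in range(4):
                p = rng.dirichlet(base * conc * 10)
                pop = _pop_from_freq(rng, p, 12, loci=4)
                pops.append(pop)
                colonies.append(pop)
            fsts.append(st.fst(pops, permutations=0).mean_fst)
            res = st.amova3(_toy_dataset(colonies), permutations=0)
            phis.append(res.phi["phi_ct"])
        assert np.argsort(fsts).tolist() == np.argsort(phis).tolist()


class TestPaternalPipeline:
    def test_paternal_populations_from_inference(self):
        cfg = sd.SimConfig(n_colonies=4, n_loci=4, workers_per_colony=15, seed=3)
        ds, _ = sd.simulate_population(cfg)
        peds = [qi.infer_colony(c, ds.loci) for c in ds.colonies]
        pops, loci = st.paternal_populations(peds)
        assert len(pops) == 4 and len(loci) == 4
        res = st.fst(pops, loci, permutations=0)
        assert 0.0 <= res.mean_fst <= 1.0
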