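"""Simulate colonies, worker genotypes and nest coordinates with ground truth.

The generative model mirrors the assumptions of the inference pipeline:
one diploid queen per colony drawn under Hardy-Weinberg from per-locus
allele frequencies (themselves Dirichlet-distributed), a pool of haploid
drones from the same frequencies (panmictic drone congregation), skewed
paternity shares over drones (Dirichlet), and each worker formed as one
random queen allele plus the allele of her assigned drone. Optional
genotyping error replaces an allele with a uniform random allele of the
locus. Nest coordinates come from either complete spatial randomness or a
Thomas cluster process. Everything is reproducible from the seed.

Relatedness scenarios plant known structure among queens for recovery
tests: ``mother-daughter`` pairs (daughter = one maternal allele + a
random drone allele, expected R ~ 0.5) and ``duplicated-queen`` pairs
(identical genotypes, expected R ~ 1, emulating the same queen sampled
twice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import ColonyRecord, Dataset, LocusDef, genotype


@dataclass
class SimConfig:
    """Study-condition knobs for the generator.

    Defaults emulate the reference field study: 20 colonies, 15 loci with
    6-11 alleles each, ~10 equally-contributing drones per queen, 20
    workers per colony, no genotyping error, nests scattered at random
    over a 17 x 22 km window.
    """

    n_colonies: int = 20
    n_loci: int = 15
    alleles_per_locus: tuple[int, int] = (6, 11)  # inclusive range, or (k, k)
    freq_concentration: float = 1.0  # Dirichlet parameter for allele freqs
    drones_per_queen: int = 10
    drones_poisson: bool = False  # if True, draw counts ~ 1 + Poisson(drones_per_queen - 1)
    paternity_skew: float = 100.0  # Dirichlet parameter; large -> even shares
    workers_per_colony: int = 20
    error_rate: float = 0.0
    scenario: str = "unrelated"  # unrelated | mother-daughter | duplicated-queen
    n_scenario_pairs: int = 1
    spatial: str = "csr"  # csr | thomas
    window: tuple[float, float] = (17_000.0, 22_000.0)
    thomas_parents: int = 4
    thomas_sd: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 1 or self.n_loci < 1 or self.workers_per_colony < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.alleles_per_locus
        if lo < 1 or hi < lo:
            raise ValueError("invalid allele count range")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")
        if self.scenario not in ("unrelated", "mother-daughter", "duplicated-queen"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.spatial not in ("csr", "thomas"):
            raise ValueError(f"unknown spatial pattern {self.spatial!r}")


@dataclass
class SimTruth:
    """Ground truth recorded alongside the emitted Dataset."""

    queens: dict[str, list[tuple[int, int]]]
    drones: dict[str, list[list[int]]]  # colony -> drone -> allele per locus
    drone_worker_counts: dict[str, list[int]]
    drone_assignments: dict[str, list[int]]  # colony -> worker -> drone index
    me_true: dict[str, float]
    kin_pairs: list[tuple[str, str, str]]  # (id_a, id_b, label)
    allele_freqs: list[dict[int, float]]
    spatial: str

    def paternal_allele_counts(self, colony_id: str, locus: int) -> dict[int, int]:
        """Realized paternal allele counts at one locus (the per-locus truth).

        Per-locus inference resolves paternity only to the paternal
        *allele*; drones sharing an allele are indistinguishable there, so
        estimators of the per-locus effective paternity must be compared
        against these counts, not against drone-level counts.
        """
        out: dict[int, int] = {}
        for d in self.drone_assignments[colony_id]:
            a = self.drones[colony_id][d][locus]
            out[a] = out.get(a, 0) + 1
        return out

    def me_true_allelic(self, colony_id: str, n_loci: int) -> float:
        """Colony mean over loci of 1/sum(q^2) on true paternal allele counts."""
        vals = []
        for l in range(n_loci):
            c = self.paternal_allele_counts(colony_id, l)
            n = sum(c.values())
            vals.append(1.0 / sum((v / n) ** 2 for v in c.values()))
        return float(np.mean(vals))


def _locus_alleles(k: int, locus_index: int) -> list[int]:
    # fragment-size-like labels, distinct across loci
    base = 100 + 30 * (locus_index % 6)
    return [base + 2 * j for j in range(k)]


def simulate_colony(
    queen: Sequence[tuple[int, int]],
    drones: Sequence[Sequence[int]],
    skew: Sequence[float],
    n_workers: int,
    error_rate: float,
    rng: np.random.Generator,
    locus_alleles: Sequence[Sequence[int]] | None = None,
) -> tuple[list[list[tuple[int, int]]], list[int], list[int]]:
    """Workers for one colony.

    Returns (worker genotypes, per-drone worker counts, per-worker drone
    assignment).
    """
    if len(drones) < 1:
        raise ValueError("need at least one drone")
    skew = np.asarray(skew, float)
    skew = skew / skew.sum()
    L = len(queen)
    workers: list[list[tuple[int, int]]] = []
    drone_counts = [0] * len(drones)
    assignments: list[int] = []
    for _ in range(n_workers):
        d = int(rng.choice(len(drones), p=skew))
        drone_counts[d] += 1
        assignments.append(d)
        geno_vec = []
        for l in range(L):
            maternal = queen[l][int(rng.integers(2))]
            paternal = drones[d][l]
            a, b = maternal, paternal
            if error_rate > 0.0 and locus_alleles is not None:
                if rng.random() < error_rate:
                    a = int(rng.choice(locus_alleles[l]))
                if rng.random() < error_rate:
                    b = int(rng.choice(locus_alleles[l]))
            geno_vec.append(genotype(a, b))
        workers.append(geno_vec)
    return workers, drone_counts, assignments


def _csr(n: int, window: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    return rng.uniform([0, 0], window, size=(n, 2))


def _thomas(
    n: int,
    window: tuple[float, float],
    n_parents: int,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thomas cluster process conditioned to yield exactly n points."""
    parents = rng.uniform([0, 0], window, size=(max(n_parents, 1), 2))
    pts = []
    while len(pts) < n:
        p = parents[int(rng.integers(len(parents)))]
        xy = p + rng.normal(0.0, sd, size=2)
        if 0 <= xy[0] <= window[0] and 0 <= xy[1] <= window[1]:
            pts.append(xy)
    return np.array(pts)


def simulate_population(config: SimConfig) -> tuple[Dataset, SimTruth]:
    """Generate a full Dataset plus its SimTruth, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.alleles_per_locus
    loci = [LocusDef(f"L{j + 1:02d}", j + 1) for j in range(config.n_loci)]
    alleles: list[list[int]] = []
    freqs: list[np.ndarray] = []
    for j in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        alleles.append(_locus_alleles(k, j))
        freqs.append(rng.dirichlet([config.freq_concentration] * k))

    def draw_queen() -> list[tuple[int, int]]:
        return [
            genotype(
                int(rng.choice(alleles[j], p=freqs[j])),
                int(rng.choice(alleles[j], p=freqs[j])),
            )
            for j in range(config.n_loci)
        ]

    ids = [str(i + 1) for i in range(config.n_colonies)]
    queens: dict[str, list[tuple[int, int]]] = {}
    kin_pairs: list[tuple[str, str, str]] = []
    npairs = min(config.n_scenario_pairs, config.n_colonies // 2)
    paired = {ids[2 * p]: ids[2 * p + 1] for p in range(npairs)} if config.scenario != "unrelated" else {}
    for cid in ids:
        queens[cid] = draw_queen()
    for a, b in paired.items():
        if config.scenario == "duplicated-queen":
            queens[b] = list(queens[a])
            kin_pairs.append((a, b, "duplicated-queen"))
        else:  # mother-daughter: one maternal allele + one random drone allele
            queens[b] = [
                genotype(
                    queens[a][j][int(rng.integers(2))],
                    int(rng.choice(alleles[j], p=freqs[j])),
                )
                for j in range(config.n_loci)
            ]
            kin_pairs.append((a, b, "mother-daughter"))

    drones: dict[str, list[list[int]]] = {}
    drone_counts: dict[str, list[int]] = {}
    drone_assignments: dict[str, list[int]] = {}
    me_true: dict[str, float] = {}
    colonies: list[ColonyRecord] = []
    if config.spatial == "csr":
        coords = _csr(config.n_colonies, config.window, rng)
    else:
        coords = _thomas(
            config.n_colonies, config.window, config.thomas_parents, config.thomas_sd, rng
        )
    for i, cid in enumerate(ids):
        nd = (
            1 + int(rng.poisson(max(config.drones_per_queen - 1, 0)))
            if config.drones_poisson
            else config.drones_per_queen
        )
        dr = [
            [int(rng.choice(alleles[j], p=freqs[j])) for j in range(config.n_loci)]
            for _ in range(nd)
        ]
        skew = rng.dirichlet([config.paternity_skew] * nd)
        workers, counts, assigns = simulate_colony(
            queens[cid], dr, skew, config.workers_per_colony,
            config.error_rate, rng, locus_alleles=alleles,
        )
        drones[cid] = dr
        drone_counts[cid] = counts
        drone_assignments[cid] = assigns
        tot = sum(counts)
        me_true[cid] = (
            1.0 / sum((c / tot) ** 2 for c in counts if c) if tot else float("nan")
        )
        colonies.append(
            ColonyRecord(colony_id=cid, x=float(coords[i, 0]), y=float(coords[i, 1]), workers=workers)
        )
    dataset = Dataset(loci=loci, colonies=colonies)
    truth = SimTruth(
        queens=queens,
        drones=drones,
        drone_worker_counts=drone_counts,
        drone_assignments=drone_assignments,
        me_true=me_true,
        kin_pairs=kin_pairs,
        allele_freqs=[dict(zip(a, f)) for a, f in zip(alleles, freqs)],
        spatial=config.spatial,
    )
    return dataset, truth


def paper_like_config(seed: int = 0) -> SimConfig:
    """Conditions matching the reference study's sampling design."""
    return SimConfig(seed=seed)
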