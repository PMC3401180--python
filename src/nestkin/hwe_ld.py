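"""Exact Hardy-Weinberg and genotypic linkage-disequilibrium tests.

The HWE exact test conditions on the observed allele counts: under the
null every pairing of the 2n allele copies into n diploid genotypes is
equally likely, giving Levene's distribution over genotype tables

    P(table) = n! * prod_i n_i! * 2^H / ((2n)! * prod_{i<=j} a_ij!)

with n_i the allele counts, a_ij the genotype counts and H the number of
heterozygotes. The exact P-value is the total probability of tables no
more probable than the observed one. It is estimated by a Markov chain
over the ordered 2 x n allele arrangement: a uniformly random
transposition of two allele copies is a symmetric proposal whose
stationary distribution is uniform over arrangements, hence exactly
Levene's distribution over tables — every proposal is accepted, and the
chain visits the same target as the classic switch chain of exact-HWE
practice. Chain length and burn-in ("dememorization") default to
100 000 / 1 000 steps; the Monte Carlo standard error comes from 20
batch means. Small tables can instead be enumerated in full.

The LD test applies the same machinery to the genotype-by-genotype
contingency table of two loci: locus-2 genotype columns are shuffled
against locus-1 by random transpositions (margins fixed), and the
log-likelihood-ratio statistic G decides extremeness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import MISSING

_TOL = 1e-9


@dataclass
class ExactTestResult:
    name: str
    p_value: float
    mc_se: float
    steps: int
    dememorization: int
    seed: int | None
    method: str  # "mc" | "enumeration" | "degenerate"


def _genotype_categories(
    genotypes: Sequence["tuple[int, int] | None"],
) -> list[tuple[int, int]]:
    return [g for g in genotypes if g is not MISSING]


# ---------------------------------------------------------------------------
# Levene log-probability machinery

def hwe_exact_mc(
    genotypes: Sequence["tuple[int, int] | None"],
    steps: int = 100_000,
    dememorization: int = 1_000,
    seed: int = 0,
    n_batches: int = 20,
) -> ExactTestResult:
    """Markov-chain estimate of the exact HWE P-value at one locus."""
    genos = _genotype_categories(genotypes)
    if len(genos) < 2:
        raise ValueError("need at least two scored individuals")
    if steps < dememorization or dememorization < 0:
        raise ValueError("need steps >= dememorization >= 0")
    alleles = sorted({a for g in genos for a in g})
    if len(alleles) == 1:
        return ExactTestResult("hwe", 1.0, 0.0, 0, 0, seed, "degenerate")
    idx = {a: i for i, a in enumerate(alleles)}
    flat = [idx[a] for g in genos for a in g]
    n = len(genos)
    log2 = math.log(2.0)
    logs = [0.0] + [math.log(i) for i in range(1, n + 1)]

    # running statistic: -sum log a_ij! + H log 2, updated per transposition
    counts: dict[tuple[int, int], int] = {}
    stat = 0.0
    for i in range(n):
        a, b = flat[2 * i], flat[2 * i + 1]
        cell = (a, b) if a <= b else (b, a)
        c = counts.get(cell, 0) + 1
        counts[cell] = c
        stat -= logs[c]
        if a != b:
            stat += log2

    def move_cell(pair: tuple[int, int], sign: int) -> None:
        """Add (sign=+1) or remove (sign=-1) one individual's cell."""
        nonlocal stat
        a, b = pair
        cell = (a, b) if a <= b else (b, a)
        c = counts.get(cell, 0)
        if sign > 0:
            counts[cell] = c + 1
            stat -= logs[c + 1]
            if a != b:
                stat += log2
        else:
            counts[cell] = c - 1
            stat += logs[c]
            if a != b:
                stat -= log2

    obs_stat = stat
    rng = np.random.default_rng(seed)
    kept = steps - dememorization
    batch = np.zeros(n_batches)
    batch_sizes = np.zeros(n_batches)
    u_all = rng.integers(0, 2 * n, size=steps)
    v_all = rng.integers(0, 2 * n, size=steps)
    for t in range(steps):
        u, v = int(u_all[t]), int(v_all[t])
        if flat[u] != flat[v] and u // 2 != v // 2:
            iu, iv = u // 2, v // 2
            move_cell((flat[2 * iu], flat[2 * iu + 1]), -1)
            move_cell((flat[2 * iv], flat[2 * iv + 1]), -1)
            flat[u], flat[v] = flat[v], flat[u]
            move_cell((flat[2 * iu], flat[2 * iu + 1]), +1)
            move_cell((flat[2 * iv], flat[2 * iv + 1]), +1)
        if t >= dememorization:
            b = (t - dememorization) * n_batches // kept
            batch[b] += stat <= obs_stat + _TOL
            batch_sizes[b] += 1
    means = batch / batch_sizes
    p = float(means.mean())
    se = float(means.std(ddof=1) / math.sqrt(n_batches))
    return ExactTestResult("hwe", p, se, steps, dememorization, seed, "mc")


def hwe_exact_enum(
    genotypes: Sequence["tuple[int, int] | None"],
) -> ExactTestResult:
    """Full-enumeration exact HWE P-value (small tables only).

    Enumerates every genotype table compatible with the observed allele
    counts and sums Levene probabilities of tables no more probable than
    the observed one. Independent of the Markov-chain route.
    """
    genos = _genotype_categories(genotypes)
    if len(genos) < 2:
        raise ValueError("need at least two scored individuals")
    alleles = sorted({a for g in genos for a in g})
    if len(alleles) == 1:
        return ExactTestResult("hwe", 1.0, 0.0, 0, 0, None, "degenerate")
    idx = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    n = len(genos)
    allele_counts = [0] * k
    obs_counts: dict[tuple[int, int], int] = {}
    for g in genos:
        a, b = idx[g[0]], idx[g[1]]
        if a > b:
            a, b = b, a
        obs_counts[(a, b)] = obs_counts.get((a, b), 0) + 1
        allele_counts[a] += 1
        allele_counts[b] += 1

    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def logprob(counts: dict[tuple[int, int], int]) -> float:
        H = sum(c for (i, j), c in counts.items() if i != j)
        lp = (
            math.lgamma(n + 1)
            + sum(math.lgamma(c + 1) for c in allele_counts)
            + H * math.log(2.0)
            - math.lgamma(2 * n + 1)
            - sum(math.lgamma(c + 1) for c in counts.values())
        )
        return lp

    obs_lp = logprob(obs_counts)
    total_p = 0.0
    extreme_p = 0.0

    def recurse(cell_i: int, remaining: list[int], used: int, current: dict):
        nonlocal total_p, extreme_p
        if cell_i == len(cells):
            if used == n and all(r == 0 for r in remaining):
                lp = logprob(current)
                p = math.exp(lp)
                total_p += p
                if lp <= obs_lp + _TOL:
                    extreme_p += p
            return
        i, j = cells[cell_i]
        if i == j:
            max_c = min(remaining[i] // 2, n - used)
        else:
            max_c = min(remaining[i], remaining[j], n - used)
        for c in range(max_c + 1):
            rem = list(remaining)
            if i == j:
                rem[i] -= 2 * c
            else:
                rem[i] -= c
                rem[j] -= c
            if c:
                current[(i, j)] = c
            recurse(cell_i + 1, rem, used + c, current)
            current.pop((i, j), None)

    recurse(0, list(allele_counts), 0, {})
    if not math.isclose(total_p, 1.0, rel_tol=1e-6):
        raise AssertionError(f"enumeration probabilities sum to {total_p}")
    return ExactTestResult("hwe", extreme_p, 0.0, 0, 0, None, "enumeration")


# ---------------------------------------------------------------------------
# Genotypic LD

def _g_statistic(table: np.ndarray) -> float:
    n = table.sum()
    if n == 0:
        return 0.0
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    e = rows @ cols / n
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / e[mask])).sum())


def ld_test_mc(
    genotypes_locus1: Sequence["tuple[int, int] | None"],
    genotypes_locus2: Sequence["tuple[int, int] | None"],
    steps: int = 100_000,
    dememorization: int = 1_000,
    seed: int = 0,
    n_batches: int = 20,
) -> ExactTestResult:
    """MC exact test of genotypic association between two loci.

    Individuals missing at either locus are dropped. Tables are resampled
    conditional on both genotype margins by shuffling the locus-2 column
    with random transpositions; extremeness is measured by the G
    (log-likelihood-ratio) statistic.
    """
    pairs = [
        (g1, g2)
        for g1, g2 in zip(genotypes_locus1, genotypes_locus2)
        if g1 is not MISSING and g2 is not MISSING
    ]
    if len(pairs) < 2:
        raise ValueError("need at least two individuals scored at both loci")
    cats1 = sorted({g for g, _ in pairs})
    cats2 = sorted({g for _, g in pairs})
    if len(cats1) < 2 or len(cats2) < 2:
        return ExactTestResult("ld", 1.0, 0.0, 0, 0, seed, "degenerate")
    i1 = {g: i for i, g in enumerate(cats1)}
    i2 = {g: i for i, g in enumerate(cats2)}
    col1 = [i1[a] for a, _ in pairs]
    cur = [i2[b] for _, b in pairs]
    n = len(pairs)
    table = np.zeros((len(cats1), len(cats2)))
    np.add.at(table, (col1, cur), 1)
    # expected counts depend only on the (fixed) margins
    e = table.sum(axis=1, keepdims=True) @ table.sum(axis=0, keepdims=True) / n

    def term(r: int, c: int) -> float:
        o = table[r, c]
        return float(o * math.log(o / e[r, c])) if o else 0.0

    g_cur = 2.0 * sum(
        term(r, c) for r in range(len(cats1)) for c in range(len(cats2))
    )
    g_obs = g_cur

    def retally(r: int, c: int, delta: int) -> None:
        nonlocal g_cur
        g_cur -= 2.0 * term(r, c)
        table[r, c] += delta
        g_cur += 2.0 * term(r, c)

    rng = np.random.default_rng(seed)
    kept = steps - dememorization
    batch = np.zeros(n_batches)
    batch_sizes = np.zeros(n_batches)
    u_all = rng.integers(0, n, size=steps)
    v_all = rng.integers(0, n, size=steps)
    for t in range(steps):
        u, v = int(u_all[t]), int(v_all[t])
        if cur[u] != cur[v]:
            retally(col1[u], cur[u], -1)
            retally(col1[v], cur[v], -1)
            cur[u], cur[v] = cur[v], cur[u]
            retally(col1[u], cur[u], +1)
            retally(col1[v], cur[v], +1)
        if t >= dememorization:
            b = (t - dememorization) * n_batches // kept
            batch[b] += g_cur >= g_obs - _TOL
            batch_sizes[b] += 1
    means = batch / batch_sizes
    p = float(means.mean())
    se = float(means.std(ddof=1) / math.sqrt(n_batches))
    return ExactTestResult("ld", p, se, steps, dememorization, seed, "mc")
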