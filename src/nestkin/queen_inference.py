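"""Queen-genotype and paternal-pool inference under single-queen polyandry.

In haplodiploid colonies headed by one multiply-mated queen, each worker
carries one maternal allele (from the diploid queen) and one paternal
allele (from a haploid drone). Loci are unlinked, so inference runs
independently per locus: enumerate every candidate queen genotype
Q = (q1, q2) built from alleles observed in the workers such that every
worker shares at least one allele with Q, and score each candidate by the
profile likelihood

    L(Q) = max_f  prod_workers P(worker | Q, f)

where f is the paternal allele frequency vector and
P({w1, w2} | Q, f) sums 0.5 * f(paternal) over the worker's compatible
maternal/paternal splits (the 0.5 is the Mendelian transmission
probability of a heterozygous queen). The maximization over f has a
closed form: with a heterozygous queen the only ambiguous workers are
those whose genotype equals {q1, q2}; merging them with the q1- and
q2-homozygote-derived counts into one multinomial cell makes the profile
likelihood an ordinary multinomial maximum.

Ties in likelihood are broken deterministically: fewest distinct paternal
alleles, then queen homozygote over heterozygote, then smallest allele
pair. From the inferred paternal counts the module estimates the
effective mating number m_e = 1 / sum(q_i^2) (q_i the paternity
proportions) and the intracolonial pedigree relatedness of workers
r = 0.25 + 0.5 / m_e (super-sisters share 0.75, maternal half-sisters
0.25, under monogyny).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import MISSING, ColonyRecord, LocusDef

_TIE_TOL = 1e-9


class InferenceError(ValueError):
    """Raised when a colony (or locus) admits no valid inference."""


@dataclass
class LocusInference:
    """Per-locus result: queen genotype, paternal counts, diagnostics."""

    queen: tuple[int, int]
    paternal_counts: dict[int, int]
    log_likelihood: float
    n_workers: int
    dropped: list[int] = field(default_factory=list)
    flagged: bool = False


@dataclass
class ColonyPedigree:
    colony_id: str
    loci: list[str]
    per_locus: dict[str, LocusInference]
    me_per_locus: dict[str, float]
    me_mean: float
    me_se: float
    r: float


def _profile_loglik(
    q: tuple[int, int], workers: Sequence[tuple[int, int]]
) -> tuple[float, dict[int, int]]:
    """Closed-form profile log-likelihood and ML hard paternal counts."""
    q1, q2 = q
    n = len(workers)
    if q1 == q2:
        counts: dict[int, int] = {}
        for a, b in workers:
            pat = b if a == q1 else a
            counts[pat] = counts.get(pat, 0) + 1
        ll = sum(c * math.log(c / n) for c in counts.values())
        return ll, dict(sorted(counts.items()))
    c_other: dict[int, int] = {}
    c1 = c2 = m = 0
    for a, b in workers:
        if (a, b) == (q1, q2):
            m += 1
        elif a == b == q1:
            c1 += 1
        elif a == b == q2:
            c2 += 1
        elif a == q1 or a == q2:
            c_other[b] = c_other.get(b, 0) + 1
        else:  # b is the queen allele
            c_other[a] = c_other.get(a, 0) + 1
    ll = n * math.log(0.5)
    merged = c1 + c2 + m
    for c in c_other.values():
        ll += c * math.log(c / n)
    if merged:
        ll += merged * math.log(merged / n)
        if c1 + c2:
            if c1:
                ll += c1 * math.log(c1 / (c1 + c2))
            if c2:
                ll += c2 * math.log(c2 / (c1 + c2))
    counts = dict(c_other)
    if c1:
        counts[q1] = counts.get(q1, 0) + c1
    if c2:
        counts[q2] = counts.get(q2, 0) + c2
    if m:
        # ambiguous {q1,q2} workers -> the more frequent queen allele; tie -> smaller
        target = q1 if c1 >= c2 else q2
        counts[target] = counts.get(target, 0) + m
    return ll, dict(sorted(counts.items()))


def _compatible(q: tuple[int, int], g: tuple[int, int]) -> bool:
    return q[0] in g or q[1] in g


def infer_queen_locus(
    worker_genotypes: Sequence["tuple[int, int] | None"],
    allow_drop: bool = True,
) -> LocusInference:
    """ML queen genotype and paternal allele counts at one locus.

    Missing worker genotypes are ignored. If no candidate queen covers all
    workers (possible genotyping error), the result is flagged and the
    minimal set of incompatible workers is dropped (``allow_drop=False``
    raises instead).
    """
    present = [(i, g) for i, g in enumerate(worker_genotypes) if g is not MISSING]
    if not present:
        raise InferenceError("no non-missing worker genotype at this locus")
    alleles = sorted({a for _, g in present for a in g})
    candidates = [
        (alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    ]
    genos = [g for _, g in present]
    coverage = {q: sum(_compatible(q, g) for g in genos) for q in candidates}
    best_cov = max(coverage.values())
    flagged = best_cov < len(genos)
    if flagged and not allow_drop:
        raise InferenceError("no queen genotype covers all workers")
    pool = [q for q, c in coverage.items() if c == best_cov]
    best: tuple | None = None
    for q in pool:
        kept = [g for g in genos if _compatible(q, g)]
        ll, counts = _profile_loglik(q, kept)
        key = (ll, -len(counts), 1 if q[0] == q[1] else 0, (-q[0], -q[1]))
        if best is None or _tie_better(key, best[0]):
            best = (key, q, counts, ll)
    _, q, counts, ll = best
    dropped = [i for i, g in present if not _compatible(q, g)]
    return LocusInference(
        queen=q,
        paternal_counts=counts,
        log_likelihood=ll,
        n_workers=len(genos) - len(dropped),
        dropped=dropped,
        flagged=flagged,
    )


def _tie_better(key_new: tuple, key_old: tuple) -> bool:
    """Likelihood (with tolerance), then the deterministic tie-break chain."""
    ll_n, ll_o = key_new[0], key_old[0]
    if ll_n > ll_o + _TIE_TOL:
        return True
    if ll_n < ll_o - _TIE_TOL:
        return False
    return key_new[1:] > key_old[1:]


def effective_mating_number(
    paternal_counts: Mapping[int, int], corrected: bool = False
) -> float:
    """m_e = 1 / sum(q_i^2) over paternity proportions q_i.

    ``corrected=True`` uses the unbiased estimate of sum(q^2),
    (sum(c^2) - n) / (n (n - 1)); it is infinite when every worker has a
    distinct father.
    """
    counts = [c for c in paternal_counts.values() if c > 0]
    n = sum(counts)
    if n < 1:
        raise ValueError("paternal counts are all zero")
    if corrected:
        if n == 1:
            raise ValueError("corrected estimator needs >= 2 workers")
        s = (sum(c * c for c in counts) - n) / (n * (n - 1))
        return math.inf if s == 0 else 1.0 / s
    return 1.0 / sum((c / n) ** 2 for c in counts)


def intracolonial_relatedness(m_e: float) -> float:
    """Pedigree relatedness among workers: r = 0.25 + 0.5 / m_e."""
    if m_e < 1:
        raise ValueError("effective mating number must be >= 1")
    return 0.25 + 0.5 / m_e


def infer_colony(
    colony: ColonyRecord,
    loci: Sequence[LocusDef],
    allow_drop: bool = True,
    corrected_me: bool = False,
) -> ColonyPedigree:
    """Run per-locus inference over a colony and aggregate m_e and r."""
    if not colony.workers:
        raise InferenceError(f"colony {colony.colony_id}: no workers")
    per_locus: dict[str, LocusInference] = {}
    me: dict[str, float] = {}
    for i, locus in enumerate(loci):
        genos = [w[i] for w in colony.workers]
        if all(g is MISSING for g in genos):
            warnings.warn(f"colony {colony.colony_id}, locus {locus.name}: all missing")
            continue
        res = infer_queen_locus(genos, allow_drop=allow_drop)
        per_locus[locus.name] = res
        me[locus.name] = effective_mating_number(res.paternal_counts, corrected=corrected_me)
    if not per_locus:
        raise InferenceError(f"colony {colony.colony_id}: no scorable locus")
    if all(r.flagged for r in per_locus.values()):
        raise InferenceError(f"colony {colony.colony_id}: every locus flagged")
    vals = np.array([v for v in me.values() if math.isfinite(v)])
    me_mean = float(vals.mean())
    me_se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return ColonyPedigree(
        colony_id=colony.colony_id,
        loci=[l.name for l in loci if l.name in per_locus],
        per_locus=per_locus,
        me_per_locus=me,
        me_mean=me_mean,
        me_se=me_se,
        r=intracolonial_relatedness(me_mean),
    )


def write_pedigree_csv(pedigrees: Sequence[ColonyPedigree], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["colony_id", "locus", "queen_allele_1", "queen_allele_2",
             "paternal_counts", "m_e", "n_workers", "dropped", "flagged"]
        )
        for p in pedigrees:
            for locus in p.loci:
                r = p.per_locus[locus]
                pat = ";".join(f"{a}:{c}" for a, c in r.paternal_counts.items())
                w.writerow(
                    [p.colony_id, locus, r.queen[0], r.queen[1], pat,
                     f"{p.me_per_locus[locus]:.4f}", r.n_workers,
                     ";".join(map(str, r.dropped)), int(r.flagged)]
                )


def write_colony_summary_csv(pedigrees: Sequence[ColonyPedigree], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["colony_id", "me_mean", "me_se", "r"])
        for p in pedigrees:
            w.writerow([p.colony_id, f"{p.me_mean:.4f}", f"{p.me_se:.4f}", f"{p.r:.4f}"])
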