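"""Genetic differentiation: Fst over populations and hierarchical AMOVA.

Fst defaults to the heterozygosity-based Nei form Gst = (Ht - Hs) / Ht,
with Hs the unweighted mean within-population expected heterozygosity and
Ht the expected heterozygosity of the unweighted mean allele frequencies
(the convention of the spreadsheet tools this pipeline mirrors). The
Weir-Cockerham theta estimator is available via ``method="wc"``.
Significance is by permutation of individuals among populations.

The three-level AMOVA decomposes allele-count distances among diploid
workers into among-colony, among-individual-within-colony and
within-individual components. With one-hot allele encoding the squared
Euclidean distance between two allele copies is 0/2, and the nested
sums of squares reduce to ordinary group-mean algebra; variance
components follow the standard unbalanced nested ANOVA expected mean
squares. Phi-statistics and permutation P-values accompany the table.

Paternal haploid pools are brought into these diploid analyses by
"diploidization": each paternal allele becomes a homozygous
pseudo-individual, replicated with the smallest integer weights that
preserve the paternity proportions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, Dataset
from .queen_inference import ColonyPedigree

Population = Sequence[Sequence["tuple[int, int] | None"]]  # individuals x loci


@dataclass
class DifferentiationResult:
    per_locus: dict[str, float]
    mean_fst: float
    p_value: float | None
    pairwise: pd.DataFrame | None = None
    method: str = "gst"
    n_permutations: int = 0


@dataclass
class AmovaResult:
    df: dict[str, int]
    ss: dict[str, float]
    components: dict[str, float]  # truncated at 0
    components_raw: dict[str, float]
    percentages: dict[str, float]
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int = 0
    excluded_colonies: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for level in ("among_colonies", "among_workers_within", "within_workers"):
            rows.append(
                [level, self.df[level], self.ss[level], self.components[level],
                 self.percentages[level]]
            )
        return pd.DataFrame(
            rows, columns=["source", "df", "SS", "variance_component", "percent"]
        )


# ---------------------------------------------------------------------------
# Diploidization of paternal pools

def diploidize_paternal(pedigree: ColonyPedigree) -> dict[str, list[tuple[int, int]]]:
    """Homozygous pseudo-individuals per locus, weights reduced by the GCD.

    Paternal counts {A: 2, B: 1} become [(A,A), (A,A), (B,B)];
    {A: 10, B: 10} reduce to [(A,A), (B,B)].
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for locus in pedigree.loci:
        counts = pedigree.per_locus[locus].paternal_counts
        if not counts:
            raise ValueError(f"{pedigree.colony_id}/{locus}: empty paternal pool")
        g = math.gcd(*counts.values()) if len(counts) > 1 else next(iter(counts.values()))
        out[locus] = [
            (a, a) for a, c in sorted(counts.items()) for _ in range(c // g)
        ]
    return out


# ---------------------------------------------------------------------------
# Fst

def _locus_freqs(pop: Population, locus_idx: int) -> dict[int, float] | None:
    counts: dict[int, int] = {}
    for ind in pop:
        g = ind[locus_idx]
        if g is MISSING:
            continue
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    n = sum(counts.values())
    if n == 0:
        return None
    return {a: c / n for a, c in counts.items()}


def _gst_locus(pops: Sequence[Population], locus_idx: int) -> float | None:
    freq_list = [f for f in (_locus_freqs(p, locus_idx) for p in pops) if f is not None]
    if len(freq_list) < 2:
        return None
    alleles = sorted({a for f in freq_list for a in f})
    P = np.array([[f.get(a, 0.0) for a in alleles] for f in freq_list])
    hs = float(np.mean(1.0 - (P**2).sum(axis=1)))
    pbar = P.mean(axis=0)
    ht = float(1.0 - (pbar**2).sum())
    if ht <= 0:
        return None
    return (ht - hs) / ht


def _wc_theta(pops: Sequence[Population], n_loci: int) -> tuple[dict[int, float], float]:
    """Weir-Cockerham theta: per-locus and overall (sum a / sum (a+b+c))."""
    per_locus: dict[int, float] = {}
    A = BC = 0.0
    for l in range(n_loci):
        a_sum = abc_sum = 0.0
        # per-population sample sizes, allele freqs, observed het
        ns, freqs, hets = [], [], []
        for p in pops:
            genos = [ind[l] for ind in p if ind[l] is not MISSING]
            if not genos:
                continue
            ns.append(len(genos))
            c: dict[int, int] = {}
            for g in genos:
                for al in g:
                    c[al] = c.get(al, 0) + 1
            tot = sum(c.values())
            freqs.append({al: v / tot for al, v in c.items()})
            hets.append(
                {al: sum(1 for g in genos if (g[0] == al) != (g[1] == al)) / len(genos)
                 for al in c}
            )
        r = len(ns)
        if r < 2:
            continue
        ns_arr = np.array(ns, float)
        nbar = ns_arr.mean()
        nc = (r * nbar - (ns_arr**2).sum() / (r * nbar)) / (r - 1)
        alleles = sorted({al for f in freqs for al in f})
        for al in alleles:
            p_i = np.array([f.get(al, 0.0) for f in freqs])
            h_i = np.array([h.get(al, 0.0) for h in hets])
            pbar = (ns_arr * p_i).sum() / (r * nbar)
            s2 = (ns_arr * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (ns_arr * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            cc = hbar / 2
            a_sum += a
            abc_sum += a + b + cc
        if abc_sum > 0:
            per_locus[l] = a_sum / abc_sum
            A += a_sum
            BC += abc_sum
    return per_locus, (A / BC if BC > 0 else float("nan"))


def fst(
    populations: Sequence[Population],
    locus_names: Sequence[str] | None = None,
    method: str = "gst",
    permutations: int = 999,
    seed: int = 0,
    pairwise: bool = False,
) -> DifferentiationResult:
    """Per-locus and mean Fst over >=2 populations of diploid genotypes.

    Monomorphic (Ht = 0) loci are skipped with a warning. P-value by
    permuting individuals among populations (``permutations=0`` skips it).
    """
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    n_loci = len(populations[0][0])
    names = list(locus_names) if locus_names else [f"L{i+1}" for i in range(n_loci)]

    def mean_stat(pops: Sequence[Population]) -> tuple[dict[str, float], float]:
        if method == "wc":
            per_idx, overall = _wc_theta(pops, n_loci)
            return {names[i]: v for i, v in per_idx.items()}, overall
        per: dict[str, float] = {}
        for l in range(n_loci):
            v = _gst_locus(pops, l)
            if v is None:
                warnings.warn(f"locus {names[l]}: monomorphic or unscored, skipped")
                continue
            per[names[l]] = v
        if not per:
            raise ValueError("no polymorphic locus shared across populations")
        return per, float(np.mean(list(per.values())))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_locus, mean_obs = mean_stat(populations)
    p_val = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        all_inds = [ind for p in populations for ind in p]
        sizes = [len(p) for p in populations]
        hits = 0
        for _ in range(permutations):
            order = rng.permutation(len(all_inds))
            k = 0
            perm_pops = []
            for s in sizes:
                perm_pops.append([all_inds[i] for i in order[k:k + s]])
                k += s
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    _, m = mean_stat(perm_pops)
                except ValueError:
                    m = -np.inf
            hits += m >= mean_obs
        p_val = (1 + hits) / (1 + permutations)
    pw = None
    if pairwise:
        n = len(populations)
        M = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    _, m = mean_stat([populations[i], populations[j]])
                except ValueError:
                    m = np.nan
            M[i, j] = M[j, i] = m
        pw = pd.DataFrame(M)
    return DifferentiationResult(
        per_locus=per_locus, mean_fst=mean_obs, p_value=p_val,
        pairwise=pw, method=method, n_permutations=permutations,
    )


# ---------------------------------------------------------------------------
# AMOVA

def _encode(dataset: Dataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """One-hot allele-count rows per individual, colony labels, het counts."""
    keep = [c for c in dataset.colonies if len(c.workers) >= 2]
    excluded = [c.colony_id for c in dataset.colonies if len(c.workers) < 2]
    if len(keep) < 2:
        raise ValueError("AMOVA needs >= 2 colonies with >= 2 workers")
    blocks = []
    hets = None
    labels = []
    for ci, c in enumerate(keep):
        labels.extend([ci] * len(c.workers))
    labels = np.array(labels)
    n_ind = len(labels)
    offset = 0
    cols = []
    for li in range(len(dataset.loci)):
        alleles = sorted(
            {a for c in keep for w in c.workers for a in (w[li] or ()) }
        )
        if any(w[li] is MISSING for c in keep for w in c.workers):
            raise ValueError("AMOVA requires complete genotypes (no missing data)")
        idx = {a: k for k, a in enumerate(alleles)}
        M = np.zeros((n_ind, len(alleles)))
        h = np.zeros(n_ind)
        i = 0
        for c in keep:
            for w in c.workers:
                a, b = w[li]
                M[i, idx[a]] += 1
                M[i, idx[b]] += 1
                h[i] += a != b
                i += 1
        cols.append(M)
        hets = h if hets is None else hets + h
    return np.hstack(cols), labels, hets, excluded


def _amova_components(
    M: np.ndarray, labels: np.ndarray, hets: np.ndarray
) -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """Nested SS -> variance components from one-hot count rows.

    M rows are per-individual allele counts (sum = 2 per locus); ``hets``
    is the per-individual heterozygous-locus count, which equals the
    within-individual SS contribution.
    """
    n_groups = labels.max() + 1
    N = len(labels)
    m_c = np.bincount(labels, minlength=n_groups).astype(float)
    V = M / 2.0  # per-individual allele frequency vectors
    col_sums = np.zeros((n_groups, M.shape[1]))
    np.add.at(col_sums, labels, V)
    col_means = col_sums / m_c[:, None]
    grand = V.sum(axis=0) / N
    ss_w = float(hets.sum())
    ss_ai = float(2.0 * ((V - col_means[labels]) ** 2).sum())
    ss_ac = float(2.0 * (m_c[:, None] * (col_means - grand) ** 2).sum())
    df = {
        "among_colonies": int(n_groups - 1),
        "among_workers_within": int(N - n_groups),
        "within_workers": int(N),
    }
    sigma_w = ss_w / N
    ms_ai = ss_ai / (N - n_groups)
    sigma_b = (ms_ai - sigma_w) / 2.0
    n0 = (N - (m_c**2).sum() / N) / (n_groups - 1)
    ms_ac = ss_ac / (n_groups - 1)
    sigma_a = (ms_ac - sigma_w - 2.0 * sigma_b) / (2.0 * n0)
    ss = {"among_colonies": ss_ac, "among_workers_within": ss_ai, "within_workers": ss_w}
    comps = {
        "among_colonies": sigma_a,
        "among_workers_within": sigma_b,
        "within_workers": sigma_w,
    }
    return comps, ss, df


def amova3(
    dataset: Dataset, permutations: int = 999, seed: int = 0
) -> AmovaResult:
    """Three-level AMOVA on worker genotypes.

    Levels: among colonies / among workers within colonies / within
    workers (the two allele copies of each individual). Colonies with a
    single worker are excluded with a warning. P-values: among-colony
    component by permuting workers among colonies; within-colony levels
    by permuting allele copies among workers of the same colony.
    """
    M, labels, hets, excluded = _encode(dataset)
    if excluded:
        warnings.warn(f"excluded single-worker colonies: {excluded}")
    comps_raw, ss, df = _amova_components(M, labels, hets)
    comps = {k: max(v, 0.0) for k, v in comps_raw.items()}
    total = sum(comps.values())
    perc = {k: (100.0 * v / total if total > 0 else 0.0) for k, v in comps.items()}
    tot_raw = sum(comps_raw.values())
    phi = {
        "phi_ct": comps_raw["among_colonies"] / tot_raw if tot_raw else float("nan"),
        "phi_is": (
            comps_raw["among_workers_within"]
            / (comps_raw["among_workers_within"] + comps_raw["within_workers"])
        ),
        "phi_it": (comps_raw["among_colonies"] + comps_raw["among_workers_within"]) / tot_raw
        if tot_raw
        else float("nan"),
    }
    p_values: dict[str, float] = {}
    if permutations > 0:
        rng = np.random.default_rng(seed)
        obs_ct, obs_is = phi["phi_ct"], phi["phi_is"]
        hits_ct = 0
        for _ in range(permutations):
            perm = rng.permutation(len(labels))
            c, _, _ = _amova_components(M[perm], labels, hets[perm])
            t = sum(c.values())
            hits_ct += (c["among_colonies"] / t if t else -np.inf) >= obs_ct
        p_values["among_colonies"] = (1 + hits_ct) / (1 + permutations)
        p_values["among_workers_within"] = _perm_within(
            M, labels, permutations, rng, obs_is
        )
    return AmovaResult(
        df=df, ss=ss, components=comps, components_raw=comps_raw,
        percentages=perc, phi=phi, p_values=p_values,
        n_permutations=permutations, excluded_colonies=excluded,
    )


def _perm_within(
    M: np.ndarray,
    labels: np.ndarray,
    permutations: int,
    rng: np.random.Generator,
    observed: float,
) -> float:
    """Permute allele copies among individuals within colonies; Phi_IS null.

    Reconstructs per-individual rows from reshuffled copies. M must encode
    complete diploid data (row sums = 2 per locus block); the locus block
    structure is recovered from cumulative row sums.
    """
    # recover locus blocks: columns where the cumulative sum over a row hits 2,4,...
    # simpler: blocks were hstacked; infer via searching split points from any row
    # We instead carry copy-level data: decompose each row of M into two unit vectors
    # per locus block using the stored column structure.
    # Split M into blocks by walking columns until each block's row-sum is 2.
    blocks = []
    start = 0
    ncol = M.shape[1]
    rowsum = np.cumsum(M.sum(axis=0))
    N = M.shape[0]
    target = 2 * N
    for j in range(ncol):
        if np.isclose(rowsum[j] - (rowsum[start - 1] if start else 0.0), target):
            blocks.append((start, j + 1))
            start = j + 1
    hits = 0
    n_groups = labels.max() + 1
    group_idx = [np.where(labels == g)[0] for g in range(n_groups)]
    for _ in range(permutations):
        het = np.zeros(N)
        Vsq_rows = np.zeros(N)
        M2 = np.zeros_like(M)
        for (s, e) in blocks:
            B = M[:, s:e]
            # copy list per individual
            for idx in group_idx:
                copies = []
                for i in idx:
                    row = B[i]
                    als = np.repeat(np.arange(e - s), row.astype(int))
                    copies.extend(als)
                copies = np.array(copies)
                rng.shuffle(copies)
                for k, i in enumerate(idx):
                    a, b = copies[2 * k], copies[2 * k + 1]
                    M2[i, s + a] += 1
                    M2[i, s + b] += 1
                    het[i] += a != b
        c, _, _ = _amova_components(M2, labels, het)
        phi_is = c["among_workers_within"] / (
            c["among_workers_within"] + c["within_workers"]
        )
        hits += phi_is >= observed
    return (1 + hits) / (1 + permutations)


def colonies_as_populations(dataset: Dataset) -> list[Population]:
    return [c.workers for c in dataset.colonies]


def paternal_populations(
    pedigrees: Sequence[ColonyPedigree],
) -> tuple[list[Population], list[str]]:
    """Diploidized paternal pseudo-individuals per colony, aligned on loci.

    Each colony becomes one population; loci are the intersection of the
    pedigrees' loci. Pseudo-individual counts differ per locus, so
    individuals are padded per locus into rectangular form by treating
    each locus independently: the returned 'individuals' are per-locus
    homozygote lists zipped to the longest locus with missing fill.
    """
    loci = list(pedigrees[0].loci)
    for p in pedigrees[1:]:
        loci = [l for l in loci if l in p.loci]
    pops: list[Population] = []
    for p in pedigrees:
        dip = diploidize_paternal(p)
        width = max(len(dip[l]) for l in loci)
        inds = []
        for i in range(width):
            inds.append([dip[l][i] if i < len(dip[l]) else MISSING for l in loci])
        pops.append(inds)
    return pops, loci
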