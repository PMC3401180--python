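"""Per-locus microsatellite diversity statistics.

For a set of diploid genotypes at one locus with allele frequencies p_i:

* Na — number of distinct alleles
* Ne — effective number of alleles, 1 / sum(p_i^2)
* Ho — observed fraction of heterozygous individuals
* He — expected heterozygosity, 1 - sum(p_i^2) (uncorrected; no 2N/(2N-1)
  small-sample factor — this is the convention the reference tables use)
* PIC — polymorphism information content (Botstein):
  1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2

By default the statistics are computed on the colony queens' genotypes
(one diploid genotype per colony), the natural sampling unit when worker
genotypes are non-independent within colonies.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, LocusDef


@dataclass
class AlleleFrequencyTable:
    """Allele relative frequencies at one locus, from 2N allele copies."""

    locus: str
    freqs: dict[int, float]
    n_copies: int

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"{self.locus}: frequencies sum to {total}")
        if any(f <= 0 for f in self.freqs.values()):
            raise ValueError(f"{self.locus}: non-positive frequency")


@dataclass
class DiversityRow:
    locus: str
    na: int
    ne: float
    ho: float
    he: float
    pic: float


def allele_frequencies(
    genotypes: Sequence["tuple[int, int] | None"], locus: str = ""
) -> AlleleFrequencyTable:
    """Tally allele copies (a homozygote contributes 2) into frequencies."""
    counts: dict[int, int] = {}
    for g in genotypes:
        if g is MISSING:
            continue
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"{locus or 'locus'}: all genotypes missing")
    return AlleleFrequencyTable(locus, {a: c / n for a, c in sorted(counts.items())}, n)


def pic_botstein(freqs: Mapping[int, float]) -> float:
    p = list(freqs.values())
    return 1.0 - sum(x * x for x in p) - sum(
        2.0 * p[i] ** 2 * p[j] ** 2 for i, j in combinations(range(len(p)), 2)
    )


def locus_summary(
    genotypes: Sequence["tuple[int, int] | None"], locus: str = ""
) -> DiversityRow:
    """Na, Ne, Ho, He and PIC for one locus."""
    aft = allele_frequencies(genotypes, locus)
    sum_p2 = sum(f * f for f in aft.freqs.values())
    present = [g for g in genotypes if g is not MISSING]
    ho = sum(g[0] != g[1] for g in present) / len(present)
    return DiversityRow(
        locus=locus,
        na=len(aft.freqs),
        ne=1.0 / sum_p2,
        ho=ho,
        he=1.0 - sum_p2,
        pic=pic_botstein(aft.freqs),
    )


def summary_table(
    genotype_matrix: Mapping[str, Sequence["tuple[int, int] | None"]],
    loci: Sequence[LocusDef],
) -> pd.DataFrame:
    """Per-locus diversity rows plus a final mean +/- SE row.

    ``genotype_matrix`` maps individual id -> genotype vector aligned with
    ``loci``. The returned frame has one row per locus in input order, a
    ``Mean+/-SE`` row (SE = sd/sqrt(L), ddof=1), and carries the total
    allele count in ``frame.attrs['total_alleles']``.
    """
    rows = []
    for i, locus in enumerate(loci):
        genos = [v[i] for v in genotype_matrix.values()]
        r = locus_summary(genos, locus.name)
        rows.append([r.locus, r.na, r.ne, r.ho, r.he, r.pic])
    df = pd.DataFrame(rows, columns=["locus", "Na", "Ne", "Ho", "He", "PIC"])
    stats = df[["Na", "Ne", "Ho", "He", "PIC"]].to_numpy(float)
    mean = stats.mean(axis=0)
    se = (
        stats.std(axis=0, ddof=1) / np.sqrt(len(df))
        if len(df) > 1
        else np.zeros(stats.shape[1])
    )
    mean_row = pd.DataFrame(
        [["Mean±SE", *mean]], columns=df.columns
    )
    out = pd.concat([df, mean_row], ignore_index=True)
    out.attrs["se"] = dict(zip(["Na", "Ne", "Ho", "He", "PIC"], se))
    out.attrs["total_alleles"] = int(df["Na"].sum())
    return out


def write_summary_csv(table: pd.DataFrame, path) -> None:
    """Write the diversity table with the SE spelled out on the mean row."""
    tab = table.astype(object)
    se = table.attrs.get("se", {})
    if se:
        last = tab.index[-1]
        for col, s in se.items():
            tab.loc[last, col] = f"{float(table.loc[last, col]):.3f}±{s:.3f}"
    tab.to_csv(path, index=False)
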