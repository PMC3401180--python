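"""Queller-Goodnight pairwise relatedness among colony queens.

The Queller-Goodnight estimator for a focal individual x against y, pooled
over loci l with reference allele frequencies p:

    r_x(y) = sum_l sum_{a in x} (share_y(a) - p_a)
             -----------------------------------------
             sum_l sum_{a in x} (share_x(a) - p_a)

where the inner sums run over x's two allele slots and share_g(a) is the
fraction of g's two slots carrying allele a. The reported R is by default
the average of the two directional estimates r_x(y) and r_y(x) — the
convention of the spreadsheet tools used for codominant colony data and
the form that reproduces published matrices. A fully pooled single-ratio
variant (both directions summed into one numerator and denominator before
dividing) is available via ``symmetric="pooled"``.

R is ~1 for the same genotype (same queen sampled twice), ~0.5 for
first-degree relatives, ~0 for unrelated pairs; negative values (less
similar than random draws from the reference frequencies) are reported
as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import AlleleFrequencyTable, allele_frequencies
from .genotype_io import MISSING, LocusDef


@dataclass
class RelatednessMatrix:
    """Symmetric colony x colony R matrix (diagonal = 1 by construction)."""

    ids: list[str]
    values: np.ndarray
    reference: list[AlleleFrequencyTable]

    def pair(self, x: str, y: str) -> float:
        return float(self.values[self.ids.index(x), self.ids.index(y)])

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def _share(g: tuple[int, int], a: int) -> float:
    # float() before adding: numpy bools saturate under + (True + True == True)
    return (float(g[0] == a) + float(g[1] == a)) / 2.0


def _directional_terms(
    gx: tuple[int, int], gy: tuple[int, int], p: Mapping[int, float]
) -> tuple[float, float]:
    """(numerator, denominator) contribution of one locus, x focal."""
    num = den = 0.0
    for a in gx:
        pa = p.get(a, 0.0)
        num += _share(gy, a) - pa
        den += _share(gx, a) - pa
    return num, den


def qg_relatedness(
    genotype_x: Sequence["tuple[int, int] | None"],
    genotype_y: Sequence["tuple[int, int] | None"],
    reference: Sequence[AlleleFrequencyTable],
    symmetric: str = "average",
) -> float:
    """Multilocus Queller-Goodnight R between two diploid individuals.

    ``symmetric="average"`` (default) averages the two directional pooled
    ratios; ``"pooled"`` pools both directions into a single ratio.
    Loci where either genotype is missing are skipped. Returns ``nan``
    (with a warning) if a denominator is zero.
    """
    nx = dx = ny = dy = 0.0
    used = 0
    for gx, gy, aft in zip(genotype_x, genotype_y, reference):
        if gx is MISSING or gy is MISSING:
            continue
        used += 1
        p = aft.freqs
        n, d = _directional_terms(gx, gy, p)
        nx += n
        dx += d
        n, d = _directional_terms(gy, gx, p)
        ny += n
        dy += d
    if used == 0:
        raise ValueError("no locus scored in both individuals")
    if symmetric == "pooled":
        den = dx + dy
        if den == 0:
            warnings.warn("zero denominator in pooled QG estimator")
            return float("nan")
        return (nx + ny) / den
    if symmetric != "average":
        raise ValueError(f"unknown symmetric mode {symmetric!r}")
    if dx == 0 or dy == 0:
        warnings.warn("zero denominator in directional QG estimator")
        return float("nan")
    return 0.5 * (nx / dx + ny / dy)


def reference_frequencies(
    queens: Mapping[str, Sequence["tuple[int, int] | None"]],
    loci: Sequence[LocusDef],
    exclude: tuple[str, ...] = (),
) -> list[AlleleFrequencyTable]:
    """Whole-sample allele frequencies per locus, optionally excluding ids."""
    out = []
    for i, locus in enumerate(loci):
        genos = [v[i] for cid, v in queens.items() if cid not in exclude]
        out.append(allele_frequencies(genos, locus.name))
    return out


def relatedness_matrix(
    queens: Mapping[str, Sequence["tuple[int, int] | None"]],
    loci: Sequence[LocusDef],
    symmetric: str = "average",
    pair_excluded_freqs: bool = False,
) -> RelatednessMatrix:
    """All pairwise R among queens.

    Reference frequencies are computed once from the full queen sample
    (focal pair included), matching the convention of the published
    matrices; ``pair_excluded_freqs=True`` recomputes them per pair with
    the focal pair left out (bias-corrected variant).
    """
    ids = list(queens)
    if len(ids) < 2:
        raise ValueError("need at least two colonies")
    ref = reference_frequencies(queens, loci)
    n = len(ids)
    R = np.eye(n)
    for i, j in combinations(range(n), 2):
        r = ref
        if pair_excluded_freqs:
            r = reference_frequencies(queens, loci, exclude=(ids[i], ids[j]))
        R[i, j] = R[j, i] = qg_relatedness(
            queens[ids[i]], queens[ids[j]], r, symmetric=symmetric
        )
    return RelatednessMatrix(ids=ids, values=R, reference=ref)


def mean_relatedness(matrix: RelatednessMatrix) -> tuple[float, float]:
    """Mean and SE (sd/sqrt(#pairs)) over defined off-diagonal pairs."""
    vals = matrix.offdiag()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined pairs")
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return float(vals.mean()), se


def bootstrap_ci(
    queens: Mapping[str, Sequence["tuple[int, int] | None"]],
    loci: Sequence[LocusDef],
    reps: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    symmetric: str = "average",
) -> tuple[float, float]:
    """Bootstrap CI of the mean pairwise R, resampling loci with replacement.

    Loci (not colonies or pairs) are the resampling unit: with few colonies
    and moderately many markers they carry the sampling noise of the
    estimator. Deterministic given ``seed``.
    """
    L = len(loci)
    if L < 2:
        warnings.warn("single locus: degenerate CI equal to the point estimate")
        m, _ = mean_relatedness(relatedness_matrix(queens, loci, symmetric=symmetric))
        return m, m
    if reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    means = np.empty(reps)
    ids = list(queens)
    for b in range(reps):
        take = rng.integers(0, L, size=L)
        boot_loci = [LocusDef(f"{loci[k].name}#{t}", t + 1) for t, k in enumerate(take)]
        boot_queens = {cid: [queens[cid][k] for k in take] for cid in ids}
        m, _ = mean_relatedness(
            relatedness_matrix(boot_queens, boot_loci, symmetric=symmetric)
        )
        means[b] = m
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


DEFAULT_THRESHOLDS = (0.0, 0.5, 0.9)


def classify_pairs(
    matrix: RelatednessMatrix,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Label each pair: unrelated (R <= low), related (low < R <= mid),
    half-sib-or-closer (R > mid), same-queen (R >= high, overrides)."""
    low, mid, high = thresholds
    if not low < mid < high:
        raise ValueError("thresholds must be increasing")
    rows = []
    n = len(matrix.ids)
    for i, j in combinations(range(n), 2):
        r = matrix.values[i, j]
        if np.isnan(r):
            label = "undefined"
        elif r >= high:
            label = "same-queen"
        elif r > mid:
            label = "half-sib-or-closer"
        elif r > low:
            label = "related"
        else:
            label = "unrelated"
        rows.append((matrix.ids[i], matrix.ids[j], float(r), label))
    df = pd.DataFrame(rows, columns=["colony_i", "colony_j", "R", "class"])
    df.attrs["counts"] = df["class"].value_counts().to_dict()
    return df


def write_matrix_csv(matrix: RelatednessMatrix, path) -> None:
    """Lower-triangle matrix CSV (diagonal shown as 0, published style)."""
    n = len(matrix.ids)
    with open(path, "w") as fh:
        fh.write("colony," + ",".join(matrix.ids) + "\n")
        for i in range(n):
            cells = []
            for j in range(n):
                if j > i:
                    cells.append("")
                elif j == i:
                    cells.append("0")
                else:
                    cells.append(f"{matrix.values[i, j]:.3f}")
            fh.write(matrix.ids[i] + "," + ",".join(cells) + "\n")
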