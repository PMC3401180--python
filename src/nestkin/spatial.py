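"""Quadrat-count dispersion analysis of nest coordinates.

Points are binned into an axis-aligned grid (default cell 1000 m — the
estimated forage radius of a nest) anchored at the bounding-box lower
left, zero cells included. The count histogram is then fitted by a
Poisson model (random placement) and a negative binomial (aggregation):
Poisson lambda is the sample mean; NB uses moment estimates
k = m^2/(s^2 - m) refined by one-dimensional maximum likelihood, and is
inapplicable when s^2 <= m. Goodness of fit is a chi-square on count
classes with expected frequencies pooled from the upper tail until each
class expects at least ``min_expected`` (default 1 — with only a few
dozen points the textbook threshold of 5 would leave no classes);
df = classes - 1 - #fitted parameters. The pattern is classified as
random / aggregated / uniform / indeterminate from the two fits plus the
index-of-dispersion test for significant underdispersion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats


@dataclass
class GofFit:
    """Distribution fit with chi-square goodness of fit (P None if df < 1)."""

    name: str
    params: dict[str, float]
    chi2: float | None
    df: int | None
    p_value: float | None
    applicable: bool = True


@dataclass
class DispersionResult:
    cell_size: float
    counts: np.ndarray
    mean: float
    variance: float
    poisson: GofFit
    negbin: GofFit
    label: str


def quadrat_counts(
    coords: Sequence[tuple[float, float]] | np.ndarray,
    cell_size: float,
    origin: tuple[float, float] | None = None,
) -> np.ndarray:
    """Counts per grid cell over the bounding box, zeros included.

    The grid is anchored at the bounding-box lower-left corner (so the
    histogram is invariant to translating all points), or at an explicit
    ``origin`` (which must not exceed the minimum coordinate).
    """
    if cell_size <= 0:
        raise ValueError("cell size must be positive")
    xy = np.asarray([(c[-2], c[-1]) if len(c) == 3 else c for c in coords], float)
    if xy.ndim != 2 or xy.shape[0] == 0:
        raise ValueError("need at least one point")
    lo = xy.min(axis=0) if origin is None else np.asarray(origin, float)
    if (lo > xy.min(axis=0)).any():
        raise ValueError("origin must be <= the minimum coordinate")
    span = xy.max(axis=0) - lo
    nx = max(int(np.ceil(span[0] / cell_size)), 1)
    ny = max(int(np.ceil(span[1] / cell_size)), 1)
    ix = np.minimum((xy[:, 0] - lo[0]) // cell_size, nx - 1).astype(int)
    iy = np.minimum((xy[:, 1] - lo[1]) // cell_size, ny - 1).astype(int)
    grid = np.zeros((nx, ny), int)
    np.add.at(grid, (ix, iy), 1)
    return grid.ravel()


def _pooled_chi2(
    counts: np.ndarray, pmf, n_params: int, min_expected: float = 1.0
) -> tuple[float | None, int | None, float | None]:
    """Chi-square GOF with upper-tail pooling of sparse expected classes."""
    n = len(counts)
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    probs = pmf(ks)
    tail = max(1.0 - probs.sum(), 0.0)
    obs = np.bincount(counts, minlength=kmax + 1).astype(float)
    exp = n * probs
    # fold the analytic tail beyond kmax into the last class
    exp[-1] += n * tail
    # pool from the upper tail until every class expects >= min_expected
    classes_obs, classes_exp = list(obs), list(exp)
    while len(classes_exp) > 1 and classes_exp[-1] < min_expected:
        e_last, o_last = classes_exp.pop(), classes_obs.pop()
        classes_exp[-1] += e_last
        classes_obs[-1] += o_last
    # pool any remaining sparse interior classes into their right neighbour
    i = 0
    while i < len(classes_exp) - 1:
        if classes_exp[i] < min_expected:
            e_i, o_i = classes_exp.pop(i), classes_obs.pop(i)
            classes_exp[i] += e_i
            classes_obs[i] += o_i
        else:
            i += 1
    df = len(classes_exp) - 1 - n_params
    o = np.array(classes_obs)
    e = np.array(classes_exp)
    chi2 = float(((o - e) ** 2 / e).sum())
    if df < 1:
        return chi2, None, None
    return chi2, df, float(stats.chi2.sf(chi2, df))


def fit_poisson(counts: np.ndarray, min_expected: float = 1.0) -> GofFit:
    """Poisson fit: lambda = sample mean; chi-square GOF (df = classes - 2)."""
    counts = np.asarray(counts, int)
    if counts.size < 2:
        raise ValueError("need at least two cells")
    lam = float(counts.mean())
    chi2, df, p = _pooled_chi2(
        counts, lambda k: stats.poisson.pmf(k, lam), n_params=1, min_expected=min_expected
    )
    return GofFit("poisson", {"lambda": lam}, chi2, df, p)


def fit_negbin(counts: np.ndarray, min_expected: float = 1.0) -> GofFit:
    """Negative binomial fit by moments then ML refinement of k.

    Parametrization: mean m, clumping parameter k; variance m + m^2/k.
    Inapplicable (flagged) when the sample variance does not exceed the
    mean — the aggregation model is then degenerate.
    """
    counts = np.asarray(counts, int)
    if counts.size < 2:
        raise ValueError("need at least two cells")
    m = float(counts.mean())
    s2 = float(counts.var(ddof=1))
    if s2 <= m or m == 0:
        return GofFit("negbin", {"k": float("nan"), "p": float("nan"), "mean": m},
                      None, None, None, applicable=False)
    k0 = m * m / (s2 - m)

    def nll(log_k: float) -> float:
        k = float(np.exp(log_k))
        return -float(stats.nbinom.logpmf(counts, k, k / (k + m)).sum())

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(k0) - 5.0, np.log(k0) + 5.0), method="bounded"
    )
    k = float(np.exp(res.x)) if res.success else k0
    p_nb = k / (k + m)
    chi2, df, p = _pooled_chi2(
        counts, lambda kk: stats.nbinom.pmf(kk, k, p_nb), n_params=2,
        min_expected=min_expected,
    )
    return GofFit("negbin", {"k": k, "p": p_nb, "mean": m}, chi2, df, p)


def dispersion_index_p(counts: np.ndarray) -> float:
    """Lower-tail P of the index-of-dispersion test (small = underdispersed).

    (n-1) s^2 / m is chi-square(n-1) under Poisson.
    """
    counts = np.asarray(counts, float)
    n = counts.size
    m = counts.mean()
    if m == 0:
        return 1.0
    stat = (n - 1) * counts.var(ddof=1) / m
    return float(stats.chi2.cdf(stat, n - 1))


def classify_dispersion(
    poisson_fit: GofFit,
    negbin_fit: GofFit,
    counts: np.ndarray | None = None,
    alpha: float = 0.05,
    alpha_nb: float = 0.01,
) -> str:
    """Label the pattern: random / aggregated / uniform / indeterminate.

    Rules, in order:
    1. random — Poisson not rejected at alpha, or NB rejected at alpha_nb
       while the Poisson fit is the better of the two;
    2. aggregated — NB accepted while Poisson is rejected at alpha;
    3. uniform — Poisson rejected and counts significantly underdispersed
       (index-of-dispersion lower-tail P < alpha);
    4. indeterminate — otherwise.
    """
    p_pois = poisson_fit.p_value
    p_nb = negbin_fit.p_value if negbin_fit.applicable else None
    if p_pois is not None and p_pois >= alpha:
        return "random"
    if negbin_fit.applicable and p_nb is not None and p_nb < alpha_nb and (
        p_pois is None or p_pois >= p_nb
    ):
        return "random"
    if negbin_fit.applicable and p_nb is not None and p_nb >= alpha and (
        p_pois is not None and p_pois < alpha
    ):
        return "aggregated"
    if counts is not None and dispersion_index_p(counts) < alpha:
        return "uniform"
    if not negbin_fit.applicable and p_pois is None:
        return "random"
    return "indeterminate"


def dispersion_analysis(
    coords: Sequence[tuple[float, float]] | np.ndarray,
    cell_size: float = 1000.0,
    min_expected: float = 1.0,
    origin: tuple[float, float] | None = None,
) -> DispersionResult:
    """Full quadrat analysis at one cell size."""
    counts = quadrat_counts(coords, cell_size, origin=origin)
    if counts.size < 2:
        warnings.warn("single quadrat; dispersion untestable")
    pois = fit_poisson(counts, min_expected) if counts.size >= 2 else GofFit(
        "poisson", {"lambda": float(counts.mean())}, None, None, None
    )
    nb = fit_negbin(counts, min_expected) if counts.size >= 2 else GofFit(
        "negbin", {}, None, None, None, applicable=False
    )
    return DispersionResult(
        cell_size=cell_size,
        counts=counts,
        mean=float(counts.mean()),
        variance=float(counts.var(ddof=1)) if counts.size > 1 else 0.0,
        poisson=pois,
        negbin=nb,
        label=classify_dispersion(pois, nb, counts),
    )


def anchor_sensitivity(
    coords: Sequence[tuple[float, float]] | np.ndarray,
    cell_size: float = 1000.0,
    offsets: int = 4,
) -> list[DispersionResult]:
    """Re-run the analysis over shifted grid anchors (offsets per axis)."""
    xy = np.asarray([(c[-2], c[-1]) if len(c) == 3 else c for c in coords], float)
    lo = xy.min(axis=0)
    out = []
    for i in range(offsets):
        for j in range(offsets):
            shift = np.array([i, j]) * cell_size / offsets
            out.append(dispersion_analysis(xy, cell_size, origin=tuple(lo - shift)))
    return out
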