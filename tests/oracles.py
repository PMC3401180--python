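"""Independent reference computations used to check the package's routines.

Each oracle recomputes a quantity by a different route than the
implementation under test: EM maximization instead of the closed-form
profile likelihood for queen inference, explicit pairwise-draw
enumeration for expected heterozygosity, direct transcription of the
Queller-Goodnight formula for a single pair/locus, and literal nested
sums of squares for the AMOVA decomposition.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# Queen inference via EM on the mixture likelihood


def _em_loglik(q, workers, n_iter=500, tol=1e-13, starts=4, rng=None):
    """Maximize the paternal-frequency mixture likelihood for queen q by EM."""
    q1, q2 = q
    het = q1 != q2
    # possible paternal alleles per worker
    pat_options = []
    for a, b in workers:
        opts = set()
        if a in (q1, q2):
            opts.add(b)
        if b in (q1, q2):
            opts.add(a)
        if het and {a, b} == {q1, q2}:
            opts = {q1, q2}
        elif not het and a == b == q1:
            opts = {q1}
        pat_options.append(sorted(opts))
    support = sorted({o for opts in pat_options for o in opts})
    k = len(support)
    idx = {a: i for i, a in enumerate(support)}
    n = len(workers)
    rng = rng or np.random.default_rng(12345)
    best = -math.inf
    best_f = None
    inits = [np.full(k, 1.0 / k)] + [rng.dirichlet(np.ones(k)) for _ in range(starts - 1)]
    for f in inits:
        f = f.copy()
        prev = -math.inf
        for _ in range(n_iter):
            # E-step: responsibilities over paternal options
            counts = np.zeros(k)
            ll = n * math.log(0.5) if het else 0.0
            for opts in pat_options:
                ps = np.array([f[idx[o]] for o in opts])
                tot = ps.sum()
                if tot <= 0:
                    ll = -math.inf
                    break
                ll += math.log(tot)
                counts[[idx[o] for o in opts]] += ps / tot
            if not math.isfinite(ll):
                break
            f = counts / n
            if abs(ll - prev) < tol:
                break
            prev = ll
        if ll > best:
            best, best_f = ll, f
    return best, dict(zip(support, best_f if best_f is not None else []))


def infer_queen_locus_oracle(workers):
    """Exhaustive queen-candidate search scored by EM; same tie-break chain.

    Returns (queen, log-likelihood). ``workers`` must be non-missing sorted
    tuples.
    """
    alleles = sorted({a for g in workers for a in g})
    pairs = [
        (alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i, len(alleles))
    ]
    coverage = {
        q: sum(q[0] in g or q[1] in g for g in workers) for q in pairs
    }
    best_cov = max(coverage.values())
    cands = [q for q, c in coverage.items() if c == best_cov]
    results = []
    for q in cands:
        covered = [g for g in workers if q[0] in g or q[1] in g]
        ll, f = _em_loglik(q, covered)
        # hard paternal assignment under the fitted frequencies
        counts: dict[int, int] = {}
        for a, b in covered:
            opts = []
            if a in q:
                opts.append(b)
            if b in q:
                opts.append(a)
            opts = sorted(set(opts))
            pick = max(opts, key=lambda o: (f.get(o, 0.0), -o))
            counts[pick] = counts.get(pick, 0) + 1
        results.append((ll, q, counts))
    best_ll = max(r[0] for r in results)
    tied = [r for r in results if r[0] >= best_ll - 1e-6]
    tied.sort(
        key=lambda r: (-len(r[2]), 1 if r[1][0] == r[1][1] else 0, (-r[1][0], -r[1][1])),
        reverse=True,
    )
    ll, q, counts = tied[0]
    return q, ll


# ---------------------------------------------------------------------------
# Expected heterozygosity by explicit pairwise draws


def expected_het_bruteforce(genotypes):
    """P(two allele copies drawn with replacement differ), by enumeration."""
    copies = [a for g in genotypes if g is not None for a in g]
    n = len(copies)
    diff = sum(1 for a in copies for b in copies if a != b)
    return diff / (n * n)


# ---------------------------------------------------------------------------
# Queller-Goodnight single-pair direct transcription


def qg_direct(gx, gy, p):
    """Directional-average QG for one locus, written out symbol by symbol.

    gx, gy: (a, b) tuples; p: allele -> reference frequency.
    """
    a, b = gx
    c, d = gy

    def delta(u, v):
        return 1.0 if u == v else 0.0

    num_x = 0.5 * (delta(a, c) + delta(a, d) + delta(b, c) + delta(b, d)) - p[a] - p[b]
    den_x = 1.0 + delta(a, b) - p[a] - p[b]
    num_y = 0.5 * (delta(c, a) + delta(c, b) + delta(d, a) + delta(d, b)) - p[c] - p[d]
    den_y = 1.0 + delta(c, d) - p[c] - p[d]
    return 0.5 * (num_x / den_x + num_y / den_y)


# ---------------------------------------------------------------------------
# AMOVA nested sums of squares, literal form


def amova_ss_bruteforce(colonies):
    """(SS_among, SS_among_within, SS_within) from explicit one-hot algebra.

    ``colonies``: list of colonies; colony = list of individuals; individual
    = list of per-locus (a, b) genotypes. Complete data only.
    """
    n_loci = len(colonies[0][0])
    ss_ac = ss_ai = ss_wi = 0.0
    for l in range(n_loci):
        alleles = sorted({a for col in colonies for ind in col for a in ind[l]})
        k = len(alleles)
        ix = {a: i for i, a in enumerate(alleles)}

        def onehot(allele):
            v = np.zeros(k)
            v[ix[allele]] = 1.0
            return v

        copies = []  # (colony_index, ind_index, vector)
        for ci, col in enumerate(colonies):
            for wi, ind in enumerate(col):
                for a in ind[l]:
                    copies.append((ci, wi, onehot(a)))
        grand = np.mean([v for _, _, v in copies], axis=0)
        for ci, col in enumerate(colonies):
            col_vs = [v for c, _, v in copies if c == ci]
            col_mean = np.mean(col_vs, axis=0)
            ss_ac += len(col_vs) * float(((col_mean - grand) ** 2).sum())
            for wi, ind in enumerate(col):
                ind_vs = [v for c, w, v in copies if c == ci and w == wi]
                ind_mean = np.mean(ind_vs, axis=0)
                ss_ai += len(ind_vs) * float(((ind_mean - col_mean) ** 2).sum())
                for v in ind_vs:
                    ss_wi += float(((v - ind_mean) ** 2).sum())
    return ss_ac, ss_ai, ss_wi


def amova_components_bruteforce(colonies):
    """Variance components from the brute-force SS via expected mean squares."""
    ss_ac, ss_ai, ss_wi = amova_ss_bruteforce(colonies)
    m = [len(col) for col in colonies]
    a = len(colonies)
    N = sum(m)
    sigma_w = ss_wi / N
    sigma_b = (ss_ai / (N - a) - sigma_w) / 2.0
    n0 = (N - sum(x * x for x in m) / N) / (a - 1)
    sigma_a = (ss_ac / (a - 1) - sigma_w - 2 * sigma_b) / (2 * n0)
    return sigma_a, sigma_b, sigma_w

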