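"""Contact-matrix normalization and concordance.

Knight-Ruiz-style matrix balancing, cross-sample quantile normalization
(optionally stratified by genomic distance, since raw contact values are
strongly distance-confounded), distance-decay expectation fitting, and a
random-walk concordance score in the GenomeDISCO family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class BalanceError(RuntimeError):
    pass


@dataclass
class BalancedMatrix:
    matrix: np.ndarray        # D M D, constant row sums over unmasked bins
    scaling: np.ndarray       # diagonal scaling vector (NaN on masked bins)
    mask: np.ndarray          # True = usable bin (nonzero marginal)
    iterations: int
    residual: float           # final row-sum coefficient of variation


def kr_balance(matrix: np.ndarray, tol: float = 1e-8,
               max_iter: int = 1000) -> BalancedMatrix:
    """Balance a symmetric non-negative matrix to constant row sums of 1.

    Bins with zero marginal are masked before balancing and carry NaN in the
    scaling vector. Convergence criterion: coefficient of variation of the
    unmasked row sums below ``tol``.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("matrix must be symmetric")
    if (m < 0).any():
        raise ValueError("matrix must be non-negative")
    marg = m.sum(1)
    mask = marg > 0
    sub = m[np.ix_(mask, mask)]
    n = sub.shape[0]
    if n == 0:
        return BalancedMatrix(np.zeros_like(m), np.full(m.shape[0], np.nan),
                              mask, 0, 0.0)
    x = 1.0 / np.sqrt(sub.sum(1))
    it = 0
    cv = np.inf
    for it in range(1, max_iter + 1):
        r = x * (sub @ x)           # current row sums of diag(x) sub diag(x)
        cv = r.std() / r.mean()
        if cv < tol:
            break
        # damped multiplicative update toward row sums = 1
        x = x / np.sqrt(np.maximum(r, 1e-300)) ** 1.0
    else:
        raise BalanceError(f"KR balancing did not converge: row-sum CV {cv:.3e} "
                           f"after {max_iter} iterations")
    bal = np.zeros_like(m)
    bal[np.ix_(mask, mask)] = sub * np.outer(x, x)
    scaling = np.full(m.shape[0], np.nan)
    scaling[mask] = x
    return BalancedMatrix(bal, scaling, mask, it, float(cv))


def quantile_normalize(matrices: list, stratify_by_distance: bool = True,
                       reference_matrices: list = None) -> list:
    """Map each sample's nonzero values onto the mean quantile function.

    With ``stratify_by_distance`` the mapping is done independently within
    each |i-j| diagonal stratum so that the strong distance decay does not
    dominate the pooled distribution. The reference distribution is the mean
    order statistics of ``reference_matrices`` (the inputs themselves by
    default); zeros stay zero, within-sample rank order is preserved.

    When the per-stratum nonzero counts of all samples (and the reference)
    agree — the usual case for balanced maps on one binning — the mapping is
    exact and applying the transform twice equals applying it once; unequal
    counts fall back to interpolated quantile mapping.
    """
    mats = [np.asarray(m, float) for m in matrices]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("matrices must share one binning")
    refs = mats if reference_matrices is None \
        else [np.asarray(m, float) for m in reference_matrices]
    if any(m.shape != shape for m in refs):
        raise ValueError("reference matrices must share the input binning")
    out = [m.copy() for m in mats]
    n = shape[0]
    strata = range(n) if stratify_by_distance else [None]
    for d in strata:
        if d is None:
            idx = np.triu_indices(n)
        else:
            i = np.arange(n - d)
            idx = (i, i + d)
        vals = [m[idx] for m in mats]
        nz = [v > 0 for v in vals]
        counts = [int(z.sum()) for z in nz]
        if not any(counts):
            continue
        rvals = [r[idx] for r in refs]
        rnz = [v[v > 0] for v in rvals if (v > 0).any()]
        if not rnz:
            continue
        rcounts = {len(v) for v in rnz}
        if len(rcounts) == 1 and set(c for c in counts if c) <= rcounts:
            # equal nonzero counts everywhere: exact mean order statistics
            ref = np.mean([np.sort(v) for v in rnz], axis=0)
            for m, v, z in zip(out, vals, nz):
                if not z.any():
                    continue
                order = np.argsort(v[z], kind="stable")
                new = v.copy()
                nzv = np.empty(len(ref))
                nzv[order] = ref
                new[z] = nzv
                m[idx] = new
                m[idx[1], idx[0]] = new
        else:
            probs = np.linspace(0, 1, 101)
            ref = np.mean([np.quantile(v, probs) for v in rnz], axis=0)
            for m, v, z in zip(out, vals, nz):
                if not z.any():
                    continue
                ranks = np.argsort(np.argsort(v[z], kind="stable"), kind="stable")
                p = ranks / max(int(z.sum()) - 1, 1)
                new = v.copy()
                new[z] = np.interp(p, probs, ref)
                m[idx] = new
                m[idx[1], idx[0]] = new
    return out


def expected_by_distance(matrix: np.ndarray, fit_range: tuple = None) -> tuple:
    """Mean contact per bin distance and the log-log power-law exponent.

    Returns ``(distances, means, exponent)``. ``fit_range`` restricts the
    least-squares fit to (min_d, max_d) in bins.
    """
    m = np.asarray(matrix, float)
    n = m.shape[0]
    dists = np.arange(n)
    means = np.array([np.diagonal(m, d).mean() for d in dists])
    pos = (dists > 0) & (means > 0)
    if fit_range is not None:
        pos &= (dists >= fit_range[0]) & (dists <= fit_range[1])
    if pos.sum() < 3:
        raise ValueError("need at least 3 positive distance points for the fit")
    slope, _ = np.polyfit(np.log(dists[pos]), np.log(means[pos]), 1)
    return dists, means, float(slope)


@dataclass
class ConcordanceScore:
    score: float
    t: int


def genomedisco_score(m1: np.ndarray, m2: np.ndarray, t: int = 3) -> ConcordanceScore:
    """Random-walk concordance between two contact maps.

    Each matrix is row-normalized to a transition matrix R; the score is
    1 - sum|R1^t - R2^t| / mean(number of nonzero rows of the two inputs).
    Identical inputs score exactly 1.
    """
    a = np.asarray(m1, float)
    b = np.asarray(m2, float)
    if a.shape != b.shape:
        raise ValueError("matrices must share one binning")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("empty matrix")

    def transition(m):
        rs = m.sum(1, keepdims=True)
        return np.divide(m, rs, out=np.zeros_like(m), where=rs > 0)

    ra = np.linalg.matrix_power(transition(a), t)
    rb = np.linalg.matrix_power(transition(b), t)
    nnz = ((a.sum(1) > 0).sum() + (b.sum(1) > 0).sum()) / 2.0
    d = np.abs(ra - rb).sum() / nnz
    return ConcordanceScore(float(1.0 - d), t)
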