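"""Gene-set overlap significance and basic set bookkeeping.

The overlap of two gene sets A and B within a stated universe is scored
by a Z-score against the null of a random size-|A| subset of the
universe.  Two nulls are available:

* ``analytic`` — exact hypergeometric moments: with n = |A|, K = |B|,
  N = |universe|, E[X] = nK/N, Var[X] = nK(N-K)(N-n)/(N^2 (N-1)), and an
  exact hypergeometric upper-tail p-value P(X >= x).
* ``permutation`` — Monte-Carlo resampling of size-n subsets; the
  Z-score uses the empirical mean/sd and the p-value the add-one
  estimator (1 + #{overlap >= x}) / (1 + n_perm), so p is never 0.

The universe is always an explicit argument: the Z-score depends
strongly on it and different analyses legitimately use different
backgrounds (all clustered genes vs differentially expressed genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from ._errors import DataError

__all__ = ["OverlapResult", "overlap_zscore", "set_ops"]


@dataclass
class OverlapResult:
    observed: int
    expected: float
    sd: float
    z: float
    p: float
    method: str
    n_perm: int | None = None
    seed: int | None = None


def _hypergeom_moments(n: int, K: int, N: int) -> tuple[float, float]:
    expected = n * K / N
    var = n * K * (N - K) * (N - n) / (N**2 * (N - 1))
    return expected, var


def overlap_zscore(
    set_a,
    set_b,
    universe,
    method: str = "analytic",
    n_perm: int = 1000,
    seed: int | None = None,
) -> OverlapResult:
    """Z-score and p-value for the overlap of two gene sets in a universe.

    ``set_a`` is the resampled set under the permutation null (``set_b``
    is held fixed).  Raises when either set is empty, escapes the
    universe, or when the null is degenerate (a set equals the whole
    universe).
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A or not B:
        raise DataError("both gene sets must be nonempty")
    if not A <= U:
        raise DataError("set_a is not contained in the universe")
    if not B <= U:
        raise DataError("set_b is not contained in the universe")
    n, K, N = len(A), len(B), len(U)
    if N <= max(n, K):
        raise DataError("universe must be strictly larger than each set")
    x = len(A & B)
    if method == "analytic":
        expected, var = _hypergeom_moments(n, K, N)
        if var == 0:
            raise DataError("degenerate null: overlap variance is 0")
        sd = float(np.sqrt(var))
        z = (x - expected) / sd
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        return OverlapResult(x, float(expected), sd, float(z), p, "analytic")
    if method == "permutation":
        if n_perm < 1:
            raise DataError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        uni = np.array(sorted(U))
        in_b = np.isin(uni, np.array(sorted(B)))
        overlaps = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            idx = rng.choice(N, size=n, replace=False)
            overlaps[i] = int(in_b[idx].sum())
        mean = overlaps.mean()
        sd = overlaps.std(ddof=1)
        if sd == 0:
            raise DataError("degenerate permutation null: zero variance")
        z = (x - mean) / sd
        p = (1 + int((overlaps >= x).sum())) / (1 + n_perm)
        return OverlapResult(
            x, float(mean), float(sd), float(z), float(p), "permutation", n_perm, seed
        )
    raise DataError(f"unknown method {method!r}")


def set_ops(sets: dict[str, set]) -> dict:
    """Pairwise and full intersections/unions of named gene sets.

    Returns a report dict with per-set sizes, every pairwise
    intersection/union (keys ordered by name), and the full intersection
    and union across all sets.
    """
    if len(sets) < 2:
        raise DataError("set_ops needs at least 2 sets")
    names = sorted(sets)
    report = {
        "sizes": {name: len(sets[name]) for name in names},
        "pairwise": {},
    }
    for a, b in combinations(names, 2):
        inter = sets[a] & sets[b]
        union = sets[a] | sets[b]
        report["pairwise"][(a, b)] = {
            "intersection": set(inter),
            "union": set(union),
            "n_intersection": len(inter),
            "n_union": len(union),
        }
    full_inter = set.intersection(*(set(sets[n]) for n in names))
    full_union = set.union(*(set(sets[n]) for n in names))
    report["intersection"] = full_inter
    report["union"] = full_union
    report["n_intersection"] = len(full_inter)
    report["n_union"] = len(full_union)
    return report
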