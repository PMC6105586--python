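"""Permutation tests on distance matrices and the surrounding inference.

Implements the Mantel test (correlation between two distance matrices under
joint row/column permutation of one of them), the first-order Partial
Mantel test (partial correlation controlling for a third matrix, permuting
the first), Holm's step-down family-wise correction, and the exact binomial
probability of observing at least k out of n independent tests at p <= 0.05
by chance.

Conventions
-----------
* The Mantel statistic is the Pearson correlation of the vectorised strict
  upper triangles.
* Monte-Carlo p-values use the add-one estimator ``(1 + b) / (1 + m)`` so
  p is never 0 and the estimator is unbiased for the exceedance
  probability; the identity permutation is not forced into the sample.
* When ``n!`` does not exceed the permutation budget, all permutations are
  enumerated and the p-value is the exact fraction ``b / n!`` (the identity
  is part of the enumeration, so p >= 1/n!).
* The default tail is two-sided: both a positive (stasis-like) and a
  negative (convergence-like) relation were live alternatives, and the
  sign of r is always reported so direction is never lost.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .distances import DistanceMatrix
from .io_formats import ValidationError

_TAILS = ("two_sided", "greater", "less")
_EPS = 1e-12


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    tail: str
    n_entities: int
    exhaustive: bool
    statistic: str = "mantel_r"

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValidationError(f"|r|={abs(self.r)} exceeds 1")

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "r": self.r, "p": self.p,
                "n_permutations": self.n_permutations, "tail": self.tail,
                "n_entities": self.n_entities, "exhaustive": self.exhaustive}


@dataclass(frozen=True)
class HolmOutcome:
    raw_p: tuple[float, ...]
    adjusted_p: tuple[float, ...]
    rejected: tuple[bool, ...]
    alpha: float


def _triangles(A: DistanceMatrix, B: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    if A.labels != B.labels:
        raise ValidationError("distance matrices carry different labels/order")
    if len(A) < 3:
        raise ValidationError("Mantel test needs >= 3 entities")
    a, b = A.upper_triangle(), B.upper_triangle()
    if a.std() == 0 or b.std() == 0:
        raise ValidationError("zero variance in a distance triangle; "
                              "Mantel statistic undefined")
    return a, b


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with the fixed vector y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    den = np.sqrt((Xc * Xc).sum(axis=1) * (yc @ yc))
    return num / den


def mantel_statistic(A: DistanceMatrix, B: DistanceMatrix) -> float:
    """Pearson correlation between the strict upper triangles of A and B."""
    a, b = _triangles(A, B)
    return _pearson(a, b)


def _tail_count(r_perm: np.ndarray, r_obs: float, tail: str) -> int:
    if tail == "greater":
        return int((r_perm >= r_obs - _EPS).sum())
    if tail == "less":
        return int((r_perm <= r_obs + _EPS).sum())
    if tail == "two_sided":
        return int((np.abs(r_perm) >= abs(r_obs) - _EPS).sum())
    raise ValidationError(f"unknown tail {tail!r}")


def _permutation_rows(perms: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    """Upper-triangle vectors of vals under each row/column permutation.

    ``perms[k]`` maps position i to original entity perms[k, i]; the
    permuted matrix is vals[perm][:, perm], of which we need only the
    strict upper triangle.
    """
    iu, ju = np.triu_indices(n, k=1)
    return vals[perms[:, iu], perms[:, ju]]


def _make_perms(n: int, n_permutations: int, seed,
                exhaustive: bool | None) -> tuple[np.ndarray, bool]:
    full = math.factorial(n)
    do_exhaustive = (full <= n_permutations) if exhaustive is None else exhaustive
    if do_exhaustive:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        return perms, True
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n), dtype=np.intp)
    for k in range(n_permutations):
        perms[k] = rng.permutation(n)
    return perms, False


def mantel_test(A: DistanceMatrix, B: DistanceMatrix,
                n_permutations: int = 100_000, tail: str = "two_sided",
                seed: int = 0, exhaustive: bool | None = None) -> MantelResult:
    """Permutation Mantel test between two labelled distance matrices.

    A single permutation is applied simultaneously to the rows and columns
    of B.  With ``exhaustive=None`` (default) all ``n!`` permutations are
    enumerated whenever that count is within the permutation budget,
    giving an exact p-value; otherwise ``n_permutations`` seeded random
    permutations are drawn.
    """
    if tail not in _TAILS:
        raise ValidationError(f"unknown tail {tail!r}")
    a, _ = _triangles(A, B)
    n = len(A)
    r_obs = mantel_statistic(A, B)
    perms, is_exhaustive = _make_perms(n, n_permutations, seed, exhaustive)
    b_perm = _permutation_rows(perms, B.values, n)
    r_perm = _pearson_rows(b_perm, a)
    count = _tail_count(r_perm, r_obs, tail)
    if is_exhaustive:
        p = count / len(perms)
    else:
        p = (1 + count) / (1 + len(perms))
    return MantelResult(r_obs, p, len(perms), tail, n, is_exhaustive)


def _partial_r(r_ab: np.ndarray | float, r_ac: np.ndarray | float,
               r_bc: float):
    return (r_ab - r_ac * r_bc) / np.sqrt((1 - np.square(r_ac)) * (1 - r_bc ** 2))


def partial_mantel_statistic(A: DistanceMatrix, B: DistanceMatrix,
                             C: DistanceMatrix) -> float:
    """First-order partial correlation r_AB.C over upper triangles."""
    a, b = _triangles(A, B)
    _, c = _triangles(A, C)
    r_ab, r_ac, r_bc = _pearson(a, b), _pearson(a, c), _pearson(b, c)
    if min(1 - abs(r_ac), 1 - abs(r_bc)) < 1e-10:
        raise ValidationError(
            "control matrix collinear with a tested matrix (|r|=1); "
            "partial correlation undefined")
    return float(_partial_r(r_ab, r_ac, r_bc))


def partial_mantel_test(A: DistanceMatrix, B: DistanceMatrix, C: DistanceMatrix,
                        n_permutations: int = 100_000, tail: str = "two_sided",
                        seed: int = 0,
                        exhaustive: bool | None = None) -> MantelResult:
    """Partial Mantel test of A vs B controlling for C.

    The null distribution permutes A (rows and columns jointly) and
    recomputes the full partial statistic, so both r_AB and r_AC vary
    across permutations while r_BC is fixed.
    """
    if tail not in _TAILS:
        raise ValidationError(f"unknown tail {tail!r}")
    r_obs = partial_mantel_statistic(A, B, C)
    a, b = _triangles(A, B)
    _, c = _triangles(A, C)
    r_bc = _pearson(b, c)
    n = len(A)
    perms, is_exhaustive = _make_perms(n, n_permutations, seed, exhaustive)
    a_perm = _permutation_rows(perms, A.values, n)
    r_ab = _pearson_rows(a_perm, b)
    r_ac = _pearson_rows(a_perm, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = np.asarray(_partial_r(r_ab, r_ac, r_bc))
    r_perm = r_perm[np.isfinite(r_perm)]
    count = _tail_count(r_perm, r_obs, tail)
    if is_exhaustive:
        p = count / len(perms)
    else:
        p = (1 + count) / (1 + len(perms))
    return MantelResult(r_obs, p, len(perms), tail, n, is_exhaustive,
                        statistic="partial_mantel_r")


def holm_correct(raw_p, alpha: float = 0.05) -> HolmOutcome:
    """Holm's step-down adjustment controlling the family-wise error rate.

    Sort p-values ascending; the i-th order statistic is multiplied by
    (m - i + 1), running maxima enforce monotonicity, and rejections form
    a prefix of the rank order.
    """
    p = np.asarray(list(raw_p), dtype=float)
    if p.size == 0:
        return HolmOutcome((), (), (), alpha)
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(stepped), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    rejected = adjusted <= alpha
    return HolmOutcome(tuple(p), tuple(adjusted), tuple(bool(x) for x in rejected),
                       alpha)


def binomial_exceedance(n: int, k: int, p: float = 0.05) -> float:
    """Exact probability of at least k successes in n Bernoulli(p) trials.

    prob = sum_{i=k}^{n} C(n, i) p^i (1-p)^(n-i), evaluated with exact
    rational arithmetic so tail values of order 1e-8 carry no floating
    underflow or cancellation error.
    """
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p < 1:
        raise ValidationError("p must be in (0, 1)")
    pf = Fraction(str(p)) if isinstance(p, float) else Fraction(p)
    q = 1 - pf
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * pf ** i * q ** (n - i)
    return float(total)
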