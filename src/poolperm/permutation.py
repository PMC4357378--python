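"""Sign-flip permutation null for the pooling disequilibrium statistic.

Exchanging case and control labels within pooling set j leaves every
within-set allele measurement intact but negates column j of the
difference matrix D.  Under the null of no association and exchangeable
labels, all 2^J sign patterns are equally likely, so the permutation
distribution of T is generated by multiplying columns of D by random
+/-1 and recomputing T (candidate and null chi-squares alike) for each
pattern.

Because the row sums of squares are sign-invariant, only the numerators
(signed row sums) vary across patterns; the implementation precomputes
the denominators and evaluates all patterns with one matrix product.
"""

from __future__ import annotations

import numpy as np

from .stats import (
    DegenerateNullError,
    DifferenceMatrix,
    PoolDataError,
    TestResult,
    _as_d_array,
    chi2_per_marker,
    t_statistic,
)

__all__ = [
    "TIE_RULES",
    "apply_signs",
    "permutation_pvalue",
    "exhaustive_pvalue",
]

#: Recognised tie rules.  "greater" is the literal proportion of permutation
#: T statistics strictly larger than the observed one; the default
#: "greater-or-equal-plus-one" rule, p = (1 + #{T_perm >= T_obs}) / (1 + B),
#: counts the observed data as one more draw from the null and can never
#: return 0, guaranteeing a valid (conservative) test at any B.
TIE_RULES = ("greater", "greater-or-equal-plus-one")

DEFAULT_N_PERMUTATIONS = 10_000

_EXHAUSTIVE_MAX_J = 20
_CHUNK = 1 << 15


def apply_signs(D: DifferenceMatrix | np.ndarray, signs: np.ndarray) -> DifferenceMatrix:
    """Multiply column j of D by signs[j] (one sign per pooling set).

    The sign is shared by every marker row of that pooling set: flipping a
    set's disease labels flips the case-control difference of all markers
    measured on its pools simultaneously.
    """
    d = _as_d_array(D)
    s = np.asarray(signs)
    if s.ndim != 1 or s.shape[0] != d.shape[1]:
        raise PoolDataError(
            f"sign pattern length {s.shape} does not match J = {d.shape[1]} pooling sets"
        )
    if not np.all(np.abs(s) == 1):
        raise PoolDataError("sign pattern entries must be +1 or -1")
    markers = D.markers if isinstance(D, DifferenceMatrix) else None
    return DifferenceMatrix(D=d * s[None, :], markers=markers)


def _t_for_patterns(d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """T statistic for each sign pattern (rows of ``signs``), vectorized.

    Row denominators sum_j D_ij^2 are invariant under sign flips, so each
    pattern costs one matrix-vector product for the signed row sums.
    """
    den = (d * d).sum(axis=1)  # (L+1,)
    if not den[1:].any():
        raise DegenerateNullError(
            "every null-marker row is identically zero; the permutation "
            "distribution of T is undefined"
        )
    num = (d @ signs.T) ** 2  # (L+1, B)
    chi2 = np.zeros_like(num)
    nz = den > 0.0
    chi2[nz] = num[nz] / den[nz, None]
    return chi2[0] / chi2[1:].mean(axis=0)


def permutation_pvalue(
    D: DifferenceMatrix | np.ndarray,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    tie_rule: str = "greater-or-equal-plus-one",
) -> TestResult:
    """Monte-Carlo sign-flip permutation p-value for the T statistic.

    Parameters
    ----------
    D
        Difference matrix, candidate row first.
    n_permutations
        Number of independent uniform sign patterns to draw (default 10000).
    seed
        Integer seed or a ``numpy.random.Generator``; with an integer seed
        the result is bit-reproducible.
    tie_rule
        ``"greater-or-equal-plus-one"`` (default) or ``"greater"``; see
        :data:`TIE_RULES`.
    """
    if tie_rule not in TIE_RULES:
        raise PoolDataError(f"unknown tie rule {tie_rule!r}; expected one of {TIE_RULES}")
    if n_permutations < 1:
        raise PoolDataError("n_permutations must be at least 1")
    d = _as_d_array(D)
    t_obs = t_statistic(chi2_per_marker(d))
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_exceed = 0
    for start in range(0, n_permutations, _CHUNK):
        b = min(_CHUNK, n_permutations - start)
        signs = rng.integers(0, 2, size=(b, d.shape[1])) * 2 - 1
        t_perm = _t_for_patterns(d, signs)
        if tie_rule == "greater":
            n_exceed += int((t_perm > t_obs).sum())
        else:
            n_exceed += int((t_perm >= t_obs).sum())

    if tie_rule == "greater":
        p = n_exceed / n_permutations
    else:
        p = (1 + n_exceed) / (1 + n_permutations)
    return TestResult(
        T_observed=t_obs,
        p_value=float(p),
        n_permutations=n_permutations,
        tie_rule=tie_rule,
        seed=seed_out,
    )


def exhaustive_pvalue(
    D: DifferenceMatrix | np.ndarray,
    tie_rule: str = "greater-or-equal-plus-one",
) -> TestResult:
    """Exact permutation p-value by enumerating all 2^J sign patterns.

    With the default rule p = #{T >= T_obs} / 2^J; the identity pattern
    always ties, so p >= 2^-J.  Under ``"greater"`` the strict count is
    used.  Intended as ground truth for small J (refuses J > 20).
    """
    if tie_rule not in TIE_RULES:
        raise PoolDataError(f"unknown tie rule {tie_rule!r}; expected one of {TIE_RULES}")
    d = _as_d_array(D)
    J = d.shape[1]
    if J > _EXHAUSTIVE_MAX_J:
        raise PoolDataError(
            f"exhaustive enumeration of 2^{J} sign patterns refused "
            f"(J = {J} > {_EXHAUSTIVE_MAX_J}); use permutation_pvalue"
        )
    t_obs = t_statistic(chi2_per_marker(d))
    total = 1 << J
    bit = np.arange(J)
    n_exceed = 0
    for start in range(0, total, _CHUNK):
        codes = np.arange(start, min(start + _CHUNK, total))
        signs = ((codes[:, None] >> bit) & 1) * 2 - 1
        t_perm = _t_for_patterns(d, signs)
        if tie_rule == "greater":
            n_exceed += int((t_perm > t_obs).sum())
        else:
            n_exceed += int((t_perm >= t_obs).sum())
    return TestResult(
        T_observed=t_obs,
        p_value=n_exceed / total,
        n_permutations=total,
        tie_rule=tie_rule,
        seed=None,
        exhaustive=True,
    )
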