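"""Core statistics for stratum-matched DNA pooling association tests.

A pooling study measures, for each marker ``i = 0..L`` (``i = 0`` the
candidate, ``i = 1..L`` unlinked null markers used for genomic control)
and each pooling set ``j = 1..J``, the case-pool allele frequency
``p1[i, j]`` and the average control-pool allele frequency ``p0[i, j]``.
The per-marker pooling-set statistic is

    chi2[i] = (sum_j D[i, j])**2 / sum_j D[i, j]**2,   D = p1 - p0,

and the disequilibrium (genomic-control) test statistic is the candidate
chi-square divided by the mean null-marker chi-square,

    T = chi2[0] / mean(chi2[1:]).

Large T indicates case-control allele-frequency divergence at the
candidate beyond the residual stratification shared by the null markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import f as _f_dist

__all__ = [
    "PoolDataError",
    "DegenerateNullError",
    "PoolFrequencyTable",
    "DifferenceMatrix",
    "TestResult",
    "build_difference_matrix",
    "chi2_per_marker",
    "t_statistic",
    "large_sample_pvalue",
]


class PoolDataError(ValueError):
    """Structural or validation problem in pooling-study data."""


class DegenerateNullError(PoolDataError):
    """Every null-marker row is identically zero; T cannot be calibrated."""


def _check_freq_matrix(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise PoolDataError(f"{name} must be a 2-d (markers x pool sets) matrix")
    if not np.all(np.isfinite(x)):
        i, j = np.argwhere(~np.isfinite(x))[0]
        raise PoolDataError(f"{name}[{i}, {j}] is not a finite number")
    bad = (x < 0.0) | (x > 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PoolDataError(
            f"{name}[{i}, {j}] = {x[i, j]!r} is outside the allele-frequency range [0, 1]"
        )
    return x


@dataclass(frozen=True)
class PoolFrequencyTable:
    """Measured pool allele frequencies for L+1 markers across J pooling sets.

    Row 0 is the candidate marker; rows 1..L are the genomic-control null
    markers.  ``p1`` holds case-pool frequencies, ``p0`` the average of the
    ``m`` matched control pools.

    Parameters
    ----------
    markers
        Marker identifiers, candidate first.
    p1, p0
        Arrays of shape ``(L + 1, J)`` with entries in ``[0, 1]``.
    """

    markers: tuple[str, ...]
    p1: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        p1 = _check_freq_matrix("p1", self.p1)
        p0 = _check_freq_matrix("p0", self.p0)
        if p1.shape != p0.shape:
            raise PoolDataError(
                f"p1 shape {p1.shape} does not match p0 shape {p0.shape}"
            )
        n_markers, n_sets = p1.shape
        if n_sets < 2:
            raise PoolDataError(
                f"need at least 2 pooling sets (J >= 2), got J = {n_sets}; "
                "the pooling-set chi-square is degenerate at J = 1"
            )
        if n_markers < 2:
            raise PoolDataError(
                "need the candidate plus at least one null marker (L >= 1)"
            )
        markers = tuple(str(m) for m in self.markers)
        if len(markers) != n_markers:
            raise PoolDataError(
                f"{len(markers)} marker ids for {n_markers} marker rows"
            )
        object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "p1", p1)
        object.__setattr__(self, "p0", p0)

    @property
    def n_markers(self) -> int:
        return self.p1.shape[0]

    @property
    def n_null(self) -> int:
        """Number of genomic-control null markers, L."""
        return self.p1.shape[0] - 1

    @property
    def n_sets(self) -> int:
        """Number of pooling sets, J."""
        return self.p1.shape[1]


@dataclass(frozen=True)
class DifferenceMatrix:
    """Case-minus-control pooled frequency differences, candidate row first."""

    D: np.ndarray
    markers: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2:
            raise PoolDataError("D must be a 2-d (markers x pool sets) matrix")
        if not np.all(np.isfinite(D)):
            raise PoolDataError("D contains non-finite entries")
        if D.shape[1] < 2:
            raise PoolDataError(f"need J >= 2 pooling sets, got J = {D.shape[1]}")
        if D.shape[0] < 2:
            raise PoolDataError("need the candidate plus at least one null marker")
        if self.markers is not None:
            markers = tuple(str(m) for m in self.markers)
            if len(markers) != D.shape[0]:
                raise PoolDataError("marker ids do not match the number of rows")
            object.__setattr__(self, "markers", markers)
        object.__setattr__(self, "D", D)

    @property
    def n_sets(self) -> int:
        return self.D.shape[1]

    @property
    def n_null(self) -> int:
        return self.D.shape[0] - 1


@dataclass(frozen=True)
class TestResult:
    """Outcome of a disequilibrium test on one difference matrix.

    ``n_permutations`` is the Monte-Carlo replicate count, or ``2**J`` with
    ``exhaustive=True`` when every sign pattern was enumerated.
    """

    T_observed: float
    p_value: float
    n_permutations: int
    tie_rule: str
    seed: int | None = None
    exhaustive: bool = False
    comparator_p_value: float | None = None


def build_difference_matrix(table: PoolFrequencyTable) -> DifferenceMatrix:
    """Form D = p1 - p0, preserving marker order (candidate row 0)."""
    return DifferenceMatrix(D=table.p1 - table.p0, markers=table.markers)


def _as_d_array(D: DifferenceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(D, DifferenceMatrix):
        return D.D
    return np.asarray(D, dtype=float)


def chi2_per_marker(D: DifferenceMatrix | np.ndarray) -> np.ndarray:
    """Pooling-set chi-square per marker: (row sum)^2 / (row sum of squares).

    An identically-zero row is defined to give chi2 = 0 (no evidence of
    association); this keeps T well defined when a null marker happens to
    show no case-control difference in any pooling set.

    Returns
    -------
    numpy.ndarray
        Nonnegative vector of length L+1; each entry is bounded by J
        (Cauchy-Schwarz), with equality only for constant nonzero rows.
    """
    d = _as_d_array(D)
    if d.ndim == 1:
        d = d[None, :]
    if d.shape[1] < 2:
        raise PoolDataError("chi2_per_marker requires J >= 2 pooling sets")
    num = d.sum(axis=1) ** 2
    den = (d * d).sum(axis=1)
    out = np.zeros(d.shape[0])
    nz = den > 0.0
    out[nz] = num[nz] / den[nz]
    return out


def t_statistic(chi2: np.ndarray) -> float:
    """Genomic-control ratio T = chi2[0] / mean(chi2[1:]).

    Raises
    ------
    DegenerateNullError
        If every null-marker chi-square is zero, i.e. there is no
        genomic-control signal to calibrate against.
    """
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size < 2:
        raise PoolDataError("need the candidate plus at least one null marker")
    null_mean = chi2[1:].mean()
    if null_mean <= 0.0:
        raise DegenerateNullError(
            "mean null-marker chi-square is zero: every null-marker row is "
            "identically zero, so T cannot be calibrated"
        )
    return float(chi2[0] / null_mean)


def large_sample_pvalue(T_observed: float, n_null: int | None = None) -> float:
    """Upper-tail p-value of T under its large-sample reference distribution.

    Under the large-sample (polyset) model the candidate chi-square is a
    scaled 1-df chi-square and the genomic-control denominator — the mean
    of L independent null chi-squares — is the same scale times a
    chi-square(L)/L, so T is referred to F(1, L) when ``n_null`` (= L) is
    given.  With ``n_null=None`` the L -> infinity limit is used and T is
    referred to chi-square(1), the classical genomic-control convention;
    the two coincide for large null panels.

    For oligoset J the permutation null is the primary inference; this
    large-sample comparator is conservative there, because the bounded
    pooling-set chi-square (chi2 <= J) has a lighter tail than its
    chi-square(1) limit.
    """
    if T_observed < 0:
        raise PoolDataError("T must be nonnegative")
    if n_null is None:
        return float(_chi2_dist.sf(T_observed, df=1))
    if n_null < 1:
        raise PoolDataError("n_null must be a positive integer")
    return float(_f_dist.sf(T_observed, 1, n_null))
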