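"""Synthetic data generator for stratum-matched DNA pooling studies.

The generator reproduces the standard simulation model for evaluating
pooling-based association tests under population stratification:

* a source population of hidden strata (default five, equal weight) that
  differ in both allele frequency and baseline disease risk, so that
  ignoring stratum structure biases the naive case-control comparison;
* ``n`` cases, each with ``m`` stratum-matched controls; matching is
  imperfect: with probability ``delta`` (the mismatch index) a control is
  drawn at random from the population instead of from the case's stratum;
* random allocation of each matched set to one of ``J`` pooling sets; in
  set j all cases form one case pool and the k-th control of each set
  forms control pool k, for ``J * (1 + m)`` pools in total;
* quantitative-PCR measurement of each pool's allele frequency with
  unequal allelic amplification (a per-marker coefficient
  ``kappa ~ Uniform(1, 2)`` distorting p to ``kappa*p / (kappa*p + 1 - p)``)
  and logit-normal noise calibrated so the frequency-scale SD is
  approximately ``sigma``.

Cases carry a per-allele multiplicative odds effect at the candidate
marker (``effect_size = 1`` for null scenarios).  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit
from scipy.stats import binom as _binom

from .stats import PoolDataError, PoolFrequencyTable

__all__ = [
    "StratumModel",
    "ScenarioConfig",
    "MatchedSets",
    "default_stratum_model",
    "draw_matched_sets",
    "allocate_to_pools",
    "true_pool_frequency",
    "measure_pool",
    "simulate_dataset",
]


@dataclass(frozen=True)
class StratumModel:
    """Hidden-stratum structure of the source population.

    Parameters
    ----------
    allele_freqs
        ``(L + 1, n_strata)`` true allele frequencies, candidate row first;
        all strictly inside (0, 1).
    stratum_weights
        Population stratum proportions, summing to 1.
    disease_risk
        Per-stratum baseline disease probability (for a candidate genotype
        of 0 copies).
    """

    allele_freqs: np.ndarray
    stratum_weights: np.ndarray
    disease_risk: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.allele_freqs, dtype=float)
        w = np.asarray(self.stratum_weights, dtype=float)
        r = np.asarray(self.disease_risk, dtype=float)
        if f.ndim != 2:
            raise PoolDataError("allele_freqs must be (markers x strata)")
        if np.any(f <= 0.0) or np.any(f >= 1.0):
            raise PoolDataError("allele frequencies must lie strictly inside (0, 1)")
        if w.shape != (f.shape[1],) or r.shape != (f.shape[1],):
            raise PoolDataError("stratum_weights/disease_risk must have one entry per stratum")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise PoolDataError("stratum_weights must be a probability vector")
        if np.any(r <= 0) or np.any(r >= 1):
            raise PoolDataError("disease_risk entries must lie strictly inside (0, 1)")
        object.__setattr__(self, "allele_freqs", f)
        object.__setattr__(self, "stratum_weights", w)
        object.__setattr__(self, "disease_risk", r)

    @property
    def n_strata(self) -> int:
        return self.allele_freqs.shape[1]

    @property
    def n_null(self) -> int:
        return self.allele_freqs.shape[0] - 1


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one simulation scenario.

    Defaults are the canonical null scenario: 900 cases with 1:1 matching,
    10 pooling sets, 10 null markers, mismatch index 0.1, measurement error
    0.01, per-marker amplification kappa ~ Uniform(1, 2), no candidate
    effect.
    """

    n_cases: int = 900
    m: int = 1
    J: int = 10
    L: int = 10
    delta: float = 0.1
    sigma: float = 0.01
    kappa_range: tuple[float, float] = (1.0, 2.0)
    effect_size: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cases < self.J:
            raise PoolDataError("need at least one matched set per pooling set (n_cases >= J)")
        if self.m < 1:
            raise PoolDataError("matching ratio m must be >= 1")
        if self.J < 2:
            raise PoolDataError("need J >= 2 pooling sets")
        if self.L < 1:
            raise PoolDataError("need L >= 1 null markers")
        if not 0.0 <= self.delta <= 1.0:
            raise PoolDataError("mismatch index delta must lie in [0, 1]")
        if self.sigma < 0.0:
            raise PoolDataError("measurement error sigma must be >= 0")
        lo, hi = self.kappa_range
        if lo < 1.0 or hi < lo:
            raise PoolDataError("kappa_range must satisfy 1 <= lo <= hi")
        if self.effect_size <= 0.0:
            raise PoolDataError("effect_size (per-allele odds ratio) must be > 0")

    @property
    def n_pools(self) -> int:
        """Total number of DNA pools, J * (1 + m)."""
        return self.J * (1 + self.m)

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MatchedSets:
    """Genotypes and strata of n matched case-control sets.

    ``case_genotypes`` is ``(n, L + 1)`` allele-copy counts (0/1/2);
    ``control_genotypes`` is ``(n, m, L + 1)``.
    """

    case_genotypes: np.ndarray
    control_genotypes: np.ndarray
    case_strata: np.ndarray
    control_strata: np.ndarray


def default_stratum_model(
    n_null: int,
    n_strata: int = 5,
    rng: np.random.Generator | None = None,
    null_freq_range: tuple[float, float] = (0.1, 0.9),
    candidate_freqs: np.ndarray | None = None,
    disease_risk: np.ndarray | None = None,
) -> StratumModel:
    """Build the default confounded five-stratum population.

    Null-marker frequencies are drawn once per (marker, stratum) from
    ``Uniform(0.1, 0.9)`` — each simulated study gets a fresh random panel
    of genomic-control markers.  The candidate's stratum frequencies
    (0.2..0.6) and the baseline disease risks (0.02..0.10) increase
    together across strata, so hidden structure confounds the naive
    case-control comparison at the candidate.
    """
    rng = np.random.default_rng(rng)
    if candidate_freqs is None:
        candidate_freqs = np.linspace(0.2, 0.6, n_strata)
    if disease_risk is None:
        disease_risk = np.linspace(0.02, 0.10, n_strata)
    lo, hi = null_freq_range
    null_freqs = rng.uniform(lo, hi, size=(n_null, n_strata))
    return StratumModel(
        allele_freqs=np.vstack([np.asarray(candidate_freqs, float), null_freqs]),
        stratum_weights=np.full(n_strata, 1.0 / n_strata),
        disease_risk=np.asarray(disease_risk, float),
    )


def _case_control_genotype_probs(
    model: StratumModel, effect_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate-genotype distributions among cases and controls, per stratum.

    Disease follows a per-allele multiplicative odds model:
    odds(D | g, s) = odds_s * effect_size**g.  Returns the (strata, 3)
    conditional genotype distributions P(g | s, D) and P(g | s, not D),
    each row normalised.
    """
    g = np.arange(3)
    f0 = model.allele_freqs[0][:, None]  # (S, 1)
    pg = _binom.pmf(g[None, :], 2, f0)  # (S, 3) Hardy-Weinberg
    odds = (model.disease_risk / (1.0 - model.disease_risk))[:, None]
    odds_g = odds * effect_size ** g[None, :]
    p_disease = odds_g / (1.0 + odds_g)  # (S, 3)
    case = pg * p_disease
    ctrl = pg * (1.0 - p_disease)
    return case / case.sum(axis=1, keepdims=True), ctrl / ctrl.sum(axis=1, keepdims=True)


def draw_matched_sets(
    model: StratumModel,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> MatchedSets:
    """Sample n cases with m matched controls each, with genotypes.

    Case strata and candidate genotypes are drawn jointly from the
    case-ascertained distribution (population weights tilted by stratum
    disease risk and the per-allele effect).  Each control is from the
    case's stratum with probability 1 - delta and from the population
    stratum distribution otherwise; control candidate genotypes follow the
    non-diseased conditional distribution, null-marker genotypes are
    binomial(2, f) within stratum for everyone.
    """
    rng = np.random.default_rng(rng)
    n, m = config.n_cases, config.m
    S = model.n_strata
    L1 = model.allele_freqs.shape[0]
    w = model.stratum_weights

    case_g_probs, ctrl_g_probs = _case_control_genotype_probs(model, config.effect_size)
    # joint case distribution over (stratum, candidate genotype):
    # P(s, g | D) propto w_s * P(g | s) * P(D | g, s), which factors as
    # P(s | D) * P(g | s, D) with P(s | D) propto w_s * P(D | s)
    g = np.arange(3)
    f0 = model.allele_freqs[0][:, None]
    pg = _binom.pmf(g[None, :], 2, f0)
    odds = (model.disease_risk / (1.0 - model.disease_risk))[:, None]
    odds_g = odds * config.effect_size ** g[None, :]
    p_disease_s = (pg * odds_g / (1.0 + odds_g)).sum(axis=1)  # P(D | s)
    case_stratum_probs = w * p_disease_s
    case_stratum_probs = case_stratum_probs / case_stratum_probs.sum()

    case_strata = rng.choice(S, size=n, p=case_stratum_probs)
    case_G = np.empty((n, L1), dtype=np.int64)
    case_G[:, 0] = _categorical_rows(case_g_probs[case_strata], rng)
    case_G[:, 1:] = rng.binomial(2, model.allele_freqs[1:, case_strata].T)

    random_match = rng.random((n, m)) < config.delta
    ctrl_strata = np.where(
        random_match,
        rng.choice(S, size=(n, m), p=w),
        case_strata[:, None],
    )
    ctrl_G = np.empty((n, m, L1), dtype=np.int64)
    ctrl_G[:, :, 0] = _categorical_rows(
        ctrl_g_probs[ctrl_strata].reshape(-1, 3), rng
    ).reshape(n, m)
    ctrl_G[:, :, 1:] = rng.binomial(
        2, np.moveaxis(model.allele_freqs[1:, ctrl_strata], 0, -1)
    )
    return MatchedSets(
        case_genotypes=case_G,
        control_genotypes=ctrl_G,
        case_strata=case_strata,
        control_strata=ctrl_strata,
    )


def _categorical_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of ``probs`` (rows sum to 1)."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def allocate_to_pools(
    n_sets: int, J: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Assign each matched set independently and uniformly to one of J pooling sets.

    Redraws the whole allocation in the (vanishingly rare for n >> J) event
    that some pooling set receives no matched set, so every pool is
    non-empty.
    """
    if n_sets < J:
        raise PoolDataError("cannot fill J pooling sets with fewer matched sets")
    rng = np.random.default_rng(rng)
    while True:
        pool = rng.integers(0, J, size=n_sets)
        if np.bincount(pool, minlength=J).min() > 0:
            return pool


def true_pool_frequency(genotypes: np.ndarray) -> float:
    """True allele fraction of a pool: total allele copies / (2 * pool size)."""
    g = np.asarray(genotypes)
    if g.size == 0:
        raise PoolDataError("empty pool has no allele frequency")
    return float(g.sum() / (2 * g.shape[0])) if g.ndim == 1 else float(
        g.sum() / (2 * g.size)
    )


def measure_pool(
    true_freq: np.ndarray | float,
    kappa: np.ndarray | float,
    sigma: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray | float:
    """Quantitative-PCR measurement of a pool allele frequency.

    Two-step error model: unequal allelic amplification distorts the true
    frequency p to p' = kappa*p / (kappa*p + 1 - p), then the measured
    value is logit-normal about p' with logit-scale SD
    tau = sigma / (p' * (1 - p')), the delta-method calibration making the
    frequency-scale SD approximately sigma.  With sigma = 0 the distorted
    value p' is returned exactly.  Monomorphic pools (p in {0, 1}) are
    returned unchanged with a warning, since their logit is undefined.
    """
    p = np.asarray(true_freq, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    k = np.broadcast_to(np.asarray(kappa, dtype=float), p.shape)
    if np.any(k < 1.0):
        raise PoolDataError("amplification coefficient kappa must be >= 1")
    if sigma < 0:
        raise PoolDataError("sigma must be >= 0")

    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        warnings.warn(
            "monomorphic pool frequency (0 or 1) passed through unmeasured",
            RuntimeWarning,
            stacklevel=2,
        )
    out = p.copy()
    ok = ~mono
    pp = k[ok] * p[ok] / (k[ok] * p[ok] + 1.0 - p[ok])
    if sigma == 0.0:
        out[ok] = pp
    else:
        rng = np.random.default_rng(rng)
        tau = sigma / (pp * (1.0 - pp))
        out[ok] = expit(logit(pp) + tau * rng.standard_normal(pp.shape))
    return float(out[0]) if scalar else out


def simulate_dataset(
    config: ScenarioConfig,
    model: StratumModel | None = None,
    rng: np.random.Generator | None = None,
) -> PoolFrequencyTable:
    """End-to-end simulation of one pooling study's frequency table.

    Matched sets -> uniform pool allocation -> per-pool true frequencies ->
    per-pool measured frequencies; p1[i, j] is the measured case-pool
    frequency, p0[i, j] the mean of the m measured control-pool
    frequencies.  With ``model=None`` a fresh :func:`default_stratum_model`
    (random null-marker panel) is drawn from the same random stream.
    Fully reproducible from (model, config, seed).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if model is None:
        model = default_stratum_model(config.L, rng=rng)
    if model.n_null != config.L:
        raise PoolDataError(
            f"stratum model has {model.n_null} null markers, scenario expects {config.L}"
        )

    sets = draw_matched_sets(model, config, rng)
    pool = allocate_to_pools(config.n_cases, config.J, rng)
    counts = np.bincount(pool, minlength=config.J).astype(float)

    L1 = config.L + 1
    case_sum = np.zeros((config.J, L1))
    np.add.at(case_sum, pool, sets.case_genotypes.astype(float))
    p_case = case_sum / (2.0 * counts[:, None])  # (J, L+1)

    p_ctrl = np.empty((config.m, config.J, L1))
    for k in range(config.m):
        ctrl_sum = np.zeros((config.J, L1))
        np.add.at(ctrl_sum, pool, sets.control_genotypes[:, k, :].astype(float))
        p_ctrl[k] = ctrl_sum / (2.0 * counts[:, None])

    lo, hi = config.kappa_range
    kappa = rng.uniform(lo, hi, size=L1) if hi > lo else np.full(L1, lo)

    meas_case = measure_pool(p_case, kappa[None, :], config.sigma, rng)
    meas_ctrl = np.empty_like(p_ctrl)
    for k in range(config.m):
        meas_ctrl[k] = measure_pool(p_ctrl[k], kappa[None, :], config.sigma, rng)

    markers = ("candidate",) + tuple(f"null_{i}" for i in range(1, L1))
    return PoolFrequencyTable(
        markers=markers,
        p1=np.asarray(meas_case).T,
        p0=meas_ctrl.mean(axis=0).T,
    )
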