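"""Monte-Carlo drivers: type-I error and power grids for the permutation test.

Each grid cell simulates many independent pooling studies under one
scenario, runs the sign-flip permutation test (and, on the very same
replicates, the large-sample chi-square(1) comparator) on each, and
reports the rejection rate at each nominal level with its binomial
Monte-Carlo standard error.  Replicate seeds are derived from the master
seed with ``numpy.random.SeedSequence`` spawning, so grids are
deterministic and cells independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .permutation import permutation_pvalue
from .simulate import ScenarioConfig, simulate_dataset
from .stats import build_difference_matrix, large_sample_pvalue

__all__ = [
    "ExperimentSummary",
    "replicate_pvalues",
    "run_type1_grid",
    "run_power_grid",
    "typing_cost_ratio",
]

DEFAULT_ALPHAS = (0.05, 0.005)
TEST_KINDS = ("permutation", "large_sample")


@dataclass(frozen=True)
class ExperimentSummary:
    """Rejection rate of one test in one (scenario, alpha) cell."""

    scenario: ScenarioConfig
    alpha: float
    n_replicates: int
    rejection_rate: float
    mc_standard_error: float
    test_kind: str

    @staticmethod
    def from_rejections(
        scenario: ScenarioConfig, alpha: float, rejected: np.ndarray, test_kind: str
    ) -> "ExperimentSummary":
        n = rejected.size
        r = float(rejected.mean())
        return ExperimentSummary(
            scenario=scenario,
            alpha=alpha,
            n_replicates=n,
            rejection_rate=r,
            mc_standard_error=float(np.sqrt(r * (1.0 - r) / n)),
            test_kind=test_kind,
        )


def replicate_pvalues(
    scenario: ScenarioConfig,
    n_replicates: int,
    n_permutations: int,
    seed_seq: np.random.SeedSequence,
    tie_rule: str = "greater-or-equal-plus-one",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_replicates`` studies; return paired (permutation,
    large-sample) p-value arrays.

    One child seed per replicate drives the dataset simulation and the
    permutation draws, so both tests see identical data.
    """
    perm_p = np.empty(n_replicates)
    ls_p = np.empty(n_replicates)
    for r, child in enumerate(seed_seq.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        table = simulate_dataset(scenario, rng=rng)
        D = build_difference_matrix(table)
        res = permutation_pvalue(
            D, n_permutations=n_permutations, seed=rng, tie_rule=tie_rule
        )
        perm_p[r] = res.p_value
        ls_p[r] = large_sample_pvalue(res.T_observed, n_null=scenario.L)
    return perm_p, ls_p


def _run_grid(
    scenarios: Sequence[ScenarioConfig],
    n_replicates: int,
    n_permutations: int,
    seed: int,
    alphas: Iterable[float],
    test_kinds: Sequence[str],
    tie_rule: str,
) -> list[ExperimentSummary]:
    for kind in test_kinds:
        if kind not in TEST_KINDS:
            raise ValueError(f"unknown test kind {kind!r}; expected one of {TEST_KINDS}")
    alphas = tuple(alphas)
    out: list[ExperimentSummary] = []
    for k, scenario in enumerate(scenarios):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(k,))
        perm_p, ls_p = replicate_pvalues(
            scenario, n_replicates, n_permutations, ss, tie_rule
        )
        pvals = {"permutation": perm_p, "large_sample": ls_p}
        for alpha in alphas:
            for kind in test_kinds:
                out.append(
                    ExperimentSummary.from_rejections(
                        scenario, alpha, pvals[kind] <= alpha, kind
                    )
                )
    return out


def run_type1_grid(
    scenarios: Sequence[ScenarioConfig],
    n_replicates: int = 2000,
    n_permutations: int = 1000,
    seed: int = 0,
    alphas: Iterable[float] = DEFAULT_ALPHAS,
    test_kinds: Sequence[str] = TEST_KINDS,
    tie_rule: str = "greater-or-equal-plus-one",
) -> list[ExperimentSummary]:
    """Type-I error rates over null scenarios (effect_size = 1).

    Rejection uses p <= alpha.  Returns one summary per
    (scenario, alpha, test_kind); permutation and large-sample summaries in
    a cell share the same simulated replicates (paired comparison).
    """
    for s in scenarios:
        if s.effect_size != 1.0:
            raise ValueError(
                "type-I grid requires null scenarios (effect_size = 1); "
                f"got effect_size = {s.effect_size}"
            )
    return _run_grid(
        scenarios, n_replicates, n_permutations, seed, alphas, test_kinds, tie_rule
    )


def run_power_grid(
    scenarios: Sequence[ScenarioConfig],
    n_replicates: int = 2000,
    n_permutations: int = 1000,
    seed: int = 0,
    alphas: Iterable[float] = DEFAULT_ALPHAS,
    test_kinds: Sequence[str] = ("permutation",),
    tie_rule: str = "greater-or-equal-plus-one",
) -> list[ExperimentSummary]:
    """Power over alternative scenarios (effect_size > 1).

    Same machinery as :func:`run_type1_grid`; with effect_size = 1 the
    estimate degenerates to the test's size.
    """
    return _run_grid(
        scenarios, n_replicates, n_permutations, seed, alphas, test_kinds, tie_rule
    )


def typing_cost_ratio(J: int, m: int, n_cases: int, n_controls: int) -> Fraction:
    """Assays per marker under pooling relative to individual genotyping.

    A pooling study types J * (1 + m) pools per marker where individual
    genotyping types every one of the n_cases + n_controls subjects.
    """
    if min(J, m, n_cases, n_controls) <= 0:
        raise ValueError("all arguments must be positive")
    return Fraction(J * (1 + m), n_cases + n_controls)
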