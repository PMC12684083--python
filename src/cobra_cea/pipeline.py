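"""Glue: run the full model for every strategy and sex and compare.

Sex is handled by two independent cohort runs at the profile's mean
covariates, pooled downstream at the cohort's sex mix (64.3% female by
default, the trial's).
"""

from __future__ import annotations

from dataclasses import dataclass

from .cea import IncrementalResult, incremental, pool_sexes
from .markov_engine import run_trace
from .outcomes import StrategyResult, summarize
from .parameters import ParameterBundle, Sex

__all__ = ["BaseCaseResult", "run_strategy", "evaluate_bundle"]


def run_strategy(bundle: ParameterBundle, strategy_name: str) -> dict[str, StrategyResult]:
    """Run one strategy for both sexes and pool; returns keys
    'male', 'female', 'pooled'."""
    strategy = bundle.strategy(strategy_name)
    results: dict[str, StrategyResult] = {}
    for sex in ("male", "female"):
        trace = run_trace(bundle, strategy, sex)
        results[sex] = summarize(trace, bundle, strategy)
    results["pooled"] = pool_sexes(
        results["male"], results["female"], bundle.cohort.prop_female
    )
    return results


@dataclass
class BaseCaseResult:
    """Per-strategy results at every pooling level plus incrementals."""

    strategies: dict[str, dict[str, StrategyResult]]
    incrementals: dict[str, IncrementalResult]  # keyed by pooling level
    reference: str
    alternative: str


def evaluate_bundle(
    bundle: ParameterBundle,
    reference: str = "SoC",
    alternative: str = "COBRA",
) -> BaseCaseResult:
    """Full base case: both strategies, both sexes, pooled, incrementals."""
    strategies = {name: run_strategy(bundle, name) for name in (reference, alternative)}
    thresholds = bundle.settings.thresholds
    incrementals = {
        level: incremental(strategies[reference][level], strategies[alternative][level], thresholds)
        for level in ("male", "female", "pooled")
    }
    return BaseCaseResult(
        strategies=strategies,
        incrementals=incrementals,
        reference=reference,
        alternative=alternative,
    )
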