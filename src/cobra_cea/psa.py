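"""Probabilistic sensitivity analysis.

Every uncertain parameter carries a distribution specification addressed by
its dotted bundle path (beta for probabilities and disability weights,
gamma/lognormal for costs and relative risks, normal for coefficients and
the SBP effect).  Each iteration jointly redraws all listed parameters,
re-runs both strategies for both sexes, pools at the cohort sex mix and
computes the incremental comparison; the cohort's baseline characteristics
are never resampled, so the PSA reflects parameter uncertainty rather than
cohort variability.

Reproducibility: iteration i uses ``numpy.random.default_rng([seed, i])`` —
a documented counter scheme giving independent, parallel-safe streams, so
identical seeds give bit-identical iteration tables.  Failed iterations are
skipped and logged, never resampled (resampling would bias the empirical
distribution); more than 1% failures aborts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .cea import net_monetary_benefit
from .parameters import ParameterBundle, PSADistribution, resolve_path, set_path
from .pipeline import evaluate_bundle

__all__ = ["PSAResult", "sample_bundle", "run_psa", "ceac", "export_ce_plane",
           "summarize_psa"]

log = logging.getLogger(__name__)

RESAMPLE_CAP = 100
MAX_FAILURE_FRACTION = 0.01


def _draw(dist: PSADistribution, rng: np.random.Generator):
    p = dist.params or {}
    if dist.family == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    if dist.family == "gamma":
        return float(rng.gamma(p["shape"], p["scale"]))
    if dist.family == "normal":
        return float(rng.normal(p["mu"], p["sigma"]))
    if dist.family == "lognormal":
        return float(rng.lognormal(p["mu"], p["sigma"]))
    if dist.family == "dirichlet":
        return [float(x) for x in rng.dirichlet(dist.alpha)]
    raise ValueError(f"unknown family {dist.family}")


def sample_bundle(base: ParameterBundle, rng: np.random.Generator) -> ParameterBundle:
    """One joint draw of all uncertain parameters.

    Values that violate a bundle invariant trigger a full joint resample (up
    to a cap) so the accepted draw is always a valid bundle.  Degenerate
    (zero-variance) distributions return the base values exactly.
    """
    for _ in range(RESAMPLE_CAP):
        candidate = base.model_copy(deep=True)
        for path, dist in base.psa.distributions.items():
            set_path(candidate, path, _draw(dist, rng))
        try:
            revalidated = ParameterBundle.model_validate(candidate.model_dump(mode="json"))
        except ValidationError:
            continue
        return revalidated
    raise RuntimeError(f"no valid parameter draw within {RESAMPLE_CAP} attempts")


@dataclass
class PSAResult:
    """Iteration table plus equal-tailed intervals and the CEAC."""

    iterations: pd.DataFrame
    intervals: pd.DataFrame          # index: outcome; columns: mean, lo, hi
    ceac: dict[float, float]         # threshold -> P(cost-effective)
    seed: int
    n_requested: int
    n_failed: int = 0
    failures: list[int] = field(default_factory=list)


ITERATION_COLUMNS = [
    "iteration",
    "cost_ref", "cost_alt", "dalys_ref", "dalys_alt",
    "years_alive_ref", "years_alive_alt",
    "delta_cost", "dalys_averted", "delta_years_alive",
]


def run_psa(
    base: ParameterBundle,
    seed: int | None = None,
    n_iterations: int | None = None,
    reference: str = "SoC",
    alternative: str = "COBRA",
) -> PSAResult:
    """Run the PSA; fully reproducible from the seed.

    ``seed`` and ``n_iterations`` default to the bundle's PSA settings.
    """
    seed = base.psa.seed if seed is None else seed
    n = base.psa.n_iterations if n_iterations is None else n_iterations
    if n < 1:
        raise ValueError("need at least one iteration")
    rows = []
    failures: list[int] = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        try:
            sampled = sample_bundle(base, rng)
            res = evaluate_bundle(sampled, reference, alternative)
        except Exception:  # noqa: BLE001 - failures are recorded, not fatal
            log.warning("PSA iteration %d failed", i, exc_info=True)
            failures.append(i)
            if len(failures) > max(MAX_FAILURE_FRACTION * n, 1):
                raise RuntimeError(
                    f"{len(failures)} of {i + 1} PSA iterations failed; aborting"
                )
            continue
        ref, alt = res.strategies[reference]["pooled"], res.strategies[alternative]["pooled"]
        inc = res.incrementals["pooled"]
        rows.append({
            "iteration": i,
            "cost_ref": ref.cost, "cost_alt": alt.cost,
            "dalys_ref": ref.dalys, "dalys_alt": alt.dalys,
            "years_alive_ref": ref.years_alive, "years_alive_alt": alt.years_alive,
            "delta_cost": inc.delta_cost,
            "dalys_averted": inc.dalys_averted,
            "delta_years_alive": inc.delta_years_alive,
        })
    iterations = pd.DataFrame(rows, columns=ITERATION_COLUMNS)
    intervals = summarize_psa(iterations)
    curve = ceac(iterations, base.settings.thresholds)
    return PSAResult(
        iterations=iterations, intervals=intervals, ceac=curve,
        seed=seed, n_requested=n, n_failed=len(failures), failures=failures,
    )


def summarize_psa(iterations: pd.DataFrame) -> pd.DataFrame:
    """Mean and equal-tailed 95% interval (2.5th/97.5th percentiles, inclusive
    linear interpolation) for every outcome column."""
    out = {}
    for col in iterations.columns:
        if col == "iteration":
            continue
        x = iterations[col].to_numpy()
        lo, hi = np.percentile(x, [2.5, 97.5], method="linear")
        out[col] = {"mean": float(x.mean()), "lo": float(lo), "hi": float(hi)}
    return pd.DataFrame(out).T[["mean", "lo", "hi"]]


def ceac(iterations: pd.DataFrame, thresholds: list[float]) -> dict[float, float]:
    """Probability that the alternative is cost-effective (NMB > 0) at each
    willingness-to-pay threshold."""
    if iterations.empty:
        raise ValueError("CEAC requires at least one iteration")
    de = iterations["dalys_averted"].to_numpy()
    dc = iterations["delta_cost"].to_numpy()
    return {
        float(lam): float(np.mean(net_monetary_benefit(lam, de, dc) > 0))
        for lam in thresholds
    }


def export_ce_plane(
    iterations: pd.DataFrame,
    path: str | Path,
    figure_path: str | Path | None = None,
    thresholds: tuple[float, ...] = (183.0, 500.0, 1000.0),
) -> None:
    """Write the cost-effectiveness plane (ΔE, ΔC) pairs as CSV and,
    optionally, a scatter figure with threshold rays."""
    if iterations.empty:
        raise ValueError("cannot export an empty iteration table")
    plane = iterations[["dalys_averted", "delta_cost"]]
    plane.to_csv(path, index=False)
    if figure_path is None:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(plane["dalys_averted"], plane["delta_cost"], s=6, alpha=0.4)
    xmax = max(plane["dalys_averted"].max(), 0) * 1.1 or 1.0
    xs = np.linspace(0, xmax, 50)
    for lam in thresholds:
        ax.plot(xs, lam * xs, "r:", lw=1, label=f"US${lam:.0f}/DALY")
    ax.axhline(0, color="b", ls="--", lw=0.8)
    ax.axvline(0, color="b", ls="--", lw=0.8)
    ax.set_xlabel("DALYs averted")
    ax.set_ylabel("Incremental cost (US$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(figure_path, dpi=150)
    plt.close(fig)
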