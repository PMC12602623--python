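"""Factorial simulation driver: replications, methods, and aggregation.

For each scenario, ``run_scenario`` generates ``n_reps`` independent samples,
applies the requested inference methods to the slope of the first predictor
(the coefficient of interest), and aggregates rejection rates, coverage
rates, coefficient moments and mean estimated SEs.  Each replication has its
own RNG substream derived from the scenario seed, so any single replication
is reproducible in isolation and replication order cannot affect results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap_inference import (
    BootstrapDistribution,
    bca_ci,
    bootstrap_p_value,
    pairs_resample,
    percentile_ci,
    wild_resample,
)
from .ols_core import InferenceResult, classical_inference, fit_ols
from .robust_se import hc_covariance, hc_inference
from .synthetic_data import Scenario, generate_sample

__all__ = [
    "ALL_METHODS",
    "PerformanceSummary",
    "TestStatArchive",
    "run_scenario",
    "run_grid",
    "se_bias_table",
    "summaries_to_frame",
]

#: The nine evaluated inference procedures.
ALL_METHODS = (
    "classical",
    "HC3",
    "HC4",
    "pairs_p",
    "pairs_percentile",
    "pairs_BCa",
    "wild_p",
    "wild_percentile",
    "wild_BCa",
)

_SE_METHODS = frozenset({"classical", "HC3", "HC4"})
_CI_METHODS = frozenset(
    {"classical", "HC3", "HC4", "pairs_percentile", "pairs_BCa",
     "wild_percentile", "wild_BCa"}
)
COEF_OF_INTEREST = 1  # the x1 slope, in every model


@dataclass
class PerformanceSummary:
    """Aggregated performance of one method in one scenario."""

    scenario: Scenario
    method: str
    n_reps_done: int
    rejection_rate: float
    coverage_rate: float | None  # None for p-value-only methods
    mean_beta: float
    sd_beta: float  # the "simulated SE"
    mean_se: float | None  # None for bootstrap methods
    flagged_reps: int = 0
    mean_attempts: float = 1.0


@dataclass
class TestStatArchive:
    """Per-replication test statistics (classical/HC3/HC4 only)."""

    scenario: Scenario
    method: str
    t_values: np.ndarray = field(default_factory=lambda: np.empty(0))


class ExcessiveDegeneracyError(RuntimeError):
    """Too many replications hit degenerate numerical corners."""


def _bootstrap_results(
    scheme: str,
    dist: BootstrapDistribution,
    fit,
    methods: set[str],
    beta_true: float,
    alpha: float,
) -> dict[str, InferenceResult]:
    out: dict[str, InferenceResult] = {}
    est = dist.original_estimate
    if f"{scheme}_p" in methods:
        p = bootstrap_p_value(dist)
        out[f"{scheme}_p"] = InferenceResult(
            method=f"{scheme}_p", coef_index=COEF_OF_INTEREST, estimate=est,
            p_value=p, reject=bool(p < alpha),
        )
    if f"{scheme}_percentile" in methods:
        lo, hi = percentile_ci(dist, 1.0 - alpha)
        out[f"{scheme}_percentile"] = InferenceResult(
            method=f"{scheme}_percentile", coef_index=COEF_OF_INTEREST,
            estimate=est, ci_low=lo, ci_high=hi,
            reject=not (lo <= 0.0 <= hi), covers=bool(lo <= beta_true <= hi),
        )
    if f"{scheme}_BCa" in methods:
        bca = bca_ci(dist, fit, 1.0 - alpha, k=COEF_OF_INTEREST)
        out[f"{scheme}_BCa"] = InferenceResult(
            method=f"{scheme}_BCa", coef_index=COEF_OF_INTEREST, estimate=est,
            ci_low=bca.low, ci_high=bca.high,
            reject=not (bca.low <= 0.0 <= bca.high),
            covers=bool(bca.low <= beta_true <= bca.high),
            flagged=bca.flagged,
        )
    return out


def run_replication(
    scenario: Scenario,
    rng: np.random.Generator,
    methods: set[str],
    *,
    alpha: float = 0.05,
    coef=None,
) -> tuple[dict[str, InferenceResult], int]:
    """One replication: simulate, fit, apply every requested method."""
    sample = generate_sample(scenario, rng, coef=coef)
    fit = fit_ols(sample.X, sample.y)
    beta_true = float(scenario.beta[COEF_OF_INTEREST])
    results: dict[str, InferenceResult] = {}
    if "classical" in methods:
        results["classical"] = classical_inference(
            fit, COEF_OF_INTEREST, alpha, beta_true
        )
    for est in ("HC3", "HC4"):
        if est in methods:
            results[est] = hc_inference(
                fit, hc_covariance(fit, est), COEF_OF_INTEREST, alpha, beta_true
            )
    if methods & {"pairs_p", "pairs_percentile", "pairs_BCa"}:
        dist = pairs_resample(
            sample.X, sample.y, scenario.B, rng, k=COEF_OF_INTEREST, fit=fit
        )
        results.update(
            _bootstrap_results("pairs", dist, fit, methods, beta_true, alpha)
        )
    if methods & {"wild_p", "wild_percentile", "wild_BCa"}:
        dist = wild_resample(fit, scenario.B, rng, k=COEF_OF_INTEREST)
        results.update(
            _bootstrap_results("wild", dist, fit, methods, beta_true, alpha)
        )
    return results, sample.attempts


def run_scenario(
    scenario: Scenario,
    methods=ALL_METHODS,
    *,
    alpha: float = 0.05,
    collect_t: bool = False,
    degenerate_fraction_cap: float = 0.01,
) -> tuple[list[PerformanceSummary], list[TestStatArchive]]:
    """Run all replications of one scenario and aggregate per method.

    Replication ``i`` uses the RNG substream seeded by ``(seed, i)``.
    Degenerate replications (clamped BCa etc.) are flagged and counted; the
    scenario aborts if the flagged fraction exceeds ``degenerate_fraction_cap``.
    """
    methods = set(methods)
    unknown = methods - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    coef = scenario.dist.coefficients()  # solve once, reuse across reps

    R = scenario.n_reps
    rej = {m: np.zeros(R, dtype=bool) for m in methods}
    cov = {m: np.zeros(R, dtype=bool) for m in methods if m in _CI_METHODS}
    est = {m: np.zeros(R) for m in methods}
    ses = {m: np.zeros(R) for m in methods if m in _SE_METHODS}
    tvals = {m: np.zeros(R) for m in methods & _SE_METHODS} if collect_t else {}
    flags = {m: 0 for m in methods}
    attempts_total = 0

    for i in range(R):
        rng = np.random.default_rng([scenario.seed, i])
        results, attempts = run_replication(
            scenario, rng, methods, alpha=alpha, coef=coef
        )
        attempts_total += attempts
        for m, r in results.items():
            rej[m][i] = r.reject
            est[m][i] = r.estimate
            if m in cov:
                cov[m][i] = bool(r.covers)
            if m in ses:
                ses[m][i] = r.se
            if m in tvals:
                tvals[m][i] = r.t_stat
            if r.flagged:
                flags[m] += 1

    summaries = []
    for m in sorted(methods, key=ALL_METHODS.index):
        if flags[m] > degenerate_fraction_cap * R:
            raise ExcessiveDegeneracyError(
                f"{flags[m]}/{R} replications flagged for {m} in "
                f"scenario {scenario.key()}"
            )
        summaries.append(
            PerformanceSummary(
                scenario=scenario,
                method=m,
                n_reps_done=R,
                rejection_rate=float(rej[m].mean()),
                coverage_rate=float(cov[m].mean()) if m in cov else None,
                mean_beta=float(est[m].mean()),
                sd_beta=float(est[m].std(ddof=1)),
                mean_se=float(ses[m].mean()) if m in ses else None,
                flagged_reps=flags[m],
                mean_attempts=attempts_total / R,
            )
        )
    archives = [
        TestStatArchive(scenario=scenario, method=m, t_values=tvals[m])
        for m in sorted(tvals, key=ALL_METHODS.index)
    ]
    return summaries, archives


def summaries_to_frame(summaries: list[PerformanceSummary]) -> pd.DataFrame:
    """Flatten summaries into a tidy table, one row per scenario x method."""
    rows = []
    for s in summaries:
        sc = s.scenario
        rows.append(
            {
                "model": sc.model_id,
                "n": sc.n,
                "distribution": sc.dist.label,
                "g": sc.g,
                "n_reps": s.n_reps_done,
                "B": sc.B,
                "seed": sc.seed,
                "method": s.method,
                "rejection_rate": s.rejection_rate,
                "coverage_rate": s.coverage_rate,
                "mean_beta": s.mean_beta,
                "sd_beta": s.sd_beta,
                "mean_se": s.mean_se,
                "flagged_reps": s.flagged_reps,
                "mean_attempts": s.mean_attempts,
            }
        )
    return pd.DataFrame(rows)


def run_grid(
    scenarios: list[Scenario],
    methods=ALL_METHODS,
    *,
    out_dir: str | Path | None = None,
    alpha: float = 0.05,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario and return (and optionally persist) a tidy table.

    With ``out_dir`` set, each scenario's rows are written to
    ``<out_dir>/<scenario key>.csv`` as soon as it finishes, and scenarios
    whose file already exists are skipped — interrupted grids resume cheaply.
    """
    frames = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i, sc in enumerate(scenarios):
        cache = out_path / f"{sc.key()}.csv" if out_path is not None else None
        if cache is not None and cache.exists():
            frames.append(pd.read_csv(cache))
            continue
        summaries, _ = run_scenario(sc, methods, alpha=alpha)
        frame = summaries_to_frame(summaries)
        if cache is not None:
            frame.to_csv(cache, index=False)
        frames.append(frame)
        if progress:
            print(f"[{i + 1}/{len(scenarios)}] {sc.key()}", flush=True)
    return pd.concat(frames, ignore_index=True)


def se_bias_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Compare mean estimated SEs against the simulated SE per scenario.

    Returns one row per scenario x SE method with the difference
    ``mean_se - sd_beta`` and the ratio ``mean_se / sd_beta``; ratios below 1
    mean the method underestimates the true sampling variability.
    """
    df = summaries[summaries["method"].isin(_SE_METHODS)].copy()
    if df.empty:
        raise ValueError("summaries contain no classical/HC3/HC4 rows")
    df["se_bias"] = df["mean_se"] - df["sd_beta"]
    df["se_ratio"] = df["mean_se"] / df["sd_beta"]
    cols = [
        "model", "n", "distribution", "g", "method",
        "mean_se", "sd_beta", "se_bias", "se_ratio",
    ]
    return df[cols].reset_index(drop=True)
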