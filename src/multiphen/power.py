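"""Monte-Carlo power engine: calibrated thresholds and power surfaces.

A fair power comparison requires every method to have the same type-I
error.  Nominal p-value cutoffs do not achieve this — Bonferroni is
conservative with correlated traits, MANOVA's F approximation is only
asymptotic — so each method's threshold is calibrated: simulate replicates
under the matched null (delta = 1, same n, m, r), take the empirical
alpha-quantile of the method's null p-values, and reject when
p <= threshold.  Power is then the rejection proportion over independent
replicates under the alternative.

Replicates are seeded from counter-based streams (stream, replicate), so
whole grids are bit-identical under a fixed root seed regardless of
execution order or parallelism, and calibration and evaluation sets never
share randomness.  All methods at a grid point are evaluated on the same
simulated datasets (paired comparison).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import association as assoc
from .simulate import SimulationConfig, replicate_rng, simulate_genotypes, simulate_phenotypes

__all__ = [
    "METHODS",
    "PowerEstimate",
    "PowerGridResult",
    "replicate_pvalues",
    "calibrate_threshold",
    "calibrate_thresholds",
    "estimate_power",
    "power_grid",
    "plot_power_grid",
]

METHODS = ("one_by_one", "permutation", "manova", "pca")

# disjoint seed-stream tags; grid point j shifts by _GRID_STRIDE * (j + 1)
_STREAM_CALIBRATION = 1
_STREAM_POWER = 2
_GRID_STRIDE = 16


@dataclass
class PowerEstimate:
    """Empirical rejection rate of one method in one scenario."""

    method: str
    config: SimulationConfig
    threshold: float
    power: float
    mc_se: float
    n_replicates: int


@dataclass
class PowerGridResult:
    """Power of several methods along one varying parameter (tidy layout)."""

    varying_parameter: str
    values: List[float]
    estimates: List[PowerEstimate]

    def to_frame(self):
        import pandas as pd

        rows = []
        for value, est in zip(np.repeat(self.values, self._n_methods()), self.estimates):
            rows.append(
                {
                    "method": est.method,
                    "vary": self.varying_parameter,
                    "value": value,
                    "threshold": est.threshold,
                    "power": est.power,
                    "mc_se": est.mc_se,
                    "reps": est.n_replicates,
                }
            )
        return pd.DataFrame(rows)

    def _n_methods(self) -> int:
        return len({e.method for e in self.estimates})

    def powers(self, method: str) -> np.ndarray:
        return np.array([e.power for e in self.estimates if e.method == method])


def _validate_methods(methods) -> List[str]:
    if isinstance(methods, str):
        methods = [methods]
    methods = list(methods)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    return methods


def _method_pvalue(method, y, g, rng, mode, n_perms, manova_statistic, n_pcs) -> float:
    if method == "one_by_one":
        return assoc.one_by_one_test(y, g, mode=mode).p_value
    if method == "permutation":
        return assoc.permutation_minp_test(y, g, n_perms=n_perms, seed=rng, mode=mode).p_value
    if method == "manova":
        return assoc.manova_test(y, g, statistic=manova_statistic).p_value
    if method == "pca":
        return assoc.pca_test(y, g, k=n_pcs, mode=mode).p_value
    raise ValueError(f"unknown method {method!r}")


def replicate_pvalues(
    methods,
    config: SimulationConfig,
    n_replicates: Optional[int] = None,
    stream: int = 0,
    mode: str = "regression",
    n_perms: int = 200,
    manova_statistic: str = "pillai",
    n_pcs: int = 1,
) -> Dict[str, np.ndarray]:
    """p-values of each method over independent simulated replicates.

    All methods see the same dataset in each replicate.  The permutation
    method draws its permutations from the replicate's own stream.
    """
    methods = _validate_methods(methods)
    reps = int(n_replicates if n_replicates is not None else config.n_replicates)
    out = {m: np.empty(reps) for m in methods}
    for i in range(reps):
        rng = replicate_rng(config, replicate=i, stream=stream)
        g = simulate_genotypes(config.n_samples, config.allele_freq, seed=rng)
        y = simulate_phenotypes(g, config, rng=rng)
        for m in methods:
            out[m][i] = _method_pvalue(m, y, g, rng, mode, n_perms, manova_statistic, n_pcs)
    return out


def _empirical_threshold(pvalues: np.ndarray, alpha: float) -> float:
    """Lower empirical quantile: the ceil(alpha*R)-th smallest null p-value."""
    r = pvalues.size
    k = math.ceil(alpha * r)
    if k < 1:
        raise ValueError(f"alpha={alpha} too small for {r} null replicates")
    return float(np.sort(pvalues)[k - 1])


def calibrate_threshold(
    method: str,
    config_null: SimulationConfig,
    alpha: float = 0.05,
    n_null: int = 1000,
    stream: int = _STREAM_CALIBRATION,
    **method_opts,
) -> float:
    """Per-method significance threshold with empirical size alpha.

    Simulates ``n_null`` replicates under the null configuration and
    returns the empirical alpha-quantile (lower interpolation) of the
    method's p-values, so the rule ``p <= threshold`` rejects a fraction
    alpha of the calibration set.
    """
    return calibrate_thresholds([method], config_null, alpha, n_null, stream, **method_opts)[method]


def calibrate_thresholds(
    methods,
    config_null: SimulationConfig,
    alpha: float = 0.05,
    n_null: int = 1000,
    stream: int = _STREAM_CALIBRATION,
    **method_opts,
) -> Dict[str, float]:
    """Calibrated thresholds for several methods from one shared null set."""
    if config_null.effect_size != 1.0:
        raise ValueError(
            f"threshold calibration requires the null (delta=1); got delta={config_null.effect_size}"
        )
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_null < 500:
        warnings.warn(
            f"n_null={n_null} < 500 gives a noisy calibrated threshold",
            UserWarning,
            stacklevel=2,
        )
    null_p = replicate_pvalues(methods, config_null, n_null, stream=stream, **method_opts)
    return {m: _empirical_threshold(ps, alpha) for m, ps in null_p.items()}


def estimate_power(
    method: str,
    config: SimulationConfig,
    threshold: float,
    n_replicates: Optional[int] = None,
    stream: int = _STREAM_POWER,
    **method_opts,
) -> PowerEstimate:
    """Rejection proportion p <= threshold over independent replicates."""
    return estimate_powers([method], config, {method: threshold}, n_replicates, stream, **method_opts)[method]


def estimate_powers(
    methods,
    config: SimulationConfig,
    thresholds: Dict[str, float],
    n_replicates: Optional[int] = None,
    stream: int = _STREAM_POWER,
    **method_opts,
) -> Dict[str, PowerEstimate]:
    """Power of several methods on one shared replicate set (paired)."""
    methods = _validate_methods(methods)
    for m in methods:
        if not 0.0 < thresholds[m] < 1.0:
            raise ValueError(f"threshold for {m!r} must be in (0, 1), got {thresholds[m]}")
    pvals = replicate_pvalues(methods, config, n_replicates, stream=stream, **method_opts)
    out = {}
    for m in methods:
        ps = pvals[m]
        reps = ps.size
        power = float(np.mean(ps <= thresholds[m]))
        out[m] = PowerEstimate(
            method=m,
            config=config,
            threshold=float(thresholds[m]),
            power=power,
            mc_se=float(np.sqrt(power * (1.0 - power) / reps)),
            n_replicates=reps,
        )
    return out


_VARYABLE = ("correlation", "n_phenotypes", "n_samples", "effect_size")


def _grid_point(args):
    (j, value, methods, base_config, vary, alpha, n_null, n_replicates, opts) = args
    config = base_config.replace(**{vary: value})
    base = _GRID_STRIDE * (j + 1)
    thresholds = calibrate_thresholds(
        methods, config.null(), alpha, n_null, stream=base + _STREAM_CALIBRATION, **opts
    )
    powers = estimate_powers(
        methods, config, thresholds, n_replicates, stream=base + _STREAM_POWER, **opts
    )
    return [powers[m] for m in methods]


def power_grid(
    methods,
    base_config: SimulationConfig,
    vary: str,
    values: Sequence[float],
    alpha: float = 0.05,
    n_null: int = 1000,
    n_replicates: Optional[int] = None,
    n_jobs: int = 1,
    **method_opts,
) -> PowerGridResult:
    """Power of each method along one varying parameter (a figure's design).

    At every grid point the thresholds are re-calibrated under the matched
    null (same n, m, r; delta = 1) before power is estimated, so curves are
    comparable at equal type-I error.  ``n_jobs`` parallelizes over grid
    points without changing any result.
    """
    methods = _validate_methods(methods)
    if vary not in _VARYABLE:
        raise ValueError(f"vary must be one of {_VARYABLE}, got {vary!r}")
    if vary == "n_phenotypes" or vary == "n_samples":
        values = [int(v) for v in values]
    else:
        values = [float(v) for v in values]
    jobs = [
        (j, v, methods, base_config, vary, alpha, n_null, n_replicates, method_opts)
        for j, v in enumerate(values)
    ]
    if n_jobs != 1:
        from joblib import Parallel, delayed

        per_point = Parallel(n_jobs=n_jobs)(delayed(_grid_point)(a) for a in jobs)
    else:
        per_point = [_grid_point(a) for a in jobs]
    estimates = [est for point in per_point for est in point]
    return PowerGridResult(varying_parameter=vary, values=list(values), estimates=estimates)


_VARY_LABEL = {
    "correlation": "correlation coefficient r",
    "n_phenotypes": "number of phenotypes m",
    "n_samples": "sample size n",
    "effect_size": "effect size delta",
}


def plot_power_grid(result: PowerGridResult, path: str, title: Optional[str] = None) -> None:
    """Render power-vs-parameter curves, one line per method, to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = result.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, sub in frame.groupby("method"):
        sub = sub.sort_values("value")
        ax.errorbar(sub["value"], sub["power"], yerr=sub["mc_se"], marker="o",
                    capsize=2, label=method)
    ax.set_xlabel(_VARY_LABEL.get(result.varying_parameter, result.varying_parameter))
    ax.set_ylabel("power")
    ax.set_ylim(0, 1)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
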