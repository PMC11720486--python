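"""Sensitivity-vs-awareness curves from a fitted GRT-wIND model.

Two functions of a point ``a`` on the awareness axis summarize what the
model says about processing without awareness:

* RLNA(a) - relative likelihood of no awareness: the marginal awareness
  density of the absent class divided by the equal-weight mixture of the
  square and diamond awareness densities.  RLNA > 1 means the percept is
  better explained by "nothing was shown".
* d'_cond(a) - conditional sensitivity: the separation of the square and
  diamond identity distributions conditional on awareness = a, over their
  pooled conditional SD.  Nonzero d'_cond where RLNA is high is the model's
  signature of shape processing in the absence of awareness.

Curves are evaluated at the group level (attention scale kappa = 1).  The
ideal-observer awareness criterion is the point where RLNA = 1.  Confidence
bands come from a parametric bootstrap: simulate datasets from the fitted
model at the observed trial counts, refit the same template, recompute the
curves, and take pointwise percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError
from .grt import (
    GRTDataset,
    GRTFitResult,
    GRTModelSpec,
    PRESENT,
    fit_grt_wind,
    simulate_dataset,
)

_DENS_FLOOR = 1e-300


def _awareness_marginals(spec: GRTModelSpec):
    mys = [spec.means[lbl][1] for lbl in PRESENT]
    sys_ = [spec.sds[lbl][1] for lbl in PRESENT]
    return mys, sys_


def rlna(spec: GRTModelSpec, a) -> np.ndarray:
    """Relative likelihood of no awareness at awareness value(s) ``a``."""
    a = np.asarray(a, float)
    f_absent = stats.norm.pdf(a, 0.0, 1.0)
    mys, sys_ = _awareness_marginals(spec)
    f_present = 0.5 * (
        stats.norm.pdf(a, mys[0], sys_[0]) + stats.norm.pdf(a, mys[1], sys_[1])
    )
    if np.any(f_present < _DENS_FLOOR):
        warnings.warn("present-class density underflow; RLNA clipped")
    return f_absent / np.maximum(f_present, _DENS_FLOOR)


def conditional_dprime(spec: GRTModelSpec, a) -> np.ndarray:
    """Shape sensitivity conditional on awareness = a (Gaussian conditionals)."""
    a = np.asarray(a, float)
    cond_means = []
    cond_vars = []
    for lbl in PRESENT:
        mx, my = spec.means[lbl]
        sx, sy = spec.sds[lbl]
        rho = spec.rhos[lbl]
        cond_means.append(mx + rho * sx / sy * (a - my))
        cond_vars.append(sx**2 * (1.0 - rho**2))
    pooled_sd = np.sqrt(0.5 * (cond_vars[0] + cond_vars[1]))
    return np.abs(cond_means[0] - cond_means[1]) / pooled_sd


@dataclass
class SvACurve:
    awareness_grid: np.ndarray
    rlna: np.ndarray
    d_cond: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    rlna_ci_lower: np.ndarray | None = None
    rlna_ci_upper: np.ndarray | None = None
    ideal_criterion: float | None = None
    participant_bounds: np.ndarray = field(default_factory=lambda: np.array([]))
    n_boot: int = 0
    n_boot_failed: int = 0


def ideal_observer_criterion(spec: GRTModelSpec) -> float | None:
    """Awareness value where RLNA = 1, solved between the class means.

    Returns None (with a warning) when RLNA - 1 does not change sign in the
    bracket from the absent mean (0) to the highest present awareness mean.
    """
    mys, _ = _awareness_marginals(spec)
    hi = float(max(mys))
    lo = 0.0
    if hi <= lo:
        warnings.warn("present awareness means not above absent; no RLNA=1 crossing")
        return None
    f = lambda a: np.log(rlna(spec, a))
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        warnings.warn("no RLNA = 1 crossing between absent and present means")
        return None
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def sva_curve(fit: GRTFitResult, n_grid: int = 200) -> SvACurve:
    """Point-estimate SvA curve on the default awareness grid.

    The grid spans [absent mean - 3 SD, max present mean + 3 max SD].
    """
    spec = fit.spec
    mys, sys_ = _awareness_marginals(spec)
    lo = 0.0 - 3.0 * 1.0
    hi = float(max(mys)) + 3.0 * float(max(max(sys_), 1.0))
    grid = np.linspace(lo, hi, n_grid)
    return SvACurve(
        awareness_grid=grid,
        rlna=rlna(spec, grid),
        d_cond=conditional_dprime(spec, grid),
        ideal_criterion=ideal_observer_criterion(spec),
        participant_bounds=spec.cuts[:, 0].copy(),
    )


def bootstrap_sva(
    fit: GRTFitResult,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    n_grid: int = 200,
    restarts: int = 1,
    maxiter: int = 200,
    max_failure_rate: float = 0.20,
) -> SvACurve:
    """Parametric-bootstrap confidence bands for the SvA curve.

    Each replicate simulates counts from the fitted model at the observed
    per-condition trial totals, refits the selected template (warm-started
    at the fitted parameters), and re-evaluates both curves on the common
    grid; bands are pointwise 2.5/97.5 percentiles.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = rng if rng is not None else np.random.default_rng()
    base = sva_curve(fit, n_grid=n_grid)
    grid = base.awareness_grid
    d_curves, r_curves = [], []
    n_failed = 0
    for _ in range(n_boot):
        sim = simulate_dataset(fit.spec, fit.trial_counts, rng)
        try:
            refit = fit_grt_wind(
                sim,
                fit.spec.flags,
                restarts=restarts,
                rng=rng,
                maxiter=maxiter,
                init=fit.theta,
            )
        except Exception:
            n_failed += 1
            continue
        d_curves.append(conditional_dprime(refit.spec, grid))
        r_curves.append(rlna(refit.spec, grid))
    if n_failed > max_failure_rate * n_boot:
        raise ConvergenceError(
            f"bootstrap refit failure rate {n_failed}/{n_boot} exceeds "
            f"{max_failure_rate:.0%}"
        )
    d_arr = np.array(d_curves)
    r_arr = np.array(r_curves)
    base.ci_lower = np.percentile(d_arr, 2.5, axis=0)
    base.ci_upper = np.percentile(d_arr, 97.5, axis=0)
    base.rlna_ci_lower = np.percentile(r_arr, 2.5, axis=0)
    base.rlna_ci_upper = np.percentile(r_arr, 97.5, axis=0)
    base.n_boot = n_boot
    base.n_boot_failed = n_failed
    return base


def plot_sva(curve: SvACurve, ax=None, label: str | None = None):
    """Quick d'_cond-vs-RLNA plot with bootstrap band when available."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.log10(curve.rlna)
    ax.plot(x, curve.d_cond, label=label)
    if curve.ci_lower is not None:
        ax.fill_between(x, curve.ci_lower, curve.ci_upper, alpha=0.3)
    ax.axvline(0.0, linestyle=":", color="gray")
    ax.set_xlabel("log10 RLNA")
    ax.set_ylabel("conditional d'")
    return ax
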