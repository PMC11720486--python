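"""Simulation-based calibration harnesses.

These run the full estimate-from-synthetic-truth loops used to validate the
pipeline: measurement-error regression bias/coverage and null Bayes-factor
rates, GRT-wIND parameter recovery, AIC model-selection rates, and
parametric-bootstrap band coverage.  They are ordinary package functionality
(the generative modules make them cheap) and the basis of the acceptance
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import grt, me_regression, sva

# Constraint tolerances for judging a fitted unconstrained model
# "nesting-equivalent" to a constrained truth: the extra freedom is unused.
_EV_TOL = 0.12
_PS_TOL = 0.12
_PI_TOL = 0.12
_DS_TOL = 0.15


@dataclass(frozen=True)
class MECalibration:
    bias_ms: float
    coverage: float
    mean_ci_width_ms: float
    n_cohorts: int


def me_regression_calibration(
    n_cohorts: int = 100,
    seed: int = 0,
    alpha_ms: float = 30.0,
    n_participants: int = 24,
    n_trials: int = 256,
    **fit_kwargs,
) -> MECalibration:
    """Intercept bias and 95% credible-interval coverage over true-alpha cohorts."""
    means, covered, widths = [], 0, []
    for rep in range(n_cohorts):
        rng = np.random.default_rng([seed, 1, rep])
        data = me_regression.simulate_me_cohort(
            n_participants=n_participants, n_trials=n_trials, alpha_ms=alpha_ms,
            beta_ms=0.0, rng=rng,
        )
        post = me_regression.fit_me_regression(
            data, seed=int(rng.integers(2**31 - 1)), **fit_kwargs
        )
        means.append(post.intercept_mean_ms)
        lo, hi = post.intercept_ci95
        covered += lo <= alpha_ms <= hi
        widths.append(hi - lo)
    return MECalibration(
        bias_ms=float(np.mean(means) - alpha_ms),
        coverage=covered / n_cohorts,
        mean_ci_width_ms=float(np.mean(widths)),
        n_cohorts=n_cohorts,
    )


@dataclass(frozen=True)
class MENullCheck:
    bf_below_1_rate: float
    mean_posterior_intercept_ms: float
    mean_naive_intercept_ms: float
    n_cohorts: int


def me_regression_null_check(
    n_cohorts: int = 50,
    seed: int = 0,
    beta_ms: float = 200.0,
    **fit_kwargs,
) -> MENullCheck:
    """Awareness-driven priming only (alpha = 0): the corrected intercept
    should stay near zero with BF10 < 1, while the naive regression's
    intercept inherits an upward attenuation bias."""
    bf_below, post_means, naive_means = 0, [], []
    for rep in range(n_cohorts):
        rng = np.random.default_rng([seed, 2, rep])
        data = me_regression.simulate_me_cohort(
            alpha_ms=0.0, beta_ms=beta_ms, rng=rng
        )
        post = me_regression.fit_me_regression(
            data, seed=int(rng.integers(2**31 - 1)), **fit_kwargs
        )
        naive = me_regression.naive_greenwald_regression(data)
        bf_below += post.bf10_intercept < 1.0
        post_means.append(post.intercept_mean_ms)
        naive_means.append(naive.intercept_ms)
    return MENullCheck(
        bf_below_1_rate=bf_below / n_cohorts,
        mean_posterior_intercept_ms=float(np.mean(post_means)),
        mean_naive_intercept_ms=float(np.mean(naive_means)),
        n_cohorts=n_cohorts,
    )


def default_recovery_spec(n_participants: int = 20,
                          rng: np.random.Generator | None = None) -> grt.GRTModelSpec:
    """The canonical fully-constrained truth used in recovery experiments."""
    rng = rng if rng is not None else np.random.default_rng(0)
    n = n_participants
    return grt.GRTModelSpec(
        flags=grt.MOST_CONSTRAINED,
        means={"square": (0.7, 0.9), "diamond": (-0.3, 0.9), "absent": (0.0, 0.0)},
        sds={lbl: (1.0, 1.0) for lbl in grt.STIMULI},
        rhos={lbl: 0.0 for lbl in grt.STIMULI},
        kappa=np.ones(n),
        bounds=rng.normal(0.1, 0.2, n),
        cuts=np.tile(np.array([0.8, 1.6, 2.4]), (n, 1)) + rng.normal(0, 0.1, (n, 1)),
        slopes=np.zeros(n),
    )


_TRIALS_PER_CONDITION = np.array([128, 128, 64])  # 320-trial block split


@dataclass(frozen=True)
class RecoveryResult:
    success_rate: float
    max_abs_errors: list[float]
    kappa_median_range: tuple[float, float]
    n_reps: int


def grt_mean_recovery(
    n_reps: int = 20, seed: int = 0, tol: float = 0.15, restarts: int = 2
) -> RecoveryResult:
    """Fraction of replicates with all present-class means within ``tol``."""
    successes, max_errs, kappa_meds = 0, [], []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 3, rep])
        truth = default_recovery_spec(rng=rng)
        ds = grt.simulate_dataset(truth, _TRIALS_PER_CONDITION, rng)
        fit = grt.fit_grt_wind(ds, truth.flags, restarts=restarts, rng=rng)
        errs = [
            abs(fit.spec.means[lbl][k] - truth.means[lbl][k])
            for lbl in ("square", "diamond")
            for k in (0, 1)
        ]
        max_errs.append(max(errs))
        successes += max(errs) <= tol
        kappa_meds.append(float(np.median(fit.spec.kappa)))
    return RecoveryResult(
        success_rate=successes / n_reps,
        max_abs_errors=max_errs,
        kappa_median_range=(float(np.min(kappa_meds)), float(np.max(kappa_meds))),
        n_reps=n_reps,
    )


def _constraints_effectively_hold(spec: grt.GRTModelSpec) -> bool:
    """Is a (possibly unconstrained) fitted spec equivalent to the all-true one?"""
    sds = [s for lbl in grt.STIMULI for s in spec.sds[lbl]]
    ev = all(abs(s - 1.0) <= _EV_TOL for s in sds)
    ps = (
        abs(spec.means["square"][1] - spec.means["diamond"][1]) <= _PS_TOL
        and abs(spec.sds["square"][1] - spec.sds["diamond"][1]) <= _PS_TOL
    )
    pi = all(abs(spec.rhos[lbl]) <= _PI_TOL for lbl in grt.STIMULI)
    ds = float(np.median(np.abs(spec.slopes))) <= _DS_TOL
    return ev and ps and pi and ds


@dataclass(frozen=True)
class SelectionResult:
    success_rate: float
    selected_labels: list[str]
    n_reps: int


def grt_model_selection(
    n_reps: int = 20, seed: int = 0, restarts: int = 1
) -> SelectionResult:
    """AIC selection over all 16 variants for fully-constrained truths.

    A replicate succeeds when the minimum-AIC model is the generating
    (all-constraints) variant, or a richer variant whose fitted parameters
    satisfy the generating constraints within tolerance (nesting-equivalent:
    the extra freedom went unused).
    """
    successes, labels = 0, []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 4, rep])
        truth = default_recovery_spec(rng=rng)
        ds = grt.simulate_dataset(truth, _TRIALS_PER_CONDITION, rng)
        fits = [
            grt.fit_grt_wind(ds, flags, restarts=restarts, rng=rng)
            for flags in grt.enumerate_models()
        ]
        best = grt.select_model(fits)
        labels.append(best.spec.flags.label())
        if best.spec.flags == grt.MOST_CONSTRAINED or _constraints_effectively_hold(
            best.spec
        ):
            successes += 1
    return SelectionResult(
        success_rate=successes / n_reps, selected_labels=labels, n_reps=n_reps
    )


@dataclass(frozen=True)
class BootstrapCoverage:
    d_cond_coverage: float
    rlna_coverage: float
    n_boot: int
    n_grid: int


def grt_bootstrap_coverage(
    seed: int = 0, n_boot: int = 100, n_participants: int = 20, n_reps: int = 2
) -> BootstrapCoverage:
    """Do bootstrap bands contain the generating SvA curve?

    The truth relaxes perceptual independence so the conditional-d' curve
    genuinely varies along the awareness axis.  The fraction of covered grid
    points in a single truth -> fit -> bootstrap cycle is a high-variance
    measurement (grid points are strongly correlated, so one fit landing a
    couple of SEs off drops a whole stretch of the curve outside the band);
    the harness therefore averages the fraction over ``n_reps`` independent
    cycles.
    """
    flags = grt.GRTFlags(
        equal_variances=True,
        perceptual_separability=True,
        perceptual_independence=False,
        decisional_separability=True,
    )
    d_covs, r_covs, n_grid = [], [], 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 5, rep])
        base = default_recovery_spec(n_participants=n_participants, rng=rng)
        truth = grt.GRTModelSpec(
            flags=flags,
            means=base.means,
            sds=base.sds,
            rhos={"square": 0.4, "diamond": -0.3, "absent": 0.0},
            kappa=base.kappa,
            bounds=base.bounds,
            cuts=base.cuts,
            slopes=base.slopes,
        )
        ds = grt.simulate_dataset(truth, _TRIALS_PER_CONDITION, rng)
        fit = grt.fit_grt_wind(ds, flags, restarts=2, rng=rng)
        curve = sva.bootstrap_sva(fit, n_boot=n_boot, rng=rng)
        true_d = sva.conditional_dprime(truth, curve.awareness_grid)
        true_r = sva.rlna(truth, curve.awareness_grid)
        d_covs.append(
            float(np.mean((curve.ci_lower <= true_d) & (true_d <= curve.ci_upper)))
        )
        r_covs.append(
            float(
                np.mean(
                    (curve.rlna_ci_lower <= true_r) & (true_r <= curve.rlna_ci_upper)
                )
            )
        )
        n_grid = len(curve.awareness_grid)
    return BootstrapCoverage(
        d_cond_coverage=float(np.mean(d_covs)),
        rlna_coverage=float(np.mean(r_covs)),
        n_boot=n_boot,
        n_grid=n_grid,
    )


@dataclass(frozen=True)
class EngineCheck:
    max_dev_over_limit: float
    n_specs: int
    n_draws: int


def engine_monte_carlo_check(
    n_specs: int = 20, n_draws: int = 10**6, seed: int = 0
) -> EngineCheck:
    """Analytic response-cell probabilities vs direct bivariate sampling.

    For each random parameter set, every cell must agree with the empirical
    frequency within 3 Monte-Carlo standard errors (plus a 2/n guard for
    near-empty cells).  Returns the worst deviation/limit ratio.
    """
    rng = np.random.default_rng([seed, 6])
    worst = 0.0
    for _ in range(n_specs):
        mx, my = rng.normal(0, 1.2, 2)
        sx, sy = np.exp(rng.normal(0, 0.3, 2))
        rho = rng.uniform(-0.85, 0.85)
        b = rng.normal(0, 0.7)
        c1 = rng.normal(-0.6, 0.5)
        gaps = np.exp(rng.normal(0, 0.3, 2))
        cuts = np.array([c1, c1 + gaps[0], c1 + gaps[0] + gaps[1]])
        slope = rng.uniform(-1.2, 1.2)
        ana = grt._cell_probs(mx, my, sx, sy, rho, b, cuts, slope)
        cov = [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]]
        z = rng.multivariate_normal([mx, my], cov, size=n_draws)
        w = z[:, 1] - slope * z[:, 0]
        pas = np.searchsorted(cuts - slope * b, w)
        sq = z[:, 0] > b
        for r in range(2):
            for k in range(4):
                emp = np.mean((sq == (r == 0)) & (pas == k))
                limit = 3.0 * np.sqrt(
                    max(ana[r, k] * (1 - ana[r, k]), 1e-12) / n_draws
                ) + 2.0 / n_draws
                worst = max(worst, abs(ana[r, k] - emp) / limit)
    return EngineCheck(max_dev_over_limit=worst, n_specs=n_specs, n_draws=n_draws)
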