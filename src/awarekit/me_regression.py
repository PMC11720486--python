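"""Bayesian measurement-error correction of the awareness regression.

The classical (Greenwald-style) approach regresses per-participant priming
effects on centered awareness scores and reads the intercept as the priming
effect of a completely unaware participant (awareness at chance).  Because
the observed proportion correct is a noisy binomial estimate of the latent
awareness, ordinary least squares attenuates the slope and biases the
intercept; the generative model here corrects this by modelling both error
sources explicitly:

    correct_i ~ Binomial(trial_count_i, theta_i)
    theta_i   ~ Beta(m * nu, (1 - m) * nu)          (hierarchy near chance)
    a_i        = theta_i - 1/2                       (centered awareness)
    effect_i  ~ Normal(alpha + beta * a_i, sqrt(tau^2 + se_i^2))

with weakly-informative priors on the RT-millisecond scale.  The intercept
``alpha`` is the priming effect at exactly chance awareness; its Bayes
factor against alpha = 0 comes from the Savage-Dickey density ratio, with
the posterior ordinate at zero computed two ways: a Rao-Blackwellized
conditional-Gaussian average (default; exact conditional density averaged
over draws) and a Silverman-bandwidth Gaussian KDE (audit cross-check).

Sampling is by affine-invariant ensemble MCMC (emcee) with a vectorized
log-posterior; convergence is checked with split-ensemble R-hat and an
explicit error is raised when it fails.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, expit, log_expit

from .errors import ConvergenceError, DegenerateInputError

CHANCE = 0.5


@dataclass(frozen=True)
class MEPriors:
    """Prior scales; Bayes factors depend on these, so they are explicit."""

    alpha_sd_ms: float = 50.0
    beta_sd_ms: float = 300.0
    tau_sd_ms: float = 30.0
    m_beta: tuple[float, float] = (2.0, 2.0)
    log_nu_mu: float = math.log(50.0)
    log_nu_sd: float = 1.0


@dataclass
class RegressionPosterior:
    intercept_mean_ms: float
    intercept_ci95: tuple[float, float]
    slope_mean: float
    slope_ci95: tuple[float, float]
    bf10_intercept: float
    bf10_intercept_kde: float
    tau_mean_ms: float
    rhat_max: float
    ess_min: float
    n_chains: int
    n_draws: int
    seed: int
    draws: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "intercept_mean_ms": self.intercept_mean_ms,
            "intercept_ci95": list(self.intercept_ci95),
            "slope_mean": self.slope_mean,
            "slope_ci95": list(self.slope_ci95),
            "bf10_intercept": self.bf10_intercept,
            "bf10_intercept_kde": self.bf10_intercept_kde,
            "tau_mean_ms": self.tau_mean_ms,
            "rhat_max": self.rhat_max,
            "ess_min": self.ess_min,
            "n_chains": self.n_chains,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }


def _validate(data: pd.DataFrame) -> pd.DataFrame:
    required = {"correct_count", "trial_count", "effect_ms", "effect_se_ms"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (data["trial_count"] <= 0).any():
        raise ValueError("trial_count must be positive")
    if ((data["correct_count"] < 0) | (data["correct_count"] > data["trial_count"])).any():
        raise ValueError("correct_count out of [0, trial_count]")
    if (data["effect_se_ms"] <= 0).any():
        raise ValueError("effect_se_ms must be positive")
    return data.reset_index(drop=True)


class _LogPost:
    """Vectorized log posterior over walkers.

    Parameter vector: [alpha, beta, log tau, logit m, log nu,
    logit theta_1..n]; all transforms carry their Jacobians so the priors
    apply on the natural scales.
    """

    def __init__(self, data: pd.DataFrame, priors: MEPriors,
                 predictor: str = "proportion"):
        self.c = data["correct_count"].to_numpy(dtype=float)
        self.t = data["trial_count"].to_numpy(dtype=float)
        self.y = data["effect_ms"].to_numpy(dtype=float)
        self.se2 = data["effect_se_ms"].to_numpy(dtype=float) ** 2
        self.priors = priors
        if predictor not in ("proportion", "dprime"):
            raise ValueError("predictor must be 'proportion' or 'dprime'")
        self.predictor = predictor
        self.n = len(data)
        self.ndim = 5 + self.n

    def awareness(self, theta: np.ndarray) -> np.ndarray:
        """Centered awareness: theta - 1/2, or its 2AFC d' transform."""
        if self.predictor == "proportion":
            return theta - CHANCE
        from scipy.special import ndtri

        return math.sqrt(2.0) * ndtri(np.clip(theta, 1e-9, 1 - 1e-9))

    def __call__(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        pr = self.priors
        alpha, beta = p[:, 0], p[:, 1]
        log_tau, logit_m, log_nu = p[:, 2], p[:, 3], p[:, 4]
        lt = p[:, 5:]
        tau = np.exp(np.clip(log_tau, -20.0, 20.0))
        nu = np.exp(np.clip(log_nu, -20.0, 20.0))
        theta = expit(lt)
        log_theta = log_expit(lt)
        log_1mtheta = log_expit(-lt)
        log_m = log_expit(logit_m)
        log_1mm = log_expit(-logit_m)
        m = expit(logit_m)

        am, bm = pr.m_beta
        lp = (
            -0.5 * (alpha / pr.alpha_sd_ms) ** 2
            - 0.5 * (beta / pr.beta_sd_ms) ** 2
            # half-normal on tau, sampled as log tau
            + (-0.5 * (tau / pr.tau_sd_ms) ** 2 + log_tau)
            + (am - 1) * log_m + (bm - 1) * log_1mm
            + log_m + log_1mm  # logit-m Jacobian
            - 0.5 * ((log_nu - pr.log_nu_mu) / pr.log_nu_sd) ** 2
        )
        # Beta(m nu, (1-m) nu) hierarchy on theta, with logit Jacobian
        a = (m * nu)[:, None]
        b = ((1.0 - m) * nu)[:, None]
        lp = lp + np.sum(
            (a - 1) * log_theta + (b - 1) * log_1mtheta
            - betaln(a, b)
            + log_theta + log_1mtheta,
            axis=1,
        )
        # binomial awareness counts
        lp = lp + np.sum(self.c * log_theta + (self.t - self.c) * log_1mtheta, axis=1)
        # observed effects with latent true-effect dispersion tau
        var = tau[:, None] ** 2 + self.se2
        mu = alpha[:, None] + beta[:, None] * self.awareness(theta)
        lp = lp - 0.5 * np.sum(np.log(var) + (self.y - mu) ** 2 / var, axis=1)
        return lp


def _init_walkers(
    lp: _LogPost, n_walkers: int, rng: np.random.Generator
) -> np.ndarray:
    """Overdispersed start: each parameter jittered on its own posterior scale.

    The slope is the critical case - its posterior can be as wide as the
    prior when awareness varies little, and ensemble moves scale proposals
    by the current walker spread, so a too-tight start mixes very slowly.
    """
    phat = np.clip((lp.c + 1.0) / (lp.t + 2.0), 1e-3, 1 - 1e-3)
    a = phat - CHANCE
    denom = np.var(a) * len(a)
    slope0 = float(np.sum((a - a.mean()) * (lp.y - lp.y.mean())) / denom) if denom > 0 else 0.0
    base = np.concatenate(
        [
            [np.mean(lp.y), slope0, math.log(10.0), 0.0, math.log(50.0)],
            np.log(phat / (1 - phat)),
        ]
    )
    scale = np.concatenate(
        [
            [
                max(2.0 * lp.y.std(ddof=1) / math.sqrt(len(lp.y)), 1.0),
                60.0,
                0.5,
                0.3,
                0.5,
            ],
            np.full(lp.n, 0.15),
        ]
    )
    return base + scale * rng.standard_normal((n_walkers, lp.ndim))


def _ensemble_rhat_ess(chains: list[np.ndarray]) -> tuple[float, float]:
    """R-hat / ESS across independent ensembles for alpha, beta, log tau.

    Each element of ``chains`` is one ensemble's (steps, walkers, dim) chain;
    ensembles were run from different seeds, so pooling each one's walkers in
    step order gives genuinely independent chains for the diagnostic.
    """
    rhats, esss = [], []
    for j in range(3):
        grouped = np.stack([c[:, :, j].reshape(-1) for c in chains])
        ds = az.convert_to_dataset(grouped)
        rhats.append(float(az.rhat(ds)["x"].values))
        esss.append(float(az.ess(ds)["x"].values))
    return max(rhats), min(esss)


def fit_me_regression(
    data: pd.DataFrame,
    priors: MEPriors | None = None,
    n_walkers: int = 64,
    n_ensembles: int = 2,
    n_steps: int = 500,
    n_burn: int = 400,
    seed: int = 0,
    rhat_tol: float = 1.01,
    max_tries: int = 2,
    predictor: str = "proportion",
) -> RegressionPosterior:
    """Fit the measurement-error regression and the intercept Bayes factor.

    Raises :class:`ConvergenceError` when split-ensemble R-hat exceeds
    ``rhat_tol`` even after doubling the chain length ``max_tries`` times.
    """
    data = _validate(data)
    if len(data) < 5:
        raise DegenerateInputError("need at least 5 participants")
    priors = priors or MEPriors()
    if data["correct_count"].nunique() == 1 and data["trial_count"].nunique() == 1:
        warnings.warn("all awareness counts identical; slope weakly identified")

    lp = _LogPost(data, priors, predictor=predictor)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    steps, burn = n_steps, n_burn
    for attempt in range(max_tries + 1):
        chains = []
        for ens in range(n_ensembles):
            rng = np.random.default_rng([seed, attempt, ens])
            sampler = emcee.EnsembleSampler(
                n_walkers, lp.ndim, lp, vectorize=True, moves=moves
            )
            # fixed-seed RandomState keeps runs reproducible
            sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
            p0 = _init_walkers(lp, n_walkers, rng)
            sampler.run_mcmc(p0, burn + steps, progress=False)
            chains.append(sampler.get_chain(discard=burn))
        rhat_max, ess_min = _ensemble_rhat_ess(chains)
        if rhat_max < rhat_tol:
            break
        steps *= 2
        burn *= 2
    else:
        raise ConvergenceError(
            f"R-hat {rhat_max:.4f} >= {rhat_tol} after {max_tries + 1} attempts"
        )

    flat = np.concatenate([c.reshape(-1, lp.ndim) for c in chains])
    alpha_d = flat[:, 0]
    beta_d = flat[:, 1]
    tau_d = np.exp(flat[:, 2])
    theta_d = 1.0 / (1.0 + np.exp(-flat[:, 5:]))

    prior0 = stats.norm.pdf(0.0, 0.0, priors.alpha_sd_ms)
    post0_rb = _posterior_alpha_density_at_zero(
        lp, priors, beta_d, tau_d, theta_d
    )
    bf10_rb = float(prior0 / post0_rb)
    kde = stats.gaussian_kde(alpha_d, bw_method="silverman")
    bf10_kde = float(prior0 / max(kde(0.0)[0], 1e-300))

    ci_a = np.percentile(alpha_d, [2.5, 97.5])
    ci_b = np.percentile(beta_d, [2.5, 97.5])
    return RegressionPosterior(
        intercept_mean_ms=float(alpha_d.mean()),
        intercept_ci95=(float(ci_a[0]), float(ci_a[1])),
        slope_mean=float(beta_d.mean()),
        slope_ci95=(float(ci_b[0]), float(ci_b[1])),
        bf10_intercept=bf10_rb,
        bf10_intercept_kde=bf10_kde,
        tau_mean_ms=float(tau_d.mean()),
        rhat_max=float(rhat_max),
        ess_min=float(ess_min),
        n_chains=n_ensembles * n_walkers,
        n_draws=int(flat.shape[0]),
        seed=seed,
        draws={"alpha": alpha_d, "beta": beta_d, "tau": tau_d},
    )


def _posterior_alpha_density_at_zero(
    lp: _LogPost,
    priors: MEPriors,
    beta_d: np.ndarray,
    tau_d: np.ndarray,
    theta_d: np.ndarray,
) -> float:
    """Rao-Blackwellized p(alpha = 0 | data).

    Conditional on (beta, tau, theta) the model is Gaussian-linear in alpha,
    so p(alpha | rest, data) is Normal in closed form; averaging its ordinate
    at zero over posterior draws of the rest gives the marginal ordinate.
    """
    inv_prior_var = 1.0 / priors.alpha_sd_ms**2
    var_i = tau_d[:, None] ** 2 + lp.se2  # (draws, n)
    w = 1.0 / var_i
    prec = inv_prior_var + w.sum(axis=1)
    resid = lp.y - beta_d[:, None] * lp.awareness(theta_d)
    mean = (w * resid).sum(axis=1) / prec
    sd = np.sqrt(1.0 / prec)
    return float(np.mean(stats.norm.pdf(0.0, mean, sd)))


@dataclass(frozen=True)
class NaiveRegression:
    intercept_ms: float
    slope_ms: float
    intercept_se_ms: float
    slope_se_ms: float
    n: int


def naive_greenwald_regression(data: pd.DataFrame) -> NaiveRegression:
    """Ordinary least squares of effect on centered observed accuracy.

    The error-ignoring baseline: its slope is attenuated toward zero by
    binomial noise in the predictor, which distorts the intercept whenever
    mean awareness is off-chance.
    """
    data = _validate(data)
    if len(data) < 3:
        raise DegenerateInputError("need at least 3 participants")
    a = data["correct_count"].to_numpy(float) / data["trial_count"].to_numpy(float) - CHANCE
    y = data["effect_ms"].to_numpy(float)
    if np.ptp(a) == 0:
        raise DegenerateInputError("constant awareness predictor")
    res = stats.linregress(a, y)
    return NaiveRegression(
        intercept_ms=float(res.intercept),
        slope_ms=float(res.slope),
        intercept_se_ms=float(res.intercept_stderr),
        slope_se_ms=float(res.stderr),
        n=len(data),
    )


def simulate_me_cohort(
    n_participants: int = 24,
    n_trials: int = 256,
    alpha_ms: float = 30.0,
    beta_ms: float = 0.0,
    tau_ms: float = 8.0,
    effect_se_ms: float = 10.0,
    theta_beta: tuple[float, float] = (55.0, 45.0),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one cohort from the generative model itself.

    Defaults mirror the calibration conditions: 24 participants, 256
    awareness trials each, latent awareness Beta(55, 45) (mean 0.55, so
    participants are on average slightly above chance), true-effect spread
    tau = 8 ms and measured-effect SE 10 ms, in the range produced by
    ~100 RT trials per congruency cell.
    """
    rng = rng if rng is not None else np.random.default_rng()
    theta = rng.beta(*theta_beta, size=n_participants)
    correct = rng.binomial(n_trials, theta)
    true_eff = alpha_ms + beta_ms * (theta - CHANCE) + rng.normal(0, tau_ms, n_participants)
    observed = true_eff + rng.normal(0, effect_se_ms, n_participants)
    return pd.DataFrame(
        {
            "participant": np.arange(n_participants),
            "correct_count": correct,
            "trial_count": n_trials,
            "effect_ms": observed,
            "effect_se_ms": effect_se_ms,
        }
    )
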