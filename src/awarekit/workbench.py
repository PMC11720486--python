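"""End-to-end orchestration: simulate/ingest -> preprocess -> SDT -> BFs ->
measurement-error regression -> GRT/SvA -> machine-readable report.

The report mirrors the analysis taxonomy of the study design: per block a
congruency Bayes-factor test (plus the PAS-1-filtered variant for the
multiple-task block), one-sample Bayes factors on the participant d' values,
the measurement-error regression of priming on awareness, GRT-wIND model
selection with SvA summaries for the blocks that measure the prime, and the
cross-block objective/subjective sensitivity comparison (2 x 2 Bayesian
ANOVA and correlations).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import bayes, grt, me_regression, preprocess, sdt, simulate, sva
from .errors import AwarekitError

log = logging.getLogger("awarekit")


class StageResult(BaseModel):
    status: str  # "ok", "failed", "skipped"
    detail: str = ""
    data: dict[str, Any] = {}


class AnalysisReport(BaseModel):
    """Validated, JSON-serializable pipeline output."""

    config_hash: str
    seed: int
    package_version: str
    blocks: list[str]
    priming_bf: dict[str, StageResult] = {}
    sensitivity_bf: dict[str, StageResult] = {}
    regression: dict[str, StageResult] = {}
    grt: dict[str, StageResult] = {}
    comparison: StageResult | None = None


def _block_priming(cohort: pd.DataFrame, block: str, pas1_only: bool,
                   prior_scale: float) -> StageResult:
    effects = preprocess.cohort_effects(cohort, block, pas1_only=pas1_only)
    if len(effects) < 2:
        return StageResult(status="failed", detail="fewer than 2 usable participants")
    res = bayes.jzs_ttest_bf(effects["effect_ms"].to_numpy(), prior_scale=prior_scale)
    return StageResult(
        status="ok",
        data={
            "bf10": res.bf10,
            "error_pct": res.error_pct,
            "t": res.statistic,
            "n": res.n,
            "mean_effect_ms": float(effects["effect_ms"].mean()),
            "pas1_only": pas1_only,
        },
    )


def _block_sensitivity(cohort: pd.DataFrame, block: str, measure: str,
                       prior_scale: float) -> StageResult:
    table = sdt.participant_sensitivities(cohort, block, measure)
    res = bayes.jzs_ttest_bf(table["d_prime"].to_numpy(), mu0=0.0,
                             prior_scale=prior_scale)
    return StageResult(
        status="ok",
        data={
            "measure": measure,
            "mean_d_prime": float(table["d_prime"].mean()),
            "bf10": res.bf10,
            "n": res.n,
        },
    )


def _block_regression(cohort: pd.DataFrame, effect_block: str, awareness_block: str,
                      seed: int, mcmc: dict) -> StageResult:
    effects = preprocess.cohort_effects(cohort, effect_block)
    counts = sdt.awareness_counts(cohort, awareness_block)
    data = counts.merge(effects[["participant", "effect_ms", "effect_se_ms"]],
                        on="participant")
    post = me_regression.fit_me_regression(data, seed=seed, **mcmc)
    naive = me_regression.naive_greenwald_regression(data)
    out = post.to_dict()
    out["awareness_block"] = awareness_block
    out["naive_intercept_ms"] = naive.intercept_ms
    out["naive_slope_ms"] = naive.slope_ms
    return StageResult(status="ok", data=out)


def _block_grt(cohort: pd.DataFrame, block: str, seed: int, models,
               restarts: int, n_boot: int) -> StageResult:
    dataset = grt.GRTDataset.from_trials(cohort, block)
    rng = np.random.default_rng([seed, hash(block) % (2**16)])
    flag_list = grt.enumerate_models() if models == "all" else models
    fits = [grt.fit_grt_wind(dataset, f, restarts=restarts, rng=rng)
            for f in flag_list]
    best = grt.select_model(fits)
    curve = sva.sva_curve(best)
    if n_boot >= 2:
        curve = sva.bootstrap_sva(best, n_boot=n_boot, rng=rng)
    return StageResult(
        status="ok",
        data={
            "selected_model": best.spec.flags.label(),
            "aic": best.aic,
            "loglik": best.loglik,
            "n_params": best.n_params,
            "pct_accounted": best.pct_accounted,
            "n_models_fit": len(fits),
            "ideal_criterion": curve.ideal_criterion,
            "rlna_at_zero": float(sva.rlna(best.spec, 0.0)),
            "d_cond_at_criterion": (
                float(sva.conditional_dprime(best.spec, curve.ideal_criterion))
                if curve.ideal_criterion is not None else None
            ),
            "n_boot": curve.n_boot,
        },
    )


def common_dprime_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-participant d'_obj and d'_subj for multiple-task + visibility blocks.

    Long format (participant, block, measure, d_prime), the input to the
    2 x 2 Bayesian ANOVA and the cross-measure correlations.
    """
    blocks = set(cohort["block"].unique())
    if not {"multiple", "visibility"} <= blocks:
        raise AwarekitError("common d' table needs multiple and visibility blocks")
    frames = []
    for block in ("multiple", "visibility"):
        for measure in ("objective", "subjective"):
            frames.append(
                sdt.participant_sensitivities(cohort, block, measure)[
                    ["participant", "block", "measure", "d_prime"]
                ]
            )
    return pd.concat(frames, ignore_index=True)


def _comparison(cohort: pd.DataFrame) -> StageResult:
    table = common_dprime_table(cohort)
    anova = bayes.rm_anova_bf(
        table, dv="d_prime", within=("block", "measure"), subject="participant"
    )
    wide = table.pivot_table(index="participant", columns=["block", "measure"],
                             values="d_prime")
    corrs = {}
    pairs = [
        ("obj_multiple_vs_visibility", ("multiple", "objective"), ("visibility", "objective")),
        ("subj_multiple_vs_visibility", ("multiple", "subjective"), ("visibility", "subjective")),
        ("obj_vs_subj_multiple", ("multiple", "objective"), ("multiple", "subjective")),
        ("obj_vs_subj_visibility", ("visibility", "objective"), ("visibility", "subjective")),
    ]
    for name, a, b in pairs:
        res = bayes.jeffreys_corr_bf(wide[a].to_numpy(), wide[b].to_numpy())
        corrs[name] = {"r": res.statistic, "bf10": res.bf10}
    return StageResult(
        status="ok",
        data={
            "anova_bf_models": anova.bf_models,
            "anova_bf_incl": anova.bf_incl,
            "correlations": corrs,
        },
    )


def _failed(exc: Exception) -> StageResult:
    return StageResult(status="failed", detail=f"{type(exc).__name__}: {exc}")


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> AnalysisReport:
    """Run every applicable stage; failed stages are recorded, dependents skipped.

    ``config`` either carries a ``simulate`` section (design + params
    overrides) or an ``input_csv`` path; ``seed`` drives all randomness.
    """
    t_start = time.time()
    seed = int(config.get("seed", 0))
    cfg_hash = hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]

    if "simulate" in config:
        sim = config["simulate"] or {}
        spec = simulate.DesignSpec(**{**sim.get("design", {}), "seed": seed})
        params = simulate.GenerativeParams(**sim.get("params", {}))
        cohort = simulate.simulate_experiment(spec, params)
    elif "input_csv" in config:
        cohort = simulate.read_trials_csv(config["input_csv"])
    else:
        raise AwarekitError("config needs a 'simulate' section or 'input_csv'")

    prior_scale = float(config.get("t_prior_scale", bayes.DEFAULT_T_PRIOR_SCALE))
    mcmc = dict(config.get("mcmc", {}))
    grt_cfg = config.get("grt", {})
    grt_models = grt_cfg.get("models", "all")
    grt_restarts = int(grt_cfg.get("restarts", 4))
    grt_boot = int(grt_cfg.get("n_boot", 0))

    blocks = [b for b in simulate.BLOCKS if b in set(cohort["block"])]
    report = AnalysisReport(
        config_hash=cfg_hash,
        seed=seed,
        package_version=_version(),
        blocks=blocks,
    )

    for block in blocks:
        if block in ("single", "multiple"):
            try:
                report.priming_bf[block] = _block_priming(
                    cohort, block, pas1_only=False, prior_scale=prior_scale
                )
            except Exception as exc:
                report.priming_bf[block] = _failed(exc)
        if block == "multiple":
            try:
                report.priming_bf["multiple_pas1"] = _block_priming(
                    cohort, block, pas1_only=True, prior_scale=prior_scale
                )
            except Exception as exc:
                report.priming_bf["multiple_pas1"] = _failed(exc)
        if block in ("multiple", "visibility"):
            for measure in ("objective", "subjective"):
                key = f"{block}_{measure}"
                try:
                    report.sensitivity_bf[key] = _block_sensitivity(
                        cohort, block, measure, prior_scale
                    )
                except Exception as exc:
                    report.sensitivity_bf[key] = _failed(exc)
            try:
                report.grt[block] = _block_grt(
                    cohort, block, seed, grt_models, grt_restarts, grt_boot
                )
            except Exception as exc:
                report.grt[block] = _failed(exc)

    # regressions: single-task effects use visibility-block awareness,
    # multiple-task effects use the same block's prime discrimination
    reg_plan = []
    if "single" in blocks and "visibility" in blocks:
        reg_plan.append(("single", "visibility"))
    if "multiple" in blocks:
        reg_plan.append(("multiple", "multiple"))
    for effect_block, awareness_block in reg_plan:
        try:
            report.regression[effect_block] = _block_regression(
                cohort, effect_block, awareness_block, seed, mcmc
            )
        except Exception as exc:
            report.regression[effect_block] = _failed(exc)

    if {"multiple", "visibility"} <= set(blocks):
        try:
            report.comparison = _comparison(cohort)
        except Exception as exc:
            report.comparison = _failed(exc)

    log.info("pipeline finished in %.1f s (seed=%d)", time.time() - t_start, seed)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.model_dump_json(indent=2))
        simulate.write_trials_csv(cohort, out / "trials.csv")
    return report


def has_failures(report: AnalysisReport) -> bool:
    stages = list(report.priming_bf.values()) + list(report.sensitivity_bf.values())
    stages += list(report.regression.values()) + list(report.grt.values())
    if report.comparison is not None:
        stages.append(report.comparison)
    return any(s.status == "failed" for s in stages)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_report_schema(path: str | Path) -> None:
    Path(path).write_text(json.dumps(AnalysisReport.model_json_schema(), indent=2))


def _version() -> str:
    from . import __version__

    return __version__


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
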