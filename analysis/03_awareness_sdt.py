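"""Objective and subjective prime-awareness sensitivity on a common d' metric.

Per participant and block: d'_obj from the 2AFC prime-shape task (square =
signal) and d'_subj from visibility detection (PAS >= 2 vs catch trials),
each sent to a one-sample JZS test against 0; then the cross-block
comparison: 2 x 2 Bayesian repeated-measures ANOVA (block x d'-type) with
inclusion BFs, and Jeffreys correlations between the four measures.
Writes results/sensitivity.csv and results/sensitivity_comparison.json.
"""

import json
from pathlib import Path

from awarekit import bayes, sdt, simulate, workbench

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = simulate.read_trials_csv(OUT / "trials.csv")
    table = workbench.common_dprime_table(cohort)
    table.to_csv(OUT / "sensitivity.csv", index=False)

    print("one-sample JZS tests of d' = 0:")
    for (block, measure), sub in table.groupby(["block", "measure"]):
        res = bayes.jzs_ttest_bf(sub["d_prime"].to_numpy())
        print(
            f"  {block:10s} {measure:10s} mean d' {sub['d_prime'].mean():6.3f}  "
            f"BF10 {res.bf10:9.3f}"
        )

    anova = bayes.rm_anova_bf(
        table, dv="d_prime", within=("block", "measure"), subject="participant"
    )
    print("2x2 Bayesian ANOVA inclusion BFs (block, d'-type, interaction):")
    for k, v in anova.bf_incl.items():
        print(f"  {k:8s} BF_incl {v:9.3f}")

    wide = table.pivot_table(index="participant", columns=["block", "measure"],
                             values="d_prime")
    corrs = {}
    for name, a, b in [
        ("obj_across_blocks", ("multiple", "objective"), ("visibility", "objective")),
        ("subj_across_blocks", ("multiple", "subjective"), ("visibility", "subjective")),
        ("obj_vs_subj_multiple", ("multiple", "objective"), ("multiple", "subjective")),
        ("obj_vs_subj_visibility", ("visibility", "objective"), ("visibility", "subjective")),
    ]:
        res = bayes.jeffreys_corr_bf(wide[a].to_numpy(), wide[b].to_numpy())
        corrs[name] = {"r": res.statistic, "bf10": res.bf10}
        print(f"  corr {name:24s} r {res.statistic:6.3f}  BF10 {res.bf10:9.3f}")

    payload = {
        "anova_bf_models": anova.bf_models,
        "anova_bf_incl": anova.bf_incl,
        "correlations": corrs,
    }
    (OUT / "sensitivity_comparison.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {OUT / 'sensitivity.csv'} and sensitivity_comparison.json")


if __name__ == "__main__":
    main()
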