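"""Trim RTs and test for congruency (priming) effects block by block.

Applies the trial filters (incorrect trials, 200-2000 ms window, +/-2 SD),
computes each participant's incongruent-minus-congruent effect, and runs
paired JZS Bayes-factor tests: single-task, multiple-task unfiltered, and
multiple-task restricted to PAS-1 ("no perception") trials.
Writes results/priming_effects.csv and results/priming_bf.json.
"""

import json
from pathlib import Path

import pandas as pd

from awarekit import bayes, preprocess, simulate

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = simulate.read_trials_csv(OUT / "trials.csv")
    frames, bfs = [], {}
    for label, block, pas1 in [
        ("single", "single", False),
        ("multiple_unfiltered", "multiple", False),
        ("multiple_pas1", "multiple", True),
    ]:
        eff = preprocess.cohort_effects(cohort, block, pas1_only=pas1)
        eff.insert(0, "analysis", label)
        frames.append(eff)
        res = bayes.jzs_ttest_bf(eff["effect_ms"].to_numpy())
        bfs[label] = {
            "mean_effect_ms": round(float(eff["effect_ms"].mean()), 2),
            "bf10": res.bf10,
            "error_pct": res.error_pct,
            "t": res.statistic,
            "n": res.n,
        }
        verdict = "priming" if res.bf10 > 3 else (
            "null favored" if res.bf10 < 1 / 3 else "inconclusive")
        print(
            f"{label:22s} effect {bfs[label]['mean_effect_ms']:6.2f} ms  "
            f"BF10 {res.bf10:10.3f}  ({verdict})"
        )
    pd.concat(frames, ignore_index=True).to_csv(
        OUT / "priming_effects.csv", index=False
    )
    (OUT / "priming_bf.json").write_text(json.dumps(bfs, indent=2))
    print(f"wrote {OUT / 'priming_effects.csv'} and priming_bf.json")


if __name__ == "__main__":
    main()
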