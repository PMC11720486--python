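"""Predict the priming effect of a completely unaware participant.

Regresses per-participant priming effects on centered awareness (proportion
correct in the prime discrimination task minus chance), once naively (OLS,
attenuation-biased) and once with the Bayesian measurement-error correction
whose intercept posterior and Savage-Dickey BF answer: is there priming at
exactly chance awareness?  Single-task effects use the visibility block's
discrimination data; multiple-task effects use the same block's.
Writes results/me_regression.json.
"""

import json
import sys
from pathlib import Path

from awarekit import me_regression, preprocess, sdt, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = simulate.read_trials_csv(OUT / "trials.csv")
    payload = {}
    for effect_block, awareness_block in [("single", "visibility"),
                                          ("multiple", "multiple")]:
        effects = preprocess.cohort_effects(cohort, effect_block)
        counts = sdt.awareness_counts(cohort, awareness_block)
        data = counts.merge(
            effects[["participant", "effect_ms", "effect_se_ms"]], on="participant"
        )
        post = me_regression.fit_me_regression(data, seed=SEED)
        naive = me_regression.naive_greenwald_regression(data)
        payload[effect_block] = post.to_dict() | {
            "naive_intercept_ms": naive.intercept_ms,
            "naive_slope_ms": naive.slope_ms,
        }
        lo, hi = post.intercept_ci95
        print(
            f"{effect_block:8s} corrected intercept {post.intercept_mean_ms:6.2f} ms "
            f"[{lo:6.2f}, {hi:6.2f}]  BF10 {post.bf10_intercept:8.3f}  "
            f"(naive: {naive.intercept_ms:6.2f} ms)"
        )
    (OUT / "me_regression.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {OUT / 'me_regression.json'}")


if __name__ == "__main__":
    main()
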