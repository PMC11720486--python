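"""Simulate the reference masked-priming cohort used by the later steps.

24 participants x 3 blocks (single-task, multiple-task, visibility) x 320
trials with 64 catch trials per block, a 10-ms awareness-independent priming
effect, and weak prime visibility (identity separation 0.5 SD, awareness
elevation 0.5 SD, boosted 1.25x in the visibility block).
Writes results/trials.csv.
"""

import sys
from pathlib import Path

from awarekit import simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    spec = simulate.DesignSpec(n_participants=24, seed=SEED)
    params = simulate.GenerativeParams()
    trials = simulate.simulate_experiment(spec, params)
    simulate.write_trials_csv(trials, OUT / "trials.csv")

    per_block = trials.groupby("block").size()
    catch = (
        trials[trials["prime_identity"] == "none"].groupby("block").size()
    )
    soa = simulate.soa_ms(spec)
    print(f"simulated {len(trials)} trials for 24 participants (seed {SEED})")
    print(f"trials per block:\n{per_block.to_string()}")
    print(f"catch trials per block:\n{catch.to_string()}")
    print(f"prime->probe SOA: {soa:.1f} ms (printed convention: {round(soa)} ms)")
    print(f"wrote {OUT / 'trials.csv'}")


if __name__ == "__main__":
    main()
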