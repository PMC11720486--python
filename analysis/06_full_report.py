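"""One-shot pipeline run producing the machine-readable analysis report.

Equivalent to `awarekit run`: simulate (or ingest) -> preprocess -> SDT ->
Bayes-factor tests -> measurement-error regression -> GRT/SvA -> report.json
mirroring the study's summary-of-results table layout.
"""

import sys
from pathlib import Path

from awarekit import workbench

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
OUT = Path(__file__).resolve().parent.parent / "results" / "report"


def main() -> None:
    workbench.setup_logging()
    config = {
        "seed": SEED,
        "simulate": {"design": {"n_participants": 24}},
        "grt": {"models": "all", "restarts": 2, "n_boot": 0},
    }
    report = workbench.run_pipeline(config, out_dir=OUT)
    for name, stage in report.priming_bf.items():
        print(f"priming {name}: {stage.status}, BF10 "
              f"{stage.data.get('bf10', float('nan')):.3f}")
    for name, stage in report.regression.items():
        print(f"regression {name}: {stage.status}, intercept "
              f"{stage.data.get('intercept_mean_ms', float('nan')):.2f} ms")
    for name, stage in report.grt.items():
        print(f"grt {name}: {stage.status}, model "
              f"{stage.data.get('selected_model')}")
    print(f"report at {OUT / 'report.json'}; "
          f"failures: {workbench.has_failures(report)}")


if __name__ == "__main__":
    main()
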