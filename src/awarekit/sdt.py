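"""Signal-detection measures of prime awareness.

Two sensitivities share one yes/no SDT convention so they can be compared on
a common metric:

* objective d' (``d_obj``): prime-shape discrimination, square primes treated
  as signal and diamond primes as noise (hit = square prime answered
  "square"; false alarm = diamond prime answered "square"); catch trials are
  excluded.
* subjective d' (``d_subj``): visibility detection, hit = prime present and
  PAS >= 2, false alarm = catch trial reported with PAS >= 2.

d' = z(H) - z(F) and c = -(z(H) + z(F))/2.  The log-linear correction
(+0.5 to each cell, +1 to each denominator) is applied unconditionally so
the estimate is finite and continuous in the counts; the uncorrected value
is reported alongside for audit (it may be infinite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DegenerateInputError

PAS_AWARE_MIN = 2


@dataclass(frozen=True)
class SDTCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    signal_definition: str = ""

    def __post_init__(self) -> None:
        for v in (self.hits, self.misses, self.false_alarms, self.correct_rejections):
            if v < 0:
                raise ValueError("SDT counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SensitivityEstimate:
    d_prime: float
    criterion_c: float
    hit_rate: float
    fa_rate: float
    correction: str
    source: str
    block: str = ""
    d_prime_uncorrected: float = float("nan")


def counts_objective(trials: pd.DataFrame) -> SDTCounts:
    """Tally the 2AFC prime-shape task with square primes as signal."""
    present = trials[trials["prime_identity"].isin(("square", "diamond"))]
    if len(present) == 0:
        raise DegenerateInputError("no prime-present trials")
    sq = present[present["prime_identity"] == "square"]
    di = present[present["prime_identity"] == "diamond"]
    hits = int((sq["prime_choice"] == "square").sum())
    fas = int((di["prime_choice"] == "square").sum())
    return SDTCounts(
        hits=hits,
        misses=len(sq) - hits,
        false_alarms=fas,
        correct_rejections=len(di) - fas,
        signal_definition="square prime = signal; choice 'square' = yes",
    )


def counts_subjective(trials: pd.DataFrame) -> SDTCounts:
    """Tally visibility detection: PAS >= 2 = 'aware', catch trials = noise."""
    catch = trials[trials["prime_identity"] == "none"]
    if len(catch) == 0:
        raise DegenerateInputError("no catch trials; false-alarm rate undefined")
    present = trials[trials["prime_identity"] != "none"]
    hits = int((present["pas"] >= PAS_AWARE_MIN).sum())
    fas = int((catch["pas"] >= PAS_AWARE_MIN).sum())
    return SDTCounts(
        hits=hits,
        misses=len(present) - hits,
        false_alarms=fas,
        correct_rejections=len(catch) - fas,
        signal_definition="prime present = signal; PAS >= 2 = yes",
    )


def dprime(
    counts: SDTCounts, source: str = "objective", block: str = ""
) -> SensitivityEstimate:
    """d' and criterion with the log-linear correction applied always."""
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise DegenerateInputError("zero total in signal or noise class")
    h = (counts.hits + 0.5) / (counts.n_signal + 1.0)
    f = (counts.false_alarms + 0.5) / (counts.n_noise + 1.0)
    zh, zf = norm.ppf(h), norm.ppf(f)
    raw_h = counts.hits / counts.n_signal
    raw_f = counts.false_alarms / counts.n_noise
    with np.errstate(divide="ignore", invalid="ignore"):
        d_raw = float(norm.ppf(raw_h) - norm.ppf(raw_f))
    return SensitivityEstimate(
        d_prime=float(zh - zf),
        criterion_c=float(-0.5 * (zh + zf)),
        hit_rate=float(h),
        fa_rate=float(f),
        correction="log-linear",
        source=source,
        block=block,
        d_prime_uncorrected=d_raw,
    )


def participant_sensitivities(
    cohort: pd.DataFrame, block: str, measure: str
) -> pd.DataFrame:
    """One SensitivityEstimate row per participant for a block.

    Group-level d' is the mean of these per-participant values (never the d'
    of pooled counts).
    """
    if measure not in ("objective", "subjective"):
        raise ValueError("measure must be 'objective' or 'subjective'")
    tally = counts_objective if measure == "objective" else counts_subjective
    rows = []
    for pid, df in cohort[cohort["block"] == block].groupby("participant", sort=True):
        est = dprime(tally(df), source=measure, block=block)
        rows.append(
            {
                "participant": pid,
                "block": block,
                "measure": measure,
                "d_prime": est.d_prime,
                "criterion_c": est.criterion_c,
                "hit_rate": est.hit_rate,
                "fa_rate": est.fa_rate,
            }
        )
    return pd.DataFrame(rows)


def awareness_counts(cohort: pd.DataFrame, block: str) -> pd.DataFrame:
    """Correct/total counts in the prime-shape task, one row per participant.

    This is the awareness measure feeding the measurement-error regression:
    the proportion correct in the 2AFC prime discrimination, whose chance
    level is 0.5.
    """
    rows = []
    for pid, df in cohort[cohort["block"] == block].groupby("participant", sort=True):
        present = df[df["prime_identity"].isin(("square", "diamond"))]
        if len(present) == 0:
            raise DegenerateInputError(f"participant {pid}: no prime-present trials")
        correct = int((present["prime_choice"] == present["prime_identity"]).sum())
        rows.append(
            {"participant": pid, "correct_count": correct, "trial_count": len(present)}
        )
    return pd.DataFrame(rows)
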