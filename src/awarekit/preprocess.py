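"""Trial trimming, PAS-based selection, participant exclusion, priming effects.

The trimming pipeline applies, in order: (1) removal of probe-incorrect
trials (RT analyses only); (2) an absolute RT window keeping 200-2000 ms
inclusive; (3) a single mean +/- 2 SD pass with the mean and SD computed on
the window survivors of the same participant x block.  The +/- 2 SD pass is
applied once, per participant x block, not per congruency condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

RT_MIN_MS = 200.0
RT_MAX_MS = 2000.0
SD_MULTIPLIER = 2.0
MIN_PAS1_PER_CELL = 10
ACCURACY_CUTOFF = 0.75
PAS4_CATCH_CUTOFF = 0.10


@dataclass(frozen=True)
class TrimAudit:
    """Bookkeeping of how many trials each trimming step removed."""

    n_input: int
    n_removed_incorrect: int
    n_removed_window: int
    n_removed_sd: int
    n_kept: int

    def __post_init__(self) -> None:
        total = (
            self.n_removed_incorrect
            + self.n_removed_window
            + self.n_removed_sd
            + self.n_kept
        )
        if total != self.n_input:
            raise ValueError("trim audit counts do not add up")


@dataclass(frozen=True)
class ParticipantEffect:
    """Per-participant congruency (priming) effect: incongruent - congruent."""

    participant: object
    block: str
    effect_ms: float
    effect_se_ms: float
    n_congruent: int
    n_incongruent: int


def trim_rts(
    trials: pd.DataFrame, for_rt_analysis: bool = True
) -> tuple[pd.DataFrame, TrimAudit]:
    """Trim one participant x block of trials; returns survivors and audit.

    Boundary RTs of exactly 200 or 2000 ms are kept (the removal rule is
    strictly below/above).  The SD pass keeps trials strictly inside
    mean +/- 2 SD boundaries inclusive.
    """
    n_input = len(trials)
    kept = trials
    n_inc = 0
    if for_rt_analysis:
        ok = kept["probe_correct"].astype(bool)
        n_inc = int((~ok).sum())
        kept = kept[ok]

    rt = kept["rt_ms"].to_numpy(dtype=float)
    in_window = (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS)
    n_window = int((~in_window).sum())
    kept = kept[in_window]

    if len(kept) == 0:
        raise DegenerateInputError("no trials survive the RT window; SD undefined")

    rt = kept["rt_ms"].to_numpy(dtype=float)
    mean, sd = rt.mean(), rt.std(ddof=1) if len(rt) > 1 else 0.0
    in_band = (rt >= mean - SD_MULTIPLIER * sd) & (rt <= mean + SD_MULTIPLIER * sd)
    n_sd = int((~in_band).sum())
    kept = kept[in_band]

    audit = TrimAudit(
        n_input=n_input,
        n_removed_incorrect=n_inc,
        n_removed_window=n_window,
        n_removed_sd=n_sd,
        n_kept=len(kept),
    )
    return kept, audit


def select_pas1(trials: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Keep PAS-1 (no perception) trials; flag sparse congruency cells.

    The warning flag is raised when either congruency cell retains fewer than
    ten PAS-1 trials, mirroring the caveat applied to low-report participants.
    """
    subset = trials[trials["pas"] == 1]
    cong = subset["congruent"]
    n_c = int(cong.eq(True).sum())
    n_i = int(cong.eq(False).sum())
    warn = n_c < MIN_PAS1_PER_CELL or n_i < MIN_PAS1_PER_CELL
    return subset, warn


def exclusion_flags(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-participant exclusion flags from the multiple-task/visibility blocks.

    ``low_accuracy``: probe accuracy strictly below 75% in the multiple-task
    block.  ``pas4_catch_abuse``: more than 10% PAS-4 ("clear perception")
    reports on catch trials in the multiple-task or the visibility block.
    A flag is pd.NA when the block needed to compute it is absent.
    """
    records = []
    for pid, df in cohort.groupby("participant", sort=True):
        multi = df[df["block"] == "multiple"]
        vis = df[df["block"] == "visibility"]

        if len(multi):
            low_acc = multi["probe_correct"].mean() < ACCURACY_CUTOFF
        else:
            low_acc = pd.NA

        rates = []
        for block_df in (multi, vis):
            catch = block_df[block_df["prime_identity"] == "none"]
            if len(catch):
                rates.append((catch["pas"] == 4).mean())
        abuse = max(rates) > PAS4_CATCH_CUTOFF if rates else pd.NA

        records.append(
            {"participant": pid, "low_accuracy": low_acc, "pas4_catch_abuse": abuse}
        )
    out = pd.DataFrame(records)
    out["low_accuracy"] = out["low_accuracy"].astype("boolean")
    out["pas4_catch_abuse"] = out["pas4_catch_abuse"].astype("boolean")
    return out


def congruency_effect(trials: pd.DataFrame) -> ParticipantEffect:
    """Mean incongruent minus mean congruent RT with its standard error."""
    cong = trials[trials["congruent"].eq(True)]["rt_ms"].to_numpy(dtype=float)
    incong = trials[trials["congruent"].eq(False)]["rt_ms"].to_numpy(dtype=float)
    if len(cong) == 0 or len(incong) == 0:
        raise DegenerateInputError("empty congruency cell")
    var_c = cong.var(ddof=1) if len(cong) > 1 else 0.0
    var_i = incong.var(ddof=1) if len(incong) > 1 else 0.0
    se = float(np.sqrt(var_c / len(cong) + var_i / len(incong)))
    participant = trials["participant"].iloc[0] if "participant" in trials else None
    block = str(trials["block"].iloc[0]) if "block" in trials else ""
    return ParticipantEffect(
        participant=participant,
        block=block,
        effect_ms=float(incong.mean() - cong.mean()),
        effect_se_ms=se,
        n_congruent=len(cong),
        n_incongruent=len(incong),
    )


def cohort_effects(
    cohort: pd.DataFrame,
    block: str,
    pas1_only: bool = False,
    for_rt_analysis: bool = True,
    pas1_before_trim: bool = False,
) -> pd.DataFrame:
    """Trim and compute the congruency effect for every participant in a block.

    PAS-1 selection, when requested, happens after trimming by default (the
    +/- 2 SD pass then uses all of the participant's in-window trials);
    ``pas1_before_trim`` flips the order so the SD pass sees only PAS-1
    trials.
    """
    rows = []
    for pid, df in cohort[cohort["block"] == block].groupby("participant", sort=True):
        low_pas1 = False
        if pas1_only and pas1_before_trim:
            df, low_pas1 = select_pas1(df)
            if len(df) == 0:
                continue
        kept, audit = trim_rts(df, for_rt_analysis=for_rt_analysis)
        if pas1_only and not pas1_before_trim:
            kept, low_pas1 = select_pas1(kept)
        try:
            eff = congruency_effect(kept)
        except DegenerateInputError:
            continue
        rows.append(
            {
                "participant": pid,
                "block": block,
                "effect_ms": eff.effect_ms,
                "effect_se_ms": eff.effect_se_ms,
                "n_congruent": eff.n_congruent,
                "n_incongruent": eff.n_incongruent,
                "n_trimmed": audit.n_input - audit.n_kept,
                "low_pas1": low_pas1,
            }
        )
    return pd.DataFrame(rows)
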