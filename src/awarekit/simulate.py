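"""Synthetic masked-priming experiments.

The generator mirrors the structure of a three-block masked-priming study:
a single-task priming block (respond to the probe only), a multiple-task
priming block (probe response, then prime discrimination and a PAS visibility
rating on every trial), and a prime visibility block.  Each block has 320
trials of which 20% are prime-absent catch trials; present trials split
equally between square and diamond primes and, within shape, between
congruent and incongruent prime-probe pairings.

Behaviour is generated from a two-dimensional Gaussian percept model
(identity evidence x awareness evidence), the generative counterpart of the
GRT model fitted downstream: the prime 2AFC choice is a criterion cut on the
identity axis, the PAS rating bins the awareness axis at three ordered
cutpoints, and the probe RT is lognormal around a base time plus a congruency
effect that may scale with the trial's awareness evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidDesignError

BLOCKS = ("single", "multiple", "visibility")
PRIME_LABELS = ("square", "diamond")

# Display timings are multiples of the 75-Hz monitor frame (13.33 ms); the
# usual integer write-ups (67, 53, 13 ms) are roundings of 5, 4 and 1 frames.
FRAME_MS = 1000.0 / 75.0

DEFAULT_DURATIONS_MS: dict[str, float] = {
    "fixation": 1000.0,
    "forward_mask": 100.0,
    "prime": 3 * FRAME_MS,  # 40 ms
    "isi": 0.0,
    "backward_mask": 5 * FRAME_MS,  # ~67 ms
    "iti": 800.0,
}


def mask_settings() -> dict[str, dict[str, float]]:
    """The two backward-masking configurations used across experiments.

    'immediate' masks right after the prime (5 frames); 'isi' inserts a
    one-frame blank and shortens the mask to 4 frames.  Both give the same
    prime-to-probe SOA (8 frames = 106.7 ms, conventionally reported as
    107 ms).
    """
    return {
        "immediate": dict(DEFAULT_DURATIONS_MS, isi=0.0, backward_mask=5 * FRAME_MS),
        "isi": dict(
            DEFAULT_DURATIONS_MS, isi=1 * FRAME_MS, backward_mask=4 * FRAME_MS
        ),
    }

CSV_COLUMNS = [
    "participant",
    "block",
    "trial",
    "prime_identity",
    "congruent",
    "probe_identity",
    "rt_ms",
    "probe_correct",
    "prime_choice",
    "pas",
]


@dataclass(frozen=True)
class DesignSpec:
    """Trial-count and timing layout of one simulated experiment."""

    n_participants: int = 24
    blocks: tuple[str, ...] = BLOCKS
    trials_per_block: int = 320
    catch_proportion: float = 0.20
    event_durations_ms: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DURATIONS_MS)
    )
    prime_labels: tuple[str, str] = PRIME_LABELS
    congruency_balance: float = 0.5
    balance_probe: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_block <= 0:
            raise InvalidDesignError("trials_per_block must be positive")
        if self.n_participants <= 0:
            raise InvalidDesignError("n_participants must be positive")
        if not 0.0 <= self.catch_proportion < 1.0:
            raise InvalidDesignError("catch_proportion must be in [0, 1)")
        unknown = set(self.blocks) - set(BLOCKS)
        if unknown:
            raise InvalidDesignError(f"unknown block labels: {sorted(unknown)}")

    @property
    def n_catch(self) -> int:
        return int(round(self.catch_proportion * self.trials_per_block))


def soa_ms(spec: DesignSpec) -> float:
    """Prime-to-probe stimulus onset asynchrony in milliseconds.

    Prime onset to probe onset spans the prime itself, the (possibly zero)
    inter-stimulus blank, and the backward mask; both mask settings used in
    the study (isi 0 / mask 67 and isi 13 / mask 53) give 107 ms.
    """
    d = spec.event_durations_ms
    try:
        return float(d["prime"]) + float(d["isi"]) + float(d["backward_mask"])
    except KeyError as exc:
        raise ConfigurationError(f"missing event duration: {exc.args[0]}") from exc


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the behaviour-generating model.

    ``class_means``/``class_sds``/``class_rhos`` define one bivariate Gaussian
    over (identity evidence, awareness evidence) per stimulus class; the
    ``absent`` class anchors the space at mean (0, 0) with unit variances.
    ``attention_scale_by_block`` multiplies present-class mean vectors, the
    simplest monotone visibility manipulation.  ``pas_criteria`` are the three
    ordered cutpoints turning awareness evidence into a PAS 1-4 rating, and
    ``identity_criterion`` the cut deciding the 2AFC prime choice.

    The RT model is lognormal with mean ``base_rt_ms[block]`` on congruent
    trials and base + ``alpha_ms`` + ``beta_ms``*(awareness - present mean)
    on incongruent trials, so ``alpha_ms`` is the true awareness-independent
    (unconscious) priming effect and ``beta_ms`` its awareness dependence.
    ``participant_sd`` is the SD of per-participant awareness offsets added
    to present-class awareness means.
    """

    class_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "square": (0.25, 0.5),
            "diamond": (-0.25, 0.5),
            "absent": (0.0, 0.0),
        }
    )
    class_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "square": (1.0, 1.0),
            "diamond": (1.0, 1.0),
            "absent": (1.0, 1.0),
        }
    )
    class_rhos: Mapping[str, float] = field(
        default_factory=lambda: {"square": 0.0, "diamond": 0.0, "absent": 0.0}
    )
    attention_scale_by_block: Mapping[str, float] = field(
        default_factory=lambda: {"single": 1.0, "multiple": 1.0, "visibility": 1.25}
    )
    pas_criteria: tuple[float, float, float] = (1.0, 2.0, 3.0)
    identity_criterion: float = 0.0
    base_rt_ms: Mapping[str, float] = field(
        default_factory=lambda: {"single": 520.0, "multiple": 650.0, "visibility": 600.0}
    )
    alpha_ms: float = 10.0
    beta_ms: float = 0.0
    rt_sigma_log: float = 0.15
    probe_error_rate: float = 0.03
    participant_sd: float = 0.3

    def __post_init__(self) -> None:
        c = np.asarray(self.pas_criteria, dtype=float)
        if not np.all(np.diff(c) > 0):
            raise ConfigurationError("pas_criteria must be strictly increasing")
        if not 0.0 <= self.probe_error_rate < 1.0:
            raise ConfigurationError("probe_error_rate must be in [0, 1)")
        for label, (sx, sy) in self.class_sds.items():
            if sx <= 0 or sy <= 0:
                raise ConfigurationError(f"non-positive SD for class {label!r}")
        for label, rho in self.class_rhos.items():
            if not -1.0 < rho < 1.0:
                raise ConfigurationError(f"correlation out of (-1,1) for {label!r}")
        for b, k in self.attention_scale_by_block.items():
            if k <= 0:
                raise ConfigurationError(f"attention scale for {b!r} must be > 0")

    def mean_present_awareness(self, block: str) -> float:
        """Population mean awareness evidence over present classes in a block."""
        kappa = self.attention_scale_by_block[block]
        mys = [self.class_means[lbl][1] for lbl in ("square", "diamond")]
        return kappa * float(np.mean(mys))


def build_design(spec: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Build one participant's randomized trial list.

    Returns a frame with columns block, trial, prime_identity, congruent,
    probe_identity.  Counts are exact per block (catch count, equal prime
    split, balanced congruency); only the order is random.
    """
    frames = []
    for block in spec.blocks:
        rows = _block_rows(spec)
        order = rng.permutation(len(rows))
        df = pd.DataFrame([rows[i] for i in order])
        df.insert(0, "block", block)
        df.insert(1, "trial", np.arange(len(rows)))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _block_rows(spec: DesignSpec) -> list[dict]:
    n = spec.trials_per_block
    n_catch = spec.n_catch
    n_present = n - n_catch
    if n_present <= 0:
        raise InvalidDesignError("no prime-present trials in design")
    a, b = spec.prime_labels
    rows: list[dict] = []
    # catch trials: no prime; probe balanced across shapes when requested
    for i in range(n_catch):
        probe = (a, b)[i % 2] if spec.balance_probe else a
        rows.append(
            {"prime_identity": "none", "congruent": pd.NA, "probe_identity": probe}
        )
    per_shape = _split(n_present, 2)
    for shape, n_shape in zip((a, b), per_shape):
        n_congruent = int(round(spec.congruency_balance * n_shape))
        other = b if shape == a else a
        for i in range(n_shape):
            congruent = i < n_congruent
            rows.append(
                {
                    "prime_identity": shape,
                    "congruent": congruent,
                    "probe_identity": shape if congruent else other,
                }
            )
    return rows


def _split(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def participant_rng(seed: int, participant: int) -> np.random.Generator:
    """Independent substream for one participant, derived by counter."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(participant,)))


def simulate_participant(
    params: GenerativeParams,
    design: pd.DataFrame,
    rng: np.random.Generator,
    participant: int = 0,
) -> pd.DataFrame:
    """Simulate one participant's responses for a prepared trial list."""
    blocks = design["block"].unique()
    unknown = set(blocks) - set(params.attention_scale_by_block)
    if unknown:
        raise ConfigurationError(f"no attention scale for blocks {sorted(unknown)}")
    unknown = set(blocks) - set(params.base_rt_ms)
    if unknown:
        raise ConfigurationError(f"no base RT for blocks {sorted(unknown)}")

    offset = rng.normal(0.0, params.participant_sd) if params.participant_sd > 0 else 0.0

    out = design.copy()
    n = len(out)
    ident = np.empty(n)
    aware = np.empty(n)
    for block in blocks:
        kappa = params.attention_scale_by_block[block]
        for label in ("square", "diamond", "none"):
            mask = (out["block"] == block) & (out["prime_identity"] == label).to_numpy()
            m = int(mask.sum())
            if m == 0:
                continue
            cls = "absent" if label == "none" else label
            mx, my = params.class_means[cls]
            sx, sy = params.class_sds[cls]
            rho = params.class_rhos[cls]
            if cls != "absent":
                mx, my = kappa * mx, kappa * my + offset
            z = rng.multivariate_normal(
                [mx, my],
                [[sx**2, rho * sx * sy], [rho * sx * sy, sy**2]],
                size=m,
            )
            ident[mask], aware[mask] = z[:, 0], z[:, 1]

    out["prime_choice"] = np.where(
        ident > params.identity_criterion, "square", "diamond"
    )
    out["pas"] = 1 + np.searchsorted(
        np.asarray(params.pas_criteria, dtype=float), aware
    ).astype(np.int64)

    # RT: congruency effect applies on incongruent trials; may scale with the
    # trial's awareness evidence centered on the block's mean present awareness.
    congruent = out["congruent"]
    incong = congruent.eq(False).to_numpy()
    base = out["block"].map(params.base_rt_ms).to_numpy(dtype=float)
    centered = np.zeros(n)
    for block in blocks:
        bmask = (out["block"] == block).to_numpy()
        centered[bmask] = aware[bmask] - params.mean_present_awareness(block)
    mean_rt = base + incong * (params.alpha_ms + params.beta_ms * centered)
    mean_rt = np.maximum(mean_rt, 1.0)
    sig = params.rt_sigma_log
    out["rt_ms"] = np.exp(rng.normal(np.log(mean_rt) - sig**2 / 2.0, sig))
    out["probe_correct"] = rng.random(n) >= params.probe_error_rate
    out.insert(0, "participant", participant)
    out["congruent"] = out["congruent"].astype("boolean")
    return out[CSV_COLUMNS]


def simulate_experiment(
    spec: DesignSpec, params: GenerativeParams
) -> pd.DataFrame:
    """Simulate the full cohort; participant substreams derive from spec.seed."""
    frames = []
    for p in range(spec.n_participants):
        rng = participant_rng(spec.seed, p)
        design = build_design(spec, rng)
        frames.append(simulate_participant(params, design, rng, participant=p))
    return pd.concat(frames, ignore_index=True)


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    """Write the trial table; catch-trial congruency becomes an empty field."""
    df = trials.copy()
    df["congruent"] = df["congruent"].map({True: "True", False: "False", pd.NA: ""})
    df["probe_correct"] = df["probe_correct"].astype(bool)
    df.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials_csv` (or real data)."""
    df = pd.read_csv(path, dtype={"congruent": "string"})
    cong = df["congruent"].str.strip().str.lower()
    df["congruent"] = (
        cong.map({"true": True, "false": False}).astype("boolean")
    )
    df["pas"] = df["pas"].astype(np.int64)
    df["probe_correct"] = df["probe_correct"].astype(bool)
    return df


def null_params(**overrides) -> GenerativeParams:
    """Params with absent and present classes identical and no RT effect.

    Convenience for calibration tests: every awareness and identity signal is
    absent, so d' estimates and priming effects should converge to zero.
    """
    base = GenerativeParams(
        class_means={
            "square": (0.0, 0.0),
            "diamond": (0.0, 0.0),
            "absent": (0.0, 0.0),
        },
        alpha_ms=0.0,
        beta_ms=0.0,
        participant_sd=0.0,
    )
    return replace(base, **overrides) if overrides else base
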