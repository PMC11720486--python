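"""GRT-wIND: two-dimensional signal detection over identity and awareness.

Each stimulus class (square prime, diamond prime, absent/catch) produces a
bivariate Gaussian percept over (identity evidence, awareness evidence).
The absent class is anchored at mean (0, 0) with unit variances for
identifiability.  Individual differences ("wIND"): each participant scales
present-class mean vectors by an attention parameter kappa (anchored so the
kappas have geometric mean 1, which ties the global mean scale to the whole
cohort rather than any single participant), and owns an identity criterion (vertical bound: answer
"square" when identity evidence exceeds it) plus three ordered awareness
cutpoints that bin awareness evidence into PAS 1-4.  When decisional
separability on the awareness dimension is relaxed, the awareness bounds are
parallel lines of common slope through the cutpoints at the identity-bound
location.

Sixteen model variants arise from the four binary constraints:

* ``equal_variances`` - every class has unit variances on both dimensions;
* ``perceptual_separability`` - square and diamond share the awareness
  marginal (mean and SD);
* ``perceptual_independence`` - zero identity-awareness correlation within
  every class;
* ``decisional_separability`` - awareness bounds orthogonal to the awareness
  axis (zero slope).

Decision-region probabilities are exact: with sloped bounds the variable
w = awareness - slope * identity is jointly Gaussian with identity evidence,
so every one of the 8 response cells is a bivariate-normal rectangle.
Fitting is penalized-free maximum likelihood (multinomial) by L-BFGS-B with
multi-start, using a block-structured finite-difference gradient that
exploits the fact that each participant's parameters only enter their own
likelihood term.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from ._bvn import bvn_cdf
from .errors import ConvergenceError, DegenerateInputError

STIMULI = ("square", "diamond", "absent")
RESPONSES = ("square", "diamond")
PRESENT = ("square", "diamond")
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class GRTFlags:
    """The four binary constraints defining one of the 16 model variants."""

    equal_variances: bool
    perceptual_separability: bool
    perceptual_independence: bool
    decisional_separability: bool

    def label(self) -> str:
        bits = [
            "EV" if self.equal_variances else "ev",
            "PS" if self.perceptual_separability else "ps",
            "PI" if self.perceptual_independence else "pi",
            "DS" if self.decisional_separability else "ds",
        ]
        return "-".join(bits)


FULL_MODEL = GRTFlags(False, False, False, False)
MOST_CONSTRAINED = GRTFlags(True, True, True, True)


def enumerate_models() -> list[GRTFlags]:
    """All 2^4 constraint combinations; the full model is all-flags-false."""
    combos = itertools.product([False, True], repeat=4)
    return [GRTFlags(*c) for c in combos]


def param_names(flags: GRTFlags, n_participants: int) -> list[str]:
    """Free-parameter names; constrained sets are subsets of the full set."""
    names = ["mx_square", "mx_diamond", "my_square"]
    if not flags.perceptual_separability:
        names.append("my_diamond")
    if not flags.equal_variances:
        names += ["log_sx_square", "log_sx_diamond", "log_sy_square"]
        if not flags.perceptual_separability:
            names.append("log_sy_diamond")
    if not flags.perceptual_independence:
        names += ["z_rho_square", "z_rho_diamond", "z_rho_absent"]
    for i in range(n_participants):
        if i > 0:
            names.append(f"log_kappa_{i}")
        names += [f"bound_{i}", f"cut1_{i}", f"log_gap2_{i}", f"log_gap3_{i}"]
        if not flags.decisional_separability:
            names.append(f"slope_{i}")
    return names


@dataclass(frozen=True)
class GRTModelSpec:
    """A (possibly fitted) GRT-wIND parameterization."""

    flags: GRTFlags
    means: dict[str, tuple[float, float]]
    sds: dict[str, tuple[float, float]]
    rhos: dict[str, float]
    kappa: np.ndarray
    bounds: np.ndarray
    cuts: np.ndarray  # (n, 3), strictly increasing per row
    slopes: np.ndarray

    @property
    def n_participants(self) -> int:
        return len(self.kappa)

    def validate(self) -> None:
        if self.means["absent"] != (0.0, 0.0):
            raise ValueError("absent class must be anchored at (0, 0)")
        for lbl in STIMULI:
            sx, sy = self.sds[lbl]
            if sx <= 0 or sy <= 0:
                raise ValueError(f"non-positive SD for {lbl}")
            if not -1.0 < self.rhos[lbl] < 1.0:
                raise ValueError(f"invalid correlation for {lbl}")
        if not np.all(np.diff(self.cuts, axis=1) > 0):
            raise ValueError("awareness cutpoints must be strictly increasing")
        if np.any(self.kappa <= 0):
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class GRTDataset:
    """Per-participant response counts over stimulus x (2 shapes x 4 PAS)."""

    counts: np.ndarray  # (n, 3, 2, 4) in STIMULI x RESPONSES x PAS order
    participants: tuple = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 4 or c.shape[1:] != (3, 2, 4):
            raise ValueError("counts must have shape (n, 3, 2, 4)")
        if np.any(c < 0):
            raise ValueError("negative counts")

    @property
    def n_participants(self) -> int:
        return self.counts.shape[0]

    @property
    def has_catch(self) -> bool:
        return bool(self.counts[:, STIMULI.index("absent")].sum() > 0)

    def content_hash(self) -> str:
        return hashlib.sha1(np.ascontiguousarray(self.counts).tobytes()).hexdigest()

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, block: str) -> "GRTDataset":
        """Aggregate a trial table (one block) into the count tensor."""
        df = trials[trials["block"] == block] if "block" in trials else trials
        pids = sorted(df["participant"].unique())
        counts = np.zeros((len(pids), 3, 2, 4), dtype=float)
        stim_of = {"square": 0, "diamond": 1, "none": 2}
        for i, pid in enumerate(pids):
            sub = df[df["participant"] == pid]
            for (prime, choice, pas), n in (
                sub.groupby(["prime_identity", "prime_choice", "pas"]).size().items()
            ):
                counts[i, stim_of[prime], RESPONSES.index(choice), int(pas) - 1] = n
        return cls(counts=counts, participants=tuple(pids))


# ---------------------------------------------------------------------------
# Probability engine
# ---------------------------------------------------------------------------

def _cell_probs(mx, my, sx, sy, rho, b, cuts, slope):
    """Response-cell probabilities for broadcastable parameter arrays.

    Leading dims broadcast; ``cuts`` carries a trailing axis of length 3.
    Returns an array with trailing shape (..., 2, 4) over
    (shape response: square, diamond) x PAS 1-4.
    """
    mx, my, sx, sy, rho, b, slope = np.broadcast_arrays(
        *(np.asarray(v, float) for v in (mx, my, sx, sy, rho, b, slope))
    )
    cuts = np.broadcast_to(np.asarray(cuts, float), mx.shape + (3,))

    # w = y - slope * x is Gaussian jointly with x
    mw = my - slope * mx
    var_w = sy**2 - 2.0 * slope * rho * sx * sy + (slope * sx) ** 2
    sw = np.sqrt(var_w)
    cov_xw = rho * sx * sy - slope * sx**2
    rho_xw = cov_xw / (sx * sw)

    hb = (b - mx) / sx  # standardized identity bound
    tk = (cuts - slope[..., None] * b[..., None] - mw[..., None]) / sw[..., None]

    F = bvn_cdf(hb[..., None], tk, rho_xw[..., None])  # P(x<=b, w<=t_k)
    Phi_w = ndtr(tk)
    Phi_b = ndtr(hb)

    left = np.concatenate(  # x <= b: diamond response
        [
            F[..., :1],
            F[..., 1:] - F[..., :-1],
            (Phi_b - F[..., -1])[..., None],
        ],
        axis=-1,
    )
    marg = np.concatenate(
        [
            Phi_w[..., :1],
            Phi_w[..., 1:] - Phi_w[..., :-1],
            (1.0 - Phi_w[..., -1])[..., None],
        ],
        axis=-1,
    )
    right = marg - left  # x > b: square response
    out = np.stack([right, left], axis=-2)
    return np.clip(out, 0.0, 1.0)


def _spec_param_arrays(spec: GRTModelSpec):
    """Per-(participant, stimulus) parameter arrays, shape (n, 3)."""
    n = spec.n_participants
    mx = np.empty((n, 3))
    my = np.empty((n, 3))
    sx = np.empty((n, 3))
    sy = np.empty((n, 3))
    rho = np.empty((n, 3))
    for s, lbl in enumerate(STIMULI):
        mmx, mmy = spec.means[lbl]
        scale = spec.kappa if lbl != "absent" else np.ones(n)
        mx[:, s] = scale * mmx
        my[:, s] = scale * mmy
        sx[:, s], sy[:, s] = spec.sds[lbl]
        rho[:, s] = spec.rhos[lbl]
    return mx, my, sx, sy, rho


def predict_all(spec: GRTModelSpec) -> np.ndarray:
    """Predicted response probabilities, shape (n, 3, 2, 4)."""
    mx, my, sx, sy, rho = _spec_param_arrays(spec)
    return _cell_probs(
        mx,
        my,
        sx,
        sy,
        rho,
        spec.bounds[:, None],
        spec.cuts[:, None, :],
        spec.slopes[:, None],
    )


def predict_response_probs(
    spec: GRTModelSpec, participant: int, stimulus: str
) -> np.ndarray:
    """The 8 response probabilities (2 shapes x 4 PAS) for one condition."""
    spec.validate()
    probs = predict_all(spec)
    return probs[participant, STIMULI.index(stimulus)]


def negloglik(spec: GRTModelSpec, dataset: GRTDataset) -> float:
    """Multinomial negative log-likelihood over participants and stimuli."""
    if dataset.n_participants != spec.n_participants:
        raise ValueError("participant count mismatch between spec and dataset")
    p = np.maximum(predict_all(spec), _P_FLOOR)
    return float(-(dataset.counts * np.log(p)).sum())


def simulate_dataset(
    spec: GRTModelSpec, trial_counts: np.ndarray, rng: np.random.Generator
) -> GRTDataset:
    """Multinomial samples from the model at given (n, 3) per-condition totals."""
    probs = predict_all(spec)
    n = spec.n_participants
    counts = np.zeros((n, 3, 2, 4))
    totals = np.broadcast_to(np.asarray(trial_counts), (n, 3))
    for i in range(n):
        for s in range(3):
            flat = probs[i, s].reshape(-1)
            flat = flat / flat.sum()
            counts[i, s] = rng.multinomial(int(totals[i, s]), flat).reshape(2, 4)
    return GRTDataset(counts=counts, participants=tuple(range(n)))


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------

class _Packing:
    """Maps between the flat optimizer vector and a GRTModelSpec."""

    def __init__(self, flags: GRTFlags, n: int):
        self.flags = flags
        self.n = n
        self.names = param_names(flags, n)
        self.dim = len(self.names)
        self.global_idx: list[int] = []
        self.local_idx: list[list[int]] = [[] for _ in range(n)]
        self.kappa_idx: list[int] = []
        for j, name in enumerate(self.names):
            tail = name.rsplit("_", 1)[-1]
            if tail.isdigit():
                self.local_idx[int(tail)].append(j)
                if name.startswith("log_kappa"):
                    self.kappa_idx.append(j)
            else:
                self.global_idx.append(j)
        self.lower = np.empty(self.dim)
        self.upper = np.empty(self.dim)
        for j, name in enumerate(self.names):
            if name.startswith(("mx", "my", "bound", "cut1")):
                lo, hi = -10.0, 10.0
            elif name.startswith(("log_sx", "log_sy", "log_kappa")):
                lo, hi = -2.3, 2.3
            elif name.startswith("z_rho"):
                lo, hi = -3.0, 3.0
            elif name.startswith("log_gap"):
                lo, hi = -7.0, 3.0
            else:  # slope
                lo, hi = -3.0, 3.0
            self.lower[j], self.upper[j] = lo, hi

    def unpack(self, theta: np.ndarray) -> GRTModelSpec:
        f = self.flags
        n = self.n
        it = iter(theta[: len(self.global_idx)])
        mx_s, mx_d, my_s = next(it), next(it), next(it)
        my_d = my_s if f.perceptual_separability else next(it)
        if f.equal_variances:
            sx_s = sx_d = sy_s = sy_d = 1.0
        else:
            sx_s, sx_d, sy_s = np.exp(next(it)), np.exp(next(it)), np.exp(next(it))
            sy_d = sy_s if f.perceptual_separability else np.exp(next(it))
        if f.perceptual_independence:
            r_s = r_d = r_a = 0.0
        else:
            r_s, r_d, r_a = np.tanh(next(it)), np.tanh(next(it)), np.tanh(next(it))

        # kappas have geometric mean 1: participant 0 carries minus the sum
        # of the other participants' log kappas
        kappa = np.ones(n)
        bounds = np.empty(n)
        cuts = np.empty((n, 3))
        slopes = np.zeros(n)
        if self.kappa_idx:
            kappa[0] = np.exp(-float(np.sum(theta[self.kappa_idx])))
        pos = len(self.global_idx)
        for i in range(n):
            if i > 0:
                kappa[i] = np.exp(theta[pos]); pos += 1
            bounds[i] = theta[pos]; pos += 1
            c1 = theta[pos]; g2 = np.exp(theta[pos + 1]); g3 = np.exp(theta[pos + 2])
            pos += 3
            cuts[i] = (c1, c1 + g2, c1 + g2 + g3)
            if not f.decisional_separability:
                slopes[i] = theta[pos]; pos += 1
        return GRTModelSpec(
            flags=f,
            means={
                "square": (float(mx_s), float(my_s)),
                "diamond": (float(mx_d), float(my_d)),
                "absent": (0.0, 0.0),
            },
            sds={
                "square": (float(sx_s), float(sy_s)),
                "diamond": (float(sx_d), float(sy_d)),
                "absent": (1.0, 1.0),
            },
            rhos={"square": float(r_s), "diamond": float(r_d), "absent": float(r_a)},
            kappa=kappa,
            bounds=bounds,
            cuts=cuts,
            slopes=slopes,
        )

    def pack(self, spec: GRTModelSpec) -> np.ndarray:
        """Flatten a spec; kappas are renormalized to geometric mean 1 with
        the scale folded into the present-class means (an equivalent model)."""
        f = self.flags
        gm = float(np.exp(np.mean(np.log(spec.kappa))))
        means = {
            lbl: (spec.means[lbl][0] * gm, spec.means[lbl][1] * gm)
            for lbl in PRESENT
        }
        kappa = spec.kappa / gm
        vals: list[float] = []
        vals += [means["square"][0], means["diamond"][0], means["square"][1]]
        if not f.perceptual_separability:
            vals.append(means["diamond"][1])
        if not f.equal_variances:
            vals += [
                np.log(spec.sds["square"][0]),
                np.log(spec.sds["diamond"][0]),
                np.log(spec.sds["square"][1]),
            ]
            if not f.perceptual_separability:
                vals.append(np.log(spec.sds["diamond"][1]))
        if not f.perceptual_independence:
            vals += [
                np.arctanh(spec.rhos["square"]),
                np.arctanh(spec.rhos["diamond"]),
                np.arctanh(spec.rhos["absent"]),
            ]
        for i in range(spec.n_participants):
            if i > 0:
                vals.append(np.log(kappa[i]))
            vals.append(spec.bounds[i])
            c = spec.cuts[i]
            vals += [c[0], np.log(c[1] - c[0]), np.log(c[2] - c[1])]
            if not f.decisional_separability:
                vals.append(spec.slopes[i])
        theta = np.asarray(vals, float)
        if theta.size != self.dim:
            raise ValueError("packing size mismatch")
        return theta


@dataclass(frozen=True)
class GRTFitResult:
    spec: GRTModelSpec
    loglik: float
    n_params: int
    aic: float
    pct_accounted: float
    mad_proportion: float
    convergence: str
    n_restarts: int
    dataset_hash: str
    theta: np.ndarray = field(repr=False, default=None)
    trial_counts: np.ndarray = field(repr=False, default=None)


def _nll_parts(packing: _Packing, theta: np.ndarray, counts: np.ndarray) -> np.ndarray:
    spec = packing.unpack(theta)
    p = np.maximum(predict_all(spec), _P_FLOOR)
    return -(counts * np.log(p)).sum(axis=(1, 2, 3))


def _participant_nll(
    packing: _Packing, theta: np.ndarray, counts_i: np.ndarray, i: int
) -> float:
    # Rebuild only participant i's cells; global unpack is cheap.
    spec = packing.unpack(theta)
    mx, my, sx, sy, rho = _spec_param_arrays(spec)
    p = _cell_probs(
        mx[i], my[i], sx[i], sy[i], rho[i],
        spec.bounds[i], spec.cuts[i][None, :].repeat(3, axis=0), spec.slopes[i],
    )
    p = np.maximum(p, _P_FLOOR)
    return float(-(counts_i * np.log(p)).sum())


def _local_values(packing: _Packing, theta: np.ndarray, i: int):
    """(kappa, bound, cuts, slope) for participant i from the flat vector."""
    idxs = packing.local_idx[i]
    pos = 0
    if i > 0:
        kappa = float(np.exp(theta[idxs[0]])); pos = 1
    else:
        kappa = (
            float(np.exp(-np.sum(theta[packing.kappa_idx])))
            if packing.kappa_idx
            else 1.0
        )
    b = float(theta[idxs[pos]])
    c1 = float(theta[idxs[pos + 1]])
    g2 = float(np.exp(theta[idxs[pos + 2]]))
    g3 = float(np.exp(theta[idxs[pos + 3]]))
    slope = 0.0
    if not packing.flags.decisional_separability:
        slope = float(theta[idxs[pos + 4]])
    return kappa, b, (c1, c1 + g2, c1 + g2 + g3), slope


def _objective_factory(packing: _Packing, counts: np.ndarray, h: float = 1e-5):
    """(nll, gradient) with block-structured central differences.

    Every finite-difference evaluation is packed into one vectorized
    cell-probability call: global-parameter perturbations contribute full
    participant blocks, while each participant-local parameter perturbs only
    that participant's row (its parameters enter no other likelihood term).
    """
    n = packing.n
    n_glob = len(packing.global_idx)

    def fun(theta: np.ndarray):
        spec = packing.unpack(theta)
        base = _spec_param_arrays(spec)  # 5 arrays of shape (n, 3)

        mx_rows = [base[0]]
        my_rows = [base[1]]
        sx_rows = [base[2]]
        sy_rows = [base[3]]
        rho_rows = [base[4]]
        b_rows = [np.broadcast_to(spec.bounds[:, None], (n, 3)).copy()]
        cut_rows = [np.broadcast_to(spec.cuts[:, None, :], (n, 3, 3)).copy()]
        slope_rows = [np.broadcast_to(spec.slopes[:, None], (n, 3)).copy()]
        cnt_rows = [counts]
        steps = np.empty(packing.dim)

        # global perturbations: one full (n, 3) block per sign
        for j in packing.global_idx:
            step = h * max(1.0, abs(theta[j]))
            steps[j] = step
            for sgn in (+1.0, -1.0):
                tp = theta.copy()
                tp[j] += sgn * step
                sp = packing.unpack(tp)
                arr = _spec_param_arrays(sp)
                mx_rows.append(arr[0]); my_rows.append(arr[1])
                sx_rows.append(arr[2]); sy_rows.append(arr[3]); rho_rows.append(arr[4])
                b_rows.append(np.broadcast_to(sp.bounds[:, None], (n, 3)).copy())
                cut_rows.append(np.broadcast_to(sp.cuts[:, None, :], (n, 3, 3)).copy())
                slope_rows.append(np.broadcast_to(sp.slopes[:, None], (n, 3)).copy())
                cnt_rows.append(counts)

        # local perturbations: one single-participant row per sign
        class_mx = np.array([spec.means["square"][0], spec.means["diamond"][0], 0.0])
        class_my = np.array([spec.means["square"][1], spec.means["diamond"][1], 0.0])
        class_sx = np.array([spec.sds[s][0] for s in STIMULI])
        class_sy = np.array([spec.sds[s][1] for s in STIMULI])
        class_rho = np.array([spec.rhos[s] for s in STIMULI])
        present = np.array([1.0, 1.0, 0.0])
        kappa_set = set(packing.kappa_idx)
        loc_mx, loc_my, loc_b, loc_cut, loc_slope, loc_cnt = [], [], [], [], [], []
        loc_order: list[tuple[int, int]] = []  # (param index, rows per sign)
        for i, idxs in enumerate(packing.local_idx):
            for j in idxs:
                step = h * max(1.0, abs(theta[j]))
                steps[j] = step
                # a kappa parameter also moves participant 0's kappa
                # (geometric-mean anchor), so it touches two participants
                affected = [i, 0] if (j in kappa_set and i != 0) else [i]
                for sgn in (+1.0, -1.0):
                    tp = theta.copy()
                    tp[j] += sgn * step
                    for who in affected:
                        kap, b_i, cuts_i, slope_i = _local_values(packing, tp, who)
                        scale = present * kap + (1.0 - present)
                        loc_mx.append(scale * class_mx)
                        loc_my.append(scale * class_my)
                        loc_b.append(np.full(3, b_i))
                        loc_cut.append(np.tile(np.asarray(cuts_i), (3, 1)))
                        loc_slope.append(np.full(3, slope_i))
                        loc_cnt.append(counts[who])
                loc_order.append((j, len(affected)))
        n_loc = sum(2 * w for _, w in loc_order)
        if n_loc:
            mx_rows.append(np.array(loc_mx)); my_rows.append(np.array(loc_my))
            sx_rows.append(np.broadcast_to(class_sx, (n_loc, 3)).copy())
            sy_rows.append(np.broadcast_to(class_sy, (n_loc, 3)).copy())
            rho_rows.append(np.broadcast_to(class_rho, (n_loc, 3)).copy())
            b_rows.append(np.array(loc_b))
            cut_rows.append(np.array(loc_cut))
            slope_rows.append(np.array(loc_slope))
            cnt_rows.append(np.array(loc_cnt))

        MX = np.concatenate(mx_rows); MY = np.concatenate(my_rows)
        SX = np.concatenate(sx_rows); SY = np.concatenate(sy_rows)
        RHO = np.concatenate(rho_rows)
        B = np.concatenate(b_rows); CUT = np.concatenate(cut_rows)
        SL = np.concatenate(slope_rows); CNT = np.concatenate(cnt_rows)

        probs = np.maximum(_cell_probs(MX, MY, SX, SY, RHO, B, CUT, SL), _P_FLOOR)
        row_nll = -(CNT * np.log(probs)).sum(axis=(1, 2, 3))  # (R,)

        f0 = float(row_nll[:n].sum())
        g = np.zeros(packing.dim)
        pos = n
        for j in packing.global_idx:
            fp = row_nll[pos:pos + n].sum(); pos += n
            fm = row_nll[pos:pos + n].sum(); pos += n
            g[j] = (fp - fm) / (2.0 * steps[j])
        for j, width in loc_order:
            fp = row_nll[pos:pos + width].sum(); pos += width
            fm = row_nll[pos:pos + width].sum(); pos += width
            g[j] = (fp - fm) / (2.0 * steps[j])
        return f0, g

    return fun


def _moment_init(flags: GRTFlags, dataset: GRTDataset) -> GRTModelSpec:
    """Closed-form starting values from marginal response rates."""
    c = dataset.counts
    n = dataset.n_participants
    eps = 0.5

    def rate(x, total):
        return (x + eps) / (total + 2 * eps)

    tot = c.sum(axis=(2, 3))  # (n, 3)
    sq_resp = c[:, :, 0, :].sum(axis=2)  # (n, 3) square responses
    p_sq_absent = rate(sq_resp[:, 2], tot[:, 2])
    bounds = -ndtri_safe(p_sq_absent)

    pas_cum = np.cumsum(c.sum(axis=2), axis=2)  # (n, 3, 4) cumulative over pas
    with np.errstate(divide="ignore", invalid="ignore"):
        cum_rate = (pas_cum[:, :, :3] + eps) / (tot[:, :, None] + 2 * eps)
    cuts_abs = ndtri_safe(cum_rate[:, 2, :])  # from absent class
    cuts = np.sort(cuts_abs, axis=1)
    # enforce strict ordering
    for i in range(n):
        for k in (1, 2):
            if cuts[i, k] <= cuts[i, k - 1]:
                cuts[i, k] = cuts[i, k - 1] + 0.1

    p_sq_square = rate(sq_resp[:, 0], tot[:, 0])
    p_sq_diamond = rate(sq_resp[:, 1], tot[:, 1])
    mx_s = float(np.mean(bounds + ndtri_safe(p_sq_square)))
    mx_d = float(np.mean(bounds + ndtri_safe(p_sq_diamond)))
    p_aware = 1.0 - cum_rate[:, :2, 0]  # P(pas >= 2 | class), (n, 2)
    my_s = float(np.mean(cuts[:, 0] + ndtri_safe(p_aware[:, 0])))
    my_d = float(np.mean(cuts[:, 0] + ndtri_safe(p_aware[:, 1])))
    if flags.perceptual_separability:
        my_s = my_d = 0.5 * (my_s + my_d)
    return GRTModelSpec(
        flags=flags,
        means={
            "square": (mx_s, my_s),
            "diamond": (mx_d, my_d),
            "absent": (0.0, 0.0),
        },
        sds={lbl: (1.0, 1.0) for lbl in STIMULI},
        rhos={lbl: 0.0 for lbl in STIMULI},
        kappa=np.ones(n),
        bounds=np.clip(bounds, -3, 3),
        cuts=np.clip(cuts, -6, 6),
        slopes=np.zeros(n),
    )


def ndtri_safe(p):
    return ndtri(np.clip(p, 1e-4, 1 - 1e-4))


def fit_grt_wind(
    dataset: GRTDataset,
    flags: GRTFlags = FULL_MODEL,
    restarts: int = 10,
    rng: np.random.Generator | None = None,
    maxiter: int = 400,
    init: np.ndarray | None = None,
) -> GRTFitResult:
    """Maximum-likelihood fit of one model variant with multi-start.

    Catch trials are required: the absent class anchors the awareness
    dimension, without it the awareness means are unidentified.
    """
    if not dataset.has_catch:
        raise DegenerateInputError("dataset has no catch trials (absent class)")
    rng = rng if rng is not None else np.random.default_rng()
    packing = _Packing(flags, dataset.n_participants)
    objective = _objective_factory(packing, dataset.counts)
    theta0 = packing.pack(_moment_init(flags, dataset)) if init is None else np.asarray(init)
    theta0 = np.clip(theta0, packing.lower + 1e-6, packing.upper - 1e-6)

    best = None
    n_ok = 0
    for r in range(max(1, restarts)):
        start = theta0 if r == 0 else np.clip(
            theta0 + rng.normal(0.0, 0.15, packing.dim),
            packing.lower + 1e-6,
            packing.upper - 1e-6,
        )
        res = optimize.minimize(
            objective,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(packing.lower, packing.upper)),
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if np.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise ConvergenceError("all restarts failed")

    spec = packing.unpack(best.x)
    loglik = -float(best.fun)
    k = packing.dim
    probs = predict_all(spec)
    tot = dataset.counts.sum(axis=(2, 3))
    mask = tot > 0
    obs = np.where(
        mask[:, :, None, None], dataset.counts / np.maximum(tot, 1)[:, :, None, None], 0.0
    )
    mad = float(np.abs(obs - probs)[mask].mean())
    mean_obs = float(obs[mask].mean())
    return GRTFitResult(
        spec=spec,
        loglik=loglik,
        n_params=k,
        aic=2.0 * k - 2.0 * loglik,
        pct_accounted=100.0 * (1.0 - mad / mean_obs),
        mad_proportion=mad,
        convergence="converged" if n_ok else "failed",
        n_restarts=max(1, restarts),
        dataset_hash=dataset.content_hash(),
        theta=best.x,
        trial_counts=tot,
    )


def select_model(fits: list[GRTFitResult]) -> GRTFitResult:
    """Minimum-AIC fit; ties go to fewer parameters, then enumeration order."""
    if not fits:
        raise ValueError("no fits to select from")
    if len({f.dataset_hash for f in fits}) > 1:
        raise ValueError("fits come from different datasets")
    order = {flags: i for i, flags in enumerate(enumerate_models())}
    return min(fits, key=lambda f: (f.aic, f.n_params, order.get(f.spec.flags, 99)))
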