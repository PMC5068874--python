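"""Semi-Markov synthetic study generator.

Generates event logs with the statistical structure the analysis assumes: a
behavior jump chain with a known (calibratable) entropy rate, and
exponentially distributed bout durations with group-specific means, laid out
on the emulated study design — 4 cohorts x 2 dams per group per cohort, two
50-minute sessions per day for 8 days, light-phase observation for every
cohort and dark-phase observation for all but the last.

The control-like regime pairs a low-entropy jump chain (each behavior has a
dominant successor) with long bouts; the adversity-like (LBN) regime pairs a
higher-entropy chain with short bouts, so high unpredictability and high
fragmentation co-occur in the same animals, as in real impoverished-cage
dams.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, InputError, ParameterError
from .ethogram import Ethogram, default_ethogram
from .events import EventLog, Interval, Session
from .inference import cohort_adjusted_group_test
from .markov import entropy_rate, max_entropy_rate, stationary_distribution
from .summary import AnalysisOptions, summarize_study

#: Calibration targets (bits): group mean entropy rates of the emulated study.
DEFAULT_ENTROPY_CTL = 1.61
DEFAULT_ENTROPY_LBN = 1.81

#: Mean bout durations in seconds. Licking/grooming means reproduce the
#: emulated study's 105 s (control) vs 42 s (LBN); other behaviors default
#: to 120/60 s placeholders.
DEFAULT_MEAN_LICK_GROOM = {"CTL": 105.0, "LBN": 42.0}
DEFAULT_MEAN_OTHER = {"CTL": 120.0, "LBN": 60.0}


def default_base_matrix(k: int, dominant: float = 0.75) -> np.ndarray:
    """Cycle-dominant jump matrix used as the calibration base.

    Row ``i`` puts probability ``dominant`` on state ``i + 1 (mod k)`` and
    splits the rest uniformly over the other ``k - 2`` non-self states. The
    dominant successors form a single cycle, so the chain is irreducible;
    tempering the rows moves its entropy anywhere in ``(~0, log(k - 1))``.
    """
    if k < 3:
        raise ParameterError("base matrix needs k >= 3 states")
    if not 1.0 / (k - 1) < dominant < 1.0:
        raise ParameterError("dominant successor probability out of range")
    P = np.full((k, k), (1.0 - dominant) / (k - 2))
    np.fill_diagonal(P, 0.0)
    for i in range(k):
        P[i, (i + 1) % k] = dominant
    return P


def temper_matrix(base: np.ndarray, tau: float) -> np.ndarray:
    """Row-wise temperature transform ``p_ij^(1/tau)``, renormalized.

    ``tau = 1`` returns the base; ``tau -> inf`` flattens every row toward
    uniform (maximum entropy); ``tau -> 0`` sharpens toward the row's
    dominant successor (entropy -> 0 when the argmax is unique).
    """
    if tau <= 0:
        raise ParameterError(f"temperature must be > 0, got {tau}")
    P = np.asarray(base, dtype=float)
    off = ~np.eye(P.shape[0], dtype=bool)
    W = np.zeros_like(P)
    with np.errstate(divide="ignore"):
        W[off] = np.where(P[off] > 0, P[off] ** (1.0 / tau), 0.0)
    return W / W.sum(axis=1, keepdims=True)


def closed_form_entropy(P: np.ndarray, base: float = 2.0) -> float:
    """Exact entropy rate of a stochastic jump matrix (stationary weights)."""
    return entropy_rate(P, stationary_distribution(P), base=base)


def calibrate_matrix(
    base: np.ndarray,
    target_entropy: float,
    base_log: float = 2.0,
    tol: float = 1e-4,
    tau_bracket: tuple[float, float] = (1e-3, 1e4),
) -> tuple[np.ndarray, float]:
    """Find the temperature at which the tempered base hits a target entropy.

    Bisection on ``tau`` over ``tau_bracket``; entropy is monotone
    non-decreasing in ``tau`` for this family, which is verified on the
    bracket. Raises :class:`CalibrationError`, reporting the achievable
    interval, when the target lies outside it.
    """
    k = np.asarray(base).shape[0]
    lo, hi = tau_bracket
    h_lo = closed_form_entropy(temper_matrix(base, lo), base_log)
    h_hi = closed_form_entropy(temper_matrix(base, hi), base_log)
    if h_hi < h_lo:
        raise CalibrationError(
            "entropy is not increasing in temperature on this bracket"
        )
    if not h_lo - tol <= target_entropy <= h_hi + tol:
        raise CalibrationError(
            f"target {target_entropy:.4f} outside achievable entropy range "
            f"[{h_lo:.4f}, {h_hi:.4f}] (max possible {max_entropy_rate(k, base_log):.4f})",
            achievable=(h_lo, h_hi),
        )
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # bisect in log space: tau spans decades
        h_mid = closed_form_entropy(temper_matrix(base, mid), base_log)
        if abs(h_mid - target_entropy) <= tol:
            return temper_matrix(base, mid), mid
        if h_mid < target_entropy:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"calibration did not converge to {target_entropy} within 200 steps"
    )


# ---------------------------------------------------------------------------
# configuration

@dataclass
class GeneratorConfig:
    """Configuration of the synthetic study.

    Defaults reproduce the emulated observation design: 4 cohorts x 2 dams
    per group per cohort (16 dams), 8 days x two 50-min sessions per phase,
    light phase for all cohorts and dark phase for all but the last — i.e.
    8 dams per group with light-phase data and 6 per group with dark-phase
    data. Jump matrices are calibrated to group entropy targets of 1.61
    (CTL) and 1.81 (LBN) bits unless explicit matrices are given.
    """

    ethogram: Ethogram = field(default_factory=default_ethogram)
    entropy_ctl: float = DEFAULT_ENTROPY_CTL
    entropy_lbn: float = DEFAULT_ENTROPY_LBN
    entropy_base: float = 2.0
    p_ctl: np.ndarray | None = None
    p_lbn: np.ndarray | None = None
    duration_means: dict[str, dict[str, float]] | None = None
    duration_family: str = "exponential"      # exponential | gamma
    gamma_shape: float = 2.0
    n_days: int = 8
    sessions_per_day: int = 2
    session_length_s: int = 3000
    n_cohorts: int = 4
    dams_per_group_per_cohort: int = 2
    n_dark_cohorts: int = 3
    cohort_duration_factors: tuple[float, ...] | None = None
    gap_prob: float = 0.0                     # I/O robustness tests only
    max_gap_s: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.duration_means is None:
            self.duration_means = {
                g: {
                    b: (
                        DEFAULT_MEAN_LICK_GROOM[g]
                        if b == "lick_groom"
                        else DEFAULT_MEAN_OTHER[g]
                    )
                    for b in self.ethogram.labels
                }
                for g in ("CTL", "LBN")
            }
        if self.cohort_duration_factors is None:
            self.cohort_duration_factors = tuple([1.0] * self.n_cohorts)
        self._validate()

    def _validate(self):
        if min(self.n_days, self.sessions_per_day, self.n_cohorts,
               self.dams_per_group_per_cohort) < 1:
            raise ParameterError("schedule values must be >= 1")
        if self.session_length_s < 1:
            raise ParameterError("session_length_s must be >= 1 second")
        if not 0 <= self.n_dark_cohorts <= self.n_cohorts:
            raise ParameterError("n_dark_cohorts out of range")
        if len(self.cohort_duration_factors) != self.n_cohorts:
            raise ParameterError(
                "cohort_duration_factors must have one entry per cohort"
            )
        if self.duration_family not in ("exponential", "gamma"):
            raise ParameterError(
                f"unknown duration family {self.duration_family!r}"
            )
        for g, means in self.duration_means.items():
            for b, m in means.items():
                if b not in self.ethogram:
                    raise ParameterError(
                        f"duration mean for unknown behavior {b!r}"
                    )
                if m <= 0:
                    raise ParameterError(f"mean duration for {g}/{b} must be > 0")
        for P in (self.p_ctl, self.p_lbn):
            if P is not None:
                P = np.asarray(P, float)
                if P.shape != (self.ethogram.k,) * 2:
                    raise ParameterError("jump matrix shape mismatch")
                if np.abs(np.diag(P)).max() > 0:
                    raise ParameterError("jump matrix diagonal must be zero")
                if np.abs(P.sum(axis=1) - 1).max() > 1e-9:
                    raise ParameterError("jump matrix rows must sum to 1")

    def jump_matrices(self) -> dict[str, np.ndarray]:
        """Per-group jump matrices (calibrating to targets when not given)."""
        base = default_base_matrix(self.ethogram.k)
        out = {}
        for g, explicit, target in (
            ("CTL", self.p_ctl, self.entropy_ctl),
            ("LBN", self.p_lbn, self.entropy_lbn),
        ):
            if explicit is not None:
                out[g] = np.asarray(explicit, dtype=float)
            else:
                out[g], _ = calibrate_matrix(base, target, self.entropy_base)
        return out

    def null(self) -> "GeneratorConfig":
        """Fully null configuration: no group differences at all.

        Both groups get the CTL jump matrix and CTL duration means, so dams
        are exchangeable across group labels — the reference configuration
        for type-I-error checks.
        """
        P = self.jump_matrices()["CTL"]
        means = {g: dict(self.duration_means["CTL"]) for g in ("CTL", "LBN")}
        return replace(
            self, p_ctl=P.copy(), p_lbn=P.copy(), duration_means=means
        )

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise InputError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise InputError(f"config {path} must be a mapping")
        kwargs = dict(data)
        if "ethogram" in kwargs:
            kwargs["ethogram"] = Ethogram(tuple(kwargs["ethogram"]))
        for key in ("p_ctl", "p_lbn"):
            if kwargs.get(key) is not None:
                kwargs[key] = np.asarray(kwargs[key], dtype=float)
        if "cohort_duration_factors" in kwargs and kwargs[
            "cohort_duration_factors"
        ] is not None:
            kwargs["cohort_duration_factors"] = tuple(
                kwargs["cohort_duration_factors"]
            )
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**kwargs)
        except (TypeError, ParameterError) as exc:
            raise InputError(f"invalid config {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("ethogram", "p_ctl", "p_lbn")
        }
        data["ethogram"] = list(self.ethogram.labels)
        for key in ("p_ctl", "p_lbn"):
            val = getattr(self, key)
            data[key] = None if val is None else np.asarray(val).tolist()
        data["cohort_duration_factors"] = list(self.cohort_duration_factors)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# simulation

def dam_seed(master_seed: int, dam_id: str) -> int:
    """Stable per-dam seed (< 2^31) hashed from the master seed and dam id.

    Hash-derived streams make generation order irrelevant: any dam can be
    regenerated bit-identically in isolation.
    """
    digest = hashlib.sha256(f"{master_seed}:{dam_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _draw_duration(rng, mean: float, family: str, gamma_shape: float) -> int:
    if family == "gamma":
        x = rng.gamma(gamma_shape, mean / gamma_shape)
    else:
        x = rng.exponential(mean)
    return max(1, int(round(x)))


def simulate_session(
    P: np.ndarray,
    duration_sampler,
    session_length_s: int,
    rng: np.random.Generator,
    ethogram: Ethogram,
    session_id: str = "s1",
    phase: str = "light",
    day: int = 1,
) -> Session:
    """Simulate one observation window of the semi-Markov process.

    The initial behavior is drawn from the stationary distribution of ``P``;
    thereafter the process alternates a bout-duration draw (from
    ``duration_sampler(state_index, rng) -> seconds``) with a jump drawn
    from the state's row of ``P``. The final bout is truncated at the window
    end, so the session is fully tiled by scored intervals.
    """
    if session_length_s < 1:
        raise ParameterError("session length must be >= 1 second")
    P = np.asarray(P, dtype=float)
    cum = P.cumsum(axis=1)
    w = stationary_distribution(P)
    state = int(np.searchsorted(np.cumsum(w), rng.random()))
    t = 0
    intervals = []
    while t < session_length_s:
        dur = int(duration_sampler(state, rng))
        if dur < 1:
            raise ParameterError("duration sampler returned < 1 second")
        end = min(t + dur, session_length_s)
        intervals.append(Interval(t, end, ethogram.labels[state]))
        t = end
        state = int(np.searchsorted(cum[state], rng.random()))
    return Session(
        session_id=session_id,
        phase=phase,
        day=day,
        window_start=0,
        window_end=session_length_s,
        intervals=intervals,
    )


def _inject_gaps(session: Session, rng, gap_prob: float, max_gap_s: int) -> None:
    """Shorten random bouts from the end, leaving unscored gaps (tests only)."""
    new = []
    for iv in session.intervals:
        if iv.duration > max_gap_s + 1 and rng.random() < gap_prob:
            cut = 1 + int(rng.integers(max_gap_s))
            iv = Interval(iv.start, iv.end - cut, iv.behavior)
        new.append(iv)
    session.intervals = new


@dataclass
class StudyDataset:
    """A simulated study: one event log per dam plus a regeneration manifest."""

    logs: list[EventLog]
    manifest: pd.DataFrame
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.logs)


def _simulate_dam(
    config: GeneratorConfig,
    dam_id: str,
    group: str,
    cohort_index: int,
    P: np.ndarray,
    phases: tuple[str, ...],
) -> EventLog:
    seed = dam_seed(config.seed, dam_id)
    rng = np.random.default_rng(seed)
    factor = config.cohort_duration_factors[cohort_index]
    means = np.array(
        [config.duration_means[group][b] * factor for b in config.ethogram.labels]
    )

    def sampler(state, rng):
        return _draw_duration(
            rng, means[state], config.duration_family, config.gamma_shape
        )

    sessions = []
    for phase in phases:
        for day in range(1, config.n_days + 1):
            for s in range(1, config.sessions_per_day + 1):
                sess = simulate_session(
                    P,
                    sampler,
                    config.session_length_s,
                    rng,
                    config.ethogram,
                    session_id=f"{phase}_d{day:02d}_s{s}",
                    phase=phase,
                    day=day,
                )
                if config.gap_prob > 0:
                    _inject_gaps(sess, rng, config.gap_prob, config.max_gap_s)
                sessions.append(sess)
    return EventLog(
        dam_id=dam_id, group=group, cohort=f"cohort{cohort_index + 1}",
        sessions=sessions,
    )


def simulate_study(config: GeneratorConfig) -> StudyDataset:
    """Simulate the full cohort design.

    Under the default configuration this yields 16 dams (8 CTL + 8 LBN)
    with light-phase data, of which 6 per group also carry dark-phase data.
    Every dam gets an independent RNG stream derived from the master seed,
    recorded in the manifest.
    """
    matrices = config.jump_matrices()
    logs = []
    rows = []
    for ci in range(config.n_cohorts):
        has_dark = ci < config.n_dark_cohorts
        phases = ("light", "dark") if has_dark else ("light",)
        for group in ("CTL", "LBN"):
            for di in range(1, config.dams_per_group_per_cohort + 1):
                dam_id = f"c{ci + 1}_{group.lower()}_{di}"
                log = _simulate_dam(
                    config, dam_id, group, ci, matrices[group], phases
                )
                logs.append(log)
                rows.append(
                    {
                        "dam_id": dam_id,
                        "group": group,
                        "cohort": f"cohort{ci + 1}",
                        "phases": "+".join(phases),
                        "seed": dam_seed(config.seed, dam_id),
                    }
                )
    return StudyDataset(logs, pd.DataFrame(rows), config)


def regenerate_dam(config: GeneratorConfig, dam_id: str) -> EventLog:
    """Re-simulate a single dam bit-identically from the manifest metadata."""
    for ci in range(config.n_cohorts):
        has_dark = ci < config.n_dark_cohorts
        phases = ("light", "dark") if has_dark else ("light",)
        for group in ("CTL", "LBN"):
            for di in range(1, config.dams_per_group_per_cohort + 1):
                if f"c{ci + 1}_{group.lower()}_{di}" == dam_id:
                    P = config.jump_matrices()[group]
                    return _simulate_dam(config, dam_id, group, ci, P, phases)
    raise ParameterError(f"dam {dam_id!r} is not part of this design")


# ---------------------------------------------------------------------------
# power analysis

def power_analysis(
    config: GeneratorConfig,
    effects,
    n_reps: int = 200,
    alpha: float = 0.05,
    measure: str = "entropy_rate",
    phase: str = "light",
    options: AnalysisOptions | None = None,
) -> pd.DataFrame:
    """Monte-Carlo power of the cohort-adjusted group test.

    For each entropy-gap ``effect`` (bits), the LBN chain is recalibrated to
    the CTL target plus the effect; ``n_reps`` studies are simulated and
    analyzed end to end, and the rejection rate of the group test at level
    ``alpha`` is recorded with its Monte-Carlo standard error. The
    ``effect = 0`` row estimates the type-I error under the configured
    (possibly duration-asymmetric) design.
    """
    if n_reps < 2:
        raise ParameterError("n_reps must be >= 2")
    base = default_base_matrix(config.ethogram.k)
    options = options or AnalysisOptions()
    rows = []
    for ei, effect in enumerate(effects):
        P_lbn, _ = calibrate_matrix(
            base, config.entropy_ctl + effect, config.entropy_base
        )
        P_ctl, _ = calibrate_matrix(base, config.entropy_ctl, config.entropy_base)
        cfg = replace(config, p_ctl=P_ctl, p_lbn=P_lbn)
        rejections = 0
        for rep in range(n_reps):
            rep_cfg = replace(
                cfg, seed=(config.seed + 100_003 * ei + rep) % (2**31)
            )
            dataset = simulate_study(rep_cfg)
            table = summarize_study(
                dataset.logs, config.ethogram, options, phases=(phase,)
            )
            res = cohort_adjusted_group_test(
                table[measure], table["group"], table["cohort"], measure=measure
            )
            rejections += res.p < alpha
        power = rejections / n_reps
        rows.append(
            {
                "effect": effect,
                "power": power,
                "mcse": float(np.sqrt(power * (1 - power) / n_reps)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
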