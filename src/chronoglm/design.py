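"""Trial schedules, hemodynamic regressors, and the model space of design matrices.

The model space encodes a 2 x 2 factorial of signal models for a cued
reaction-time task with brief emotional distractor images: events are
time-locked either to the distractor image onset (early processes) or to the
motor response (late processes), and each locking optionally carries a
mean-free parametric reaction-time (RT) modulator.  The four resulting models
correspond to distractor perception, salience attribution, task execution and
RT-modulated task execution; an eight-model variant adds first-order temporal
derivatives to absorb hemodynamic-latency differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRIANGLE_DELAY_S",
    "TrialTable",
    "HRFSpec",
    "ModelSpec",
    "DesignMatrix",
    "canonical_hrf",
    "build_event_regressor",
    "dct_highpass_basis",
    "build_model_space",
    "build_design_matrix",
]

#: Delay between distractor-image onset and the response-cue (triangle) onset.
#: Reaction times are measured from the triangle; responses therefore occur at
#: ``onset + TRIANGLE_DELAY_S + rt``.
TRIANGLE_DELAY_S = 0.200

MODEL_NAMES = (
    "DistractorPerception",
    "SalienceAttribution",
    "TaskExecution",
    "ModulatedTaskExecution",
)

CONDITIONS = ("negative", "neutral", "positive")


@dataclass
class TrialTable:
    """Per-trial timing and behaviour for one task run.

    Onsets are seconds from the first volume (0-based).  ``rt_s`` is NaN for
    trials without a (correct) response.
    """

    onset_s: np.ndarray
    rt_s: np.ndarray
    condition: np.ndarray
    correct: np.ndarray
    isi_s: np.ndarray

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.rt_s = np.asarray(self.rt_s, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.correct = np.asarray(self.correct, dtype=bool)
        self.isi_s = np.asarray(self.isi_s, dtype=float)
        n = self.onset_s.size
        for name in ("rt_s", "condition", "correct", "isi_s"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name!r} has length != {n}")
        if n and np.any(np.diff(self.onset_s) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        bad_rt = self.correct & ~(self.rt_s > 0)
        if np.any(bad_rt):
            raise ValueError(
                f"{bad_rt.sum()} correct trials have non-positive or missing RT"
            )

    @property
    def n_trials(self) -> int:
        return self.onset_s.size

    @property
    def response_s(self) -> np.ndarray:
        """Motor-response times from run start (NaN where no response)."""
        return self.onset_s + TRIANGLE_DELAY_S + self.rt_s

    @property
    def trial_index(self) -> np.ndarray:
        return np.arange(self.n_trials)

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset/duration/trial_type/...)."""
        return pd.DataFrame(
            {
                "onset": self.onset_s,
                "duration": np.zeros(self.n_trials),
                "trial_type": self.condition,
                "response_time": self.rt_s,
                "correct": self.correct.astype(int),
                "isi": self.isi_s,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        required = {"onset", "trial_type", "response_time", "correct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"events table missing columns: {sorted(missing)}")
        isi = df["isi"].to_numpy(float) if "isi" in df else np.r_[
            np.diff(df["onset"].to_numpy(float)), np.nan
        ]
        return cls(
            onset_s=df["onset"].to_numpy(float),
            rt_s=df["response_time"].to_numpy(float),
            condition=df["trial_type"].to_numpy(object),
            correct=df["correct"].to_numpy().astype(bool),
            isi_s=isi,
        )

    def __eq__(self, other: object) -> bool:  # round-trip friendly
        if not isinstance(other, TrialTable):
            return NotImplemented
        return (
            np.allclose(self.onset_s, other.onset_s)
            and np.allclose(self.rt_s, other.rt_s, equal_nan=True)
            and np.array_equal(self.condition, other.condition)
            and np.array_equal(self.correct, other.correct)
            and np.allclose(self.isi_s, other.isi_s, equal_nan=True)
        )


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response function parameters.

    The kernel is the difference of two gamma densities: a positive response
    peaking at ``peak_delay_s`` and an undershoot peaking at
    ``undershoot_delay_s`` scaled down by ``peak_undershoot_ratio``.
    ``onset_s`` shifts the whole kernel later in time (hemodynamic latency).
    """

    kind: str = "canonical_double_gamma"
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    onset_s: float = 0.0
    duration_s: float = 32.0
    microtime_dt_s: float | None = None

    def with_onset(self, onset_s: float) -> "HRFSpec":
        return replace(self, onset_s=onset_s)


@dataclass(frozen=True)
class ModelSpec:
    """One member of the model space."""

    model_id: int
    locking: str  # {"stimulus_onset", "motor_response"}
    rt_modulated: bool
    with_derivative: bool
    name: str


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with per-column role metadata."""

    values: np.ndarray
    regressor_names: list[str]
    regressor_roles: list[str]
    TR_s: float

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]

    def columns_with_role(self, role: str) -> np.ndarray:
        idx = [i for i, r in enumerate(self.regressor_roles) if r == role]
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.regressor_names)


def canonical_hrf(spec: HRFSpec) -> np.ndarray:
    """Sample the canonical double-gamma HRF on the microtime grid.

    Returns kernel values at ``t = 0, dt, ..., duration_s`` with the peak
    normalised to 1 (the scale cancels in model comparison because the
    regression weights absorb it).
    """
    if spec.microtime_dt_s is None or spec.microtime_dt_s <= 0:
        raise ValueError("HRFSpec.microtime_dt_s must be a positive time step")
    if spec.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    for par in ("peak_delay_s", "undershoot_delay_s",
                "peak_dispersion", "undershoot_dispersion"):
        if getattr(spec, par) <= 0:
            raise ValueError(f"{par} must be positive")
    dt = spec.microtime_dt_s
    t = np.arange(0.0, spec.duration_s + dt / 2, dt)
    u = t - spec.onset_s
    peak = stats.gamma.pdf(u, a=spec.peak_delay_s / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(u, a=spec.undershoot_delay_s / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = np.where(u >= 0, peak - under / spec.peak_undershoot_ratio, 0.0)
    peak_val = np.max(np.abs(h))
    if peak_val > 0:
        h = h / np.max(h)
    return h


def _microtime_signal(
    events: Sequence[tuple[float, float]],
    n_scans: int,
    TR_s: float,
    kernel: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Stick function convolved with the kernel, on the microtime grid."""
    run_end = n_scans * TR_s
    n_micro = int(np.ceil(run_end / dt))
    sticks = np.zeros(n_micro)
    for t_ev, amp in events:
        if not (0 <= t_ev <= run_end):
            raise ValueError(f"event at {t_ev:.3f} s is outside the run [0, {run_end:.3f}]")
        idx = int(round(t_ev / dt))
        if idx >= n_micro:
            idx = n_micro - 1
        sticks[idx] += amp
    return np.convolve(sticks, kernel)[:n_micro]


def _scan_sample_indices(n_scans: int, TR_s: float, dt: float) -> np.ndarray:
    # sample at the middle of each TR (reference slice at TR/2)
    times = (np.arange(n_scans) + 0.5) * TR_s
    return np.round(times / dt).astype(int)


#: Step of the temporal-derivative finite difference, seconds.  The 1 s
#: secant (rather than an instantaneous derivative) is the convention for
#: canonical-HRF temporal derivatives: the span of {HRF, derivative} then
#: absorbs hemodynamic onset shifts up to about one second.
DERIVATIVE_STEP_S = 1.0


def build_event_regressor(
    events: Sequence[tuple[float, float]],
    n_scans: int,
    TR_s: float,
    hrf_kernel: np.ndarray,
    dt: float,
    derivative: bool = False,
    derivative_step_s: float = DERIVATIVE_STEP_S,
) -> np.ndarray:
    """Convolve impulse events with an HRF kernel and sample at scan times.

    Impulses (delta sticks with the given amplitudes) are placed on the
    microtime grid of step ``dt``, convolved with ``hrf_kernel`` (sampled at
    the same ``dt``), and the result is read out at the middle of each TR.
    Linear in the amplitudes.  With ``derivative=True`` the first-order
    temporal finite difference ``(s(t) - s(t - step)) / step`` of the
    convolved microtime signal is sampled instead.
    """
    if len(events) == 0:
        return np.zeros(n_scans)
    sig = _microtime_signal(events, n_scans, TR_s, hrf_kernel, dt)
    if derivative:
        shift = max(1, int(round(derivative_step_s / dt)))
        lagged = np.r_[np.zeros(shift), sig[:-shift]]
        sig = (sig - lagged) / (shift * dt)
    idx = _scan_sample_indices(n_scans, TR_s, dt)
    idx = np.clip(idx, 0, sig.size - 1)
    return sig[idx]


def dct_highpass_basis(n_scans: int, TR_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Orthonormal discrete-cosine drift basis (constant term excluded).

    The number of regressors is ``K = floor(2 * n_scans * TR_s / cutoff_s)``,
    the standard choice for a high-pass filter with period ``cutoff_s``.
    Returns an ``n_scans x K`` matrix; K = 0 (with a warning) when the run is
    shorter than the cutoff period.
    """
    if n_scans < 1 or TR_s <= 0 or cutoff_s <= 0:
        raise ValueError("n_scans, TR_s and cutoff_s must be positive")
    duration = n_scans * TR_s
    K = int(np.floor(2.0 * duration / cutoff_s))
    if duration <= cutoff_s:
        warnings.warn(
            f"run duration {duration:.1f} s does not exceed high-pass cutoff "
            f"{cutoff_s:.1f} s; drift basis is empty", stacklevel=2)
    K = min(K, n_scans - 1)
    if K <= 0:
        return np.zeros((n_scans, 0))
    n = np.arange(n_scans)
    k = np.arange(1, K + 1)
    basis = np.sqrt(2.0 / n_scans) * np.cos(
        np.pi * np.outer(2 * n + 1, k) / (2.0 * n_scans)
    )
    return basis


def build_model_space(with_derivatives: bool = False) -> list[ModelSpec]:
    """The ordered model space: 4 base models, or 8 with derivative variants.

    Fixed order: DistractorPerception (stimulus-locked), SalienceAttribution
    (stimulus-locked, RT-modulated), TaskExecution (response-locked),
    ModulatedTaskExecution (response-locked, RT-modulated); derivative
    variants, when requested, follow the four base models in the same order.
    """
    base = []
    combos = [
        ("stimulus_onset", False),
        ("stimulus_onset", True),
        ("motor_response", False),
        ("motor_response", True),
    ]
    for i, ((locking, rt_mod), name) in enumerate(zip(combos, MODEL_NAMES), start=1):
        base.append(ModelSpec(i, locking, rt_mod, False, name))
    if not with_derivatives:
        return base
    deriv = [
        ModelSpec(m.model_id + 4, m.locking, m.rt_modulated, True, m.name + "_deriv")
        for m in base
    ]
    return base + deriv


def build_design_matrix(
    trials: TrialTable,
    model: ModelSpec,
    hrf: HRFSpec | None = None,
    motion: np.ndarray | None = None,
    TR_s: float = 0.756,
    n_scans: int | None = None,
    hp_cutoff_s: float = 128.0,
    pool_errors: bool = True,
) -> DesignMatrix:
    """Assemble the design matrix for one model of the space.

    Task events use correct trials only, locked to the distractor onset or the
    motor response according to ``model.locking``, with unit amplitude.  RT
    modulation adds a column with mean-free amplitudes ``rt_i - mean(rt)`` at
    the same event times ("mean-free" before convolution).  Missed/incorrect
    trials are pooled into one nuisance column (or one per event when
    ``pool_errors=False``).  Six motion columns enter unconvolved, followed by
    the discrete-cosine drift basis and a constant.
    """
    if n_scans is None:
        raise ValueError("n_scans is required")
    if hrf is None:
        hrf = HRFSpec()
    dt = hrf.microtime_dt_s if hrf.microtime_dt_s is not None else TR_s / 16.0
    if dt > TR_s / 8.0 + 1e-12:
        raise ValueError("microtime step must be at most TR/8")
    hrf = replace(hrf, microtime_dt_s=dt)
    kernel = canonical_hrf(hrf)

    correct = trials.correct
    if not np.any(correct):
        raise ValueError("no correct trials: task event set is empty")
    if model.locking == "stimulus_onset":
        task_times = trials.onset_s[correct]
    elif model.locking == "motor_response":
        task_times = trials.response_s[correct]
    else:
        raise ValueError(f"unknown locking {model.locking!r}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    roles: list[str] = []

    def add(col: np.ndarray, name: str, role: str) -> None:
        cols.append(col)
        names.append(name)
        roles.append(role)

    task_events = [(t, 1.0) for t in task_times]
    add(build_event_regressor(task_events, n_scans, TR_s, kernel, dt),
        "task", "task_event")

    mod_events: list[tuple[float, float]] = []
    if model.rt_modulated:
        rts = trials.rt_s[correct]
        if np.unique(rts).size < 2:
            raise ValueError("RT modulation requires >=2 correct trials with distinct RTs")
        amps = rts - rts.mean()
        mod_events = list(zip(task_times, amps))
        add(build_event_regressor(mod_events, n_scans, TR_s, kernel, dt),
            "task_xrt", "rt_modulator")

    if model.with_derivative:
        add(build_event_regressor(task_events, n_scans, TR_s, kernel, dt,
                                  derivative=True),
            "task_derivative", "derivative")
        if model.rt_modulated:
            add(build_event_regressor(mod_events, n_scans, TR_s, kernel, dt,
                                      derivative=True),
                "task_xrt_derivative", "derivative")

    bad = ~correct
    if np.any(bad):
        bad_onsets = trials.onset_s[bad]
        if pool_errors:
            ev = [(t, 1.0) for t in bad_onsets]
            add(build_event_regressor(ev, n_scans, TR_s, kernel, dt),
                "error_trials", "nuisance_event")
        else:
            for j, t in enumerate(bad_onsets):
                add(build_event_regressor([(t, 1.0)], n_scans, TR_s, kernel, dt),
                    f"error_trial_{j}", "nuisance_event")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_scans, 6):
            raise ValueError(f"motion must be (n_scans, 6), got {motion.shape}")
        for j in range(6):
            add(motion[:, j], f"motion_{j}", "motion")

    drift = dct_highpass_basis(n_scans, TR_s, hp_cutoff_s) if hp_cutoff_s else \
        np.zeros((n_scans, 0))
    for j in range(drift.shape[1]):
        add(drift[:, j], f"drift_{j + 1}", "drift")

    add(np.ones(n_scans), "constant", "constant")

    keep = []
    for i, col in enumerate(cols):
        if np.allclose(col, 0):
            warnings.warn(f"dropping all-zero regressor {names[i]!r}", stacklevel=2)
        else:
            keep.append(i)
    values = np.column_stack([cols[i] for i in keep])
    return DesignMatrix(values=values,
                        regressor_names=[names[i] for i in keep],
                        regressor_roles=[roles[i] for i in keep],
                        TR_s=TR_s)
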