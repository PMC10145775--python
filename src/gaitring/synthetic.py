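"""Synthetic annotated IMU recordings emulating the semi-controlled lap protocol.

The protocol alternates walking bouts (W1..W5) with end-of-lap activities
(A1..A5) over exactly six minutes.  A1/A2 are *non-sedentary* activities
(door opening with a 90-degree turn, short stairs) — movement that is not
walking; A3/A4/A5 are *sedentary* (leaning, standing still, sitting still).

The gait waveform is a harmonic series at the step frequency plus a
stride-frequency (half-cadence) admixture that breaks left/right step
symmetry.  This keeps the generator analytically checkable: the craniocaudal
spectrum has lines at multiples of the cadence, and each generator knob maps
monotonically onto one of the downstream gait criteria —

=================  ==================================  ====================
knob               what it perturbs                    paired criterion
=================  ==================================  ====================
amp_ml             mediolateral sway amplitude          RMSR_ML (stability)
amp_ap             anteroposterior push-off amplitude   RMSR_AP (sturdiness)
asymmetry_delta    stride-periodic admixture            P1CC (symmetry)
timing_jitter_sd   step-to-step period noise            P2CC (steadiness)
=================  ==================================  ====================

Turns at walking-bout boundaries are modeled as 1 s Gaussian-envelope
pulses on the craniocaudal angular velocity; they are the hard transitions
for the segmentation stage, so the simulator must produce them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import CHANNELS, ImuRecording

#: protocol regime identifiers -> activity class (lap-protocol annotation)
REGIME_TYPES = {
    "W1": "walking",
    "W2": "walking",
    "W3": "walking",
    "W4": "walking",
    "W5": "walking",
    "A1": "non_sedentary",  # door opening + 90-degree turn
    "A2": "non_sedentary",  # three stairs up, U-turn, three stairs down
    "A3": "sedentary",      # leaning
    "A4": "sedentary",      # standing still
    "A5": "sedentary",      # sitting still
}

#: one lap of the default protocol: (regime id, duration in seconds)
DEFAULT_SEQUENCE = (
    ("W1", 60.0),
    ("A1", 15.0),
    ("W2", 45.0),
    ("W3", 45.0),
    ("A2", 25.0),
    ("A3", 20.0),
    ("A4", 20.0),
    ("A5", 30.0),
    ("W4", 50.0),
    ("W5", 50.0),
)

CROSSFADE_S = 0.1
_GYR_STEP_AMP = 12.0   # dps, rhythmic trunk yaw during gait
_GYR_NOISE_SCALE = 25.0  # gyro white noise = noise_sd * this (g -> dps)
_TURN_AMP_DPS = 25.0
_TURN_SIGMA_S = 0.25


@dataclass(frozen=True)
class GaitKnobs:
    """Generator parameters controlling gait quality.

    Amplitudes are accelerations in g; ``asymmetry_delta`` is the relative
    amplitude of the stride-frequency admixture on the craniocaudal channel;
    ``timing_jitter_sd`` is the SD of the step-period noise in seconds.
    """

    step_freq_hz: float = 1.9
    amp_cc: float = 0.30
    amp_ap: float = 0.20
    amp_ml: float = 0.12
    asymmetry_delta: float = 0.05
    timing_jitter_sd: float = 0.010
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 1.2 <= self.step_freq_hz <= 2.5:
            raise ValueError("step_freq_hz must lie in [1.2, 2.5]")
        for name in ("amp_cc", "amp_ap", "amp_ml", "noise_sd", "timing_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.asymmetry_delta <= 1.0:
            raise ValueError("asymmetry_delta must lie in [0, 1]")


@dataclass(frozen=True)
class ProtocolConfig:
    """Regime sequence and timing of one recording session."""

    regime_sequence: tuple = DEFAULT_SEQUENCE
    total_duration_s: float = 360.0
    sampling_rate_hz: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regime_sequence:
            raise ValueError("regime_sequence is empty")
        for rid, dur in self.regime_sequence:
            if rid not in REGIME_TYPES:
                raise ValueError(f"unknown regime id {rid!r}")
            if dur <= 0:
                raise ValueError("regime durations must be positive")
        total = sum(d for _, d in self.regime_sequence)
        if abs(total - self.total_duration_s) > 1e-9:
            raise ValueError(
                f"regime durations sum to {total} s, expected {self.total_duration_s} s"
            )


@dataclass
class AnnotatedRecording:
    """A recording plus its ground-truth segmentation and regime labels."""

    recording: ImuRecording
    true_changepoints_s: np.ndarray
    regime_labels: list
    regime_ids: list = field(default_factory=list)
    subject_id: str = ""
    healthy: bool = True

    def __post_init__(self) -> None:
        cps = np.asarray(self.true_changepoints_s, dtype=float)
        if np.any(np.diff(cps) <= 0):
            raise ValueError("changepoints must be strictly increasing")
        if len(cps) and (cps[0] <= 0 or cps[-1] >= self.recording.duration_s):
            raise ValueError("changepoints must be interior to the recording")
        if len(self.regime_labels) != len(cps) + 1:
            raise ValueError("need exactly one label per regime (changepoints + 1)")
        self.true_changepoints_s = cps


def _stride_phase(duration_s: float, rate: float, step_freq: float,
                  jitter_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stride phase (pi per step) as a continuous piecewise-linear function.

    Step periods are 1/step_freq plus Gaussian noise; the phase advances by
    pi over each step, so cos(2*phase) is the step-frequency fundamental and
    cos(phase) the stride-frequency (half-cadence) line.
    """
    mean_period = 1.0 / step_freq
    n_steps = int(np.ceil(duration_s / mean_period)) + 3
    periods = mean_period + jitter_sd * rng.standard_normal(n_steps)
    periods = np.clip(periods, 0.3 * mean_period, 3.0 * mean_period)
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    while bounds[-1] < duration_s:
        bounds = np.append(bounds, bounds[-1] + mean_period)
    t = np.arange(int(round(duration_s * rate))) / rate
    return np.interp(t, bounds, np.pi * np.arange(len(bounds)))


def generate_walking_segment(
    knobs: GaitKnobs, duration_s: float, rate: float, rng: np.random.Generator
) -> dict:
    """One walking bout as a dict of the six channel arrays.

    The craniocaudal acceleration is a 3-harmonic series at the step
    frequency plus the stride-frequency asymmetry admixture; mediolateral
    sway oscillates at the stride frequency; anteroposterior at the step
    frequency.  White sensor noise is added on every channel.
    """
    if duration_s < 3.0:
        raise ValueError("walking segments must last at least 3 s (one STFT window)")
    phi = _stride_phase(duration_s, rate, knobs.step_freq_hz, knobs.timing_jitter_sd, rng)
    n = len(phi)
    acc_cc = knobs.amp_cc * (
        np.cos(2 * phi) + 0.35 * np.cos(4 * phi) + 0.15 * np.cos(6 * phi)
    ) + knobs.asymmetry_delta * knobs.amp_cc * np.cos(phi)
    acc_ap = knobs.amp_ap * (np.cos(2 * phi + 0.7) + 0.25 * np.cos(4 * phi + 0.3))
    acc_ml = knobs.amp_ml * np.cos(phi + 0.4)
    gyr_cc = _GYR_STEP_AMP * np.cos(2 * phi + 1.1)
    gyr_ml = 0.5 * _GYR_STEP_AMP * np.cos(2 * phi + 2.0)
    gyr_ap = 0.4 * _GYR_STEP_AMP * np.cos(phi + 0.9)
    out = {
        "acc_cc": acc_cc, "acc_ml": acc_ml, "acc_ap": acc_ap,
        "gyr_cc": gyr_cc, "gyr_ml": gyr_ml, "gyr_ap": gyr_ap,
    }
    if knobs.noise_sd > 0:
        for c in CHANNELS:
            scale = knobs.noise_sd * (_GYR_NOISE_SCALE if c.startswith("gyr") else 1.0)
            out[c] = out[c] + scale * rng.standard_normal(n)
    return out


def _smooth_envelope(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Random non-negative smooth envelope (sum of Gaussian bumps)."""
    t = np.arange(n) / rate
    env = np.zeros(n)
    n_bumps = max(1, int(round(n / rate / 2.5)))
    for _ in range(n_bumps):
        c = rng.uniform(0, n / rate)
        w = rng.uniform(0.4, 1.2)
        a = rng.uniform(0.5, 1.0)
        env += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return env / max(env.max(), 1e-12)


def generate_activity_segment(
    kind: str, duration_s: float, rate: float, rng: np.random.Generator,
    entry_burst: bool = False,
) -> dict:
    """A non-walking block: sedentary (still) or non-sedentary (moving).

    Sedentary blocks are low-variance sensor noise over a slow postural
    drift.  Non-sedentary blocks are broadband bursts — white noise under
    random smooth envelopes — whose energy overlaps the gait band but
    carries no sustained periodicity.  With ``entry_burst`` a short,
    smoothly decaying movement burst marks the start of the block: changing
    posture (sitting down, leaning in) is itself a movement, and it is what
    makes activity-to-activity transitions annotatable at all.
    """
    if duration_s < 1.0:
        raise ValueError("activity segments must last at least 1 s")
    if kind not in ("sedentary", "non_sedentary"):
        raise ValueError(f"unknown activity kind {kind!r}")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    out = {}
    if kind == "sedentary":
        for c in CHANNELS:
            scale = 1.0 if c.startswith("acc") else _GYR_NOISE_SCALE
            drift = 0.008 * scale * np.sin(
                2 * np.pi * rng.uniform(0.05, 0.2) * t + rng.uniform(0, 2 * np.pi)
            )
            out[c] = drift + 0.006 * scale * rng.standard_normal(n)
        if entry_burst:
            # posture change: strong trunk rotation, moderate acceleration
            env = np.exp(-0.5 * (t / 1.0) ** 2)
            for c in CHANNELS:
                amp = 0.10 if c.startswith("acc") else 60.0
                out[c] = out[c] + amp * env * rng.standard_normal(n)
    else:
        for c in CHANNELS:
            # door opening / stairs: sustained body rotation, moderate acc
            amp = 0.10 if c.startswith("acc") else 45.0
            floor = 0.01 if c.startswith("acc") else 3.0
            env = _smooth_envelope(n, rate, rng)
            out[c] = amp * env * rng.standard_normal(n) + floor * rng.standard_normal(n)
    return out


def _turn_pulse(n: int, rate: float, center_s: float) -> np.ndarray:
    t = np.arange(n) / rate
    return _TURN_AMP_DPS * np.exp(-0.5 * ((t - center_s) / _TURN_SIGMA_S) ** 2)


def generate_protocol(config: ProtocolConfig, knobs: GaitKnobs) -> AnnotatedRecording:
    """Assemble one full annotated protocol recording.

    Per-regime blocks are concatenated with 0.1 s linear cross-fades; the
    ground-truth change point sits at each fade midpoint.  Every walking
    bout gets a small deterministic cadence/amplitude variation (subjects do
    not walk identically on every lap) and turn pulses near its ends.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    durs = [d for _, d in config.regime_sequence]
    n_total = int(round(config.total_duration_s * fs))
    starts = np.concatenate([[0.0], np.cumsum(durs)])
    fade = int(round(CROSSFADE_S * fs))
    half = fade // 2
    sig = {c: np.zeros(n_total) for c in CHANNELS}
    weight = np.zeros(n_total)
    n_regimes = len(config.regime_sequence)
    for k, (rid, dur) in enumerate(config.regime_sequence):
        rtype = REGIME_TYPES[rid]
        if rtype == "walking":
            f = float(np.clip(knobs.step_freq_hz + rng.uniform(-0.25, 0.25), 1.2, 2.5))
            scale = rng.uniform(0.85, 1.15)
            local = replace(
                knobs, step_freq_hz=f,
                amp_cc=knobs.amp_cc * scale, amp_ap=knobs.amp_ap * scale,
                amp_ml=knobs.amp_ml * scale,
            )
        s = int(round(starts[k] * fs))
        e = int(round(starts[k + 1] * fs))
        ext_l = half if k > 0 else 0
        ext_r = half if k < n_regimes - 1 else 0
        block_dur = (e + ext_r - (s - ext_l)) / fs
        if rtype == "walking":
            block = generate_walking_segment(local, block_dur, fs, rng)
            nb = len(block["acc_cc"])
            # lap-corner turn where one walking bout follows another
            prev_walking = k > 0 and REGIME_TYPES[config.regime_sequence[k - 1][0]] == "walking"
            if prev_walking:
                block["gyr_cc"] = block["gyr_cc"] + _turn_pulse(nb, fs, 0.7)
        else:
            block = generate_activity_segment(rtype, block_dur, fs, rng, entry_burst=True)
            nb = len(block["acc_cc"])
        w = np.ones(nb)
        if ext_l:
            w[:fade] = (np.arange(fade) + 0.5) / fade
        if ext_r:
            w[-fade:] = 1.0 - (np.arange(fade) + 0.5) / fade
        lo = s - ext_l
        hi = min(lo + nb, n_total)
        for c in CHANNELS:
            sig[c][lo:hi] += (w * block[c])[: hi - lo]
        weight[lo:hi] += w[: hi - lo]
    rec = ImuRecording(sampling_rate_hz=fs, **sig)
    return AnnotatedRecording(
        recording=rec,
        true_changepoints_s=starts[1:-1].copy(),
        regime_labels=[REGIME_TYPES[rid] for rid, _ in config.regime_sequence],
        regime_ids=[rid for rid, _ in config.regime_sequence],
    )


#: degradation applied to one knob for each pathological subtype
PATHOLOGY_SUBTYPES = {
    "stability": {"amp_ml": 2.5},        # multiplier on the healthy draw
    "sturdiness": {"amp_ap": 0.35},
    "symmetry": {"asymmetry_delta": None},  # resampled, see _degrade
    "steadiness": {"timing_jitter_sd": None},
}

_HEALTHY_DRAWS = {
    # knob: (mean, sd) for healthy subjects; asymmetry/jitter drawn uniform
    "step_freq_hz": (1.9, 0.10),
    "amp_cc": (0.30, 0.03),
    "amp_ap": (0.20, 0.02),
    "amp_ml": (0.12, 0.015),
}


@dataclass
class Subject:
    recording: AnnotatedRecording
    healthy: bool
    subtype: str | None
    knobs: GaitKnobs
    subject_id: str


def _draw_healthy_knobs(rng: np.random.Generator, draws: dict) -> GaitKnobs:
    kw = {}
    for name, (mu, sd) in draws.items():
        kw[name] = float(np.clip(mu + sd * rng.standard_normal(), 1e-3, None))
    kw["step_freq_hz"] = float(np.clip(kw["step_freq_hz"], 1.5, 2.3))
    kw["asymmetry_delta"] = float(rng.uniform(0.0, 0.10))
    kw["timing_jitter_sd"] = float(rng.uniform(0.005, 0.015))
    return GaitKnobs(**kw)


def _degrade(knobs: GaitKnobs, subtype: str, rng: np.random.Generator) -> GaitKnobs:
    # degradations anchor on the healthy population mean so the documented
    # bounds (e.g. amp_ml >= 2x healthy mean) hold for every draw
    if subtype == "stability":
        return replace(knobs, amp_ml=_HEALTHY_DRAWS["amp_ml"][0] * rng.uniform(2.5, 3.5))
    if subtype == "sturdiness":
        return replace(knobs, amp_ap=_HEALTHY_DRAWS["amp_ap"][0] * rng.uniform(0.25, 0.40))
    if subtype == "symmetry":
        return replace(knobs, asymmetry_delta=float(rng.uniform(0.40, 0.60)))
    if subtype == "steadiness":
        return replace(knobs, timing_jitter_sd=float(rng.uniform(0.045, 0.065)))
    raise ValueError(f"unknown pathology subtype {subtype!r}")


def generate_cohort(
    n_subjects: int,
    knob_distributions: dict | None = None,
    seed: int = 0,
    healthy_fraction: float = 0.7,
    subtypes: tuple = ("stability", "symmetry", "steadiness", "sturdiness"),
) -> list:
    """Simulate a cohort of annotated recordings with per-subject health flags.

    ``healthy_fraction`` of the subjects draw knobs near the healthy
    defaults; the rest cycle through the pathology subtypes, each degrading
    the knob paired with one gait criterion.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    draws = dict(_HEALTHY_DRAWS)
    if knob_distributions:
        for name, ms in knob_distributions.items():
            if name not in draws:
                raise ValueError(f"unknown knob {name!r}")
            mu, sd = ms
            if sd < 0 or not np.isfinite(mu) or not np.isfinite(sd):
                raise ValueError(f"degenerate distribution for {name!r}")
            draws[name] = (float(mu), float(sd))
    rng = np.random.default_rng(seed)
    n_healthy = int(round(healthy_fraction * n_subjects))
    subjects = []
    for i in range(n_subjects):
        healthy = i < n_healthy
        knobs = _draw_healthy_knobs(rng, draws)
        subtype = None
        if not healthy:
            subtype = subtypes[(i - n_healthy) % len(subtypes)]
            knobs = _degrade(knobs, subtype, rng)
        cfg = ProtocolConfig(seed=int(rng.integers(0, 2**31 - 1)))
        ann = generate_protocol(cfg, knobs)
        ann.subject_id = f"S{i:02d}"
        ann.healthy = healthy
        subjects.append(Subject(ann, healthy, subtype, knobs, ann.subject_id))
    return subjects


__all__ = [
    "REGIME_TYPES",
    "DEFAULT_SEQUENCE",
    "GaitKnobs",
    "ProtocolConfig",
    "AnnotatedRecording",
    "Subject",
    "PATHOLOGY_SUBTYPES",
    "generate_walking_segment",
    "generate_activity_segment",
    "generate_protocol",
    "generate_cohort",
]
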