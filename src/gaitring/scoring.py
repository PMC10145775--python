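"""Gait-quality criteria per walking regime and healthy-reference scoring.

Four unitless criteria summarize each walking bout, computed on the
band-pass-filtered accelerations of the regime:

* **stability** — RMSR_ML, the mediolateral RMS divided by the three-axis
  RMS magnitude.  High mediolateral sway relative to overall acceleration
  indicates postural instability, so *lower is better* for this criterion.
* **sturdiness** — RMSR_AP, the anteroposterior RMS ratio; vigorous push-off
  raises it, so higher is better.
* **symmetry** — P1CC, the autocorrelation of the craniocaudal acceleration
  at a one-step lag: alike left and right steps raise it.
* **steadiness** — P2CC, the autocorrelation at a two-step (one-stride) lag:
  reproducible strides raise it.

The autocorrelation is the unbiased FFT-based estimate (Wiener–Khinchin with
zero-padding against circular wrap-around, each lag divided by n - lag).

A healthy model holds, per criterion, the mean and SD over all healthy
walking regimes plus display bounds [x_min, x_max] — the 10th and 90th
percentiles of the z-scored healthy values.  New regimes are z-scored
against it and binned into five display levels used by the annular chart.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

CRITERIA = ("rmsr_ml", "rmsr_ap", "p1cc", "p2cc")

#: +1 when a larger value means better gait; mediolateral sway is inverted
ORIENTATION = {"rmsr_ml": -1.0, "rmsr_ap": 1.0, "p1cc": 1.0, "p2cc": 1.0}

CRITERION_NAMES = {
    "rmsr_ml": "stability",
    "rmsr_ap": "sturdiness",
    "p1cc": "symmetry",
    "p2cc": "steadiness",
}

BINS = ("well_below", "slightly_below", "within", "slightly_above", "well_above")

#: shortest walking regime the criteria are defined on: the steadiness peak
#: needs lags up to 2.5 step periods plus estimation headroom
MIN_SCORED_DURATION_S = 4.0


@dataclass(frozen=True)
class GaitCriteria:
    """The four per-regime gait criteria (all unitless)."""

    rmsr_ml: float
    rmsr_ap: float
    p1cc: float
    p2cc: float

    def as_dict(self) -> dict:
        return asdict(self)


def rms_ratios(acc_cc, acc_ml, acc_ap) -> tuple:
    """(RMSR_ML, RMSR_AP, RMSR_CC): per-axis RMS over the three-axis RMS.

    The three ratios satisfy rmsr_ml^2 + rmsr_cc^2 + rmsr_ap^2 = 1.
    """
    parts = [np.sqrt(np.mean(np.asarray(a, dtype=float) ** 2)) for a in (acc_ml, acc_ap, acc_cc)]
    rms_a = float(np.sqrt(sum(p * p for p in parts)))
    if rms_a == 0:
        raise ValueError("all-zero accelerations: RMS ratios undefined")
    return parts[0] / rms_a, parts[1] / rms_a, parts[2] / rms_a


def autocorrelation_unbiased(x) -> np.ndarray:
    """Unbiased one-sided autocorrelation of a series, ACF[0] = 1.

    Computed via FFT of the mean-removed series zero-padded to >= 2n (so the
    circular convolution never wraps), with each lag divided by (n - lag)
    and the whole normalized by the lag-0 value.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series too short for autocorrelation")
    z = x - x.mean()
    if np.allclose(z, 0):
        raise ValueError("zero-variance input: autocorrelation undefined")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(z, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    acov /= n - np.arange(n)
    return acov / acov[0]


def autocorrelation_naive(x) -> np.ndarray:
    """Direct O(n^2) unbiased autocorrelation (test oracle)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    z = x - x.mean()
    acov = np.array([np.dot(z[: n - k], z[k:]) / (n - k) for k in range(n)])
    return acov / acov[0]


def dominant_frequency(x, fs: float, fmin: float = 0.5, fmax: float = 5.0) -> float:
    """Periodogram argmax within [fmin, fmax]; cadence hint for peak windows."""
    x = np.asarray(x, dtype=float)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2 / len(x)
    band = (freqs >= fmin) & (freqs <= fmax)
    if not band.any():
        raise ValueError("frequency band empty for this series length")
    return float(freqs[band][np.argmax(power[band])])


def acf_peaks(acf: np.ndarray, cadence_hint_hz: float, fs: float) -> tuple:
    """(P1, P2): ACF maxima in the one-step and two-step lag windows.

    P1 is the maximum over lags in [0.5, 1.5] step periods, P2 over
    [1.5, 2.5] step periods; windowing by the cadence keeps noise lobes
    below the step lag from masquerading as the symmetry peak.  When the
    discrete maximum is interior to its window, a 3-point parabolic fit
    refines the peak value: the true step lag rarely falls on an integer
    sample, and the quantization otherwise adds ~0.002 of spurious
    window-to-window jitter to the peak height.
    """
    if cadence_hint_hz <= 0:
        raise ValueError("cadence hint must be positive")
    step_lag = fs / cadence_hint_hz
    peaks = []
    for k0, k1 in ((0.5, 1.5), (1.5, 2.5)):
        lo = int(np.ceil(k0 * step_lag))
        hi = int(np.floor(k1 * step_lag))
        if hi >= len(acf) or lo >= hi:
            raise ValueError("peak window outside ACF support (regime too short)")
        i = lo + int(np.argmax(acf[lo : hi + 1]))
        val = float(acf[i])
        if lo < i < hi:
            y0, y1, y2 = acf[i - 1], acf[i], acf[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:  # proper local maximum
                val = float(y1 - (y0 - y2) ** 2 / (8 * denom))
        peaks.append(val)
    return peaks[0], peaks[1]


def compute_criteria(regime, fs: float | None = None) -> GaitCriteria:
    """All four criteria from a regime's filtered accelerations.

    ``regime`` is anything with acc_cc/acc_ml/acc_ap arrays and a
    sampling rate (an ImuRecording or RegimeRecord.samples), or a dict of
    channel arrays with ``fs`` given explicitly.
    """
    if isinstance(regime, dict):
        cc, ml, ap = regime["acc_cc"], regime["acc_ml"], regime["acc_ap"]
        if fs is None:
            raise ValueError("fs required with dict input")
    else:
        cc, ml, ap = regime.acc_cc, regime.acc_ml, regime.acc_ap
        fs = regime.sampling_rate_hz
    rmsr_ml, rmsr_ap, _ = rms_ratios(cc, ml, ap)
    acf = autocorrelation_unbiased(cc)
    cadence = dominant_frequency(cc, fs)
    p1, p2 = acf_peaks(acf, cadence, fs)
    return GaitCriteria(rmsr_ml=rmsr_ml, rmsr_ap=rmsr_ap, p1cc=p1, p2cc=p2)


@dataclass
class HealthyModel:
    """Per-criterion healthy statistics and display bounds.

    ``mu``/``sigma`` are the mean and SD over all healthy walking regimes;
    ``x_min``/``x_max`` are the 10th/90th percentiles of the *z-scored*
    healthy values (near -1.28/+1.28 only under normality, which is not
    assumed).
    """

    mu: dict
    sigma: dict
    x_min: dict
    x_max: dict
    orientation: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HealthyModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_healthy_model(criteria_list) -> HealthyModel:
    """Fit the healthy reference from >= 10 healthy walking regimes."""
    if len(criteria_list) < 10:
        raise ValueError("need at least 10 healthy walking regimes")
    mu, sigma, x_min, x_max = {}, {}, {}, {}
    for c in CRITERIA:
        vals = np.array([getattr(g, c) for g in criteria_list], dtype=float)
        m = float(vals.mean())
        s = float(vals.std(ddof=1))
        if s == 0:
            raise ValueError(f"zero variance for criterion {c}")
        z = (vals - m) / s
        mu[c], sigma[c] = m, s
        x_min[c] = float(np.percentile(z, 10))
        x_max[c] = float(np.percentile(z, 90))
    return HealthyModel(mu=mu, sigma=sigma, x_min=x_min, x_max=x_max,
                        orientation=dict(ORIENTATION))


@dataclass(frozen=True)
class RegimeScore:
    z: dict            # raw z-score per criterion
    oriented_z: dict   # orientation * z (higher = better)
    display_bin: dict  # one of BINS per criterion


def score_regime(criteria: GaitCriteria, model: HealthyModel) -> RegimeScore:
    """Z-score a regime against the healthy model and bin it for display.

    The oriented score flips sign for lower-is-better criteria so that
    larger always means better.  "Slightly" outside the healthy band means
    within half the healthy inter-percentile range beyond a bound.
    """
    z, oz, bins = {}, {}, {}
    for c in CRITERIA:
        zc = (getattr(criteria, c) - model.mu[c]) / model.sigma[c]
        o = model.orientation[c]
        val = o * zc
        lo, hi = sorted((o * model.x_min[c], o * model.x_max[c]))
        half = 0.5 * (hi - lo)
        if val < lo - half:
            b = "well_below"
        elif val < lo:
            b = "slightly_below"
        elif val <= hi:
            b = "within"
        elif val <= hi + half:
            b = "slightly_above"
        else:
            b = "well_above"
        z[c], oz[c], bins[c] = float(zc), float(val), b
    return RegimeScore(z=z, oriented_z=oz, display_bin=bins)


__all__ = [
    "CRITERIA",
    "ORIENTATION",
    "CRITERION_NAMES",
    "BINS",
    "GaitCriteria",
    "HealthyModel",
    "RegimeScore",
    "rms_ratios",
    "autocorrelation_unbiased",
    "autocorrelation_naive",
    "dominant_frequency",
    "acf_peaks",
    "compute_criteria",
    "fit_healthy_model",
    "score_regime",
]
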