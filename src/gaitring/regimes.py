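"""Per-regime classification features and the cascade walking/activity classifier.

Each segmented regime is summarized by a fixed vector of time- and
frequency-domain statistics computed on the six filtered channels: moments,
extrema, nearest-rank percentiles (also on the central two-thirds of the
regime, the "middle" variants), periodogram dominant frequencies and powers,
RMS — 21 per channel — plus the two craniocaudal autocorrelation peaks and
the mean acceleration vector magnitude (129 features in total).

Classification is a cascade of two linear max-margin (SVM) classifiers on
standardized, PCA-projected features (smallest component count reaching 99%
cumulative explained variance): stage 1 separates walking from everything
else; stage 2 splits the remaining regimes into sedentary (still) versus
non-sedentary (moving, not walking).  Regime-level rather than sliding-frame
classification is deliberate: the segmentation stage guarantees each regime
is stationary, so the features are stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import scoring
from .preprocess import CHANNELS, ImuRecording

logger = logging.getLogger(__name__)

LABELS = ("walking", "non_sedentary", "sedentary")

_PER_CHANNEL_STATS = (
    "mean", "std", "var", "min", "max", "PD0", "F0", "PD2", "F2", "CV",
    "p75", "p25", "p85", "p15", "p95", "p5", "p75m", "p25m", "p85m", "p15m",
    "RMS",
)

FEATURE_NAMES = tuple(
    [f"{stat}_{ch}" for ch in CHANNELS for stat in _PER_CHANNEL_STATS]
    + ["P1_aCC", "P2_aCC", "VM_mean"]
)

_F2_EXCLUSION_HZ = 0.2  # guard band around F0 when hunting the second peak


@dataclass
class RegimeRecord:
    """A time span of the filtered recording, optionally labeled."""

    span: tuple  # (start_s, end_s)
    samples: ImuRecording
    label: str | None = None
    regime_id: str = ""

    def __post_init__(self) -> None:
        if self.span[1] <= self.span[0]:
            raise ValueError("regime span must have positive duration")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return self.span[1] - self.span[0]


@dataclass(frozen=True)
class ClassificationFeatures:
    """Named, fixed-order feature vector of one regime."""

    values: np.ndarray
    names: tuple = FEATURE_NAMES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != len(self.names):
            raise ValueError("feature vector length mismatch")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature values")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


def slice_regimes(rec: ImuRecording, breakpoints_s) -> list:
    """Cut the recording into half-open spans covering it exactly once."""
    dur = rec.duration_s
    bks = [float(b) for b in breakpoints_s]
    if any(not 0 < b < dur for b in bks):
        raise ValueError("breakpoints must be interior to the recording")
    bounds = [0.0, *bks, dur]
    return [
        RegimeRecord(span=(a, b), samples=rec.slice_seconds(a, b))
        for a, b in zip(bounds, bounds[1:])
    ]


def _nearest_rank(sorted_x: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n/100)-th sorted value."""
    n = len(sorted_x)
    r = int(np.ceil(q * n / 100.0))
    return float(sorted_x[min(max(r, 1), n) - 1])


def _periodogram_peaks(x: np.ndarray, fs: float) -> tuple:
    """(PD0, F0, PD2, F2) from the periodogram FFT(X)*ConjFFT(X)/N.

    F2/PD2 is the second-largest local maximum outside a +-0.2 Hz guard
    band around F0 (the adjacent bin of F0 would otherwise always win).
    """
    n = len(x)
    spec = np.fft.rfft(x)
    power = (spec * np.conj(spec)).real / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    power = power[1:]  # drop DC: dominant *oscillation*, not the offset
    freqs = freqs[1:]
    i0 = int(np.argmax(power))
    pd0, f0 = float(power[i0]), float(freqs[i0])
    is_peak = np.ones(len(power), dtype=bool)
    is_peak[1:] &= power[1:] >= power[:-1]
    is_peak[:-1] &= power[:-1] >= power[1:]
    is_peak &= np.abs(freqs - f0) > _F2_EXCLUSION_HZ
    # a secondary peak must carry real power, not rounding residue
    is_peak &= power > 1e-12 * pd0
    if is_peak.any():
        i2 = int(np.flatnonzero(is_peak)[np.argmax(power[is_peak])])
        pd2, f2 = float(power[i2]), float(freqs[i2])
    else:
        logger.debug("no secondary periodogram peak; imputing 0")
        pd2, f2 = 0.0, 0.0
    return pd0, f0, pd2, f2


def extract_features(regime, fs: float | None = None) -> ClassificationFeatures:
    """The full feature vector of one regime (filtered time-domain samples)."""
    if isinstance(regime, RegimeRecord):
        rec = regime.samples
    else:
        rec = regime
    fs = rec.sampling_rate_hz if fs is None else fs
    if rec.n_samples < fs:
        raise ValueError("regime shorter than 1 s")
    vals = []
    for ch in CHANNELS:
        x = np.asarray(getattr(rec, ch), dtype=float)
        n = len(x)
        mean = float(x.mean())
        std = float(x.std(ddof=1))
        var = std * std
        if std == 0:
            logger.debug("zero-variance channel %s: imputing CV/F0/F2 = 0", ch)
            pd0 = f0 = pd2 = f2 = 0.0
            cv = 0.0
        else:
            pd0, f0, pd2, f2 = _periodogram_peaks(x, fs)
            # band-passed channels are zero-mean by construction; below
            # rounding level the ratio is ill-conditioned, impute 0
            cv = std / mean if abs(mean) > 1e-9 * std else 0.0
        s = np.sort(x)
        mid = np.sort(x[n // 6 : (5 * n) // 6])
        vals.extend(
            [
                mean, std, var, float(x.min()), float(x.max()),
                pd0, f0, pd2, f2, cv,
                _nearest_rank(s, 75), _nearest_rank(s, 25),
                _nearest_rank(s, 85), _nearest_rank(s, 15),
                _nearest_rank(s, 95), _nearest_rank(s, 5),
                _nearest_rank(mid, 75), _nearest_rank(mid, 25),
                _nearest_rank(mid, 85), _nearest_rank(mid, 15),
                float(np.sqrt(np.mean(x**2))),
            ]
        )
    try:
        acf = scoring.autocorrelation_unbiased(rec.acc_cc)
        cadence = scoring.dominant_frequency(rec.acc_cc, fs)
        p1, p2 = scoring.acf_peaks(acf, cadence, fs)
    except ValueError:
        logger.debug("autocorrelation peaks unavailable; imputing 0")
        p1 = p2 = 0.0
    vm = float(np.mean(np.sqrt(rec.acc_cc**2 + rec.acc_ap**2 + rec.acc_ml**2)))
    vals.extend([p1, p2, vm])
    return ClassificationFeatures(values=np.asarray(vals))


@dataclass
class RegimeClassifier:
    """Standardization + 99%-variance projection + two linear classifiers."""

    feat_mean: np.ndarray
    feat_sd: np.ndarray
    components: np.ndarray       # (m, p) orthonormal rows
    w1: np.ndarray               # stage 1: walking vs rest
    b1: float
    w2: np.ndarray               # stage 2: non_sedentary vs sedentary
    b2: float
    feature_names: tuple = FEATURE_NAMES

    def _project(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feat_mean) / self.feat_sd
        return Z @ self.components.T

    def to_json(self, path) -> None:
        obj = {
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "components": self.components.tolist(),
            "w1": self.w1.tolist(),
            "b1": self.b1,
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "feature_names": list(self.feature_names),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "RegimeClassifier":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            feat_mean=np.asarray(obj["feat_mean"]),
            feat_sd=np.asarray(obj["feat_sd"]),
            components=np.asarray(obj["components"]),
            w1=np.asarray(obj["w1"]),
            b1=float(obj["b1"]),
            w2=np.asarray(obj["w2"]),
            b2=float(obj["b2"]),
            feature_names=tuple(obj["feature_names"]),
        )


def _feature_matrix(features) -> np.ndarray:
    rows = [f.values if isinstance(f, ClassificationFeatures) else np.asarray(f, float)
            for f in features]
    return np.vstack(rows)


def n_components_99(X: np.ndarray) -> int:
    """Smallest component count with cumulative explained variance >= 0.99."""
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return 1
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, 0.99 - 1e-12) + 1)


def fit_classifiers(features, labels, C: float = 1.0) -> RegimeClassifier:
    """Train the cascade on labeled regimes.

    Stage 1 (walking vs non-walking) sees every regime; stage 2 (sedentary
    vs non-sedentary) is trained only on the non-walking training regimes.
    """
    X = _feature_matrix(features)
    labels = list(labels)
    if len(labels) != len(X):
        raise ValueError("features/labels length mismatch")
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    Zc = Z - Z.mean(axis=0)
    m = n_components_99(Z)
    _, _, Vt = np.linalg.svd(Zc, full_matrices=False)
    components = Vt[:m]
    P = Z @ components.T
    y1 = np.array([lab == "walking" for lab in labels])
    if y1.all() or not y1.any():
        raise ValueError("stage 1 needs both walking and non-walking regimes")
    clf1 = SVC(kernel="linear", C=C).fit(P, y1)
    rest = ~y1
    y2 = np.array([lab == "non_sedentary" for lab in np.asarray(labels, dtype=object)[rest]])
    if y2.all() or not y2.any():
        raise ValueError("stage 2 needs both sedentary and non-sedentary regimes")
    clf2 = SVC(kernel="linear", C=C).fit(P[rest], y2)
    return RegimeClassifier(
        feat_mean=mean,
        feat_sd=sd,
        components=components,
        w1=clf1.coef_.ravel(),
        b1=float(clf1.intercept_[0]),
        w2=clf2.coef_.ravel(),
        b2=float(clf2.intercept_[0]),
    )


def predict_labels(model: RegimeClassifier, features) -> list:
    """Cascade prediction: walking wins stage 1, stage 2 splits the rest."""
    X = _feature_matrix(features)
    if X.shape[1] != len(model.feat_mean):
        raise ValueError("feature-length mismatch with the fitted model")
    P = model._project(X)
    out = []
    for row in P:
        if float(row @ model.w1) + model.b1 > 0:
            out.append("walking")
        elif float(row @ model.w2) + model.b2 > 0:
            out.append("non_sedentary")
        else:
            out.append("sedentary")
    return out


__all__ = [
    "LABELS",
    "FEATURE_NAMES",
    "RegimeRecord",
    "ClassificationFeatures",
    "RegimeClassifier",
    "slice_regimes",
    "extract_features",
    "n_components_99",
    "fit_classifiers",
    "predict_labels",
]
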