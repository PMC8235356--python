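"""Classifier heads and non-transfer baselines.

The model zoo pairs each trunk (pretrained "Pr_" or randomly initialized
"Rd_") with either the dense softmax head ("_DC") or a Gaussian-kernel
SVM ("_SVM") fit on the GAP features.  Two non-CNN baselines complete
the table: an SVM on 34 handcrafted time-domain features per breath
("Manual_SVM") and a two-layer LSTM on the resampled raw sequences
("LSTM").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .nn.lstm import LSTMClassifier
from .preprocess import IMG_SIZE, minmax_normalize, resample_to_length
from .synth import BreathCycle

N_HANDCRAFTED = 34


@dataclass
class SVMHead:
    """Gaussian-kernel SVM on feature vectors (features, never images)."""

    C: float = 1.0
    gamma: float | str = "median"
    pipeline: Pipeline | None = None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "SVMHead":
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels)
        if features.ndim != 2 or len(features) < 2:
            raise ValueError("need a 2-D feature matrix with n >= 2")
        if len(np.unique(labels)) < 2:
            raise ValueError("both classes must be present")
        gamma = self.gamma
        if gamma == "median":
            # kernel width from the median pairwise distance heuristic
            scaled = StandardScaler().fit_transform(features)
            sub = scaled[:512]
            med = float(np.median(pdist(sub))) if len(sub) > 1 else 1.0
            gamma = 1.0 / (2 * med * med) if med > 0 else "scale"
        self.pipeline = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(C=self.C, kernel="rbf", gamma=gamma)),
        ])
        self.pipeline.fit(features, labels)
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.pipeline is None:
            raise RuntimeError("head is not fitted")
        return self.pipeline.predict(np.asarray(features, dtype=float))


def fit_svm_head(features: np.ndarray, labels: np.ndarray,
                 C: float = 1.0, gamma="median") -> SVMHead:
    return SVMHead(C=C, gamma=gamma).fit(features, labels)


# ---------------------------------------------------------------------------
# handcrafted time-domain features

def _phase_split(cycle: BreathCycle) -> int:
    """Index of the inspiration/expiration boundary: the first sample at
    which flow turns negative after the inspiratory peak."""
    flow = cycle.flow
    peak = int(np.argmax(flow))
    neg = np.nonzero(flow[peak:] < 0)[0]
    return peak + int(neg[0]) if len(neg) else len(flow) - 1


def _channel_features(x: np.ndarray, dt: float) -> list:
    """Nine summary statistics of one channel: level, spread, slope, area."""
    slope = np.diff(x) / dt
    return [float(np.mean(x)), float(np.max(x)), float(np.min(x)),
            float(np.ptp(x)), float(np.std(x)),
            float(np.mean(np.abs(slope))), float(np.max(slope)),
            float(np.min(slope)), float(np.trapezoid(x, dx=dt))]


def handcrafted_features(cycle: BreathCycle) -> np.ndarray:
    """The 34-element time-domain feature vector of one breath.

    Layout (documented in docs/methods.md): 9 per-channel statistics for
    pressure, flow and volume (27), then 7 cycle-level features:
    inspiratory time, expiratory time, their ratio, total duration,
    inspired volume, expiratory flow area magnitude, and the count of
    expiratory flow peaks.
    """
    if cycle.n_samples < 10:
        raise ValueError("cycle too short for feature extraction")
    dt = float(cycle.t[1] - cycle.t[0])
    feats = []
    for x in (cycle.pressure, cycle.flow, cycle.volume):
        feats.extend(_channel_features(x, dt))
    split = _phase_split(cycle)
    t_insp = split * dt
    t_exp = (cycle.n_samples - 1 - split) * dt
    insp_vol = float(np.trapezoid(np.clip(cycle.flow[:split + 1], 0, None), dx=dt))
    exp_flow = cycle.flow[split:]
    exp_area = float(np.trapezoid(np.abs(np.clip(exp_flow, None, 0)), dx=dt))
    d = np.diff(exp_flow)
    peaks = int(np.sum((d[:-1] > 0) & (d[1:] <= 0)))
    feats.extend([t_insp, t_exp, t_insp / max(t_exp, dt),
                  float(cycle.duration), insp_vol, exp_area, float(peaks)])
    out = np.asarray(feats, dtype=float)
    assert out.shape == (N_HANDCRAFTED,)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite handcrafted feature")
    return out


# ---------------------------------------------------------------------------
# recurrent baseline

def cycle_to_sequence(cycle: BreathCycle) -> np.ndarray:
    """(224, 3) per-breath sequence: resampled, min-max normalized P/F/V."""
    cols = [minmax_normalize(resample_to_length(x, IMG_SIZE))
            for x in (cycle.pressure, cycle.flow, cycle.volume)]
    return np.stack(cols, axis=1).astype(np.float32)


def build_recurrent_baseline(input_shape=(IMG_SIZE, 3), units: int = 32,
                             n_classes: int = 2, seed: int = 0) -> LSTMClassifier:
    """Two stacked LSTM layers over (224, 3) sequences, dense softmax out."""
    return LSTMClassifier(input_dim=input_shape[1], units=units,
                          n_classes=n_classes, seed=seed)


def lstm_param_count(input_dim: int, units: int, n_classes: int = 2) -> int:
    """Closed form: 4*(u*(u+i)+u) per layer plus the dense head."""
    layer1 = 4 * (units * (units + input_dim) + units)
    layer2 = 4 * (units * (units + units) + units)
    head = units * n_classes + n_classes
    return layer1 + layer2 + head
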