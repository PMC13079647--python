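"""Uniform classifier registry for the decoding benchmark.

Six algorithms compete on identical feature matrices: Decision Tree (DT),
Random Forest (RF), XGBoost (XGB), the random-convolutional-kernel
time-series transform (RCKT), logistic regression (GLM) and the Liquid
State Machine (LSM).  Every entry obeys the same contract — ``fit(X, y)``
then ``predict_proba(X)`` returning class probabilities — and is
deterministic given its seed.

RCKT is implemented in-repo: random kernels with random length, weights,
bias, dilation and padding are convolved with the (possibly
multichannel) series, pooled with the maximum and the proportion of
positive values (PPV), and read out by a regularized logistic model.
Keeping the transform in-repo makes its inference cost visible to the
runtime accounting: unlike the other baselines, the transform runs both
during training and whenever a trained model classifies new trials.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .lsm import LSMClassifier, ReservoirConfig

CLASSIFIER_NAMES = ("DT", "RF", "XGB", "RCKT", "GLM", "LSM")


@dataclass
class ClassifierSpec:
    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; valid names: {CLASSIFIER_NAMES}"
            )


# ---------------------------------------------------------------------------
# ROCKET


_ROCKET_CACHE: dict[tuple[str, bytes], np.ndarray] = {}
_ROCKET_CACHE_MAX = 500_000


def clear_rocket_cache() -> None:
    _ROCKET_CACHE.clear()


class RocketClassifier:
    """Random convolutional kernel transform with a logistic readout.

    Kernels follow the published recipe: length in {7, 9, 11},
    mean-centred Gaussian weights, uniform bias in [-1, 1], exponentially
    sampled dilation, and optional zero padding.  With multichannel input
    each kernel mixes a random channel subset.  Two pooled values per
    kernel — the maximum and the proportion of positive convolution
    outputs — feed a regularized logistic regression.
    """

    def __init__(
        self, n_kernels: int = 200, C: float = 1.0, n_traces: int = 1, seed: int = 0
    ) -> None:
        self.n_kernels = n_kernels
        self.C = C
        self.n_traces = n_traces
        self.seed = seed
        self._kernels: list[dict] | None = None
        self._series_len: int | None = None
        self._readout: LogisticRegression | None = None

    def _draw_kernels(self, series_len: int, n_channels: int) -> list[dict]:
        rng = np.random.default_rng(self.seed)
        kernels = []
        for _ in range(self.n_kernels):
            length = int(rng.choice([7, 9, 11]))
            if n_channels > 1:
                n_sel = int(2 ** rng.uniform(0, np.log2(n_channels + 1)))
                n_sel = min(max(n_sel, 1), n_channels)
                channels = rng.choice(n_channels, size=n_sel, replace=False)
            else:
                channels = np.array([0])
            weights = rng.standard_normal((len(channels), length))
            weights -= weights.mean(axis=1, keepdims=True)
            bias = rng.uniform(-1.0, 1.0)
            max_exp = np.log2((series_len - 1) / (length - 1)) if series_len > length else 0.0
            dilation = int(2 ** rng.uniform(0, max(max_exp, 0.0)))
            padding = ((length - 1) * dilation) // 2 if rng.random() < 0.5 else 0
            kernels.append(
                {
                    "length": length,
                    "channels": channels,
                    "weights": weights,
                    "bias": bias,
                    "dilation": dilation,
                    "padding": padding,
                }
            )
        return kernels

    def _apply_kernels(self, series: np.ndarray) -> np.ndarray:
        """(n, channels, T) -> (n, 2 * n_kernels) pooled features."""
        n = series.shape[0]
        feats = np.empty((n, 2 * self.n_kernels))
        for k, ker in enumerate(self._kernels):
            d, pad, length = ker["dilation"], ker["padding"], ker["length"]
            x = series[:, ker["channels"], :]
            if pad:
                x = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
            out_len = x.shape[2] - (length - 1) * d
            if out_len < 1:
                feats[:, 2 * k : 2 * k + 2] = 0.0
                continue
            conv = np.full((n, out_len), ker["bias"])
            for tap in range(length):
                seg = x[:, :, tap * d : tap * d + out_len]
                conv += np.einsum("nct,c->nt", seg, ker["weights"][:, tap])
            feats[:, 2 * k] = conv.max(axis=1)
            feats[:, 2 * k + 1] = (conv > 0).mean(axis=1)
        return feats

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] % self.n_traces != 0:
            raise ValueError("row length not divisible by n_traces")
        series_len = X.shape[1] // self.n_traces
        if self._kernels is None:
            self._series_len = series_len
            self._kernels = self._draw_kernels(series_len, self.n_traces)
        key = f"{self.seed}|{self.n_kernels}|{self.n_traces}|{self._series_len}"
        out = np.empty((X.shape[0], 2 * self.n_kernels))
        missing = []
        digests = []
        for i, row in enumerate(X):
            digest = hashlib.sha1(row.tobytes()).digest()
            digests.append(digest)
            cached = _ROCKET_CACHE.get((key, digest))
            if cached is None:
                missing.append(i)
            else:
                out[i] = cached
        if missing:
            series = X[missing].reshape(len(missing), self.n_traces, series_len)
            feats = self._apply_kernels(series)
            for j, i in enumerate(missing):
                if len(_ROCKET_CACHE) < _ROCKET_CACHE_MAX:
                    _ROCKET_CACHE[(key, digests[i])] = feats[j]
                out[i] = feats[j]
        return out

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RocketClassifier":
        feats = self.transform(X)
        self._readout = LogisticRegression(C=self.C, max_iter=2000)
        self._readout.fit(feats, y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._readout is None:
            raise RuntimeError("RocketClassifier is not trained")
        return self._readout.predict_proba(self.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self._readout.classes_[proba.argmax(axis=1)]


# ---------------------------------------------------------------------------
# registry


def build_classifier(spec: ClassifierSpec, n_traces: int = 1, series: bool = True):
    """Instantiate a trainable classifier from a spec.

    ``n_traces`` tells the time-series models (RCKT, LSM) how many
    equal-length traces are concatenated in each feature row (4 for the
    all-layer scenarios); ``series`` is False for FFT features, in which
    case the LSM presents the vector as a constant held current.
    """
    name, p, seed = spec.name, dict(spec.params), spec.seed
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if name == "RF":
        p.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    if name == "XGB":
        p.setdefault("n_estimators", 50)
        p.setdefault("max_depth", 3)
        return XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss", **p
        )
    if name == "GLM":
        p.setdefault("max_iter", 2000)
        return LogisticRegression(**p)
    if name == "RCKT":
        return RocketClassifier(seed=seed, n_traces=n_traces if series else 1, **p)
    if name == "LSM":
        config = p.pop("config", None) or ReservoirConfig(seed=seed)
        return LSMClassifier(
            config=config,
            input_mode="timeseries" if series else "static",
            n_traces=n_traces if series else 1,
            **p,
        )
    raise ValueError(f"unknown classifier {name!r}; valid names: {CLASSIFIER_NAMES}")


def default_grid(name: str) -> list[dict]:
    """Small documented hyperparameter grid per algorithm.

    Grids are deliberately compact (<= 4 points): the benchmark's purpose
    is the comparison protocol, not exhaustive tuning.  The GLM grid
    spans four orders of magnitude of regularization.
    """
    grids = {
        "DT": [{"max_depth": 3}, {"max_depth": 5}, {"max_depth": None}],
        "RF": [{"max_depth": None}, {"max_depth": 5}],
        "XGB": [
            {"n_estimators": 50, "max_depth": 2, "learning_rate": 0.3},
            {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
        ],
        "GLM": [{"C": 0.01}, {"C": 1.0}, {"C": 100.0}],
        "RCKT": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}],
        "LSM": [{"C": 0.1}, {"C": 1.0}, {"C": 10.0}],
    }
    if name not in grids:
        raise ValueError(f"unknown classifier {name!r}; valid names: {CLASSIFIER_NAMES}")
    return [dict(g) for g in grids[name]]
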