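"""RAW and FFT feature construction over peri-stimulus LFP windows.

Two feature families describe each trial after causal Butterworth
filtering:

* RAW — the filtered trace itself at 1 kHz: 400 samples for the
  pre-stimulus window [-400, 0) ms, 100 for the peri-stimulus window
  [0, 100) ms, 500 for the full window.
* FFT — single-sided amplitude spectra of the same windows, computed per
  window and concatenated for FULL (spontaneous and evoked activity have
  very different spectra, so they are transformed separately): 60
  pre-stimulus bins at 2.5 Hz spacing (0-147.5 Hz), 15 peri-stimulus bins
  at 10 Hz spacing (0-140 Hz), 75 for FULL.  Bin 0 is the signed window
  mean; bins k >= 1 carry the amplitude 2|X_k|/N of the corresponding
  frequency component.

Either a single cortical layer's channel or all four layers concatenated
(order L2/3, L4, L5, L6) provide the input trace.  Feature scaling is
Min-Max to [0, 1] with the minimum and maximum learned from training
trials only; test values may fall outside [0, 1] and are not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synth import SAMPLING_RATE_HZ, LAYERS, Trial, time_grid

LAYER_SELECTORS = LAYERS + ("ALL",)

#: highest retained FFT frequency per window, Hz
FFT_CAP_HZ = {"PRE": 147.5, "PERI": 140.0}


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window relative to stimulus onset, half-open in ms.

    ``peri_truncation_ms`` shortens the peri-stimulus part to its first
    ``t`` ms (used by the shortened-signal sweep); it never affects PRE.
    """

    name: str  # PRE, PERI or FULL
    peri_truncation_ms: float | None = None

    def __post_init__(self) -> None:
        if self.name not in ("PRE", "PERI", "FULL"):
            raise ValueError("window name must be PRE, PERI or FULL")
        if self.peri_truncation_ms is not None:
            if self.name == "PRE":
                raise ValueError("peri_truncation_ms only applies to PERI/FULL")
            if not 0.0 < self.peri_truncation_ms <= 100.0:
                raise ValueError("peri_truncation_ms must be in (0, 100]")

    def parts(self) -> list[tuple[str, float, float]]:
        """(label, start_ms, end_ms) of each atomic window, PRE before PERI."""
        peri_end = self.peri_truncation_ms if self.peri_truncation_ms is not None else 100.0
        if self.name == "PRE":
            return [("PRE", -400.0, 0.0)]
        if self.name == "PERI":
            return [("PERI", 0.0, peri_end)]
        return [("PRE", -400.0, 0.0), ("PERI", 0.0, peri_end)]

    def truncate(self, peri_ms: float) -> "WindowSpec":
        return replace(self, peri_truncation_ms=peri_ms)


PRE = WindowSpec("PRE")
PERI = WindowSpec("PERI")
FULL = WindowSpec("FULL")


def _window_slice(start_ms: float, end_ms: float) -> slice:
    grid = time_grid()
    return slice(int(np.searchsorted(grid, start_ms)), int(np.searchsorted(grid, end_ms)))


def _layer_channels(layer_selector: str, layer_map: dict[str, int]) -> list[tuple[str, int]]:
    if layer_selector not in LAYER_SELECTORS:
        raise ValueError(f"layer_selector must be one of {LAYER_SELECTORS}")
    wanted = LAYERS if layer_selector == "ALL" else (layer_selector,)
    out = []
    for layer in wanted:
        if layer not in layer_map:
            raise KeyError(f"layer {layer!r} missing from layer_map")
        out.append((layer, layer_map[layer]))
    return out


def extract_raw(
    trial: Trial | np.ndarray,
    window: WindowSpec,
    layer_selector: str,
    layer_map: dict[str, int],
) -> tuple[np.ndarray, list[str]]:
    """Per-sample RAW features of the selected layer(s) over a window.

    Returns the feature vector and its names (``L4:RAW:PERI:012`` style).
    Lengths per layer: PRE 400, PERI 100, FULL 500; ALL concatenates the
    four layers in fixed order.
    """
    signal = trial.signal if isinstance(trial, Trial) else np.asarray(trial)
    values, names = [], []
    for layer, ch in _layer_channels(layer_selector, layer_map):
        for label, start, end in window.parts():
            seg = signal[ch, _window_slice(start, end)]
            values.append(seg)
            names.extend(f"{layer}:RAW:{label}:{i:03d}" for i in range(len(seg)))
    return np.concatenate(values), names


def fft_amplitudes(segment: np.ndarray, cap_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum up to ``cap_hz`` inclusive.

    Bin 0 is the signed mean of the segment; bin k >= 1 is 2|X_k|/N, the
    amplitude of a unit sinusoid at k * fs / N Hz.  Returns (amplitudes,
    frequencies in Hz).
    """
    segment = np.asarray(segment, dtype=float)
    n = len(segment)
    spectrum = np.fft.rfft(segment)
    freqs = np.fft.rfftfreq(n, d=1.0 / SAMPLING_RATE_HZ)
    amps = 2.0 * np.abs(spectrum) / n
    amps[0] = spectrum.real[0] / n  # signed window mean
    if n % 2 == 0:
        amps[-1] = np.abs(spectrum[-1]) / n  # Nyquist bin is not doubled
    keep = freqs <= cap_hz + 1e-9
    return amps[keep], freqs[keep]


def extract_fft(
    trial: Trial | np.ndarray,
    window: WindowSpec,
    layer_selector: str,
    layer_map: dict[str, int],
) -> tuple[np.ndarray, list[str]]:
    """FFT amplitude features of the selected layer(s) over a window.

    PRE and PERI are transformed separately (and concatenated for FULL).
    Bins are retained up to a fixed frequency cap — 147.5 Hz for PRE
    (2.5 Hz spacing, 60 bins) and 140 Hz for PERI (10 Hz spacing, 15
    bins) — so a truncated peri window keeps the same cap and its bin
    count follows its new spacing.
    """
    signal = trial.signal if isinstance(trial, Trial) else np.asarray(trial)
    values, names = [], []
    for layer, ch in _layer_channels(layer_selector, layer_map):
        for label, start, end in window.parts():
            seg = signal[ch, _window_slice(start, end)]
            amps, freqs = fft_amplitudes(seg, FFT_CAP_HZ[label])
            values.append(amps)
            names.extend(f"{layer}:FFT:{label}:{f:g}Hz" for f in freqs)
    return np.concatenate(values), names


# ---------------------------------------------------------------------------
# feature matrices and train-anchored scaling


@dataclass
class FeatureMatrix:
    """Trials x features with unique ordered column names."""

    values: np.ndarray
    feature_names: list[str]
    trial_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count must match feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names, index=self.trial_ids)


@dataclass
class MinMaxScaler:
    """Per-feature min/max learned from training rows only.

    Transform maps the training minimum to 0 and maximum to 1; values
    outside the training range (e.g. test trials) map outside [0, 1] and
    are not clipped.  Constant training columns map to 0.
    """

    minimum: np.ndarray
    maximum: np.ndarray
    feature_names: list[str]

    def _scale(self) -> np.ndarray:
        span = self.maximum - self.minimum
        return np.where(span > 0, span, 1.0)

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if matrix.feature_names != self.feature_names:
            raise ValueError("feature names do not match the fitted scaler")
        scaled = (matrix.values - self.minimum) / self._scale()
        return FeatureMatrix(scaled, list(matrix.feature_names), matrix.trial_ids)

    def inverse_transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if matrix.feature_names != self.feature_names:
            raise ValueError("feature names do not match the fitted scaler")
        values = matrix.values * self._scale() + self.minimum
        return FeatureMatrix(values, list(matrix.feature_names), matrix.trial_ids)


def fit_minmax(training: FeatureMatrix) -> MinMaxScaler:
    """Learn per-column min/max from the training matrix only."""
    if training.values.shape[0] < 1:
        raise ValueError("need at least one training row")
    minimum = training.values.min(axis=0)
    maximum = training.values.max(axis=0)
    if np.any(maximum == minimum):
        warnings.warn(
            "constant feature column(s) in training data; scaled to 0", stacklevel=2
        )
    return MinMaxScaler(minimum, maximum, list(training.feature_names))


def apply_minmax(scaler: MinMaxScaler, matrix: FeatureMatrix) -> FeatureMatrix:
    """Scale a matrix with a scaler fitted on training data."""
    return scaler.transform(matrix)
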