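"""Trial quality control, causal filtering and laminar layer assignment.

Quality control removes trials contaminated by recording artifacts before
any decoding is attempted.  Four detectors are applied over the full trial
range (-420 to +120 ms): amplifier saturation (|v| >= 2 mV at any sample),
movement bursts (20 ms windows in which every electrode pair is strongly
Pearson-correlated), electrical line noise (excess 50 Hz spectral power)
and early licks (lick within the first 100 ms after stimulus onset, whose
muscle artifact contaminates the evoked response).  A trial is kept only
if all four detectors are silent.

The decoding features use causally Butterworth-filtered traces: a
first-order 150 Hz low-pass followed by a sixth-order 47-53 Hz band-stop.
Causality matters because the pipeline emulates an online brain-machine
interface; zero-phase (forward-backward) filtering would leak future
samples into the present.

Layer assignment follows the standard laminar-probe procedure: the second
spatial derivative of the trial-averaged evoked LFP (the current source
density, CSD) shows a prominent short-latency sink at layer 4; the
remaining layers are placed at fixed depth offsets from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import (
    SAMPLING_RATE_HZ,
    TRIAL_START_MS,
    TRIAL_END_MS,
    LAYERS,
    Session,
    Trial,
    time_grid,
)


@dataclass
class QCConfig:
    """Thresholds for the four trial filters.

    The saturation cutoff (+/-2 mV), the 20 ms burst window and the QC
    range (-420..+120 ms) are fixed by the emulated recording protocol;
    the burst correlation threshold, the line-noise band and power
    fraction, and the burst window stride are engineering defaults,
    deliberately exposed here because the protocol does not quantify
    "strongly correlated" or "strong 50 Hz power".
    """

    saturation_cutoff_mv: float = 2.0
    qc_window_ms: tuple[float, float] = (TRIAL_START_MS, TRIAL_END_MS)
    burst_window_ms: float = 20.0
    burst_stride_ms: float = 10.0
    burst_correlation_threshold: float = 0.8
    line_noise_freq_hz: float = 50.0
    line_noise_bandwidth_hz: float = 1.0
    line_noise_power_threshold: float = 0.25
    early_lick_window_ms: tuple[float, float] = (0.0, 100.0)

    def validate(self) -> None:
        if self.saturation_cutoff_mv <= 0:
            raise ValueError("saturation_cutoff_mv must be > 0")
        lo, hi = self.qc_window_ms
        if not (TRIAL_START_MS <= lo < hi <= TRIAL_END_MS):
            raise ValueError("qc_window_ms must lie within the trial time grid")
        if not 0.0 <= self.burst_correlation_threshold <= 1.0:
            raise ValueError("burst_correlation_threshold must be in [0, 1]")
        if not 0.0 < self.line_noise_power_threshold < 1.0:
            raise ValueError("line_noise_power_threshold must be in (0, 1)")


@dataclass
class FilterSpec:
    """Causal Butterworth chain: low-pass then band-stop."""

    lowpass_cutoff_hz: float = 150.0
    lowpass_order: int = 1
    bandstop_band_hz: tuple[float, float] = (47.0, 53.0)
    bandstop_order: int = 6
    causal: bool = True

    def validate(self, sampling_rate_hz: float) -> None:
        nyq = sampling_rate_hz / 2.0
        if not 0 < self.lowpass_cutoff_hz < nyq:
            raise ValueError(f"lowpass cutoff must be in (0, {nyq}) Hz")
        lo, hi = self.bandstop_band_hz
        if not 0 < lo < hi < nyq:
            raise ValueError(f"bandstop band must lie within (0, {nyq}) Hz")
        if not self.causal:
            raise ValueError("only causal filtering is supported")


def _qc_slice(qc: QCConfig) -> slice:
    grid = time_grid()
    lo, hi = qc.qc_window_ms
    return slice(int(np.searchsorted(grid, lo)), int(np.searchsorted(grid, hi)))


# ---------------------------------------------------------------------------
# detectors


def detect_saturation(trial: Trial, qc: QCConfig | None = None) -> bool:
    """True iff any sample in the QC window reaches the +/-2 mV cutoff."""
    qc = qc or QCConfig()
    window = trial.signal[:, _qc_slice(qc)]
    return bool(np.any(np.abs(window) >= qc.saturation_cutoff_mv))


def detect_burst(trial: Trial, qc: QCConfig | None = None) -> bool:
    """True iff some 20 ms window has every electrode pair correlated.

    Windows slide with a 10 ms stride; a window fires when the minimum
    pairwise Pearson r across channels reaches the threshold.  Pairs
    involving a constant channel contribute r = 0 (cannot fire).
    """
    qc = qc or QCConfig()
    x = trial.signal[:, _qc_slice(qc)]
    if x.shape[0] < 2:
        raise ValueError("burst detection requires >= 2 channels")
    win = int(round(qc.burst_window_ms * SAMPLING_RATE_HZ / 1000.0))
    stride = max(int(round(qc.burst_stride_ms * SAMPLING_RATE_HZ / 1000.0)), 1)
    if x.shape[1] < win:
        return False
    for start in range(0, x.shape[1] - win + 1, stride):
        seg = x[:, start : start + win]
        centered = seg - seg.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        if np.any(norms == 0.0):
            continue  # constant channel: treat its pairs as r = 0
        corr = (centered @ centered.T) / np.outer(norms, norms)
        iu = np.triu_indices(x.shape[0], k=1)
        if corr[iu].min() >= qc.burst_correlation_threshold:
            return True
    return False


def detect_line_noise(trial: Trial, qc: QCConfig | None = None) -> bool:
    """True iff 50 Hz power dominates the spectrum on any channel.

    A Welch periodogram over the QC window is integrated in a narrow band
    around the line frequency; the trial is flagged when that power
    exceeds ``line_noise_power_threshold`` of the total 1-150 Hz power.
    """
    qc = qc or QCConfig()
    x = trial.signal[:, _qc_slice(qc)]
    nper = min(x.shape[1], 512)
    freqs, psd = sps.welch(x, fs=SAMPLING_RATE_HZ, nperseg=nper, axis=1)
    band = np.abs(freqs - qc.line_noise_freq_hz) <= qc.line_noise_bandwidth_hz
    total = (freqs >= 1.0) & (freqs <= 150.0)
    band_power = psd[:, band].sum(axis=1)
    total_power = psd[:, total].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total_power > 0, band_power / total_power, 0.0)
    return bool(np.any(frac > qc.line_noise_power_threshold))


def detect_early_lick(trial: Trial, qc: QCConfig | None = None) -> bool:
    """True iff the animal licked within [0, 100) ms after stimulus onset."""
    qc = qc or QCConfig()
    lat = trial.lick_latency_ms
    lo, hi = qc.early_lick_window_ms
    return lat is not None and lo <= lat < hi


_DETECTORS = {
    "saturation": detect_saturation,
    "burst": detect_burst,
    "line_noise": detect_line_noise,
    "early_lick": detect_early_lick,
}


def filter_trials(
    session: Session | list[Trial], qc: QCConfig | None = None
) -> tuple[list[Trial], pd.DataFrame]:
    """Apply all four detectors; keep a trial only if all are silent.

    Returns the kept trials and a rejection table with one row per
    rejected trial listing every triggered reason.
    """
    qc = qc or QCConfig()
    qc.validate()
    trials = session.trials if isinstance(session, Session) else session
    kept, rows = [], []
    for trial in trials:
        reasons = [name for name, det in _DETECTORS.items() if det(trial, qc)]
        if reasons:
            rows.append(
                {
                    "trial_id": trial.trial_id,
                    "reasons": ";".join(reasons),
                    "session": trial.session_id,
                    "mouse": trial.mouse_id,
                }
            )
        else:
            kept.append(trial)
    table = pd.DataFrame(rows, columns=["trial_id", "reasons", "session", "mouse"])
    return kept, table


# ---------------------------------------------------------------------------
# causal Butterworth filtering


def design_filters(
    spec: FilterSpec, sampling_rate_hz: float = SAMPLING_RATE_HZ
) -> np.ndarray:
    """Second-order sections of the low-pass + band-stop chain."""
    spec.validate(sampling_rate_hz)
    sos_lp = sps.butter(
        spec.lowpass_order, spec.lowpass_cutoff_hz, "lowpass", fs=sampling_rate_hz, output="sos"
    )
    sos_bs = sps.butter(
        spec.bandstop_order, spec.bandstop_band_hz, "bandstop", fs=sampling_rate_hz, output="sos"
    )
    return np.vstack([sos_lp, sos_bs])


def apply_butterworth(
    signal: np.ndarray,
    spec: FilterSpec | None = None,
    sampling_rate_hz: float = SAMPLING_RATE_HZ,
) -> np.ndarray:
    """Causally filter a (channels x samples) or (samples,) signal.

    Zero initial conditions: each trial starts from rest, so the first few
    samples carry the filter transient.  Train and test trials are treated
    identically, which keeps the transient from biasing the decoders.
    """
    spec = spec or FilterSpec()
    sos = design_filters(spec, sampling_rate_hz)
    return sps.sosfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def frequency_response(
    spec: FilterSpec, freqs_hz: np.ndarray, sampling_rate_hz: float = SAMPLING_RATE_HZ
) -> np.ndarray:
    """|H(f)| of the filter chain at the requested frequencies."""
    sos = design_filters(spec, sampling_rate_hz)
    _, h = sps.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=sampling_rate_hz)
    return np.abs(h)


# ---------------------------------------------------------------------------
# CSD and layer assignment


def compute_csd(
    mean_lfp_by_depth: np.ndarray, spacing_um: float = 25.0
) -> np.ndarray:
    """Current source density as the (negated) second spatial difference.

    ``mean_lfp_by_depth`` is depths x time (trial-averaged evoked LFP).
    CSD_i = -(v[i+1] - 2 v[i] + v[i-1]) / h^2, so a current sink — where
    the evoked negativity is sharpest across depth — appears as a
    negative CSD value.  The output has two fewer depth rows than the
    input (no boundary padding).
    """
    v = np.asarray(mean_lfp_by_depth, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3:
        raise ValueError("CSD needs a (depths x time) array with >= 3 depths")
    return -(v[2:] - 2.0 * v[1:-1] + v[:-2]) / (spacing_um**2)


@dataclass
class LayerAssignmentConfig:
    """Depth offsets (in channels, relative to the L4 sink) per layer."""

    sink_search_ms: tuple[float, float] = (0.0, 25.0)
    smoothing_ms: float = 5.0
    layer_offsets: dict = field(
        default_factory=lambda: {"L2/3": -3, "L4": 0, "L5": 3, "L6": 6}
    )
    flat_tolerance: float = 1e-12


def assign_layers(
    csd: np.ndarray,
    channel_depths_um: np.ndarray,
    csd_time_grid_ms: np.ndarray | None = None,
    config: LayerAssignmentConfig | None = None,
) -> dict[str, int]:
    """Locate L4 at the short-latency CSD sink; place other layers by offset.

    ``csd`` has ``len(channel_depths_um) - 2`` rows (channel i+1 of the
    original probe maps to CSD row i).  L4 is the channel whose CSD is
    most negative within the first 25 ms post-onset; ties break toward
    the shallowest channel.  A flat CSD (no evoked sink) is an error.
    """
    config = config or LayerAssignmentConfig()
    csd = np.asarray(csd, dtype=float)
    n_channels = len(channel_depths_um)
    if csd.shape[0] != n_channels - 2:
        raise ValueError("csd rows must equal n_channels - 2")
    if csd_time_grid_ms is None:
        csd_time_grid_ms = time_grid()
    lo, hi = config.sink_search_ms
    tmask = (csd_time_grid_ms >= lo) & (csd_time_grid_ms < hi)
    window = csd[:, tmask]
    if window.size == 0:
        raise ValueError("sink search window contains no samples")
    # boxcar smoothing in time suppresses the noise bias of the running min
    k = max(int(round(config.smoothing_ms)), 1)
    if window.shape[1] >= k > 1:
        kernel = np.ones(k) / k
        window = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="valid"), 1, window
        )
    if np.all(np.abs(window) <= config.flat_tolerance):
        raise ValueError("flat CSD: no evoked sink to anchor layer assignment")
    per_channel_min = window.min(axis=1)
    sink_row = int(np.argmin(per_channel_min))  # argmin takes first = shallowest on ties
    l4_channel = sink_row + 1
    layer_map = {}
    for layer in LAYERS:
        ch = l4_channel + config.layer_offsets[layer]
        layer_map[layer] = int(np.clip(ch, 0, n_channels - 1))
    return layer_map


def estimate_layer_map(
    session: Session,
    intensity_pct: int = 100,
    config: LayerAssignmentConfig | None = None,
) -> dict[str, int]:
    """Recover a session's layer map from its own high-intensity trials."""
    trials = [t for t in session.trials if t.intensity_pct == intensity_pct]
    if not trials:
        raise ValueError(f"no trials at intensity {intensity_pct}")
    mean_lfp = np.mean([t.signal for t in trials], axis=0)
    spacing = float(np.diff(session.channel_depths_um).mean())
    csd = compute_csd(mean_lfp, spacing_um=spacing)
    return assign_layers(csd, session.channel_depths_um, config=config)
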