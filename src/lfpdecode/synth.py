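"""Synthetic laminar LFP cohorts.

Generates trials that emulate multi-electrode array recordings from mouse
barrel cortex during a go/no-go whisker detection task: spontaneous
background activity on a laminar probe, a stereotyped evoked deflection
whose amplitude grows with stimulus intensity, a monotone psychometric
lick response, and injectable recording artifacts (saturation, bursts,
50 Hz line noise, early licks).

Conventions
-----------
* Sampling rate 1,000 Hz; every trial spans [-420, +120) ms around stimulus
  onset (540 samples, half-open).
* Signals are in millivolts, channels ordered from superficial to deep.
* Stimulus intensity is a percentage of the maximal whisker deflection,
  one of {0, 20, 40, 60, 80, 100}; 0 % is a catch trial.
* All randomness flows from a single ``numpy`` Generator seeded from the
  config, so equal configs produce bitwise-equal cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

SAMPLING_RATE_HZ = 1000.0
TRIAL_START_MS = -420.0
TRIAL_END_MS = 120.0
N_SAMPLES = int(round((TRIAL_END_MS - TRIAL_START_MS) * SAMPLING_RATE_HZ / 1000.0))

LAYERS = ("L2/3", "L4", "L5", "L6")
INTENSITIES = (0, 20, 40, 60, 80, 100)
ARTIFACT_KINDS = ("saturation", "burst", "line_noise", "early_lick")

#: window of opportunity for a rewarded lick, ms after stimulus onset
WOP_MS = (100.0, 500.0)


class GeneratorConfigError(ValueError):
    """A generator configuration field is invalid; the message names it."""


def time_grid() -> np.ndarray:
    """Trial time axis in ms: [-420, +120) at 1 kHz, 0 = stimulus onset."""
    return TRIAL_START_MS + np.arange(N_SAMPLES) * (1000.0 / SAMPLING_RATE_HZ)


@dataclass
class Trial:
    """One behavioural trial with its multi-channel LFP.

    ``signal`` is channels x samples in mV on the grid returned by
    :func:`time_grid`.  ``lick_latency_ms`` is ``None`` when the animal did
    not lick.  ``qc_flags`` records artifacts injected by construction;
    detection is the preprocessing module's job.
    """

    trial_id: str
    mouse_id: str
    session_id: str
    signal: np.ndarray
    intensity_pct: int
    lick_latency_ms: float | None = None
    qc_flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[1] != N_SAMPLES:
            raise ValueError(
                f"signal must be channels x {N_SAMPLES} samples, got {self.signal.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.intensity_pct not in INTENSITIES:
            raise ValueError(f"intensity_pct must be one of {INTENSITIES}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def is_catch(self) -> bool:
        return self.intensity_pct == 0

    def replace(self, **kwargs) -> "Trial":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Session:
    session_id: str
    mouse_id: str
    trials: list[Trial]
    channel_depths_um: np.ndarray
    layer_map: dict[str, int]

    def __post_init__(self) -> None:
        self.channel_depths_um = np.asarray(self.channel_depths_um, dtype=float)
        if np.any(np.diff(self.channel_depths_um) <= 0):
            raise ValueError("channel depths must be strictly increasing")
        if not set(self.layer_map) <= set(LAYERS):
            raise ValueError(f"layer_map keys must be within {LAYERS}")


@dataclass
class Mouse:
    mouse_id: str
    sessions: list[Session]


@dataclass
class Cohort:
    mice: list[Mouse]
    config: "GeneratorConfig | None" = None

    def iter_sessions(self) -> Iterator[Session]:
        for mouse in self.mice:
            yield from mouse.sessions

    def iter_trials(self) -> Iterator[Trial]:
        for session in self.iter_sessions():
            yield from session.trials

    @property
    def n_trials(self) -> int:
        return sum(len(s.trials) for s in self.iter_sessions())

    @property
    def mouse_ids(self) -> list[str]:
        return [m.mouse_id for m in self.mice]


@dataclass
class PsychometricParams:
    """Weibull-type psychometric function for the lick response.

    Response probability at intensity ``I`` (percent) is

        p(I) = fa + (asymptote - fa) * (1 - exp(-(I / midpoint)**slope))

    which equals the false-alarm rate exactly at I = 0 and rises
    monotonically to the asymptote.  Lick latencies are drawn from a normal
    distribution truncated to the window of opportunity.
    """

    false_alarm_rate: float = 0.1
    asymptote: float = 0.95
    midpoint_pct: float = 40.0
    slope: float = 2.0
    latency_mean_ms: float = 220.0
    latency_sd_ms: float = 80.0

    def response_probability(self, intensity_pct: float) -> float:
        if intensity_pct < 0:
            raise ValueError("intensity must be >= 0")
        p_detect = 1.0 - np.exp(-((intensity_pct / self.midpoint_pct) ** self.slope))
        return float(self.false_alarm_rate + (self.asymptote - self.false_alarm_rate) * p_detect)


@dataclass
class GeneratorConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the emulated experiment: four mice, sessions of
    50 catch trials plus 50 repeats of each of five non-zero intensities
    (300 trials, 83 % stimulus trials), a laminar probe with 25 um channel
    spacing split evenly over layers L2/3, L4, L5 and L6, and an evoked
    deflection that is largest in layer 4.
    """

    n_mice: int = 4
    sessions_per_mouse: int = 1
    n_catch: int = 50
    intensity_repeats: int = 50

    # probe geometry
    n_channels: int = 12
    channel_spacing_um: float = 25.0
    top_depth_um: float = 150.0

    # spontaneous background: AR(1) per channel with shared innovations
    ar_coeff: float = 0.97
    noise_scale_mv: float = 0.1
    channel_correlation: float = 0.2

    # evoked response
    peak_latency_ms: float = 7.0
    peak_amplitude_mv: float = 0.4
    rise_ms: float = 2.0
    decay_ms: float = 15.0
    layer_multipliers: dict = field(
        default_factory=lambda: {"L2/3": 0.5, "L4": 1.0, "L5": 0.7, "L6": 0.4}
    )
    within_layer_taper: float = 0.2
    stim_60hz_amplitude_mv: float = 0.0

    # artifact models
    line_noise_amplitude_mv: float = 0.5
    saturation_amplitude_mv: float = 2.5
    burst_amplitude_mv: float = 1.5
    lick_artifact_amplitude_mv: float = 0.8
    artifact_rates: dict = field(
        default_factory=lambda: {k: 0.0 for k in ARTIFACT_KINDS}
    )

    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_mice", "sessions_per_mouse", "n_catch", "intensity_repeats"):
            if getattr(self, name) < 0:
                raise GeneratorConfigError(f"{name} must be >= 0")
        if self.n_channels < 4 or self.n_channels % 4 != 0:
            raise GeneratorConfigError("n_channels must be a positive multiple of 4")
        if self.channel_spacing_um <= 0:
            raise GeneratorConfigError("channel_spacing_um must be > 0")
        if not 0.0 <= self.channel_correlation <= 1.0:
            raise GeneratorConfigError("channel_correlation must be in [0, 1]")
        if not -1.0 < self.ar_coeff < 1.0:
            raise GeneratorConfigError("ar_coeff must be in (-1, 1)")
        for name in (
            "noise_scale_mv",
            "peak_amplitude_mv",
            "stim_60hz_amplitude_mv",
            "line_noise_amplitude_mv",
            "burst_amplitude_mv",
            "lick_artifact_amplitude_mv",
        ):
            if getattr(self, name) < 0:
                raise GeneratorConfigError(f"{name} must be >= 0")
        if set(self.layer_multipliers) != set(LAYERS):
            raise GeneratorConfigError("layer_multipliers must cover all four layers")
        l4 = self.layer_multipliers["L4"]
        if any(self.layer_multipliers[l] > l4 for l in LAYERS):
            raise GeneratorConfigError("layer_multipliers: L4 must be the largest")
        if not 0.0 <= self.within_layer_taper < 1.0:
            raise GeneratorConfigError("within_layer_taper must be in [0, 1)")
        for kind, rate in self.artifact_rates.items():
            if kind not in ARTIFACT_KINDS:
                raise GeneratorConfigError(f"artifact_rates: unknown kind {kind!r}")
            if not 0.0 <= rate <= 1.0:
                raise GeneratorConfigError(f"artifact_rates[{kind!r}] must be in [0, 1]")
        pp = self.psychometric
        if not 0.0 <= pp.false_alarm_rate <= 1.0:
            raise GeneratorConfigError("psychometric.false_alarm_rate must be in [0, 1]")
        if not pp.false_alarm_rate <= pp.asymptote <= 1.0:
            raise GeneratorConfigError(
                "psychometric.asymptote must be in [false_alarm_rate, 1]"
            )
        if pp.midpoint_pct <= 0 or pp.slope <= 0:
            raise GeneratorConfigError("psychometric midpoint and slope must be > 0")

    # --- probe layout -----------------------------------------------------

    def channel_depths(self) -> np.ndarray:
        return self.top_depth_um + np.arange(self.n_channels) * self.channel_spacing_um

    def channel_layers(self) -> list[str]:
        """Layer assignment of every channel: four contiguous equal bands."""
        per = self.n_channels // 4
        return [LAYERS[c // per] for c in range(self.n_channels)]

    def layer_map(self) -> dict[str, int]:
        """Representative (most central) channel per layer."""
        per = self.n_channels // 4
        return {layer: i * per + per // 2 for i, layer in enumerate(LAYERS)}

    def channel_multipliers(self) -> np.ndarray:
        """Per-channel evoked amplitude scale.

        The layer multiplier is tapered within each band so the central
        channel carries the full layer amplitude and the band edges carry
        ``1 - within_layer_taper`` of it; this yields a depth profile whose
        curvature (hence the CSD sink) is sharpest at the L4 centre.
        """
        per = self.n_channels // 4
        centers = self.layer_map()
        mult = np.empty(self.n_channels)
        for c, layer in enumerate(self.channel_layers()):
            dist = abs(c - centers[layer]) / max(per // 2, 1)
            mult[c] = self.layer_multipliers[layer] * (1.0 - self.within_layer_taper * dist)
        return mult


# ---------------------------------------------------------------------------
# component generators


def evoked_kernel(
    intensity_pct: int,
    layer: str,
    grid: np.ndarray | None = None,
    config: GeneratorConfig | None = None,
) -> np.ndarray:
    """Stimulus-evoked LFP waveform for one layer, in mV per sample.

    A difference-of-exponentials negative deflection starting at stimulus
    onset, with its most negative value at ``peak_latency_ms`` (default
    7 ms, within the 5-10 ms range typical of the barrel-cortex evoked
    response) and a magnitude linear in stimulus intensity, scaled by the
    per-layer multiplier (largest in L4).  An optional 60 Hz
    stimulus-following component is confined to the 100 ms vibration.
    """
    config = config or GeneratorConfig()
    if intensity_pct not in INTENSITIES:
        raise ValueError(f"intensity_pct must be one of {INTENSITIES}")
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}")
    if grid is None:
        grid = time_grid()
    amp = config.peak_amplitude_mv * config.layer_multipliers[layer] * intensity_pct / 100.0
    return amp * _unit_kernel(grid, config)


def _unit_kernel(grid: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Evoked waveform with peak value -1, zero before stimulus onset."""
    tau_r, tau_d = config.rise_ms, config.decay_ms
    # peak time of exp(-t/tau_d) - exp(-t/tau_r)
    t_peak = np.log(tau_d / tau_r) / (1.0 / tau_r - 1.0 / tau_d)
    t0 = max(config.peak_latency_ms - t_peak, 0.0)
    t = grid - t0
    shape = np.where(t >= 0, np.exp(-t / tau_d) - np.exp(-t / tau_r), 0.0)
    peak = np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_r)
    kernel = -shape / peak
    if config.stim_60hz_amplitude_mv > 0:
        in_stim = (grid >= 0) & (grid < 100.0)
        kernel = kernel + np.where(
            in_stim,
            -config.stim_60hz_amplitude_mv
            / max(config.peak_amplitude_mv, 1e-12)
            * np.sin(2 * np.pi * 60.0 * grid / 1000.0),
            0.0,
        )
    kernel[grid < 0] = 0.0
    return kernel


def behavioral_response(
    intensity_pct: int,
    params: PsychometricParams,
    rng: np.random.Generator,
) -> float | None:
    """Draw a lick latency (ms) or ``None`` for a non-response trial.

    The response probability follows the monotone psychometric function in
    :class:`PsychometricParams`; emitted latencies fall inside the window
    of opportunity (+100 to +500 ms).
    """
    p = params.response_probability(intensity_pct)
    if rng.random() >= p:
        return None
    lat = rng.normal(params.latency_mean_ms, params.latency_sd_ms)
    return float(np.clip(lat, WOP_MS[0] + 5.0, WOP_MS[1] - 5.0))


def _background(
    rng: np.random.Generator, n_channels: int, config: GeneratorConfig
) -> np.ndarray:
    """AR(1) spontaneous activity with shared-innovation channel coupling."""
    rho = config.channel_correlation
    common = rng.standard_normal(N_SAMPLES)
    indiv = rng.standard_normal((n_channels, N_SAMPLES))
    innov = np.sqrt(rho) * common[None, :] + np.sqrt(1.0 - rho) * indiv
    phi = config.ar_coeff
    sigma = config.noise_scale_mv * np.sqrt(1.0 - phi**2)
    x = np.empty((n_channels, N_SAMPLES))
    # stationary start
    x[:, 0] = config.noise_scale_mv * innov[:, 0]
    for t in range(1, N_SAMPLES):
        x[:, t] = phi * x[:, t - 1] + sigma * innov[:, t]
    return x


# ---------------------------------------------------------------------------
# artifacts


def inject_artifact(
    trial: Trial,
    kind: str,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> Trial:
    """Return a copy of ``trial`` carrying one injected recording artifact.

    Each artifact is constructed so the matching detector in the
    preprocessing module fires at its default threshold: saturation pushes
    a channel beyond +/-2 mV, a burst writes a common high-amplitude
    waveform on every channel for 20 ms, line noise adds a continuous
    50 Hz sinusoid, and an early lick sets a latency inside [0, 100) ms
    together with a broadband movement transient.
    """
    config = config or GeneratorConfig()
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; valid: {ARTIFACT_KINDS}")
    grid = time_grid()
    signal = trial.signal.copy()
    lick = trial.lick_latency_ms

    if kind == "saturation":
        ch = int(rng.integers(trial.n_channels))
        t0 = int(rng.integers(20, N_SAMPLES - 40))
        width = 15
        pulse = config.saturation_amplitude_mv * np.hanning(2 * width + 1)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        signal[ch, t0 - width : t0 + width + 1] += sign * pulse
    elif kind == "burst":
        n_win = 20
        t0 = int(rng.integers(0, N_SAMPLES - n_win))
        t = np.arange(n_win) / SAMPLING_RATE_HZ
        wave = config.burst_amplitude_mv * np.sin(2 * np.pi * 90.0 * t) * np.hanning(n_win)
        signal[:, t0 : t0 + n_win] += wave[None, :]
    elif kind == "line_noise":
        phase = rng.uniform(0, 2 * np.pi)
        wave = config.line_noise_amplitude_mv * np.sin(
            2 * np.pi * 50.0 * grid / 1000.0 + phase
        )
        signal += wave[None, :]
    elif kind == "early_lick":
        lick = float(rng.uniform(5.0, 95.0))
        onset = np.searchsorted(grid, lick)
        dur = min(60, N_SAMPLES - onset)
        transient = (
            config.lick_artifact_amplitude_mv
            * rng.standard_normal((trial.n_channels, dur))
            * np.hanning(2 * dur)[dur:][None, :]
        )
        signal[:, onset : onset + dur] += transient

    return trial.replace(
        signal=signal, lick_latency_ms=lick, qc_flags=trial.qc_flags | {kind}
    )


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort: mice -> sessions -> trials.

    Per session the stimulus list holds ``n_catch`` catch trials and
    ``intensity_repeats`` repeats of each non-zero intensity, presented in
    a randomized order.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = time_grid()
    mults = config.channel_multipliers()
    kernel_cache = {
        i: _unit_kernel(grid, config) * (config.peak_amplitude_mv * i / 100.0)
        for i in INTENSITIES
    }

    mice = []
    for m in range(config.n_mice):
        mouse_id = f"mouse{m:02d}"
        sessions = []
        for s in range(config.sessions_per_mouse):
            session_id = f"{mouse_id}_sess{s:02d}"
            intensities = [0] * config.n_catch
            for i in INTENSITIES[1:]:
                intensities.extend([i] * config.intensity_repeats)
            intensities = np.array(intensities)
            rng.shuffle(intensities)

            trials = []
            for k, intensity in enumerate(intensities):
                signal = _background(rng, config.n_channels, config)
                if intensity > 0:
                    signal += mults[:, None] * kernel_cache[int(intensity)][None, :]
                lick = behavioral_response(int(intensity), config.psychometric, rng)
                trial = Trial(
                    trial_id=f"{session_id}_t{k:03d}",
                    mouse_id=mouse_id,
                    session_id=session_id,
                    signal=signal,
                    intensity_pct=int(intensity),
                    lick_latency_ms=lick,
                )
                for kind in ARTIFACT_KINDS:
                    if rng.random() < config.artifact_rates.get(kind, 0.0):
                        trial = inject_artifact(trial, kind, rng, config)
                trials.append(trial)
            sessions.append(
                Session(
                    session_id=session_id,
                    mouse_id=mouse_id,
                    trials=trials,
                    channel_depths_um=config.channel_depths(),
                    layer_map=config.layer_map(),
                )
            )
        mice.append(Mouse(mouse_id=mouse_id, sessions=sessions))
    return Cohort(mice=mice, config=config)


# ---------------------------------------------------------------------------
# archive I/O


def save_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort archive: JSON manifest, CSV trial table, NPZ signals.

    Layout: ``manifest.json`` (config, seed, hierarchy), ``trials.csv``
    (one row per trial: ids, intensity, lick latency, qc flags) and one
    ``signals_<session>.npz`` per session keyed by trial id.  Metadata
    round-trips losslessly; signals round-trip exactly (float64).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"format_version": 1, "mice": []}
    if cohort.config is not None:
        cfg = dataclasses.asdict(cohort.config)
        cfg["psychometric"] = dataclasses.asdict(cohort.config.psychometric)
        manifest["config"] = cfg
    rows = []
    for mouse in cohort.mice:
        m_entry = {"mouse_id": mouse.mouse_id, "sessions": []}
        for sess in mouse.sessions:
            m_entry["sessions"].append(
                {
                    "session_id": sess.session_id,
                    "channel_depths_um": sess.channel_depths_um.tolist(),
                    "layer_map": sess.layer_map,
                    "trial_ids": [t.trial_id for t in sess.trials],
                }
            )
            np.savez_compressed(
                path / f"signals_{sess.session_id}.npz",
                **{t.trial_id: t.signal for t in sess.trials},
            )
            for t in sess.trials:
                rows.append(
                    {
                        "trial_id": t.trial_id,
                        "mouse": t.mouse_id,
                        "session": t.session_id,
                        "intensity": t.intensity_pct,
                        "lick_latency": t.lick_latency_ms,
                        "qc_flags": ";".join(sorted(t.qc_flags)),
                    }
                )
        manifest["mice"].append(m_entry)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    pd.DataFrame(rows).to_csv(path / "trials.csv", index=False)


def load_cohort(path: str | Path) -> Cohort:
    """Read a cohort archive written by :func:`save_cohort`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    meta = pd.read_csv(path / "trials.csv", dtype={"qc_flags": str}, keep_default_na=False)
    meta = meta.set_index("trial_id")
    config = None
    if "config" in manifest:
        cfg = dict(manifest["config"])
        cfg["psychometric"] = PsychometricParams(**cfg["psychometric"])
        config = GeneratorConfig(**cfg)
    mice = []
    for m_entry in manifest["mice"]:
        sessions = []
        for s_entry in m_entry["sessions"]:
            with np.load(path / f"signals_{s_entry['session_id']}.npz") as signals:
                trials = []
                for tid in s_entry["trial_ids"]:
                    row = meta.loc[tid]
                    lick = row["lick_latency"]
                    lick = None if lick == "" else float(lick)
                    flags = frozenset(f for f in str(row["qc_flags"]).split(";") if f)
                    trials.append(
                        Trial(
                            trial_id=tid,
                            mouse_id=row["mouse"],
                            session_id=row["session"],
                            signal=signals[tid],
                            intensity_pct=int(row["intensity"]),
                            lick_latency_ms=lick,
                            qc_flags=flags,
                        )
                    )
            sessions.append(
                Session(
                    session_id=s_entry["session_id"],
                    mouse_id=m_entry["mouse_id"],
                    trials=trials,
                    channel_depths_um=np.array(s_entry["channel_depths_um"]),
                    layer_map=s_entry["layer_map"],
                )
            )
        mice.append(Mouse(mouse_id=m_entry["mouse_id"], sessions=sessions))
    return Cohort(mice=mice, config=config)
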