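"""Synthetic inputs for every pipeline stage.

Three generators stand in for the study's raw data:

* :func:`generate_ecog` — chronic single-channel ECoG (512 Hz, 0.3–160 Hz
  passband) as band-limited 1/f noise, with seizure events of 50–200 s
  superimposed as a rhythmic spike-wave component, plus an exact ground-truth
  annotation track.
* :func:`generate_trial_counts` — per-animal daily/weekly seizure counts for a
  two-arm trial, drawn from a day-level gamma-Poisson (negative binomial)
  process with optional Neyman–Scott burst clustering, aggregated to weeks.
* :func:`generate_iv_dataset` — voltage-clamp step-protocol data from a
  Boltzmann conductance model: per-step plateau traces, currents, capacitance
  and series resistance.

Every generator draws all randomness from one seeded ``numpy`` generator per
call; identical seed + config gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_io import AnnotationTrack, Recording

__all__ = [
    "EcogSimConfig",
    "SeizureEventSpec",
    "TrialDesign",
    "IVSimConfig",
    "IVDataset",
    "generate_ecog",
    "draw_seizure_events",
    "generate_trial_counts",
    "generate_iv_dataset",
]


# ---------------------------------------------------------------------------
# ECoG
# ---------------------------------------------------------------------------

@dataclass
class EcogSimConfig:
    """Parameters of the synthetic ECoG generator.

    ``seizure_amplitude_ratio`` is the RMS of the ictal spike-wave component
    relative to the baseline SD; must exceed 1 so that seizures are louder
    than background.
    """

    duration: float = 3600.0
    sampling_rate: float = 512.0
    passband: tuple[float, float] = (0.3, 160.0)
    baseline_sd: float = 50.0
    seizure_amplitude_ratio: float = 10.0
    seizure_fundamental: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.seizure_amplitude_ratio <= 1:
            raise ValueError("seizure_amplitude_ratio must exceed 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class SeizureEventSpec:
    """A planned seizure: onset (s) and duration (s, typically 50–200)."""

    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


def _validate_events(events: list[SeizureEventSpec], duration: float) -> list[SeizureEventSpec]:
    evs = sorted(events, key=lambda e: e.onset)
    for i, e in enumerate(evs):
        if e.offset > duration:
            raise ValueError(
                f"event ({e.onset}, {e.offset}) extends past recording of {duration} s"
            )
        if i > 0 and e.onset < evs[i - 1].offset:
            raise ValueError(
                f"events overlap: ({evs[i-1].onset}, {evs[i-1].offset}) and "
                f"({e.onset}, {e.offset})"
            )
    return evs


def draw_seizure_events(
    duration: float,
    n_events: int,
    rng: np.random.Generator,
    duration_range: tuple[float, float] = (50.0, 200.0),
    margin: float = 30.0,
) -> list[SeizureEventSpec]:
    """Place ``n_events`` non-overlapping seizures uniformly at random.

    Event durations are uniform on ``duration_range`` (the 50–200 s range
    typical of the focal neocortical model this emulates); events keep at
    least ``margin`` seconds of baseline between them.
    """
    durs = rng.uniform(*duration_range, size=n_events)
    total = durs.sum() + margin * (n_events + 1)
    if total > duration:
        raise ValueError(
            f"cannot place {n_events} events totalling {durs.sum():.0f} s in "
            f"{duration:.0f} s with {margin:.0f} s margins"
        )
    # distribute the leftover baseline time as random gaps between events
    slack = duration - total
    gaps = rng.dirichlet(np.ones(n_events + 1)) * slack + margin
    events, t = [], 0.0
    for g, d in zip(gaps, durs):
        t += g
        events.append(SeizureEventSpec(onset=t, duration=float(d)))
        t += d
    return events


def _pink_noise(n: int, rng: np.random.Generator, fs: float) -> np.ndarray:
    """Gaussian white noise shaped to a 1/f power spectrum (above 1 Hz)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs >= 1.0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])  # amplitude ∝ f^-1/2 → power ∝ 1/f
    return np.fft.irfft(spec * shaping, n=n)


def _spike_wave(t: np.ndarray, fundamental: float) -> np.ndarray:
    """Rhythmic ictal waveform: fundamental + 2 harmonics, exponentially sharpened."""
    base = (
        np.sin(2 * np.pi * fundamental * t)
        + 0.5 * np.sin(2 * np.pi * 2 * fundamental * t)
        + 0.25 * np.sin(2 * np.pi * 3 * fundamental * t)
    )
    w = np.sign(base) * (np.expm1(1.5 * np.abs(base)))  # sharpen peaks into spikes
    return w


def generate_ecog(
    config: EcogSimConfig, events: list[SeizureEventSpec]
) -> tuple[Recording, AnnotationTrack]:
    """Simulate an ECoG recording with ground-truth seizure annotations.

    Baseline is 1/f-shaped Gaussian noise band-passed to the configured
    passband with a zero-phase filter and scaled to ``baseline_sd``. Each
    seizure superimposes the spike-wave component at
    ``seizure_amplitude_ratio × baseline_sd`` RMS, with 5 s linear
    onset/offset ramps (shortened for events under 10 s). The annotation
    track mirrors the event list exactly.
    """
    events = _validate_events(events, config.duration)
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    rng = np.random.default_rng(config.seed)

    x = _pink_noise(n, rng, fs)
    lo, hi = config.passband
    sos = sps.butter(4, [lo, min(hi, 0.49 * fs)], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    x *= config.baseline_sd / x.std()

    amp = config.seizure_amplitude_ratio * config.baseline_sd
    t_all = np.arange(n) / fs
    for ev in events:
        a, b = int(round(ev.onset * fs)), int(round(ev.offset * fs))
        seg_t = t_all[a:b]
        w = _spike_wave(seg_t, config.seizure_fundamental)
        w = w / np.sqrt(np.mean(w**2))
        ramp_s = min(5.0, ev.duration / 2)
        env = np.minimum.reduce(
            [
                np.ones(b - a),
                (seg_t - ev.onset) / ramp_s,
                (ev.offset - seg_t) / ramp_s,
            ]
        )
        x[a:b] += amp * w * np.clip(env, 0.0, 1.0)

    rec = Recording(x, fs, config.passband, channel_name="ECoG-sim")
    track = AnnotationTrack(
        [(ev.onset, ev.offset, "seizure") for ev in events], config.duration
    )
    return rec, track


# ---------------------------------------------------------------------------
# Trial counts
# ---------------------------------------------------------------------------

@dataclass
class TrialDesign:
    """Design of a two-arm seizure-count trial.

    ``baseline_rate`` is λ, the mean weekly seizure count before treatment;
    ``treatment_rate_ratio`` multiplies the treated group's post-treatment
    rate (0.6 = the 40% reduction the trials were powered for).
    ``dispersion`` ≥ 0 adds day-level gamma-Poisson overdispersion (0 = pure
    Poisson); ``cluster_intensity`` ≥ 0 adds Neyman–Scott burstiness (mean
    extra events per cluster), giving day-level Fano factors above 1.
    ``week_trend`` is a log-scale slope applied over post-treatment weeks in
    both groups (seizures abate naturally in these models).
    """

    n_per_group: int = 8
    baseline_periods: int = 1
    post_periods: int = 4
    baseline_rate: float = 10.0
    treatment_rate_ratio: float = 0.6
    week_trend: float = 0.0
    dispersion: float = 0.0
    cluster_intensity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        if self.baseline_rate <= 0 or self.treatment_rate_ratio <= 0:
            raise ValueError("rates must be positive")
        if self.dispersion < 0 or self.cluster_intensity < 0:
            raise ValueError("dispersion and cluster_intensity must be >= 0")
        if self.baseline_periods < 1 or self.post_periods < 1:
            raise ValueError("need at least one baseline and one post period")


def _draw_day_count(rate: float, c: float, rng: np.random.Generator) -> int:
    """Neyman–Scott day count: Poisson cluster centres, geometric cluster sizes.

    Mean cluster size is 1 + c; centre rate rate/(1+c), so the marginal mean
    stays ``rate`` while the Fano factor grows with ``c``.
    """
    if c == 0:
        return int(rng.poisson(rate))
    m = 1.0 + c
    centres = rng.poisson(rate / m)
    if centres == 0:
        return 0
    # geometric on {0,1,...} with mean c -> success prob 1/(1+c)
    extras = rng.geometric(1.0 / m, size=centres) - 1
    return int(centres + extras.sum())


def generate_trial_counts(design: TrialDesign) -> pd.DataFrame:
    """Simulate a seizure-count table for a randomized two-arm trial.

    Returns a long-format table with columns ``animal_id, group, period_type,
    period_index, count, is_baseline``. Day rows (period_type ``day``) are the
    primitive draws; week rows are their 7-day aggregates. Week indices follow
    the trial convention: −1 is the last baseline week ("week Bl"), 0 the
    first post-treatment week. Day indices use the same origin (day 0 = first
    post-treatment day).

    Group labels are assigned by seeded randomization of the animal order.
    """
    rng = np.random.default_rng(design.seed)
    n_total = 2 * design.n_per_group
    animals = [f"a{i:03d}" for i in range(n_total)]
    order = rng.permutation(n_total)
    groups = {animals[j]: ("treated" if k < design.n_per_group else "control")
              for k, j in enumerate(order)}

    weeks = list(range(-design.baseline_periods, design.post_periods))
    rows = []
    for animal in animals:
        g = groups[animal]
        for w in weeks:
            rate_week = design.baseline_rate
            if w >= 0:
                rate_week *= np.exp(design.week_trend * w)
                if g == "treated":
                    rate_week *= design.treatment_rate_ratio
            week_total = 0
            for d in range(7):
                day_rate = rate_week / 7.0
                if design.dispersion > 0:
                    shape = 1.0 / design.dispersion
                    day_rate *= rng.gamma(shape, design.dispersion)
                cnt = _draw_day_count(day_rate, design.cluster_intensity, rng)
                rows.append((animal, g, "day", w * 7 + d, cnt, w < 0))
                week_total += cnt
            rows.append((animal, g, "week", w, week_total, w < 0))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "group", "period_type", "period_index", "count", "is_baseline"],
    )


# ---------------------------------------------------------------------------
# Voltage-clamp IV datasets
# ---------------------------------------------------------------------------

def boltzmann(v: np.ndarray, a1: float, a2: float, v_half: float, k: float) -> np.ndarray:
    """Rising four-parameter Boltzmann sigmoid G(V)."""
    return a1 + (a2 - a1) / (1.0 + np.exp((v_half - v) / k))


@dataclass
class IVSimConfig:
    """Ground truth for a simulated voltage-clamp cell.

    ``true_params`` = (A1, A2, V0.5, k): minimum and maximum conductance
    density (nS/pF), half-activation voltage (mV) and slope factor (mV).
    Defaults mirror the protocol this emulates: −80 mV hold, 200 ms steps in
    10 mV increments up to +20 mV, K⁺ reversal −91.34 mV, half-activation
    −28.2 mV.
    """

    true_params: tuple[float, float, float, float] = (0.0, 1.0, -28.2, 8.0)
    reversal_potential: float = -91.34
    voltage_steps: tuple[float, ...] = tuple(range(-80, 30, 10))
    noise_sd: float = 0.0
    capacitance: float = 15.0
    series_resistance: float = 6.0
    holding_current: float = -20.0
    holding_potential: float = -80.0
    step_duration_ms: float = 200.0
    pre_step_ms: float = 50.0
    trace_sampling_rate: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        a1, a2, _, k = self.true_params
        if not a2 > a1:
            raise ValueError("A2 must exceed A1")
        if k <= 0:
            raise ValueError("slope factor k must be positive")
        v = np.asarray(self.voltage_steps, dtype=float)
        if v.size < 2 or np.any(np.diff(v) <= 0):
            raise ValueError("voltage_steps must be strictly increasing")
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")


@dataclass
class IVDataset:
    """Step-protocol currents for one cell.

    ``traces`` is (n_steps, n_samples) in pA at ``trace_sampling_rate``; each
    trace is ``pre_step_ms`` of holding followed by ``step_duration_ms`` of
    step, so the steady state occupies the last 40 ms of the step segment.
    """

    cell_id: str
    voltage_steps: np.ndarray
    traces: np.ndarray
    trace_sampling_rate: float
    capacitance: float
    series_resistance: float
    holding_current: float
    pre_step_ms: float
    step_duration_ms: float
    true_params: tuple[float, float, float, float] | None = None
    reversal_potential: float | None = None


def generate_iv_dataset(config: IVSimConfig, cell_id: str = "cell0") -> IVDataset:
    """Simulate one cell's voltage-step protocol from the Boltzmann model.

    At each step V the plateau current is
    ``I(V) = g(V) · (V − E_rev) · C + I_hold`` with g(V) the Boltzmann
    conductance density; current noise with SD ``noise_sd·|V−E_rev|·C``
    (i.e. ``noise_sd`` in conductance-density units) is added per sample.
    An exponential activation rise (τ = 5 ms) precedes the plateau, so the
    last 40 ms of the step are within numerical tolerance of steady state.
    """
    rng = np.random.default_rng(config.seed)
    v = np.asarray(config.voltage_steps, dtype=float)
    g = boltzmann(v, *config.true_params)  # nS/pF

    fs = config.trace_sampling_rate
    n_pre = int(round(config.pre_step_ms / 1000.0 * fs))
    n_step = int(round(config.step_duration_ms / 1000.0 * fs))
    t_step = np.arange(n_step) / fs * 1000.0  # ms within step

    traces = np.empty((v.size, n_pre + n_step))
    for i, (vi, gi) in enumerate(zip(v, g)):
        plateau = gi * (vi - config.reversal_potential) * config.capacitance
        rise = 1.0 - np.exp(-t_step / 5.0)
        trace = np.concatenate(
            [np.full(n_pre, config.holding_current),
             config.holding_current + plateau * rise]
        )
        if config.noise_sd > 0:
            sd_pa = config.noise_sd * abs(vi - config.reversal_potential) * config.capacitance
            trace = trace + rng.normal(0.0, sd_pa, size=trace.size)
        traces[i] = trace

    return IVDataset(
        cell_id=cell_id,
        voltage_steps=v,
        traces=traces,
        trace_sampling_rate=fs,
        capacitance=config.capacitance,
        series_resistance=config.series_resistance,
        holding_current=config.holding_current,
        pre_step_ms=config.pre_step_ms,
        step_duration_ms=config.step_duration_ms,
        true_params=config.true_params,
        reversal_potential=config.reversal_potential,
    )
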