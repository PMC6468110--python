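"""Recording and annotation containers, standard-format I/O, and epoching.

A :class:`Recording` is a uniformly sampled single-channel ECoG signal in
microvolts. An :class:`AnnotationTrack` is a sorted, non-overlapping list of
labelled time intervals (seconds from recording start, half-open
``[onset, offset)``) that marks seizures — either manual ground truth or
detector output. :func:`epoch_recording` slices a recording into contiguous,
non-overlapping fixed-length epochs (5 s by default), the unit of
classification downstream.

Recordings round-trip through EDF (16-bit, physical units µV) or a lossless
flat-binary + JSON-header pair; annotations and the epoch-label rule live in
plain CSV.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "AnnotationTrack",
    "EpochIndex",
    "write_recording",
    "read_recording",
    "write_annotations",
    "read_annotations",
    "epoch_recording",
    "labels_from_annotations",
]

BASELINE, SEIZURE = 0, 1
LABEL_NAMES = ("baseline", "seizure")


@dataclass
class Recording:
    """Single-channel uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray
        Signal in µV.
    sampling_rate : float
        Samples per second (the chronic-recording transmitters used here
        sample at 512 Hz).
    passband : tuple of float
        Hardware analogue passband in Hz, default (0.3, 160).
    channel_name : str
        Electrode/channel label.
    """

    samples: np.ndarray
    sampling_rate: float
    passband: tuple[float, float] = (0.3, 160.0)
    channel_name: str = "ECoG"
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class AnnotationTrack:
    """Sorted non-overlapping labelled intervals over a recording.

    ``intervals`` is a list of ``(onset_s, offset_s, label)`` with labels in
    {"baseline", "seizure"}; by convention only seizure intervals need to be
    stored (everything else is implicitly baseline).
    """

    intervals: list[tuple[float, float, str]]
    recording_duration: float

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda t: t[0])
        for i, (on, off, lab) in enumerate(ivs):
            if not on < off:
                raise ValueError(f"interval {i}: onset {on} must precede offset {off}")
            if on < 0 or off > self.recording_duration + 1e-9:
                raise ValueError(
                    f"interval {i}: ({on}, {off}) outside recording of "
                    f"{self.recording_duration} s"
                )
            if lab not in LABEL_NAMES:
                raise ValueError(f"interval {i}: unknown label {lab!r}")
            if i > 0 and on < ivs[i - 1][1]:
                raise ValueError(
                    f"intervals overlap: row {i - 1} ({ivs[i - 1][0]}, {ivs[i - 1][1]}) "
                    f"and row {i} ({on}, {off})"
                )
        self.intervals = ivs

    @property
    def seizure_intervals(self) -> list[tuple[float, float]]:
        return [(a, b) for a, b, lab in self.intervals if lab == "seizure"]

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class EpochIndex:
    """Partition of a recording prefix into fixed-length epochs.

    Epoch ``i`` covers samples ``[i*L, (i+1)*L)`` with
    ``L = epoch_length * sampling_rate``; a trailing partial epoch is
    discarded.
    """

    epoch_length: float
    sampling_rate: float
    n_epochs: int
    samples_per_epoch: int = field(init=False)

    def __post_init__(self) -> None:
        self.samples_per_epoch = int(round(self.epoch_length * self.sampling_rate))

    def sample_span(self, i: int) -> tuple[int, int]:
        """Half-open sample span of epoch ``i``."""
        if not 0 <= i < self.n_epochs:
            raise IndexError(f"epoch {i} out of range [0, {self.n_epochs})")
        return i * self.samples_per_epoch, (i + 1) * self.samples_per_epoch

    def time_span(self, i: int) -> tuple[float, float]:
        """Half-open time span of epoch ``i`` in seconds."""
        a, b = self.sample_span(i)
        return a / self.sampling_rate, b / self.sampling_rate

    def epoch_iter(self, samples: np.ndarray):
        for i in range(self.n_epochs):
            a, b = self.sample_span(i)
            yield samples[a:b]


def epoch_recording(recording: Recording, epoch_length: float = 5.0) -> EpochIndex:
    """Divide a recording into contiguous non-overlapping epochs.

    ``n_epochs = floor(duration / epoch_length)``; at 512 Hz with the default
    5 s epochs each epoch holds 2560 samples.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    spp = int(round(epoch_length * recording.sampling_rate))
    n = recording.n_samples // spp
    if n < 1:
        raise ValueError(
            f"recording of {recording.duration:.3f} s is shorter than one "
            f"{epoch_length} s epoch"
        )
    return EpochIndex(epoch_length, recording.sampling_rate, n)


def labels_from_annotations(
    track: AnnotationTrack, index: EpochIndex, min_overlap_fraction: float = 0.5
) -> np.ndarray:
    """Per-epoch integer labels (0 baseline, 1 seizure) from an annotation track.

    An epoch is labelled seizure iff its total overlap with seizure intervals
    is at least ``min_overlap_fraction`` of the epoch length (default one
    half). This overlap rule is a documented configurable default.
    """
    labels = np.zeros(index.n_epochs, dtype=int)
    for i in range(index.n_epochs):
        t0, t1 = index.time_span(i)
        overlap = 0.0
        for on, off in track.seizure_intervals:
            overlap += max(0.0, min(t1, off) - max(t0, on))
        if overlap >= min_overlap_fraction * index.epoch_length - 1e-12:
            labels[i] = SEIZURE
    return labels


# ---------------------------------------------------------------------------
# Annotation CSV round trip (columns: onset_s, offset_s, label)
# ---------------------------------------------------------------------------

def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    df = pd.DataFrame(track.intervals, columns=["onset_s", "offset_s", "label"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_annotations(path: str | Path, recording_duration: float) -> AnnotationTrack:
    df = pd.read_csv(path)
    required = {"onset_s", "offset_s", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    intervals = [
        (float(r.onset_s), float(r.offset_s), str(r.label)) for r in df.itertuples()
    ]
    # AnnotationTrack validation reports overlapping / inverted rows
    return AnnotationTrack(intervals, recording_duration)


# ---------------------------------------------------------------------------
# Recording round trip: EDF (16-bit) and flat binary + JSON header
# ---------------------------------------------------------------------------

# symmetric digital range so that 0 µV is exactly representable
_EDF_DIG_MAX = 32767
_EDF_DIG_MIN = -32767


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording(
    recording: Recording,
    path: str | Path,
    fmt: str = "edf",
    physical_range: float | None = None,
) -> None:
    """Write a recording to ``path`` in ``fmt`` ∈ {"edf", "binary"}.

    EDF stores samples as 16-bit integers over a symmetric physical range
    (default: the smallest power-of-ten-ish range covering the data), so the
    round trip is exact only to half a quantization step. The binary format
    (raw float64 little-endian + ``<path>.json`` header) is lossless.
    """
    path = Path(path)
    if fmt == "binary":
        header = {
            "sampling_rate": recording.sampling_rate,
            "passband": list(recording.passband),
            "channel_name": recording.channel_name,
            "n_samples": recording.n_samples,
            "dtype": "<f8",
            "units": "uV",
        }
        recording.samples.astype("<f8").tofile(path)
        Path(str(path) + ".json").write_text(json.dumps(header, indent=1))
        return
    if fmt != "edf":
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'binary'")

    x = recording.samples
    if physical_range is None:
        peak = float(np.max(np.abs(x))) if x.size else 1.0
        physical_range = max(peak * 1.01, 1.0)
    if np.max(np.abs(x)) > physical_range:
        raise ValueError("samples exceed the declared physical range")

    fs = recording.sampling_rate
    # one data record per second when fs divides evenly, else a single record
    if abs(fs - round(fs)) < 1e-9 and recording.n_samples % int(round(fs)) == 0:
        spr = int(round(fs))
        n_records = recording.n_samples // spr
        record_dur = 1.0
    else:
        spr = recording.n_samples
        n_records = 1
        record_dur = recording.n_samples / fs

    digital = np.clip(
        np.round(x * _EDF_DIG_MAX / physical_range), _EDF_DIG_MIN, _EDF_DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as f:
        # fixed 256-byte header + one 256-byte signal header block
        f.write(_edf_field(0, 8))                       # version
        f.write(_edf_field("ictalpipe subject", 80))
        f.write(_edf_field("ictalpipe recording", 80))
        f.write(_edf_field("01.01.00", 8))              # start date
        f.write(_edf_field("00.00.00", 8))              # start time
        f.write(_edf_field(256 + 256, 8))               # header bytes
        f.write(_edf_field("", 44))                     # reserved
        f.write(_edf_field(n_records, 8))
        dur = f"{record_dur:.6f}".rstrip("0").rstrip(".")
        f.write(_edf_field(dur, 8))
        f.write(_edf_field(1, 4))                       # number of signals
        f.write(_edf_field(recording.channel_name, 16))
        f.write(_edf_field("AgAgCl electrode", 80))
        f.write(_edf_field("uV", 8))
        f.write(_edf_field(f"{-physical_range:g}", 8))
        f.write(_edf_field(f"{physical_range:g}", 8))
        f.write(_edf_field(_EDF_DIG_MIN, 8))
        f.write(_edf_field(_EDF_DIG_MAX, 8))
        f.write(_edf_field(f"HP:{recording.passband[0]}Hz LP:{recording.passband[1]}Hz", 80))
        f.write(_edf_field(spr, 8))
        f.write(_edf_field("", 32))                     # reserved per signal
        digital.tofile(f)


def read_recording(
    path: str | Path,
    fmt: str = "edf",
    expected_sampling_rate: float | None = None,
) -> Recording:
    """Read a recording written by :func:`write_recording`.

    EDF reading goes through :mod:`mne`; physical units are converted back to
    µV. ``expected_sampling_rate`` (if given) is validated against the file.
    """
    path = Path(path)
    if fmt == "binary":
        hpath = Path(str(path) + ".json")
        if not hpath.exists():
            raise FileNotFoundError(f"missing JSON header {hpath}")
        header = json.loads(hpath.read_text())
        x = np.fromfile(path, dtype=header["dtype"])
        if x.size != header["n_samples"]:
            raise ValueError(
                f"corrupt binary recording: header says {header['n_samples']} "
                f"samples, file holds {x.size}"
            )
        rec = Recording(
            x.astype(float),
            header["sampling_rate"],
            tuple(header["passband"]),
            header["channel_name"],
        )
    elif fmt == "edf":
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        x = raw.get_data()[0] * 1e6  # mne returns Volts
        hp = raw.info.get("highpass", 0.0) or 0.0
        lp = raw.info.get("lowpass", raw.info["sfreq"] / 2)
        rec = Recording(x, raw.info["sfreq"], (hp, lp), raw.ch_names[0])
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'binary'")

    if expected_sampling_rate is not None and not math.isclose(
        rec.sampling_rate, expected_sampling_rate, rel_tol=1e-9
    ):
        raise ValueError(
            f"sampling-rate mismatch: file has {rec.sampling_rate} Hz, "
            f"expected {expected_sampling_rate} Hz"
        )
    return rec
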