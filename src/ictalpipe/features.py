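"""Per-epoch features: band powers, line length, and distributional extras.

Each 5 s epoch is summarized by the power in a set of frequency bands
(averaged modified periodogram: 1 s segments, 50% overlap, Hann taper), the
line length Σ|x[i+1] − x[i]| — a cheap surrogate for amplitude × frequency
content — and optional variance / skewness / kurtosis / max-abs extras.
Standardization is fit on a designated training set and re-applied to
held-out epochs, never re-fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .signal_io import EpochIndex, Recording

__all__ = [
    "FeatureSpec",
    "EpochFeatureMatrix",
    "band_power",
    "line_length",
    "build_feature_matrix",
    "DEFAULT_BANDS",
]

# Default band set (Hz); the canonical EEG rhythm bands up to the transmitter
# passband edge. A documented default, not a reproduction target.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
    ("gamma", 30.0, 70.0),
    ("high_gamma", 70.0, 120.0),
)

_EXTRA_FUNCS = {
    "variance": lambda x: float(np.var(x)),
    "skewness": lambda x: float(spstats.skew(x)),
    "kurtosis": lambda x: float(spstats.kurtosis(x)),
    "max_abs": lambda x: float(np.max(np.abs(x))),
}


@dataclass
class FeatureSpec:
    """Which features to compute per epoch."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    include_line_length: bool = True
    extras: tuple[str, ...] = ("variance", "skewness", "kurtosis", "max_abs")
    standardize: bool = True

    def __post_init__(self) -> None:
        names = [b[0] for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name}: low edge must be below high edge")
        for e in self.extras:
            if e not in _EXTRA_FUNCS:
                raise ValueError(f"unknown extra feature {e!r}")

    @property
    def feature_names(self) -> list[str]:
        names = [f"bp_{b[0]}" for b in self.bands]
        if self.include_line_length:
            names.append("line_length")
        names.extend(self.extras)
        return names


@dataclass
class EpochFeatureMatrix:
    """n_epochs × n_features matrix aligned with an :class:`EpochIndex`.

    If standardized, ``mean_``/``sd_`` hold the per-feature z-score
    parameters fitted on the training epochs.
    """

    values: np.ndarray
    feature_names: list[str]
    epoch_index: EpochIndex
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.values.shape != (self.epoch_index.n_epochs, len(self.feature_names)):
            raise ValueError("feature matrix shape does not match index/names")


def band_power(
    epoch: np.ndarray,
    band: tuple[float, float],
    sampling_rate: float,
    segment_length_s: float = 1.0,
) -> float:
    """Signal power (µV²) in a frequency band, from an averaged periodogram.

    Welch's method with mean removal, ``segment_length_s`` Hann-tapered
    segments and 50% overlap; the band power is the integral of the power
    spectral density over ``band``.
    """
    lo, hi = band
    if not 0 <= lo < hi <= sampling_rate / 2:
        raise ValueError(
            f"band ({lo}, {hi}) Hz must lie within (0, {sampling_rate / 2}) Hz"
        )
    x = np.asarray(epoch, dtype=float)
    nper = min(int(round(segment_length_s * sampling_rate)), x.size)
    f, pxx = sps.welch(
        x - x.mean(), fs=sampling_rate, window="hann",
        nperseg=nper, noverlap=nper // 2, detrend=False,
    )
    mask = (f >= lo) & (f <= hi)
    return float(np.trapezoid(pxx[mask], f[mask]))


def line_length(epoch: np.ndarray, per_sample: bool = False) -> float:
    """Line length Σ|x[i+1] − x[i]| of an epoch (µV).

    ``per_sample=True`` divides by the number of differences, making the
    value comparable across epoch lengths.
    """
    x = np.asarray(epoch, dtype=float)
    if x.size < 2:
        raise ValueError("line length needs at least 2 samples")
    ll = float(np.sum(np.abs(np.diff(x))))
    return ll / (x.size - 1) if per_sample else ll


def build_feature_matrix(
    recording: Recording,
    index: EpochIndex,
    spec: FeatureSpec | None = None,
    fit_epochs: np.ndarray | None = None,
) -> EpochFeatureMatrix:
    """Assemble the per-epoch feature matrix for a recording.

    ``fit_epochs`` designates the epochs used to fit the z-score parameters
    (all epochs by default); held-out epochs are transformed with the same
    parameters, guarding against leakage.
    """
    spec = spec or FeatureSpec()
    names = spec.feature_names
    vals = np.empty((index.n_epochs, len(names)))
    for i, seg in enumerate(index.epoch_iter(recording.samples)):
        col = 0
        for _, lo, hi in spec.bands:
            vals[i, col] = band_power(seg, (lo, hi), recording.sampling_rate)
            col += 1
        if spec.include_line_length:
            vals[i, col] = line_length(seg)
            col += 1
        for e in spec.extras:
            vals[i, col] = _EXTRA_FUNCS[e](seg)
            col += 1

    mean = sd = None
    if spec.standardize:
        fit = vals if fit_epochs is None else vals[np.asarray(fit_epochs)]
        mean = fit.mean(axis=0)
        sd = fit.std(axis=0, ddof=0)
        dead = np.nonzero(sd == 0)[0]
        if dead.size:
            raise ValueError(
                "zero-variance feature(s) under standardization: "
                + ", ".join(names[j] for j in dead)
            )
        vals = (vals - mean) / sd
    return EpochFeatureMatrix(vals, names, index, mean, sd)
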