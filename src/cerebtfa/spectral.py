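"""Welch cross-spectral transfer function analysis of cerebral autoregulation.

Dynamic cerebral autoregulation dampens the effect of spontaneous mean
arterial pressure (MAP) oscillations on middle cerebral artery blood flow
velocity (MCAv). It is quantified here in the frequency domain: Welch
auto- and cross-spectra of the paired 10 Hz channels give, per frequency,

    gain      = |S_xy| / S_xx          [cm s^-1 mmHg^-1]
    phase     = arg(S_xy)              [rad], positive when MCAv leads MAP
    coherence = |S_xy|^2 / (S_xx S_yy) in [0, 1]

which are then averaged over the very-low (0.02-0.07 Hz), low
(0.07-0.20 Hz) and high (0.20-0.30 Hz) frequency bands. Efficient
autoregulation shows as low gain and a large positive phase lead in the
low-frequency band. Band estimates are only trusted when the
band-averaged coherence reaches 0.4; invalid estimates are flagged, not
silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .errors import BandResolutionError, InsufficientDataError, InvalidConfigurationError

#: Coherence below this value marks gain/phase estimates as unreliable.
COHERENCE_THRESHOLD = 0.4


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimation parameters.

    Defaults reproduce the standard protocol for 10 Hz autoregulation
    data: 1,200-point (120 s) Hann-tapered segments with 60 s overlap,
    i.e. 50% segment overlap, giving 9 segments from a 600 s window and a
    frequency resolution of 1/120 Hz.
    """

    segment_length: int = 1200  # samples
    overlap_s: float = 60.0  # seconds
    window: str = "hann"
    sampling_rate: float = 10.0  # Hz

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise InvalidConfigurationError(
                f"segment_length must be >= 2, got {self.segment_length}"
            )
        if not self.sampling_rate > 0:
            raise InvalidConfigurationError("sampling_rate must be positive")
        if not 0 <= self.noverlap < self.segment_length:
            raise InvalidConfigurationError(
                f"overlap of {self.overlap_s} s ({self.noverlap} samples) must be "
                f"in [0, segment_length)"
            )

    @property
    def noverlap(self) -> int:
        return int(round(self.overlap_s * self.sampling_rate))


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[f_lo, f_hi)``.

    ``closed_upper`` includes bins at exactly ``f_hi`` (used for the last
    band so the 0.30 Hz edge belongs to HF while shared interior edges are
    never double-counted).
    """

    name: str
    f_lo: float
    f_hi: float
    closed_upper: bool = False

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise InvalidConfigurationError(
                f"band {self.name}: f_lo {self.f_lo} must be < f_hi {self.f_hi}"
            )

    def mask(self, frequencies: np.ndarray) -> np.ndarray:
        eps = 1e-12
        lo = frequencies >= self.f_lo - eps
        hi = frequencies <= self.f_hi + eps if self.closed_upper else frequencies < self.f_hi - eps
        return lo & hi


#: The standard analysis bands: very-low, low and high frequency.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("VLF", 0.02, 0.07),
    BandDefinition("LF", 0.07, 0.20),
    BandDefinition("HF", 0.20, 0.30, closed_upper=True),
)


@dataclass(frozen=True)
class SpectralEstimate:
    """Welch auto-/cross-spectral densities on a common frequency grid.

    ``s_map`` (mmHg^2/Hz) and ``s_mcav`` (cm^2 s^-2/Hz) are one-sided
    auto-spectral densities; ``s_cross`` is the complex cross-spectral
    density conj(MAP)*MCAv averaged over segments, so its argument is
    positive where MCAv leads MAP. Cauchy-Schwarz guarantees
    |s_cross|^2 <= s_map * s_mcav at every bin.
    """

    frequencies: np.ndarray  # Hz, 0 .. Nyquist
    s_map: np.ndarray
    s_mcav: np.ndarray
    s_cross: np.ndarray
    n_segments: int
    mean_map: float  # mmHg
    mean_mcav: float  # cm/s

    @property
    def df(self) -> float:
        """Frequency resolution in Hz."""
        return float(self.frequencies[1] - self.frequencies[0])


def welch_cross_spectra(
    map_series: np.ndarray, mcav_series: np.ndarray, cfg: WelchConfig = WelchConfig()
) -> SpectralEstimate:
    """Welch auto- and cross-spectra of the MAP/MCAv pair.

    Segments are mean-removed, Hann-tapered and averaged with window
    power correction (density scaling), so a one-segment call equals the
    direct Hann-windowed periodogram.
    """
    x = np.asarray(map_series, dtype=float)
    y = np.asarray(mcav_series, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("MAP and MCAv series must be equal-length 1-D arrays")
    if x.size < cfg.segment_length:
        raise InsufficientDataError(
            f"series of {x.size} samples is shorter than one Welch segment "
            f"({cfg.segment_length} samples)"
        )
    kw = dict(
        fs=cfg.sampling_rate,
        window=cfg.window,
        nperseg=cfg.segment_length,
        noverlap=cfg.noverlap,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    f, s_map = signal.welch(x, **kw)
    _, s_mcav = signal.welch(y, **kw)
    _, s_cross = signal.csd(x, y, **kw)
    step = cfg.segment_length - cfg.noverlap
    n_segments = 1 + (x.size - cfg.segment_length) // step
    return SpectralEstimate(
        frequencies=f,
        s_map=s_map,
        s_mcav=s_mcav,
        s_cross=s_cross,
        n_segments=n_segments,
        mean_map=float(np.mean(x)),
        mean_mcav=float(np.mean(y)),
    )


@dataclass(frozen=True)
class TransferFunction:
    """Per-frequency transfer quantities derived from a SpectralEstimate.

    Bins where the MAP auto-spectrum vanishes are NaN (undefined), never
    infinite. Coherence is NaN throughout when only one segment was
    averaged, since single-segment coherence is identically 1.
    """

    frequencies: np.ndarray
    gain: np.ndarray  # cm s^-1 mmHg^-1
    phase: np.ndarray  # rad, principal value; positive = MCAv leads
    coherence: np.ndarray  # [0, 1] or NaN


def transfer_function(est: SpectralEstimate) -> TransferFunction:
    """Gain, phase and squared coherence per frequency bin."""
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(est.s_map > 0, np.abs(est.s_cross) / est.s_map, np.nan)
        denom = est.s_map * est.s_mcav
        coherence = np.where(denom > 0, np.abs(est.s_cross) ** 2 / denom, np.nan)
    phase = np.where(est.s_map > 0, np.angle(est.s_cross), np.nan)
    if est.n_segments < 2:
        warnings.warn(
            "coherence is undefined for a single Welch segment (identically 1); "
            "reporting NaN",
            stacklevel=2,
        )
        coherence = np.full_like(coherence, np.nan)
    return TransferFunction(
        frequencies=est.frequencies, gain=gain, phase=phase, coherence=coherence
    )


@dataclass(frozen=True)
class BandSummary:
    """Band-averaged transfer quantities — one row block of the results table."""

    band: BandDefinition
    gain: float  # cm s^-1 mmHg^-1
    normalised_gain: float  # %MCAv per %MAP, dimensionless
    phase: float  # rad
    coherence: float
    map_power: float  # mmHg^2, band-integrated
    mcav_power: float  # cm^2 s^-2, band-integrated
    valid: bool  # coherence >= threshold
    n_bins: int = 0


def band_average(
    tf: TransferFunction,
    est: SpectralEstimate,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    coherence_threshold: float = COHERENCE_THRESHOLD,
    method: str = "binwise",
) -> list[BandSummary]:
    """Average per-frequency quantities over the analysis bands.

    The default ``binwise`` method averages the derived gain/phase/
    coherence across the bins of each band, the mainstream practice in
    autoregulation studies; ``band_spectra`` instead recomputes the
    quantities from band-averaged spectra. Band powers integrate the PSD
    over the band (density x bin width). ``normalised_gain`` rescales gain
    by mean(MAP)/mean(MCAv) to percent-per-percent units. ``valid`` flags
    whether the band-averaged coherence reaches the threshold (>= rule).
    """
    if method not in ("binwise", "band_spectra"):
        raise InvalidConfigurationError(f"unknown band-averaging method {method!r}")
    out = []
    df = est.df
    for band in bands:
        m = band.mask(est.frequencies)
        if not m.any():
            raise BandResolutionError(
                f"band {band.name} [{band.f_lo}, {band.f_hi}] contains no bins at "
                f"frequency resolution {df:.5f} Hz"
            )
        map_power = float(np.sum(est.s_map[m]) * df)
        mcav_power = float(np.sum(est.s_mcav[m]) * df)
        if method == "binwise":
            gain = float(np.nanmean(tf.gain[m]))
            phase = float(np.nanmean(tf.phase[m]))
            coherence = float(np.nanmean(tf.coherence[m]))
        else:
            sm, sv = np.mean(est.s_map[m]), np.mean(est.s_mcav[m])
            sc = np.mean(est.s_cross[m])
            gain = float(np.abs(sc) / sm) if sm > 0 else float("nan")
            phase = float(np.angle(sc)) if sm > 0 else float("nan")
            coherence = float(np.abs(sc) ** 2 / (sm * sv)) if sm * sv > 0 else float("nan")
        if est.mean_mcav != 0:
            normalised_gain = gain * est.mean_map / est.mean_mcav
        else:
            normalised_gain = float("nan")
        valid = bool(np.isfinite(coherence) and coherence >= coherence_threshold)
        out.append(
            BandSummary(
                band=band,
                gain=gain,
                normalised_gain=normalised_gain,
                phase=phase,
                coherence=coherence,
                map_power=map_power,
                mcav_power=mcav_power,
                valid=valid,
                n_bins=int(m.sum()),
            )
        )
    return out


@dataclass(frozen=True)
class DirectionVerdict:
    """Qualitative per-metric reading of an autoregulation change.

    A larger phase lead or a smaller (normalised) gain both indicate
    enhanced dynamic autoregulation; the metrics are reported separately,
    never fused. When either summary fails the coherence criterion the
    verdict is withheld.
    """

    gain: Optional[str] = None  # enhanced | diminished | unchanged
    normalised_gain: Optional[str] = None
    phase: Optional[str] = None
    withheld: bool = False
    reason: str = ""


def interpret_direction(
    before: BandSummary, after: BandSummary, atol: float = 1e-12
) -> DirectionVerdict:
    """Classify each transfer metric's change between two valid summaries."""
    if not before.valid or not after.valid:
        which = []
        if not before.valid:
            which.append(f"'before' (coherence {before.coherence:.2f})")
        if not after.valid:
            which.append(f"'after' (coherence {after.coherence:.2f})")
        return DirectionVerdict(
            withheld=True,
            reason="coherence criterion failed for " + " and ".join(which),
        )

    def verdict(delta: float, increase_means: str, decrease_means: str) -> str:
        if delta > atol:
            return increase_means
        if delta < -atol:
            return decrease_means
        return "unchanged"

    return DirectionVerdict(
        gain=verdict(after.gain - before.gain, "diminished", "enhanced"),
        normalised_gain=verdict(
            after.normalised_gain - before.normalised_gain, "diminished", "enhanced"
        ),
        phase=verdict(after.phase - before.phase, "enhanced", "diminished"),
    )
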