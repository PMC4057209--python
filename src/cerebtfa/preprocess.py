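"""Preprocessing of paired pressure/velocity recordings.

Raw recordings of invasive mean arterial pressure (MAP, mmHg) and
transcranial-Doppler middle cerebral artery blood flow velocity (MCAv,
cm/s) are reduced to the fixed-rate analysis windows that the spectral
stage consumes: the trailing steady-state window of each intervention is
extracted, the channels are anti-alias filtered and resampled to the
10 Hz analysis rate, and last-minutes channel means are computed for the
vasoreactivity calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .errors import IngestError, InsufficientDataError, UnsupportedOperationError

#: Default analysis sampling rate, Hz.
ANALYSIS_RATE = 10.0
#: Default steady-state analysis window (the trailing 10 minutes), seconds.
ANALYSIS_WINDOW_S = 600.0
#: Default averaging window for reported channel means (4 minutes), seconds.
MEAN_WINDOW_S = 240.0


@dataclass(frozen=True)
class HemodynamicRecording:
    """Uniformly sampled paired MAP/MCAv channels with provenance metadata.

    Parameters
    ----------
    map : ndarray
        Mean arterial pressure, mmHg.
    mcav : ndarray
        Middle cerebral artery blood flow velocity, cm/s.
    sampling_rate : float
        Sampling rate of both channels, Hz.
    subject_id, condition, intervention : str
        Provenance labels. ``condition`` is ``"baseline"`` or ``"LPS"``;
        ``intervention`` is ``"normoxia"``, ``"hyperoxia"`` or ``"hypoxia"``.
    """

    map: np.ndarray
    mcav: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    condition: str = ""
    intervention: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "map", np.asarray(self.map, dtype=float))
        object.__setattr__(self, "mcav", np.asarray(self.mcav, dtype=float))
        if self.map.ndim != 1 or self.mcav.ndim != 1:
            raise IngestError("channels must be one-dimensional")
        if self.map.size != self.mcav.size:
            raise IngestError(
                f"channel lengths differ: map has {self.map.size} samples, "
                f"mcav has {self.mcav.size}"
            )
        if self.map.size == 0:
            raise IngestError("recording is empty")
        if not self.sampling_rate > 0:
            raise IngestError(f"sampling_rate must be positive, got {self.sampling_rate}")
        # Gaps are an ingest error: interpolating over them would bias phase.
        if not (np.isfinite(self.map).all() and np.isfinite(self.mcav).all()):
            raise IngestError("recording contains missing or non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.map.size

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        """Time grid in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate


def extract_analysis_window(
    rec: HemodynamicRecording, window_s: float = ANALYSIS_WINDOW_S
) -> HemodynamicRecording:
    """Return the trailing ``window_s`` seconds of a recording.

    The steady-state portion of each intervention is its final stretch,
    so analysis always uses the last ``window_s`` seconds (default 600 s,
    i.e. the last 10 minutes). Metadata is preserved. Idempotent: applying
    the same window twice returns the same samples.
    """
    n_keep = int(round(window_s * rec.sampling_rate))
    if n_keep < 1:
        raise InsufficientDataError(f"window of {window_s} s contains no samples")
    if rec.n_samples < n_keep:
        shortfall = (n_keep - rec.n_samples) / rec.sampling_rate
        raise InsufficientDataError(
            f"recording lasts {rec.duration:.1f} s but {window_s:.1f} s were "
            f"requested ({shortfall:.1f} s short)"
        )
    if rec.n_samples == n_keep:
        return rec
    return replace(rec, map=rec.map[-n_keep:], mcav=rec.mcav[-n_keep:])


def _antialias_sos(target_rate: float, source_rate: float):
    # Cutoff at 0.4 x the target Nyquist (2 Hz for a 10 Hz target): far above
    # the 0.30 Hz analysis ceiling, far below the new Nyquist.
    cutoff = 0.4 * (target_rate / 2.0)
    return signal.butter(8, cutoff, btype="low", fs=source_rate, output="sos")


def resample_to_analysis_rate(
    rec: HemodynamicRecording, target_rate: float = ANALYSIS_RATE
) -> HemodynamicRecording:
    """Anti-alias filter and resample a recording to the analysis rate.

    A zero-phase (forward-backward) 8th-order Butterworth low-pass with
    cutoff at 0.4 x the target Nyquist precedes decimation, so phase
    estimates downstream are not distorted and content that would alias
    into the 0.02-0.30 Hz analysis range is strongly attenuated. Integer
    rate ratios decimate by slicing; non-integer ratios interpolate the
    filtered (hence band-limited) signal with a cubic spline.

    Upsampling is refused rather than silently interpolated.
    """
    fs = rec.sampling_rate
    if np.isclose(fs, target_rate):
        return rec
    if fs < target_rate:
        raise UnsupportedOperationError(
            f"cannot upsample from {fs} Hz to {target_rate} Hz; supply data "
            f"already sampled at >= {target_rate} Hz"
        )
    sos = _antialias_sos(target_rate, fs)
    lp_map = signal.sosfiltfilt(sos, rec.map)
    lp_mcav = signal.sosfiltfilt(sos, rec.mcav)

    ratio = fs / target_rate
    if np.isclose(ratio, round(ratio)):
        step = int(round(ratio))
        new_map, new_mcav = lp_map[::step], lp_mcav[::step]
    else:
        t_old = rec.time
        n_out = int(round(rec.n_samples * target_rate / fs))
        t_new = np.arange(n_out) / target_rate
        t_new = t_new[t_new <= t_old[-1]]
        new_map = CubicSpline(t_old, lp_map)(t_new)
        new_mcav = CubicSpline(t_old, lp_mcav)(t_new)
    return replace(rec, map=new_map, mcav=new_mcav, sampling_rate=target_rate)


def segment_mean(
    series: np.ndarray, sampling_rate: float, window_s: float = MEAN_WINDOW_S
) -> float:
    """Arithmetic mean of the trailing ``window_s`` seconds of a channel.

    Reported channel values (MAP, MCAv) are means over the final minutes
    of each intervention (default 240 s, the last 4 minutes).
    """
    series = np.asarray(series, dtype=float)
    n_keep = int(round(window_s * sampling_rate))
    if n_keep < 1:
        raise InsufficientDataError(f"window of {window_s} s contains no samples")
    if series.size < n_keep:
        raise InsufficientDataError(
            f"series has {series.size / sampling_rate:.1f} s but "
            f"{window_s:.1f} s were requested"
        )
    return float(np.mean(series[-n_keep:]))
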