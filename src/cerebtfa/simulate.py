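"""Synthetic hemodynamic-signal generator with known ground truth.

No raw pressure/velocity recordings from endotoxaemia studies are
publicly deposited, so every downstream stage is validated against
synthetic cohorts whose transfer characteristics are known exactly.

The MAP model is a setpoint plus sinusoidal oscillators — a Mayer-wave
component near 0.1 Hz, a respiratory component in the 0.20-0.30 Hz
range, a slow very-low-frequency component — plus Gaussian broadband
noise, the minimal structure that puts power in all three analysis
bands. MCAv is generated from MAP through a configurable linear
time-invariant transfer model (identity, scalar gain, pure delay, or a
frequency template interpolated between nodes), applied by frequency-
domain multiplication so the realised frequency response is exact and
checkable. Independent Gaussian noise added to the output channel after
filtering yields the closed-form band coherence
S_signal / (S_signal + S_noise).

Cohort generation layers a condition effect on top: the low-frequency
MAP-to-MCAv phase rises from its pre-endotoxin value to its
post-endotoxin value, with between-subject and within-subject scatter,
and per-intervention blood-gas panels are drawn around configurable
targets. Ground-truth parameters are kept alongside the data so
recovery tests never re-derive them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidConfigurationError, ValidationError
from .oxygen import BloodGasPanel, compute_cao2
from .preprocess import HemodynamicRecording

#: Frequency span (Hz) that a frequency_template model must cover: the
#: outer edges of the VLF and HF analysis bands.
ANALYSIS_SPAN = (0.02, 0.30)

CONDITIONS = ("baseline", "LPS")
INTERVENTIONS = ("normoxia", "hyperoxia", "hypoxia")


@dataclass(frozen=True)
class TransferModel:
    """Linear MAP-to-MCAv transfer model — the simulator's ground truth.

    ``kind`` selects the frequency response H(f):

    - ``unity``: H = 1 (MCAv mirrors MAP fluctuations around its setpoint)
    - ``scalar_gain``: H = gain_value
    - ``pure_delay``: H = gain_value * exp(-2*pi*i*f*delay) (MCAv lags)
    - ``frequency_template``: gain and phase interpolated linearly in
      frequency between ``template`` nodes (f_Hz, gain, phase_rad),
      constant beyond the end nodes

    Phases follow the analysis convention: positive phase means MCAv
    leads MAP.
    """

    kind: str
    gain_value: float = 1.0  # cm s^-1 mmHg^-1
    delay: float = 0.0  # seconds
    template: Optional[tuple[tuple[float, float, float], ...]] = None
    mcav_setpoint: float = 72.0  # cm/s

    def __post_init__(self) -> None:
        kinds = ("unity", "scalar_gain", "pure_delay", "frequency_template")
        if self.kind not in kinds:
            raise InvalidConfigurationError(f"kind must be one of {kinds}, got {self.kind!r}")
        if self.gain_value < 0:
            raise InvalidConfigurationError("gain_value must be >= 0")
        if self.kind == "pure_delay" and self.delay < 0:
            raise InvalidConfigurationError("delay must be >= 0")
        if self.kind == "frequency_template":
            if not self.template:
                raise InvalidConfigurationError("frequency_template requires template nodes")
            tpl = tuple(tuple(map(float, node)) for node in self.template)
            object.__setattr__(self, "template", tpl)
            freqs = [f for f, _, _ in tpl]
            if any(b <= a for a, b in zip(freqs, freqs[1:])):
                raise InvalidConfigurationError("template frequencies must be strictly increasing")
            for f, g, p in tpl:
                if g < 0:
                    raise InvalidConfigurationError(f"template gain at {f} Hz is negative")
                if not (-math.pi < p <= math.pi):
                    raise InvalidConfigurationError(
                        f"template phase at {f} Hz must lie in (-pi, pi], got {p}"
                    )

    def frequency_response(self, frequencies: np.ndarray) -> np.ndarray:
        """Complex H(f) at the given frequencies (Hz)."""
        f = np.asarray(frequencies, dtype=float)
        if self.kind == "unity":
            return np.ones_like(f, dtype=complex)
        if self.kind == "scalar_gain":
            return np.full_like(f, self.gain_value, dtype=complex)
        if self.kind == "pure_delay":
            return self.gain_value * np.exp(-2j * np.pi * f * self.delay)
        nodes_f = np.array([n[0] for n in self.template])
        nodes_g = np.array([n[1] for n in self.template])
        nodes_p = np.array([n[2] for n in self.template])
        gain = np.interp(f, nodes_f, nodes_g)
        phase = np.interp(f, nodes_f, nodes_p)
        return gain * np.exp(1j * phase)


#: Default MAP oscillators (frequency Hz, amplitude mmHg, phase rad):
#: a slow VLF drift, the ~0.1 Hz Mayer wave, and a respiratory component.
DEFAULT_OSCILLATORS: tuple[tuple[float, float, float], ...] = (
    (0.04, 1.5, 0.0),
    (0.10, 3.0, 0.0),
    (0.25, 1.5, 0.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """One synthetic recording: MAP composition plus the MCAv transfer model.

    The same seed always reproduces the realisation bit for bit.
    """

    duration: float  # seconds
    sampling_rate: float = 10.0  # Hz
    map_setpoint: float = 88.0  # mmHg
    oscillators: tuple[tuple[float, float, float], ...] = DEFAULT_OSCILLATORS
    background_noise_sd: float = 1.5  # mmHg
    transfer_model: TransferModel = field(default_factory=lambda: TransferModel("unity"))
    output_noise_sd: float = 0.8  # cm/s
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise InvalidConfigurationError(f"duration must be positive, got {self.duration}")
        if not self.sampling_rate > 0:
            raise InvalidConfigurationError(
                f"sampling_rate must be positive, got {self.sampling_rate}"
            )
        osc = tuple(tuple(map(float, o)) for o in self.oscillators)
        object.__setattr__(self, "oscillators", osc)
        for f, a, _ in osc:
            if a < 0:
                raise InvalidConfigurationError(f"oscillator amplitude at {f} Hz is negative")
            if self.sampling_rate <= 2 * f:
                raise InvalidConfigurationError(
                    f"sampling_rate {self.sampling_rate} Hz must exceed twice the "
                    f"oscillator frequency {f} Hz"
                )
        if self.background_noise_sd < 0 or self.output_noise_sd < 0:
            raise InvalidConfigurationError("noise SDs must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def simulate_map(config: SimulationConfig) -> np.ndarray:
    """Synthetic mean arterial pressure series (mmHg)."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_samples) / config.sampling_rate
    series = np.full(config.n_samples, config.map_setpoint, dtype=float)
    for f, a, ph in config.oscillators:
        series += a * np.sin(2 * np.pi * f * t + ph)
    if config.background_noise_sd > 0:
        series += rng.normal(0.0, config.background_noise_sd, config.n_samples)
    return series


def simulate_mcav(
    map_series: np.ndarray,
    model: TransferModel,
    output_noise_sd: float = 0.0,
    seed: Optional[int] = None,
    sampling_rate: float = 10.0,
) -> np.ndarray:
    """MCAv series (cm/s) produced by passing MAP through a transfer model.

    The mean-removed MAP is multiplied by H(f) in the frequency domain
    (conjugate-symmetric by construction via the real FFT), shifted to the
    model's MCAv setpoint, and independent Gaussian output noise is added
    last so band coherence has the closed form S_sig/(S_sig + S_noise).
    """
    x = np.asarray(map_series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidConfigurationError("map_series must be a 1-D array of >= 2 samples")
    if output_noise_sd < 0:
        raise InvalidConfigurationError("output_noise_sd must be >= 0")
    if model.kind == "frequency_template":
        lo, hi = model.template[0][0], model.template[-1][0]
        if lo > ANALYSIS_SPAN[0] or hi < ANALYSIS_SPAN[1]:
            raise InvalidConfigurationError(
                f"frequency template [{lo}, {hi}] Hz does not cover the analysis "
                f"bands {ANALYSIS_SPAN} Hz"
            )
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sampling_rate)
    spectrum = np.fft.rfft(x - x.mean()) * model.frequency_response(freqs)
    y = np.fft.irfft(spectrum, n=x.size) + model.mcav_setpoint
    if output_noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, output_noise_sd, x.size)
    return y


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class BloodGasTargets:
    """Target medians for one intervention's blood-gas panel."""

    paO2: float  # kPa
    saO2: float  # fraction
    paCO2: float  # kPa
    hb: float  # mM


#: Per-intervention targets seeded from typical arterial values under the
#: three inspired-oxygen fractions (haemoglobin back-solved so normoxic
#: CaO2 comes out near 8.4 mM).
DEFAULT_BLOOD_GAS_TARGETS: Mapping[str, BloodGasTargets] = MappingProxyType(
    {
        "normoxia": BloodGasTargets(paO2=13.2, saO2=0.98, paCO2=5.7, hb=8.44),
        "hyperoxia": BloodGasTargets(paO2=28.5, saO2=1.00, paCO2=5.6, hb=8.44),
        "hypoxia": BloodGasTargets(paO2=7.5, saO2=0.90, paCO2=5.7, hb=8.44),
    }
)

#: Per-intervention MCAv setpoints (cm/s): hyperoxia constricts, hypoxia dilates.
DEFAULT_MCAV_SETPOINTS: Mapping[str, float] = MappingProxyType(
    {"normoxia": 72.0, "hyperoxia": 69.0, "hypoxia": 79.0}
)


@dataclass(frozen=True)
class CohortEffectConfig:
    """Study-level generative settings: the condition effect and its scatter.

    The low-frequency phase lead rises from ``baseline_lf_phase`` to
    ``lps_lf_phase`` after the endotoxin condition; subjects carry a
    shared random phase offset (``between_subject_sd``) across all their
    recordings plus independent per-recording jitter
    (``within_subject_sd``). ``degraded_cell`` optionally drowns one
    recording in output noise to produce a below-threshold coherence,
    mimicking a subject whose estimates must be excluded.
    """

    n_subjects: int = 10
    baseline_lf_phase: float = 0.58  # rad
    lps_lf_phase: float = 0.82  # rad
    between_subject_sd: float = 0.08  # rad
    within_subject_sd: float = 0.04  # rad
    gain: float = 1.26  # cm s^-1 mmHg^-1
    duration: float = 1200.0  # seconds per intervention recording
    sampling_rate: float = 10.0  # Hz
    map_setpoint: float = 88.0  # mmHg
    oscillators: tuple[tuple[float, float, float], ...] = DEFAULT_OSCILLATORS
    background_noise_sd: float = 1.5  # mmHg
    output_noise_sd: float = 0.8  # cm/s
    mcav_setpoints: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_MCAV_SETPOINTS
    )
    blood_gas_targets: Mapping[str, BloodGasTargets] = field(
        default_factory=lambda: DEFAULT_BLOOD_GAS_TARGETS
    )
    blood_gas_rel_sd: float = 0.03  # relative SD on PaO2/PaCO2; absolute on SaO2
    conditions: tuple[str, ...] = CONDITIONS
    interventions: tuple[str, ...] = INTERVENTIONS
    degraded_cell: Optional[tuple[int, str, str]] = None  # (subject idx, condition, intervention)
    degraded_noise_sd: float = 30.0  # cm/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigurationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise InvalidConfigurationError("scatter SDs must be >= 0")
        for iv in self.interventions:
            if iv not in INTERVENTIONS:
                raise ValidationError(f"unknown intervention {iv!r}; expected one of {INTERVENTIONS}")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValidationError(f"unknown condition {c!r}; expected one of {CONDITIONS}")

    def phase_for(self, condition: str) -> float:
        return self.baseline_lf_phase if condition == "baseline" else self.lps_lf_phase


def simulate_blood_gases(
    effect: CohortEffectConfig, condition: str, intervention: str, seed: Optional[int] = None
) -> BloodGasPanel:
    """Draw one blood-gas panel around the intervention's targets.

    PaO2 and PaCO2 scatter multiplicatively (relative SD), SaO2
    additively with clipping into [0, 1]; CaO2 is derived from the drawn
    values. Zero ``blood_gas_rel_sd`` returns the targets exactly.
    """
    if intervention not in INTERVENTIONS:
        raise ValidationError(
            f"unknown intervention {intervention!r}; expected one of {INTERVENTIONS}"
        )
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    tgt = effect.blood_gas_targets[intervention]
    rng = np.random.default_rng(seed if seed is not None else effect.seed)
    rel = effect.blood_gas_rel_sd
    paO2 = max(0.0, tgt.paO2 * (1.0 + rng.normal(0.0, rel)))
    paCO2 = max(0.0, tgt.paCO2 * (1.0 + rng.normal(0.0, rel)))
    saO2 = float(np.clip(tgt.saO2 + rng.normal(0.0, rel / 3.0), 0.0, 1.0)) if rel > 0 else tgt.saO2
    hb = max(0.0, tgt.hb * (1.0 + rng.normal(0.0, rel / 3.0)))
    return BloodGasPanel(
        paO2=paO2, saO2=saO2, paCO2=paCO2, hb=hb, caO2=compute_cao2(saO2, hb, paO2)
    )


@dataclass(frozen=True)
class CellTruth:
    """Ground-truth parameters of one recording, kept next to the data."""

    lf_phase: float  # rad
    gain: float  # cm s^-1 mmHg^-1
    output_noise_sd: float  # cm/s
    mcav_setpoint: float  # cm/s


@dataclass(frozen=True)
class SyntheticCohort:
    """A full synthetic study: recordings, panels and their ground truth.

    Keys are ``(subject_id, condition, intervention)`` triples.
    """

    effect: CohortEffectConfig
    recordings: Mapping[tuple[str, str, str], HemodynamicRecording]
    panels: Mapping[tuple[str, str, str], BloodGasPanel]
    ground_truth: Mapping[tuple[str, str, str], CellTruth]

    @property
    def subject_ids(self) -> list[str]:
        return sorted({k[0] for k in self.recordings})


def _constant_template(gain: float, phase: float, nyquist: float) -> TransferModel:
    # Flat gain/phase across the whole analysable range; constant
    # extrapolation of the end nodes covers DC..Nyquist.
    return TransferModel(
        kind="frequency_template",
        template=((0.01, gain, phase), (max(0.31, nyquist), gain, phase)),
    )


def simulate_cohort(effect: CohortEffectConfig) -> SyntheticCohort:
    """Generate every subject x condition x intervention recording and panel.

    Deterministic for a fixed ``effect.seed``: per-cell random streams
    are spawned from one root seed sequence, so two calls produce
    bit-identical cohorts and different seeds share ground-truth
    structure but differ in realisation.
    """
    root = np.random.SeedSequence(effect.seed)
    offset_rng = np.random.default_rng(root.spawn(1)[0])
    subject_offsets = offset_rng.normal(0.0, effect.between_subject_sd, effect.n_subjects)
    nyq = effect.sampling_rate / 2.0

    recordings: dict = {}
    panels: dict = {}
    truth: dict = {}
    for s in range(effect.n_subjects):
        sid = f"s{s + 1:02d}"
        for condition in effect.conditions:
            for intervention in effect.interventions:
                cell = root.spawn(1)[0]
                map_seed, mcav_seed, gas_seed = (
                    int(v) & 0x7FFFFFFF for v in cell.generate_state(3)
                )
                jitter_rng = np.random.default_rng(cell.spawn(1)[0])
                phase = (
                    effect.phase_for(condition)
                    + subject_offsets[s]
                    + jitter_rng.normal(0.0, effect.within_subject_sd)
                )
                phase = float((phase + math.pi) % (2 * math.pi) - math.pi)
                noise_sd = effect.output_noise_sd
                if effect.degraded_cell == (s, condition, intervention):
                    noise_sd = effect.degraded_noise_sd
                model = _constant_template(effect.gain, phase, nyq)
                model = TransferModel(
                    kind=model.kind,
                    template=model.template,
                    mcav_setpoint=float(effect.mcav_setpoints[intervention]),
                )
                cfg = SimulationConfig(
                    duration=effect.duration,
                    sampling_rate=effect.sampling_rate,
                    map_setpoint=effect.map_setpoint,
                    oscillators=effect.oscillators,
                    background_noise_sd=effect.background_noise_sd,
                    transfer_model=model,
                    output_noise_sd=noise_sd,
                    seed=map_seed,
                )
                map_series = simulate_map(cfg)
                mcav_series = simulate_mcav(
                    map_series,
                    model,
                    output_noise_sd=noise_sd,
                    seed=mcav_seed,
                    sampling_rate=effect.sampling_rate,
                )
                key = (sid, condition, intervention)
                recordings[key] = HemodynamicRecording(
                    map=map_series,
                    mcav=mcav_series,
                    sampling_rate=effect.sampling_rate,
                    subject_id=sid,
                    condition=condition,
                    intervention=intervention,
                )
                panels[key] = simulate_blood_gases(effect, condition, intervention, seed=gas_seed)
                truth[key] = CellTruth(
                    lf_phase=phase,
                    gain=effect.gain,
                    output_noise_sd=noise_sd,
                    mcav_setpoint=float(effect.mcav_setpoints[intervention]),
                )
    return SyntheticCohort(
        effect=effect,
        recordings=MappingProxyType(recordings),
        panels=MappingProxyType(panels),
        ground_truth=MappingProxyType(truth),
    )
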