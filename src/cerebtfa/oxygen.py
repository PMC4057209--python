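"""Arterial oxygen content and cerebral oxygen vasoreactivity (COVR).

Arterial oxygen content combines haemoglobin-bound and dissolved oxygen:

    CaO2 [mM] = SaO2 [fraction] * Hb [mM] + 0.01 [mM/kPa] * PaO2 [kPa]

COVR is the percent change in MCAv per unit change in arterial oxygen
tension (kPa) or, in the content-based variant, per mM change in CaO2.
Because the PaO2-CBF relation is nonlinear (asymptotic above ~13.3 kPa,
hyperbolic below ~8 kPa), hyperoxic and hypoxic slopes are computed
separately against the same-condition normoxic reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError

#: Solubility of oxygen in plasma, mM per kPa.
O2_SOLUBILITY_MM_PER_KPA = 0.01


def compute_cao2(saO2: float, hb: float, paO2: float) -> float:
    """Arterial oxygen content in mM from saturation, haemoglobin and tension.

    Parameters
    ----------
    saO2 : float
        Arterial oxygen saturation as a fraction in [0, 1].
    hb : float
        Haemoglobin concentration, mM.
    paO2 : float
        Arterial oxygen tension, kPa.
    """
    if not 0.0 <= saO2 <= 1.0:
        raise ValidationError(f"saO2 must be a fraction in [0, 1], got {saO2}")
    if hb < 0:
        raise ValidationError(f"haemoglobin must be non-negative, got {hb}")
    if paO2 < 0:
        raise ValidationError(f"paO2 must be non-negative, got {paO2}")
    return saO2 * hb + O2_SOLUBILITY_MM_PER_KPA * paO2


@dataclass(frozen=True)
class BloodGasPanel:
    """Arterial blood-gas panel for one intervention.

    ``caO2`` is computed from the other fields when not supplied and must
    otherwise be consistent with :func:`compute_cao2`.
    """

    paO2: float  # kPa
    saO2: float  # fraction in [0, 1]
    paCO2: float  # kPa
    hb: float  # mM
    pH: Optional[float] = None
    hco3: Optional[float] = None  # mM
    base_excess: Optional[float] = None  # mM
    petCO2: Optional[float] = None  # kPa
    caO2: Optional[float] = None  # mM, derived

    def __post_init__(self) -> None:
        expected = compute_cao2(self.saO2, self.hb, self.paO2)
        if self.caO2 is None:
            object.__setattr__(self, "caO2", expected)
        elif abs(self.caO2 - expected) > 1e-6 + 1e-9 * abs(expected):
            raise ValidationError(
                f"caO2={self.caO2} inconsistent with SaO2*Hb + 0.01*PaO2 = {expected:.6f}"
            )


@dataclass(frozen=True)
class CovrResult:
    """Signed vasoreactivity slope with the conventional verbal rendering.

    ``slope`` is %ΔMCAv (relative to the normoxic reference) per unit
    change of the challenge variable: per kPa PaO2 (``variable='paO2'``)
    or per mM CaO2 (``variable='caO2'``). The sign follows the raw
    arithmetic, so a hypoxia-induced MCAv increase against a PaO2 drop is
    a negative slope; ``reported_magnitude`` renders the field-standard
    magnitude-with-direction phrasing.
    """

    direction: str  # 'hyperoxia' or 'hypoxia'
    variable: str  # 'paO2' or 'caO2'
    slope: float
    delta_mcav_pct: float
    delta_x: float

    @property
    def reported_magnitude(self) -> str:
        unit = "kPa" if self.variable == "paO2" else "mM"
        var = "PaO2" if self.variable == "paO2" else "CaO2"
        mcav_verb = "increase" if self.delta_mcav_pct > 0 else "decrease"
        x_verb = "increase" if self.delta_x > 0 else "decrease"
        return (
            f"{abs(self.slope):.2f}% {mcav_verb} in MCAv per {unit} "
            f"{x_verb} in {var}"
        )


def _covr(
    mcav_ref: float, mcav_test: float, x_ref: float, x_test: float, variable: str
) -> CovrResult:
    if mcav_ref <= 0:
        raise ValidationError(f"reference MCAv must be positive, got {mcav_ref}")
    dx = x_test - x_ref
    if dx == 0:
        raise ValidationError(
            f"zero change in {variable}: vasoreactivity slope is undefined"
        )
    d_pct = 100.0 * (mcav_test - mcav_ref) / mcav_ref
    direction = "hyperoxia" if dx > 0 else "hypoxia"
    return CovrResult(
        direction=direction,
        variable=variable,
        slope=d_pct / dx,
        delta_mcav_pct=d_pct,
        delta_x=dx,
    )


def compute_covr(
    mcav_ref: float, mcav_test: float, pao2_ref: float, pao2_test: float
) -> CovrResult:
    """Percent change in MCAv per kPa change in PaO2.

    ``mcav_ref``/``pao2_ref`` are the normoxic last-4-minute means of the
    same condition; ``mcav_test``/``pao2_test`` come from the hyperoxic or
    hypoxic intervention (inferred from the sign of the PaO2 change).
    """
    return _covr(mcav_ref, mcav_test, pao2_ref, pao2_test, "paO2")


def compute_covr_cao2(
    mcav_ref: float, mcav_test: float, cao2_ref: float, cao2_test: float
) -> CovrResult:
    """Percent change in MCAv per mM change in arterial oxygen content."""
    return _covr(mcav_ref, mcav_test, cao2_ref, cao2_test, "caO2")
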