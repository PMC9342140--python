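"""Hypobaric-hypoxia attenuation of oxygen extraction.

Ascent reduces the partial pressure of oxygen and hence the oxygen that can be
extracted per litre of blood, while maximal cardiac output is essentially
unchanged.  The fractional decline in V̇o2max with altitude follows the
curvilinear fit to the Fulco meta-analysis, 0.007·km² + 0.03·km, applied as a
common attenuation to both the resting and maximal AVO2diff.  The extraction
at an intermediate workload is the sea-level extraction linearly remapped
between the attenuated rest/max endpoints, and the cardiac output required to
sustain a given V̇o2 rises accordingly (Fick principle).

Supported range: 0–8 km, the domain of the underlying meta-analysis; beyond
that the quadratic extrapolates toward full attenuation and is rejected.
"""

from __future__ import annotations

from .errors import DomainError, ValidationError
from .profile import BasicCardio, basic_response, vo2_reserve_fraction

__all__ = [
    "MAX_ALTITUDE_KM",
    "altitude_attenuation",
    "avo2diff_at_altitude",
    "cardiac_output_at_altitude",
]

MAX_ALTITUDE_KM = 8.0


def altitude_attenuation(km: float) -> float:
    """Fractional decline in V̇o2max at ``km`` kilometres above sea level."""
    if km < 0:
        raise ValidationError(f"altitude must be >= 0 km, got {km}")
    if km > MAX_ALTITUDE_KM:
        raise DomainError(
            f"altitude {km} km exceeds supported range 0–{MAX_ALTITUDE_KM:g} km"
        )
    return 0.007 * km * km + 0.03 * km


def avo2diff_at_altitude(basic: BasicCardio, vo2: float, km: float) -> float:
    """Oxygen extraction (L·L⁻¹) at a given V̇o2 and altitude.

    The sea-level extraction at this workload (V̇o2 over the basic linear
    cardiac output) is remapped linearly between the altitude-attenuated
    resting and maximal extractions; at km = 0 the value is unchanged.
    """
    att = altitude_attenuation(km)
    fraction = vo2_reserve_fraction(vo2, basic)
    _, co_sea, _ = basic_response(fraction, basic)
    avo2diff_sea = vo2 / co_sea
    rest_alt = basic.avo2diff_rest * (1.0 - att)
    max_alt = basic.avo2diff_max * (1.0 - att)
    span = basic.avo2diff_max - basic.avo2diff_rest
    if span <= 0:
        raise DomainError("degenerate extraction range: avo2diff_max <= avo2diff_rest")
    position = (avo2diff_sea - basic.avo2diff_rest) / span
    return position * (max_alt - rest_alt) + rest_alt


def cardiac_output_at_altitude(basic: BasicCardio, vo2: float, km: float) -> float:
    """Cardiac output (L·min⁻¹) required to sustain ``vo2`` at altitude.

    Equals the basic cardiac output at sea level and rises strictly with
    altitude at any fixed supra-resting V̇o2.
    """
    return vo2 / avo2diff_at_altitude(basic, vo2, km)
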