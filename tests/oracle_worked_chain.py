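"""Independent spreadsheet-style recomputation of the reference worked chain.

Recomputes, with nothing but literal arithmetic (no imports from the
package), every quantity along the chain for the reference fit male
(25 yr, 75 kg, 175 cm, V̇o2max 4.0 L·min⁻¹) exercising at V̇o2 = 2.0 L·min⁻¹
with mean body temperature 39 °C, 2 % dehydration, additive heat strain
index, sea level.  The regression test compares the package output against
these numbers.
"""

# --- basic constants -------------------------------------------------------
REE_KCAL_DAY = 10 * 75 + 6.25 * 175 - 5 * 25 + 5          # 1723.75
VO2REST = REE_KCAL_DAY / 1440 / (3.941 + 1.106 * 0.7)     # ~0.25387 L/min
SV_REST = 85.1                                            # mL/beat
SV_MAX = 40.59 + 24.81 * 4.0                              # 139.83 mL/beat
HR_MAX = 208 - 0.7 * 25                                   # 190.5 /min
HR_REST = 90.93 - 0.64 * (4.0 / 75 * 1000)                # ~56.797 /min
CO_MAX = SV_MAX / 1000 * HR_MAX                           # ~26.638 L/min
CO_REST = SV_REST / 1000 * HR_REST                        # ~4.833 L/min
AVO2DIFF_MAX = 4.0 / CO_MAX                               # ~0.1502
AVO2DIFF_REST = VO2REST / CO_REST                         # ~0.0525

# --- sea-level exercise at VO2 = 2.0 ---------------------------------------
VO2 = 2.0
FRACTION = (VO2 - VO2REST) / (4.0 - VO2REST)              # ~0.4661
HR_BASIC = (HR_MAX - HR_REST) * FRACTION + HR_REST        # ~119.1
CO_BASIC = (CO_MAX - CO_REST) * FRACTION + CO_REST        # ~15.00
SV_BASIC = CO_BASIC / HR_BASIC * 1000                     # ~125.9
CO_ALTITUDE = CO_BASIC                                    # km = 0

# --- heat strain ------------------------------------------------------------
DEHYD = 2.0                                               # % body mass
DELTA_T_BODY = 39.0 - 36.54                               # 2.46 degC
CHSI_ADDITIVE = 0.5 * DEHYD + 0.5 * DELTA_T_BODY          # 2.23
CHSI_SYNERGISTIC = (
    0.433 * DEHYD + 0.091 * DELTA_T_BODY + 0.125 * DEHYD * DELTA_T_BODY
)                                                         # ~1.705

SV_REST_ENV = (1 + 0.025 * CHSI_ADDITIVE) * SV_REST       # ~89.84
CO_REST_ENV = (1 + 0.313 * CHSI_ADDITIVE) * CO_REST       # ~8.207
SV_MAX_ENV = (1 - 0.083 * CHSI_ADDITIVE) * SV_MAX
CO_MAX_ENV = (1 - 0.083 * CHSI_ADDITIVE) * CO_MAX         # ~21.71
HR_REST_ENV = CO_REST_ENV / SV_REST_ENV * 1000            # ~91.35

FRACTION_ENV = (CO_ALTITUDE - CO_REST) / (CO_MAX_ENV - CO_REST)   # ~0.602
HR_ENV = (HR_MAX - HR_REST_ENV) * FRACTION_ENV + HR_REST_ENV      # ~151.1
CO_ENV = (CO_MAX_ENV - CO_REST_ENV) * FRACTION_ENV + CO_REST_ENV  # ~16.34
SV_ENV = CO_ENV / HR_ENV * 1000                                   # ~108.1
VO2MAX_ENV = AVO2DIFF_MAX * CO_MAX_ENV                            # ~3.26

# --- blood-flow partition ---------------------------------------------------
FCO = CO_ENV / CO_MAX_ENV                                 # ~0.753
CORE_BF = CO_ENV * (0.86 * FCO**2 - 1.79 * FCO + 1.06)    # ~3.27
SKIN_BF = 0.05 * CO_REST + (CO_ENV - CO_ALTITUDE)         # ~1.58
MUSCLE_BF = CO_ENV - SKIN_BF - CORE_BF                    # ~11.49
ACTIVE_MUSCLE_AVO2DIFF = (VO2 - VO2REST) / MUSCLE_BF      # ~0.152

# --- altitude side chain (km = 5, no heat) ----------------------------------
ATTENUATION_5KM = 0.007 * 25 + 0.03 * 5                   # 0.325
AVO2DIFF_REST_5KM = AVO2DIFF_REST * (1 - ATTENUATION_5KM)
AVO2DIFF_MAX_5KM = AVO2DIFF_MAX * (1 - ATTENUATION_5KM)
_POSITION = (VO2 / CO_BASIC - AVO2DIFF_REST) / (AVO2DIFF_MAX - AVO2DIFF_REST)
AVO2DIFF_5KM = (
    _POSITION * (AVO2DIFF_MAX_5KM - AVO2DIFF_REST_5KM) + AVO2DIFF_REST_5KM
)                                                         # ~0.0900
CO_5KM = VO2 / AVO2DIFF_5KM                               # ~22.22
VO2MAX_5KM = (1 - ATTENUATION_5KM) * 4.0                  # 2.70
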