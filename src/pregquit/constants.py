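"""Single registry for the trial's cut-offs and reporting conventions.

Every threshold used by outcome classification and reporting lives here so
that the biochemical validation rules, the birth-outcome definitions and the
lapse allowance are defined in exactly one place.
"""

from __future__ import annotations

import math

# Biochemical validation of self-reported abstinence (all strict "<").
COTININE_THRESHOLD_NG_ML = 10.0    # salivary cotinine, nicotine-product non-users
ANABASINE_THRESHOLD_NG_ML = 1.0    # salivary anabasine, nicotine-product users
CO_THRESHOLD_PPM = 8.0             # expired carbon monoxide, users (overrides anabasine)

# Birth outcome definitions.
LOW_BIRTHWEIGHT_THRESHOLD_G = 2500.0   # low birthweight: < 2,500 g
PRETERM_THRESHOLD_WEEKS = 37.0         # preterm birth: < 37 weeks of gestation

# Russell-Standard prolonged abstinence: at most 5 lapses allowed between
# two weeks post target-quit-date and the end of pregnancy.
MAX_LAPSES_PROLONGED = 5

# Smoking reduction endpoint: at least 50% fewer cigarettes/day than baseline.
REDUCTION_FRACTION = 0.5

# Eligibility window at study entry.
GESTATION_WEEKS_MIN = 12.0
GESTATION_WEEKS_MAX = 24.0
FTCD_MIN, FTCD_MAX = 0, 10

# Bayes factor evidence categories (conventional cut-offs).
BF_SUPPORTS_EFFECT = 3.0
BF_SUPPORTS_NULL = 1.0 / 3.0


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as in the trial's reported tables.

    Python's built-in ``round`` is banker's rounding; report tables round
    half up (e.g. 12.195% -> 12.2%).
    """
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
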