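"""Unit system and conversion constants.

The internal unit system is mm / ms / kPa throughout the solid model and
kPa / mL / ms in the lumped circulation.  This is a consistent mechanical
system: with mass in mg, 1 kPa = 1 mN/mm^2 and force = mass * acceleration
holds without conversion factors (1 mN = 1 mg * mm/ms^2).  Pressures at the
user-facing I/O boundary (CSV records, analysis summaries) are in mmHg,
volumes in mL, flows in mL/s where stated.
"""

#: mmHg per kPa.  Single authoritative conversion constant.
MMHG_PER_KPA = 7.50062

KPA_PER_MMHG = 1.0 / MMHG_PER_KPA

#: mm^3 per mL
MM3_PER_ML = 1000.0

#: Blood density, mg/mm^3 (= 1050 kg/m^3), used in Bernoulli/inertance terms.
RHO_BLOOD = 1.05

#: Myocardial tissue density, mg/mm^3 (= 1060 kg/m^3).
RHO_TISSUE = 1.06


def kpa_to_mmhg(p):
    """Convert pressure from kPa to mmHg."""
    return p * MMHG_PER_KPA


def mmhg_to_kpa(p):
    """Convert pressure from mmHg to kPa."""
    return p * KPA_PER_MMHG
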