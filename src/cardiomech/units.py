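"""Centralized unit conversions."""

#: 1 mmHg in kPa.
MMHG_TO_KPA = 0.133322
KPA_TO_MMHG = 1.0 / MMHG_TO_KPA

#: 1 ml in mm^3.
ML_TO_MM3 = 1000.0
MM3_TO_ML = 1.0e-3


def mmhg_to_kpa(p):
    return p * MMHG_TO_KPA


def kpa_to_mmhg(p):
    return p * KPA_TO_MMHG
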