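"""Unit conversions.

Internal computations use hours, micrograms and litres throughout; the
clinical interface (CSV datasets, CLI, dosing tables) speaks minutes and
µg/kg/min. All conversions between the two live here so no factor of 60
or 70 is hand-typed anywhere else.
"""

REF_WEIGHT_KG = 70.0


def min_to_h(t_min):
    return t_min / 60.0


def h_to_min(t_h):
    return t_h * 60.0


def ug_kg_min_to_ug_h(rate_ug_kg_min, weight_kg):
    """Per-kilogram infusion rate to absolute drug input in µg/h."""
    return rate_ug_kg_min * weight_kg * 60.0


def ug_h_to_ug_kg_min(rate_ug_h, weight_kg):
    return rate_ug_h / weight_kg / 60.0


def rate70_to_ug_kg_min(rate_ug_h_70kg):
    """Rate expressed per 70 kg (µg/h/70 kg) to µg/kg/min."""
    return rate_ug_h_70kg / REF_WEIGHT_KG / 60.0


def ug_to_mg(x_ug):
    return x_ug / 1000.0
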