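"""Centralised unit conversions.

Internal convention throughout the package:

* time in hours (h)
* concentration in mg/L (numerically identical to ug/ml)
* dose per body weight in mg/kg
* volumes of distribution in L/kg
* clearances in L/h/kg internally; reported as ml/min/kg

With dose in mg/kg and volume in L/kg, a bolus initial concentration
``dose / V`` comes out directly in mg/L.  Analytes assayed in ng/ml
(the pindolol isomers) are converted on ingest and never stored in
mixed units.
"""

ML_MIN_KG_PER_L_H_KG = 1000.0 / 60.0  # 1 L/h/kg == 16.67 ml/min/kg


def ml_min_kg_to_l_h_kg(cl: float) -> float:
    """ml/min/kg -> L/h/kg."""
    return cl * 60.0 / 1000.0


def l_h_kg_to_ml_min_kg(cl: float) -> float:
    """L/h/kg -> ml/min/kg."""
    return cl * ML_MIN_KG_PER_L_H_KG


def ng_ml_to_mg_l(c: float) -> float:
    """ng/ml (= ug/L) -> mg/L (= ug/ml)."""
    return c * 1e-3


def mg_l_to_ng_ml(c: float) -> float:
    return c * 1e3
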