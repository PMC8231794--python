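"""Physical constants and study defaults used throughout the package.

Molar masses are for meropenem (parent) and its open-ring hydrolysis
metabolite (ORM).  Rate constants are first-order degradation rates of
meropenem in 0.9% saline at 22 °C and in pH-buffered human serum at 37 °C.
"""

#: Molar mass of meropenem, g/mol.
MM_MEROPENEM = 383.46

#: Molar mass of the open-ring metabolite, g/mol.
MM_ORM = 401.16

#: First-order degradation rate of 2% meropenem in normal saline at 22 °C, 1/h.
K_SALINE_22C = 0.006

#: First-order degradation rate of meropenem in buffered serum at 37 °C, 1/h.
K_SERUM_37C = 0.025

#: Literature volume of distribution for meropenem in critically ill adults, L.
V_LITERATURE_L = 26.2

#: Unit bridge: GFR in mL/min times this factor gives clearance in L/h.
GFR_TO_L_PER_H = 0.06

#: Pharmacopoeial stability criterion: fraction of initial concentration.
STABILITY_THRESHOLD = 0.90

#: Sampling schedule of the in vitro stability experiments, hours.
STABILITY_SCHEDULE_H = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0,
                        12.0, 14.0, 16.0, 20.0, 24.0)

#: Typical residual (non-GFR, non-decay) clearance, L/h.
THETA_CL_NONGFR = 3.6

#: Between-patient SD of log total clearance (exponential IIV model).
OMEGA_CL = 0.149

#: Proportional residual error SD (fraction of the prediction).
SIGMA_PROP = 0.135

#: Assay lower limits of quantification, mg/L.
LLOQ_MEROPENEM = 1.0
LLOQ_ORM = 0.62
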