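"""Bench-assay computations: 2^-ddCt qPCR quantification and standard-curve
interpolation for plate assays.
"""

import pandas as pd

import synmod as sm

# --- relative expression by the comparative 2^-ddCt method ---------------
# knockdown validation: target gene Ct rises ~2 cycles in the RNAi sample
ct = pd.DataFrame(
    [
        ("control", "target", 24.1), ("control", "target", 24.3),
        ("control", "GAPDH", 20.0), ("control", "RPL32", 21.0),
        ("RNAi", "target", 26.2), ("RNAi", "target", 26.4),
        ("RNAi", "GAPDH", 20.1), ("RNAi", "RPL32", 21.1),
    ],
    columns=["sample", "gene", "ct"],
)
rel = sm.ddct_relative_expression(
    ct, target="target", references=["GAPDH", "RPL32"], calibrator_sample="control"
)
print("relative expression (control = 1):")
print(rel.round(3).to_string())
print(f"-> the RNAi sample retains ~{100 * rel['RNAi']:.0f}% of control "
      "expression: a ~2-cycle Ct shift is a ~4-fold knockdown\n")

# --- ELISA-style standard-curve interpolation ----------------------------
curve = sm.StandardCurve(
    readings=[0.05, 0.15, 0.42, 0.95, 1.80],
    concentrations=[12.5, 25, 50, 100, 200],  # pg/mL standards
)
reading = 0.60
conc = sm.standard_curve_interpolate(curve, reading, dilution_factor=25)
print(f"plate reading {reading} with a 1:25 dilution -> "
      f"{conc:.0f} pg/mL in the original homogenate")
print("(piecewise-linear interpolation between flanking standards; "
      "readings outside the standards raise instead of extrapolating)")
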