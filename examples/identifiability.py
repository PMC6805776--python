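"""Which parameters can the 39-point design actually pin down?

Computes the weighted sensitivity matrix of the full 25-parameter free
set on a noise-free synthetic suite and screens it with the collinearity
index (reciprocal of the smallest singular value of the column-scaled
Jacobian; singular values below 0.1 are rejected greedily).
"""

from nkhif import PEPConfig, identifiability_screen, sensitivity_matrix
from nkhif.synthetic import default_design, generate_calibration_suite

design = default_design(seed=3, sd=0.0)
calibration, _ = generate_calibration_suite(design)

cfg = PEPConfig(use_priors=False, rtol=1e-7, atol=1e-9)
report = sensitivity_matrix(design.params_true, calibration, cfg)
screen = identifiability_screen(report, threshold=0.1)

print(f"sensitivity matrix: {report.jacobian.shape[0]} residual rows x "
      f"{report.jacobian.shape[1]} free parameters")
print(f"collinearity index of the full set: {screen.collinearity_index:.0f}")
print(f"estimable ({len(screen.estimable)}): {', '.join(screen.estimable)}")
print(f"rejected  ({len(screen.rejected)}): {', '.join(screen.rejected)}")

print("\nA large collinearity index means some directions in parameter "
      "space barely move the observables; the screen fixes those "
      "parameters at their priors so the remaining subset is reliably "
      "estimable from this design.")
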