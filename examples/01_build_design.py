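"""Build and inspect the 13-outcome balanced incomplete block design.

Each of the 13 scenarios shows 4 outcomes; every outcome appears in 4
scenarios and every pair of outcomes is shown together exactly once, so
the survey covers all 78 pairwise trade-offs with no redundancy.
"""

from bwsprefs import build_bibd, statin_catalogue, validate_design
from bwsprefs.design import design_to_frame

catalogue = statin_catalogue()
design = build_bibd(v=13, k=4)

print(f"BIBD parameters: v={design.v}, b={design.b}, r={design.r}, k={design.k}, lambda={design.lam}")
report = validate_design(design)
print(f"validation: {'all checks pass' if report.passed else report.failures()}")

frame = design_to_frame(design, catalogue)
print("\nFirst two scenarios (each row = one outcome shown in that scenario):")
print(frame.head(8).to_string(index=False))
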