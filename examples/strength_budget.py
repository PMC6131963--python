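"""Tensile load budget of the force-transmitting pad structures.

Capacity = measured cross-sectional area x assumed tensile strength, compared
against the largest load measured on a single digital pad (1.27 N) and the
per-digit share of body weight (3.815 mN).
"""

from frogpad.budget import budget_frame, budget_report, per_digit_load

demands = {"single_pad_max_load": 1.27, "per_digit_body_weight": per_digit_load()}
df = budget_frame(budget_report(reference_loads=demands))
print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(
    "\nCapacities are area x strength bounds (1 um^2 x 1 MPa = 1e-6 N); a row is\n"
    "'sufficient' when even its lower capacity bound exceeds the demand."
)
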