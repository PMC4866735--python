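"""Tendon force-strain curves for the packaged participant parameters.

The series-elastic element follows an exponential force-strain law with a
toe region shaped by K_sh; by construction the force equals F_max exactly
at the reference strain lambda_ref, whatever the shape factor.
"""

import numpy as np

from gaitmtu import io as gio
from gaitmtu import reference_params, tendon_force

vec = gio.load_participant(1)
print("participant 1, tendon force at the reference strain:")
for muscle in ("TA", "SOL", "GAS", "VAS"):
    block = vec.muscle_block(muscle)
    p = reference_params(muscle, F_max=block["F_max"],
                         K_sh=block["K_sh"], lambda_ref=block["lambda_ref"])
    f_ref = tendon_force(block["lambda_ref"], p)
    f_half = tendon_force(block["lambda_ref"] / 2, p)
    print(f"  {muscle:4s} F(lambda_ref) = {f_ref:7.1f} N "
          f"(F_max = {block['F_max']:.0f} N), "
          f"F(lambda_ref/2) = {f_half:6.1f} N "
          f"[{100 * f_half / f_ref:4.1f}% - the toe region]")

# The toe fraction shows how strongly K_sh curves the relation: a linear
# spring would give 50% at half strain; values well below 50% mean the
# tendon is compliant at low loads and stiffens as it is stretched.
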