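"""Reproduce the published RBE values from the two regression curves.

The iron-ion curve y = (x + 0.95)^5 - 0.774 and the X-ray curve
y = (x - 0.9)^3 + 0.729 are inverted at the published iso-effect levels
(15 and 45 rosette-shaped apoptotic clusters per optic tectum); the RBE is
the X-ray dose divided by the iron-ion dose at equal effect.
"""

from rbefit import medaka_reference, rbe_profile

ref = medaka_reference()
for est in rbe_profile(ref.iron_curve, ref.xray_curve, [15.0, 45.0]):
    print(
        f"y = {est.effect_level:>4.0f} clusters/OT: iron-ion dose {est.dose_test:.4f} Gy, "
        f"X-ray dose {est.dose_reference:.4f} Gy  ->  RBE = {est.rbe:.4f} (~{est.rbe:.1f})"
    )
# The two RBE values bracket how many times more neurocytotoxic per Gy
# iron-ions are than X-rays; the ratio shrinks at higher effect levels
# because the iron-ion curve is the steeper of the two.
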