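"""Chemostat washout of an injected nutrient impulse.

Builds the two dosing schemes (glucose and ammonium sulphate into a 1 L
working volume at D = 0.1 h^-1) and evaluates the first-order washout
closed form at a few times.
"""
import numpy as np

from pulsewave import AMMONIUM_PULSE, GLUCOSE_PULSE, residence_times_to_hours, washout_concentration

for name, model in (("glucose", GLUCOSE_PULSE), ("ammonium sulphate", AMMONIUM_PULSE)):
    print(f"{name}: stock {model.stock_conc}% w/v, {model.v_inj*1000:.0f} mL into {model.V} L "
          f"-> step of {model.delta_C0:.3f}% w/v")
    for t in (0.0, 1.0, 7.0, 10.0):
        c = washout_concentration(model, t)
        print(f"  t = {t:4.1f} h  C = {c:.4f}% w/v  ({100*c/model.delta_C0:.1f}% of the step left)")

print(f"\nsteady state needs {residence_times_to_hours(5, 0.1):.0f} h (5 residence times at D = 0.1/h)")
print("after one residence time (10 h) the increment has decayed to 1/e, "
      f"i.e. {np.exp(-1)*100:.1f}% -- the impulse is effectively gone within the 7 h sampling horizon")
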