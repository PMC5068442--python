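"""The store/usage model: what dive duration should do with mass and temperature.

Evaluates t_D = (a/c) * M^(b-d) * e^(-kT) on a few masses and temperatures,
prints the predicted log-log mass slope, and shows a Q10 temperature
normalization of an observed dive.
"""

from divescaling import (
    ScalingParams,
    mass_exponent,
    normalize_duration,
    predicted_dive_duration,
    q10_rate_coefficient,
)

params = ScalingParams()  # b=1, d=3/4, k=0.12 per degree C, Q10=2.5, T_ref=30

print("predicted mass exponent b - d =", mass_exponent(params))
print("rate coefficient equivalent to Q10=2.5:",
      round(q10_rate_coefficient(params.Q10), 5), "per degree C")
print()
print("relative dive duration (a=c=1):")
for mass_g in (1e2, 1e4, 1e6):
    for temp_C in (10.0, 25.0):
        t = predicted_dive_duration(mass_g, temp_C, params)
        print(f"  M = {mass_g:>9.0f} g, T = {temp_C:>4.1f} C -> "
              f"{t.duration_min:8.3f} min")
print()

# A 12-minute dive observed at 20 C, moved to the 30 C reference: the rate
# rises 2.5-fold over those 10 degrees, so the duration shrinks 2.5-fold.
obs, obs_temp = 12.0, 20.0
print(f"observed {obs} min at {obs_temp} C -> "
      f"{normalize_duration(obs, obs_temp, params):.2f} min at "
      f"{params.T_ref} C reference")
print("Every 10 C of warming cuts the predicted dive duration by the Q10 "
      "factor; every 16-fold mass gain doubles it (M^0.25).")
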