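"""Fit a Hill force-velocity hyperbola to one afterloaded T-V curve.

Synthesizes nine afterload points on a known hyperbola (a = 12 mN/mm²,
b = 0.9 Lo/s, To = 45 mN/mm²), perturbs the tensions with measurement
noise, and recovers the curve.  The curvature G = To/a = Vmax/b is the
single number that carries the muscle-level mechanics into the
crossbridge model.
"""

import numpy as np

import myothermo as mt

rng = np.random.default_rng(0)
truth = dict(a=12.0, b=0.9, to=45.0)

clean = mt.sample_hyperbola(**truth)
noisy_points = [mt.TVPoint(max(p.tension + rng.normal(0, 0.25), 0), p.velocity)
                for p in clean.points]
dataset = mt.TVDataset(muscle_id="demo", phase="anoxia", time_min=0,
                       points=noisy_points, vmax_measured=clean.vmax_measured)

fit = mt.fit_hill(dataset)
print(f"true   : a = {truth['a']:.2f} mN/mm2, b = {truth['b']:.3f} Lo/s, "
      f"G = {truth['to'] / truth['a']:.2f}")
print(f"fitted : a = {fit.a:.2f} mN/mm2, b = {fit.b:.3f} Lo/s, "
      f"G = {fit.g:.2f}  (r2 = {fit.r2:.5f})")
print(f"fitted zero-tension velocity Vmax = b*G = {fit.vmax:.2f} Lo/s")
print()
print("The asymptotes (a, b) set how sharply tension trades against")
print("velocity; G and b feed the attachment/detachment rate constants.")
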