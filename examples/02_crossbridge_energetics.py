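"""Molecular crossbridge parameters from cohort-mean mechanics.

Takes the control-time (t = 0) cohort means of the reference tables and
derives the two-state crossbridge observables: unitary force po,
catalytic constant kcat, crossbridge number N, and the contractile
efficiency curve with its maximum.
"""

import myothermo as mt

ref = mt.load_reference_cohort("anoxia").set_index("time_min")
c = mt.DEFAULT_CONSTANTS

f1, g1, g2 = (float(ref.loc[0, k]) for k in ("f1_mean", "g1_mean", "g2_mean"))
to = float(ref.loc[0, "tension_mean"])

po = mt.unitary_force(f1, g1, c)
kcat = mt.catalytic_constant(f1, g1, c)
eff = mt.efficiency_analysis(f1, g1, g2, c)
n_cb = (to * 1e-3) / (po * 1e-12)

print(f"rate constants      : f1 = {f1:.0f}, g1 = {g1:.0f}, "
      f"g2 = {g2:.0f} s^-1")
print(f"unitary CB force    : po = {po:.3f} pN "
      f"(ceiling w/l = {c.w_over_l_pN:.3f} pN)")
print(f"catalytic constant  : kcat = {kcat:.2f} s^-1")
print(f"crossbridge number  : N = To/po = {n_cb:.3g} per mm^2")
print(f"max efficiency      : {100 * eff.max_efficiency:.1f} % "
      f"at V/Phi = {eff.v_opt / ((f1 + g1) * c.h / 2):.2f}")
print()
print("po is the mean force of one attached myosin head; kcat its ATP")
print("turnover.  Efficiency peaks near half the characteristic sliding")
print("velocity Phi and is bounded by the work fraction w/e = 0.75.")
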