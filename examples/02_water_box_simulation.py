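"""Build, relax and run a small rigid-water box, then print bath diagnostics.

A 64-molecule SPC-parameter water box is placed on a jittered lattice,
relaxed by constrained steepest descent, given Maxwell-Boltzmann velocities
and integrated for 2 ps with a 0.8 nm single-range group cutoff (reaction
field at eps_rf = 78) under a weak-coupling bath at 298.15 K.
"""

import cutoffmd as md

scheme = md.scheme_cg_ow(r_short=0.8, r_long=0.8, update_interval=1)
params = md.RFParams(eps_rf=78.0, r_rf=0.8)

system = md.build_water_box(64, 1.7, seed=1)
system = md.minimize(system, scheme, params=params, n_steps=200)
system = md.assign_maxwell_velocities(system, 298.15, seed=2)

protocol = md.Protocol(n_steps=1000, log_interval=50, frame_interval=100)
result = md.run_simulation(system, scheme, protocol, params=params)

df = result.log_frame()
print(df[["time", "T_solvent", "e_pot", "e_kin", "pressure"]].round(2).to_string(index=False))
print(f"\nframes stored: {len(result.frames)}")
print(f"max constraint violation: {result.diagnostics['max_constraint_violation']:.2e}")
print(
    "\nThe bath pins the box at a steady temperature noticeably above its\n"
    "298.15 K reference: pair interactions crossing the short 0.8 nm cutoff\n"
    "do irregular work (cutoff noise) that the weak-coupling bath must\n"
    "continuously remove, and the steady state settles where removal\n"
    "balances injection."
)
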