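"""Solvent-structure diagnostics: O-O RDF and dipole orientation correlation.

Runs a short water simulation and computes the radial distribution function
of the oxygen atoms and the dipole-dipole orientation correlation C(r),
binned by O-O distance. In longer runs the atomistic cutoff scheme develops
artificial RDF structure at the cutoff radius that the group scheme lacks.
"""

import cutoffmd as md
from cutoffmd.study import StudyConditions, oxygen_rdf, run_scheme

conditions = StudyConditions(
    n_waters=216, t_equilibration=3.0, t_production=4.0, seeds=(1,)
)
run = run_scheme(conditions, "AT", seed=1)
system = run.result.system

curve = oxygen_rdf(run, system, conditions)
print("O-O radial distribution function (bin centers in nm):")
for r, g, n in zip(curve.bin_centers[::5], curve.values[::5], curve.counts[::5]):
    bar = "#" * int(round(20 * min(g, 3.0) / 3.0))
    print(f"  r = {r:5.3f}  g = {g:5.2f}  {bar}")

dcf = md.dipole_correlation(run.production_frames, system, 0.05, 0.9)
occ = dcf.counts > 0
print("\ndipole orientation correlation C(r):")
for r, v in zip(dcf.bin_centers[occ][::3], dcf.values[occ][::3]):
    print(f"  r = {r:5.3f}  C = {v:+.3f}")

print(
    "\ng(r) shows the liquid's first peak near 0.28 nm; C(r) is strongly\n"
    "positive for hydrogen-bonded neighbors and decays with distance.\n"
    "Comparing AT against CG(OW) over longer runs exposes the artificial\n"
    "structure at the cutoff radius (see the README's worked example)."
)
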