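"""Sample a hydration shell around dimethylphosphate and evaluate the
solvent electric field at the phosphate probe.

Runs a reduced-size Monte Carlo at 298 K and 330 K (same starting
configuration), histograms the field projected on the PO2 C2 axis, and
maps the temperature-induced mean-field change to a band shift of the
symmetric PO2 stretch via the published Stark tuning rate.
"""

import numpy as np

import shellfield as sf

dmp = sf.dmp_gauche_gauche()
cell = sf.SimulationCell("droplet", 7.6)
probe = sf.c2_probe(dmp)

samples = {}
for temp in (298.0, 330.0):
    params = sf.MCParams(
        temperature=temp, n_sweeps=120_000, equilibration_fraction=0.5,
        seed=7, sample_stride=200, max_translation=0.3, max_rotation=0.45,
    )
    traj = sf.mc_sample(dmp, 60, cell, params)
    ep = np.array([s.parallel for s in sf.trajectory_fields(traj, probe)])
    samples[temp] = ep
    print(f"T = {temp:g} K: {len(traj)} frames, acceptance "
          f"{traj.acceptance_fraction:.2f}, E_par = {ep.mean():.1f} "
          f"± {ep.std(ddof=1):.1f} MV/cm")

edges = np.arange(-160.0, 0.0, 2.0)
d_cold = sf.field_distribution(samples[298.0], bin_edges=edges, temperature=298.0)
d_hot = sf.field_distribution(samples[330.0], bin_edges=edges, temperature=330.0)
delta_e, se = sf.mean_field_change(d_cold, d_hot, seed=0)
shift = sf.stark_shift(delta_e, sf.PO2_SYMMETRIC_STRETCH)

print(f"\nmean-field change (330 K − 298 K): {delta_e:+.1f} ± {se:.1f} MV/cm")
print(f"implied symmetric-PO2-stretch shift: {shift:+.2f} cm^-1 "
      f"(a = 0.4 cm^-1/(MV/cm))")
print("\nThe field projection is negative (the shell polarizes toward the")
print("anion) at tens of MV/cm.  At this reduced sampling scale the")
print("between-run scatter of the mean exceeds the few-MV/cm thermal effect")
print("itself, so the printed change reflects sampling noise as much as")
print("temperature; the bootstrap error only captures within-run scatter.")
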