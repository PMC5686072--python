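"""Fit a dissociation constant from a fast-exchange NMR titration.

Simulates amide chemical-shift perturbations for a weak binder
(K_D = 6 mM, the affinity regime of the best tetrazole lead) at the
study conditions - 0.05 mM protein, 12 ligand points up to 40 mM, 2%
noise - then refits the two-state model sharing one K_D across residues.
"""

from dynappi.nmr_titration import fit_kd, fraction_bound
from dynappi.synthetic import simulate_titration

KD_TRUE = 6.0  # mM
DMAX = [0.66, 0.40, 0.20]  # ppm, per-residue saturation amplitudes

series = simulate_titration(KD_TRUE, DMAX, seed=42)
print(f"titration: {series.n_points} points, ligand 0-{series.ligand_totals[-1]:.0f} mM, "
      f"protein {series.protein_total} mM")
print(f"bound fraction at the final point: "
      f"{fraction_bound(series.protein_total, series.ligand_totals[-1], KD_TRUE):.3f}")

fit = fit_kd(series, mode="global_shared_kd")
print(f"\nfitted K_D = {fit.kd:.2f} +/- {fit.se_kd:.2f} mM  (true {KD_TRUE})")
for res, dm, se in zip(fit.residues, fit.dmax, fit.se_dmax):
    print(f"  residue {res}: ddelta_max = {dm:.3f} +/- {se:.3f} ppm")
print(f"converged: {fit.converged}")
# The K_D is identified by the curvature of the isotherm at high ligand
# excess; a strictly linear response would be flagged non-identifiable
# instead of returning a spurious constant.
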