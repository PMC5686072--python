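# dynappi

Tools for discovering small-molecule modulators of the SxIP–EB1
protein–protein interaction — and, more generally, of shallow, dynamic
binding sites where single-structure docking misleads. EB1's C-terminal
EBH domain recognises +TIP partners through the short Ser-x-Ile-Pro
(SxIP) motif; the pocket is formed partly by mobile side chains (Arg222,
Tyr247) that open and close it in the free protein. `dynappi` implements
the full computational workflow around that problem as a tested,
reusable library:

- **Pharmacophore screening** (`dynappi.pharmacophore`): typed
  interaction points (H-bond acceptor/donor, hydrophobic centroids)
  extracted from a peptide complex; combinatorial feature-subset queries;
  conformer matching by exhaustive kind-compatible correspondence search
  with closed-form least-squares superposition, filtered at an RMSD
  cutoff (default 0.5 Å) and deduplicated to unique compounds.
- **Compound prioritisation** (`dynappi.prioritize`): monoisotopic mass
  and Lipinski profiling, ligand efficiency (score per heavy atom),
  consensus scoring across scoring functions, Pareto non-dominated
  sorting over docking and drug-likeness objectives, solubility and
  docking-pose-consistency filters, all composed into a staged funnel
  with an audit log.
- **NMR titration analysis** (`dynappi.nmr_titration`): combined amide
  chemical-shift perturbations Δδ = √(Δδ_H² + (0.14·Δδ_N)²) and K_D
  estimation in the fast-exchange regime, where the observed CSP is the
  population-weighted average Δδ_obs = Δδ_max · f_b with

      f_b = ((P_t + L_t + K_D) − √((P_t + L_t + K_D)² − 4·P_t·L_t)) / (2·P_t)

  fitted by multi-start nonlinear least squares, optionally sharing one
  K_D across residues, with covariance-based standard errors and explicit
  non-identifiability flagging.
- **Receptor-ensemble analysis** (`dynappi.ensemble`): cross-docking
  score aggregation over conformational ensembles, rank agreement
  (Kendall τ / Spearman ρ) against experimental affinity orders, pocket
  "gate" distance series (Tyr247 Cζ ↔ Leu221/Leu246 Cα), RMSF after
  iterated mean-structure superposition, open/closed/bound-like state
  classification, and simulation-box charge arithmetic.
- **Synthetic data with ground truth** (`dynappi.synthetic`): seeded
  generators for planted conformer libraries, fast-exchange titrations,
  toy gate ensembles and score matrices, driving every test.

Formats: SDF V2000 (conformer/feature libraries), multi-model PDB
(ensembles), CSV with unit-suffixed columns (shifts, scores), JSON
(fits, audit logs). A thin `dynappi` CLI wraps the library
(`pharm`, `screen`, `csp-fit`, `ensemble-score`, `pocket`, `rmsf`,
`simulate`, `run`).

## Worked example

```python
from dynappi.synthetic import simulate_titration
from dynappi.nmr_titration import fit_kd

series = simulate_titration(kd=6.0, dmax=[0.66, 0.40, 0.20], seed=42)
fit = fit_kd(series, mode="global_shared_kd")
print(f"K_D = {fit.kd:.2f} ± {fit.se_kd:.2f} mM")
```

prints

```
K_D = 5.99 ± 0.31 mM
```

i.e. a titration simulated at the affinity of the best tetrazole lead
(6 mM, protein 0.05 mM, 12 points up to 40 mM, 2% noise) refits to
within one standard error of the truth; Δδ_max comes back per residue
(0.660 ± 0.010 ppm for the most-perturbed one). The `examples/`
directory holds one narrative script per capability — pharmacophore
screening with planted-hit recovery, the prioritisation funnel,
the titration fit above, and ensemble ranking + pocket-state analysis —
each printing the numbers it computes and what they mean.

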