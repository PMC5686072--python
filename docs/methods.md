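# Methods

This note documents the models, numerical choices and limitations behind
`dynappi`, in the order of the pipeline.

## Pharmacophore models and matching

A pharmacophore feature is a typed sphere: kind ∈ {acceptor, donor,
hydrophobic}, a centre (Å), a match radius (default 1.0 Å — the source
screening service does not publish its radii, so one consistent default
is used and exposed), and an optional unit direction vector. The shipped
SxIP preset derives 8 features from a Ser-x-Ile-Pro peptide: two
acceptors around the Ser hydroxyl (the OG atom and the OG/CB midpoint,
standing in for the two lone-pair directions), three hydrophobic
centroids (Ile CB/CG1/CD1, Ile CG2, Pro CB/CG/CD ring), one acceptor on
the Ile backbone N and donors on the Ile and Pro carbonyl O. That
acceptor/donor assignment of the backbone amine and carbonyls follows
the published description literally even though a chemist would swap
them (amines donate, carbonyls accept); `chemically_corrected=True`
performs the swap. Feature centres are centroids of the named atoms, in
the input coordinate frame — residue numbering and chains are never
rewritten.

Subset queries enumerate all index combinations of the requested sizes
in lexicographic order. For 5–7 of 8 points this gives C(8,5) + C(8,6) +
C(8,7) = 92 queries; a published count of 71 for the same construction
implies an additional, unstated constraint, so the enumeration ships
unconstrained and exposes a predicate hook for callers who know their
constraint.

Matching is exact: every injective, kind-identical assignment of query
features to conformer points is enumerated (a product of per-kind
permutations), each candidate is superposed by the closed-form SVD
(Kabsch) rotation with reflections rejected, and the minimum RMSD wins.
Exhaustive search is capped at 12 query features — factorial cost is
irrelevant at pharmacophore sizes and buys testability against an
independent brute-force oracle. Direction vectors, when present on both
sides, can additionally be checked against an angular tolerance (default
45°, off by default; no published tolerance exists). Library screening
keeps each molecule's best conformer ("unique compounds" semantics) and
reports only matches at or below the RMSD cutoff (default 0.5 Å,
boundary inclusive).

## Prioritisation

Monoisotopic masses use principal-isotope masses for C, H, N, O, S, P
and the halogens; values are exact sums, compared at two decimals in
tests because that is the precision of the published formulas. Ligand
efficiency is score / heavy-atom count — heavy atoms, the standard LE
convention, because the source text says only "number of atoms"
(configurable by passing a different count). Lipinski profiling uses
MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10 with inclusive boundaries, as do
all other filters (solubility cutoff default 10⁻⁴ M).

Consensus selection intersects the top ⌈fraction·n⌉ ids of every scoring
column (direction-aware, ties broken by id). The fraction is not
published; the default 0.25 is scale-free and configurable — the
semantics (intersection across scoring functions) is the stable part.

Pareto ranking is non-dominated sorting: front 1 is the set dominated by
no one; front k is non-dominated after removing fronts < k; dominance
means no-worse in every objective and strictly better in at least one
after aligning directions. Within a front, compounds are ordered by a
normalised rank-sum tie key (average ranks per objective, summed,
divided by n·m) — deterministic and cheaper to reason about than
crowding distance. Truncation to top-n cuts at front boundaries,
breaking the boundary front by tie key then id. The default objective
set {consensus score max, ligand efficiency max, MW min, logP min,
HBD min, HBA min, solubility max} is a documented choice; the published
description names only "docking results and desirable molecular
properties", so the set is fully configurable.

Pose consistency is the mean pairwise RMSD of docked poses computed in
the shared receptor frame **without** superposition: docked poses live
in one frame, and superposing them would hide exactly the spread the
metric measures.

## Fast-exchange titration fitting

The model is single-site binding with the physical ("minus") root of the
mass-action quadratic; the plus root exceeds total protein and is never
meaningful. Observed CSPs are Δδ_max · f_b (fast exchange). The combined
amide CSP uses the standard weighting α = 0.14 for ¹⁵N (configurable);
pre-combined profiles are accepted as-is since published Δδ values do
not state whether they are combined or ¹H-only.

Fitting is nonlinear least squares (scipy `least_squares`, TRF) over
(K_D, Δδ_max per residue), multi-started from K_D ∈ {0.1, 1, 10, 100} mM
to avoid local minima; the global mode shares one K_D across residues.
Two numerical details matter:

- The ligand-free reference point is excluded from the residual vector.
  Its CSP is zero by definition (shifts are measured against the free
  spectrum), so it carries no information and would only deflate the
  error estimate. For the same reason the synthetic generator adds no
  noise at that point.
- After an unweighted first pass, residuals are re-weighted by
  1/|Δδ_max| per residue (clamped at 10% of the largest amplitude) with
  a single pooled error scale. CSP measurement scatter scales with the
  perturbation amplitude in this pipeline's error model; the weighting
  makes residues with small amplitudes count fairly and the covariance
  estimate honest. Standard errors come from the weighted covariance at
  the optimum, scaled by the pooled residual variance.

Non-identifiability is flagged, never silently returned: a fit is marked
unconverged when (a) a straight line through the origin explains the
data essentially as well as the isotherm (K_D is identified only by
curvature), (b) the fitted K_D exceeds 25× the largest ligand
concentration (the sampled range never left the linear regime), or
(c) the normal matrix is numerically singular. Units are mM and ppm
throughout.

## Ensemble analysis

Score aggregation over receptor conformations reports mean, sd, min and
max per compound; NaN cells (failed dockings) are excluded with a logged
count rather than imputed. Ranking is by mean, ties by id. Rank
agreement against an experimental affinity order uses the tie-corrected
Kendall τ and Spearman ρ from scipy.

RMSF uses iterated mean-structure superposition: each model is Kabsch-
fitted (on the fit selection, e.g. helical-core Cα atoms) to the running
mean, the mean is recomputed, and the cycle repeats to 10⁻⁶ Å (minimum
two iterations). This removes the reference bias of fitting to an
arbitrary first model. RMSF is the RMS deviation from the converged mean
per reported atom; per-residue values are means over the residue's
reported atoms.

Pocket state classification works on two "gate" distances (for the EBH
pocket, Tyr247 Cζ to Leu221 Cα and to Leu246 Cα). No published numeric
thresholds exist, so the thresholds object is always explicit: closed
when both gates ≤ closed_max, open when both ≥ open_min, bound-like when
both fall within ±1.5 Å (configurable) of reference distances taken from
a bound-form structure — the bound-like window takes precedence, and
anything else is indeterminate. Overlapping regions are a configuration
error.

The charge utility uses the integer pH-7 model: Asp/Glu −1, Lys/Arg +1,
His 0 (pKa ≈ 6), charged termini contributing net zero (both termini
configurable). On the canonical human EB1 sequence (embedded, 268
residues, validated against its known ~30 kDa mass) residues 191–260
carry 18 acidic and 6 basic side chains, i.e. −12 per monomer and 24
neutralising cations for the dimer under this model. A published value
of −11/22 for the same construct is reproduced only if the C-terminus is
treated as neutral (capped), which the termini options allow.

The soft-sphere docking backend is a deterministic contact surrogate
(ligand points inside a pocket sphere score linearly with depth) that
exists to exercise the pipeline contract end-to-end; real scores enter
as CSV matrices.

## Synthetic data

One global seed spawns independent per-generator child seeds via
`numpy.random.SeedSequence.spawn`, keyed by a fixed generator order, so
each stage is reproducible on its own. Planted library hits are the
model's feature points under a uniform random rotation (QR of a Gaussian
matrix), random translation and isotropic Gaussian jitter; decoys are
either all-hydrophobic (no kind-compatible injection can exist against
mixed-kind queries) or kind-correct with random geometry. The titration
generator uses the forward model with noise sd = noise_fraction·Δδ_max
per residue; defaults (0.05 mM protein, 12 points 0–40 mM, 2% noise) are
a documented stand-in for an unpublished experimental schedule. The toy
gate ensemble is two ideal helical Cα traces (residues 210–232 and
239–250, gate-flanking Cα atoms 8 Å apart) with a single mobile Cζ atom
placed on the perpendicular bisector so both gate distances hit the
closed (5.5 Å) or open (12 Å) target, plus 0.3 Å jitter.

What the generators do **not** emulate: real conformer chemistry
(feature points are abstract), spectral overlap/peak tracking errors in
titrations, correlated or non-Gaussian docking-score noise, and real
side-chain sterics in the gate ensemble. Passing tests therefore
demonstrate the correctness of the algorithms under their stated models,
not performance on any particular experimental dataset.

## Problem sizes in the test suite

Tests run planted libraries of ~10–20 molecules against 5–7-point query
sets, titration ensembles of 60–200 replicates, 50×4 Pareto instances
and 200-model toy ensembles — sizes chosen so every oracle comparison is
exhaustive and the full suite stays interactive while still estimating
stochastic quantities (median bias, coverage, state fractions) with
useful precision.

## Known limitations

- Docking engines are out of scope by design; scores are consumed, not
  produced (the toy backend is a test surrogate only).
- The exhaustive matcher is exponential in query size; it is the right
  tool at ≤ 12 features but not a database-scale screening engine.
- Only pH 7 is modelled in the charge utility (integer model, no
  Henderson–Hasselbalch fractions).
- Per-residue K_D fits on weakly perturbed residues are often
  non-identifiable at realistic noise; the global shared-K_D mode is the
  recommended estimator.
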