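"""Seeded synthetic-data generators with machine-readable ground truth.

Every pipeline stage is exercised on data generated here: planted
conformer feature libraries (hits = pharmacophore points under a random
rigid motion plus jitter; decoys = kind-scrambled or geometry-randomised
point sets), fast-exchange titration curves, toy gate ensembles, and
compound x receptor-conformation score matrices with a planted affinity
order. One global seed expands into independent per-generator child
seeds via ``numpy.random.SeedSequence.spawn`` keyed by generator order,
so stages stay reproducible independently of one another.

Default study conditions (documented stand-ins where the experimental
protocol is not printed): titrations use 0.05 mM protein, 12 ligand
points from 0 to 40 mM and 2% Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nmr_titration import TitrationSeries, fraction_bound
from .pharmacophore import ConformerFeatures, Feature, PharmacophoreModel
from .structures import CoordinateEnsemble

__all__ = [
    "child_seed",
    "plant_conformer_library",
    "simulate_titration",
    "DEFAULT_TITRATION_PROTOCOL",
    "make_toy_ensemble",
    "make_score_matrix",
    "make_sxip_peptide",
]

_GENERATOR_ORDER = ("library", "titration", "ensemble", "scores")


def child_seed(seed: int, generator: str) -> np.random.SeedSequence:
    """Deterministic child seed for a named generator from one global seed."""
    if generator not in _GENERATOR_ORDER:
        raise ValueError(f"unknown generator {generator!r}; expected one of {_GENERATOR_ORDER}")
    ss = np.random.SeedSequence(int(seed))
    children = ss.spawn(len(_GENERATOR_ORDER))
    return children[_GENERATOR_ORDER.index(generator)]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


# ---------------------------------------------------------------------------
# Planted conformer libraries
# ---------------------------------------------------------------------------

def plant_conformer_library(
    model: PharmacophoreModel,
    n_hits: int,
    n_decoys: int,
    jitter_sigma: float,
    seed: int,
    *,
    decoy_mode: str = "mixed",
) -> tuple[list[ConformerFeatures], pd.DataFrame]:
    """Plant pharmacophore-matching hits among decoys.

    Hits carry the model's feature points under a random rigid motion plus
    isotropic Gaussian jitter of sd ``jitter_sigma`` (Angstrom). Decoys are
    either kind-scrambled (all points hydrophobic, so no kind-compatible
    injection exists against mixed-kind queries) or geometry-randomised
    (correct kind multiset, random geometry in a 20 A box). Returns the
    library and a truth table labelling each molecule.
    """
    if n_hits < 0 or n_decoys < 0:
        raise ValueError("counts must be >= 0")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "library"))
    centers = model.centers()
    kinds = [f.kind for f in model.features]

    library: list[ConformerFeatures] = []
    truth_rows = []

    for h in range(n_hits):
        R = _random_rotation(rng)
        t = rng.uniform(-10, 10, size=3)
        pts = centers @ R.T + t
        if jitter_sigma > 0:
            pts = pts + rng.normal(scale=jitter_sigma, size=pts.shape)
        feats = tuple(
            Feature(kind=k, center=tuple(p), label=f"pt{i}")
            for i, (k, p) in enumerate(zip(kinds, pts))
        )
        mid = f"hit{h:04d}"
        library.append(ConformerFeatures(molecule_id=mid, conformer_id="c0", points=feats))
        truth_rows.append({"molecule_id": mid, "is_hit": True, "decoy_mode": ""})

    for d in range(n_decoys):
        if decoy_mode == "kind_scrambled" or (decoy_mode == "mixed" and d % 2 == 0):
            mode = "kind_scrambled"
            dk = ["hydrophobic"] * len(kinds)
            pts = centers + rng.normal(scale=0.1, size=centers.shape)
        else:
            mode = "geometry_randomized"
            dk = list(kinds)
            pts = rng.uniform(-10, 10, size=centers.shape)
        feats = tuple(
            Feature(kind=k, center=tuple(p), label=f"pt{i}")
            for i, (k, p) in enumerate(zip(dk, pts))
        )
        mid = f"decoy{d:04d}"
        library.append(ConformerFeatures(molecule_id=mid, conformer_id="c0", points=feats))
        truth_rows.append({"molecule_id": mid, "is_hit": False, "decoy_mode": mode})

    truth = pd.DataFrame(truth_rows, columns=["molecule_id", "is_hit", "decoy_mode"])
    return library, truth


# ---------------------------------------------------------------------------
# Titration curves
# ---------------------------------------------------------------------------

#: Study-condition defaults: 0.05 mM protein, 12 points 0-40 mM, 2% noise.
DEFAULT_TITRATION_PROTOCOL = {
    "pt": 0.05,  # mM
    "lt_grid": np.linspace(0.0, 40.0, 12),  # mM
    "noise_fraction": 0.02,
}


def simulate_titration(
    kd: float,
    dmax: Sequence[float],
    pt: float = 0.05,
    lt_grid: Sequence[float] | None = None,
    noise_fraction: float = 0.02,
    seed: int = 0,
) -> TitrationSeries:
    """Forward-simulate a fast-exchange titration with Gaussian noise.

    ``dmax`` is per residue (ppm). Noise sd is ``noise_fraction * dmax``
    per residue, applied to every point except the ligand-free reference,
    which is exactly zero by construction (CSPs are measured against the
    free spectrum).
    """
    if kd <= 0 or pt <= 0:
        raise ValueError("kd and pt must be positive")
    lt = np.asarray(
        DEFAULT_TITRATION_PROTOCOL["lt_grid"] if lt_grid is None else lt_grid, dtype=float
    )
    if lt[0] != 0 or np.any(np.diff(lt) <= 0):
        raise ValueError("lt_grid must ascend from 0")
    dmax_arr = np.atleast_1d(np.asarray(dmax, dtype=float))
    rng = np.random.default_rng(child_seed(seed, "titration"))
    fb = fraction_bound(pt, lt, kd)
    clean = dmax_arr[:, None] * fb[None, :]
    noisy = clean.copy()
    if noise_fraction > 0:
        noise = rng.normal(size=clean.shape) * (noise_fraction * np.abs(dmax_arr))[:, None]
        noisy[:, 1:] += noise[:, 1:]
    return TitrationSeries(protein_total=pt, ligand_totals=lt, csp=noisy)


# ---------------------------------------------------------------------------
# Toy gate ensembles
# ---------------------------------------------------------------------------

def _helix_ca(n_res: int, start_res: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Ideal alpha-helical CA trace (rise 1.5 A, 100 deg/residue, r 2.3 A)."""
    idx = np.arange(n_res)
    theta = np.deg2rad(100.0) * idx
    xyz = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx])
    atoms = pd.DataFrame(
        {
            "name": "CA",
            "residue_number": start_res + idx,
            "residue_type": "ALA",
            "chain": "A",
        }
    )
    return atoms, xyz


def _two_helix_scaffold() -> tuple[pd.DataFrame, np.ndarray]:
    """Two packed helices flanking the gate: residues 210-232 and 239-250,
    translated so the Leu221 and Leu246 CA atoms sit 8 A apart."""
    atoms1, xyz1 = _helix_ca(23, start_res=210)
    atoms2, xyz2 = _helix_ca(12, start_res=239)
    i221 = int(np.flatnonzero(atoms1["residue_number"] == 221)[0])
    i246 = int(np.flatnonzero(atoms2["residue_number"] == 246)[0])
    xyz2 = xyz2 + (xyz1[i221] + np.array([8.0, 0.0, 0.0]) - xyz2[i246])
    atoms = pd.concat([atoms1, atoms2], ignore_index=True)
    return atoms, np.vstack([xyz1, xyz2])


def make_toy_ensemble(
    n_models: int,
    closed_fraction: float,
    gate_geometry: dict | None = None,
    seed: int = 0,
) -> tuple[CoordinateEnsemble, pd.DataFrame]:
    """Toy EBH-pocket ensemble: a rigid helical CA scaffold (residues
    210-250) plus a mobile Tyr247 Czeta gate atom whose distances to the
    Leu221/Leu246 CA atoms fall in the closed or open region per model.

    ``gate_geometry`` may override ``closed_distance`` (default 5.5 A),
    ``open_distance`` (12.0 A) and ``jitter`` (0.3 A). Returns the ensemble
    and a truth table with each model's planted state.
    """
    if n_models <= 0:
        raise ValueError("n_models must be positive")
    if not 0 <= closed_fraction <= 1:
        raise ValueError("closed_fraction must lie in [0, 1]")
    geom = {"closed_distance": 5.5, "open_distance": 12.0, "jitter": 0.3}
    if gate_geometry:
        unknown = set(gate_geometry) - set(geom)
        if unknown:
            raise ValueError(f"unknown gate_geometry keys: {sorted(unknown)}")
        geom.update(gate_geometry)

    rng = np.random.default_rng(child_seed(seed, "ensemble"))
    atoms, scaffold = _two_helix_scaffold()
    # mark the gate residues
    atoms.loc[atoms["residue_number"].isin([221, 246]), "residue_type"] = "LEU"
    atoms.loc[atoms["residue_number"] == 247, "residue_type"] = "TYR"

    i221 = int(np.flatnonzero(atoms["residue_number"] == 221)[0])
    i246 = int(np.flatnonzero(atoms["residue_number"] == 246)[0])
    a, b = scaffold[i221], scaffold[i246]
    mid = (a + b) / 2.0
    axis = b - a
    # unit vector perpendicular to the 221-246 axis
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    half = np.linalg.norm(axis) / 2.0

    def gate_position(target: float) -> np.ndarray:
        # place CZ on the perpendicular bisector so both gate distances == target
        h2 = target**2 - half**2
        if h2 <= 0:
            raise ValueError(
                f"gate target distance {target} A is below the scaffold half-span {half:.2f} A"
            )
        return mid + perp * math.sqrt(h2)

    gate_atom = pd.DataFrame(
        {"name": ["CZ"], "residue_number": [247], "residue_type": ["TYR"], "chain": ["A"]}
    )
    table = pd.concat([atoms, gate_atom], ignore_index=True)

    n_closed = int(round(closed_fraction * n_models))
    states = ["closed"] * n_closed + ["open"] * (n_models - n_closed)
    rng.shuffle(states)

    coords = np.empty((n_models, len(table), 3))
    truth_rows = []
    for m, state in enumerate(states):
        target = geom["closed_distance"] if state == "closed" else geom["open_distance"]
        cz = gate_position(target) + rng.normal(scale=geom["jitter"], size=3)
        coords[m, :-1, :] = scaffold
        coords[m, -1, :] = cz
        truth_rows.append({"model": m, "state": state})

    ens = CoordinateEnsemble(atoms=table, coords=coords, name="toy_gate_ensemble")
    return ens, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Score matrices
# ---------------------------------------------------------------------------

def make_score_matrix(
    true_order: Sequence[str],
    n_conformations: int,
    noise_sd: float,
    seed: int = 0,
    *,
    base_best: float = 64.0,
    step: float = 6.0,
):
    """Compound x conformation score matrix with a planted affinity order.

    Base scores decrease strictly along ``true_order`` (best first) from
    ``base_best`` in steps of ``step``; per-conformation Gaussian noise of
    sd ``noise_sd`` is added. Returns (ScoreMatrix, truth table).
    """
    from .prioritize import ScoreMatrix

    ids = list(true_order)
    if len(ids) < 2:
        raise ValueError("need at least 2 compound ids")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in true_order")
    rng = np.random.default_rng(child_seed(seed, "scores"))
    base = base_best - step * np.arange(len(ids), dtype=float)
    scores = base[:, None] + rng.normal(scale=noise_sd, size=(len(ids), n_conformations))
    matrix = ScoreMatrix(
        compounds=ids,
        columns=[f"conf{j}" for j in range(n_conformations)],
        scores=scores,
        higher_is_better=[True] * n_conformations,
    )
    truth = pd.DataFrame({"compound": ids, "rank": np.arange(1, len(ids) + 1), "base_score": base})
    return matrix, truth


# ---------------------------------------------------------------------------
# Synthetic SxIP peptide fixture
# ---------------------------------------------------------------------------

def make_sxip_peptide() -> CoordinateEnsemble:
    """Hand-built synthetic SxIP tetrapeptide (Ser-Lys-Ile-Pro, chain P,
    residues 5477-5480) with plausible extended-backbone geometry.

    Purely synthetic coordinates carrying every atom the SxIP preset
    names; a geometric stand-in for the crystallographic peptide, not a
    deposited structure.
    """
    rows: list[tuple[str, int, str, tuple[float, float, float]]] = []

    def res(resnum, restype, atoms):
        for name, xyz in atoms:
            rows.append((name, resnum, restype, xyz))

    # extended chain along x, ~3.5 A per residue; side chains off +y/+z
    res(5477, "SER", [
        ("N", (0.0, 0.0, 0.0)), ("CA", (1.45, 0.0, 0.0)), ("C", (2.2, 1.3, 0.0)),
        ("O", (1.6, 2.35, 0.0)), ("CB", (2.1, -1.0, 0.95)), ("OG", (2.0, -2.35, 0.5)),
    ])
    res(5478, "LYS", [
        ("N", (3.5, 1.3, 0.0)), ("CA", (4.35, 2.45, 0.0)), ("C", (5.8, 2.1, 0.0)),
        ("O", (6.3, 1.0, 0.0)), ("CB", (4.1, 3.3, 1.25)),
    ])
    res(5479, "ILE", [
        ("N", (6.55, 3.2, 0.0)), ("CA", (8.0, 3.1, 0.0)), ("C", (8.7, 4.45, 0.0)),
        ("O", (8.1, 5.5, 0.0)), ("CB", (8.6, 2.2, 1.1)), ("CG1", (10.1, 2.1, 1.0)),
        ("CG2", (8.0, 0.8, 1.1)), ("CD1", (10.8, 1.3, 2.1)),
    ])
    res(5480, "PRO", [
        ("N", (10.0, 4.55, 0.0)), ("CA", (10.8, 5.75, 0.0)), ("C", (12.25, 5.4, 0.0)),
        ("O", (12.8, 4.3, 0.0)), ("CB", (10.5, 6.6, 1.25)), ("CG", (10.0, 5.7, 2.35)),
        ("CD", (10.2, 4.35, 1.3)),
    ])

    atoms = pd.DataFrame(
        {
            "name": [r[0] for r in rows],
            "residue_number": [r[1] for r in rows],
            "residue_type": [r[2] for r in rows],
            "chain": "P",
        }
    )
    coords = np.array([r[3] for r in rows], dtype=float)[None, :, :]
    return CoordinateEnsemble(atoms=atoms, coords=coords, name="sxip_peptide_synthetic")
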