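"""Readers and writers for the pipeline's file formats.

Formats: SDF V2000 (plain or gzip) for conformer libraries, multi-model
PDB for coordinate ensembles, CSV for shift tables / score matrices /
hit tables, JSON for fits and audit logs. CSV schemas carry units in the
column names (``ligand_total_mM``, ``shift_ppm``, ``rmsd_A``) because
unit mix-ups are the dominant failure mode in titration data. Readers
validate and reject malformed records rather than coercing them.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .nmr_titration import ShiftRecord, TitrationSeries, combined_csp
from .pharmacophore import FEATURE_KINDS, ConformerFeatures, Feature
from .prioritize import ScoreMatrix
from .structures import CoordinateEnsemble

__all__ = [
    "read_sdf",
    "write_sdf",
    "read_feature_library_sdf",
    "write_feature_library_sdf",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_shift_table",
    "shift_records_to_series",
    "read_matrix",
    "write_matrix",
    "write_json",
]

_KIND_TO_ELEMENT = {"acceptor": "O", "donor": "N", "hydrophobic": "C"}
_ELEMENT_TO_KIND = {v: k for k, v in _KIND_TO_ELEMENT.items()}


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path) -> list:
    """Read molecules from an SDF V2000 file (gzipped if the name ends
    ``.gz``); parse failures raise rather than yielding None entries."""
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rb") as fh:
            supplier = Chem.ForwardSDMolSupplier(fh, removeHs=False, sanitize=False)
            mols = list(supplier)
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mols = list(supplier)
    bad = [i for i, m in enumerate(mols) if m is None]
    if bad:
        raise ValueError(f"{path}: unparsable SDF records at positions {bad[:5]}")
    return mols


def write_sdf(mols: Iterable, path: str | Path) -> None:
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            writer.write(mol)
    finally:
        writer.close()


def write_feature_library_sdf(library: Sequence[ConformerFeatures], path: str | Path) -> None:
    """Serialise a feature-point library as an SDF of pseudo-molecules.

    Feature points become atoms (acceptor -> O, donor -> N, hydrophobic ->
    C) with kinds repeated in the ``feature_kinds`` property field, so the
    file is both self-describing and viewable.
    """
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mols = []
    for conf in library:
        rw = Chem.RWMol()
        for p in conf.points:
            rw.AddAtom(Chem.Atom(_KIND_TO_ELEMENT[p.kind]))
        mol = rw.GetMol()
        c = Chem.Conformer(len(conf.points))
        for i, p in enumerate(conf.points):
            c.SetAtomPosition(i, Point3D(*p.center))
        mol.AddConformer(c)
        mol.SetProp("_Name", conf.molecule_id)
        mol.SetProp("conformer_id", conf.conformer_id)
        mol.SetProp("feature_kinds", ",".join(p.kind for p in conf.points))
        mols.append(mol)
    write_sdf(mols, path)


def read_feature_library_sdf(path: str | Path) -> list[ConformerFeatures]:
    """Read a feature-point library written by :func:`write_feature_library_sdf`."""
    out = []
    for mol in read_sdf(path):
        kinds = mol.GetProp("feature_kinds").split(",") if mol.HasProp("feature_kinds") else [
            _ELEMENT_TO_KIND[a.GetSymbol()] for a in mol.GetAtoms()
        ]
        bad = [k for k in kinds if k not in FEATURE_KINDS]
        if bad:
            raise ValueError(f"{path}: unknown feature kinds {bad}")
        pos = mol.GetConformer().GetPositions() if mol.GetNumConformers() else None
        if pos is None:
            raise ValueError(f"{path}: molecule {mol.GetProp('_Name')!r} has no coordinates")
        points = tuple(
            Feature(kind=k, center=tuple(pos[i]), label=f"pt{i}") for i, k in enumerate(kinds)
        )
        out.append(
            ConformerFeatures(
                molecule_id=mol.GetProp("_Name"),
                conformer_id=mol.GetProp("conformer_id") if mol.HasProp("conformer_id") else "0",
                points=points,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def read_pdb_ensemble(path: str | Path) -> CoordinateEnsemble:
    """Read a (multi-model) PDB file into a CoordinateEnsemble.

    All models must share the same atom table; a mismatch is an error
    naming the offending model.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    atoms = pd.DataFrame(
        {
            "name": stack.atom_name,
            "residue_number": stack.res_id.astype(int),
            "residue_type": stack.res_name,
            "chain": stack.chain_id,
        }
    )
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    return CoordinateEnsemble(atoms=atoms, coords=coords, name=path.stem)


def write_pdb_ensemble(ensemble: CoordinateEnsemble, path: str | Path) -> None:
    """Write a CoordinateEnsemble as a multi-model PDB (MODEL/ENDMDL)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_models, n_atoms = ensemble.n_models, ensemble.n_atoms
    arr = struc.AtomArrayStack(n_models, n_atoms)
    arr.coord = np.asarray(ensemble.coords, dtype=np.float32)
    arr.atom_name = ensemble.atoms["name"].to_numpy(dtype="U6")
    arr.res_id = ensemble.atoms["residue_number"].to_numpy(dtype=int)
    arr.res_name = ensemble.atoms["residue_type"].to_numpy(dtype="U5")
    arr.chain_id = ensemble.atoms["chain"].to_numpy(dtype="U4")
    arr.element = np.array([n.strip()[:1] for n in ensemble.atoms["name"]], dtype="U2")
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Shift tables
# ---------------------------------------------------------------------------

_SHIFT_COLUMNS = [
    "residue_number",
    "residue_type",
    "atom",
    "titration_point",
    "shift_ppm",
    "ligand_total_mM",
    "protein_total_mM",
]


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read a per-peak shift CSV with the documented schema.

    Columns: residue_number, residue_type, atom (H/N), titration_point,
    shift_ppm, ligand_total_mM, protein_total_mM. A missing column is a
    schema error naming it.
    """
    df = pd.read_csv(path)
    missing = [c for c in _SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: shift table missing columns {missing}")
    bad_atoms = sorted(set(df["atom"]) - {"H", "N"})
    if bad_atoms:
        raise ValueError(f"{path}: atom column must be H or N, found {bad_atoms}")
    if df["shift_ppm"].isna().any():
        raise ValueError(f"{path}: NaN shift_ppm values")
    # validate each record through the domain type
    for row in df.itertuples(index=False):
        ShiftRecord(
            residue_number=int(row.residue_number),
            residue_type=str(row.residue_type),
            atom=str(row.atom),
            shift=float(row.shift_ppm),
            titration_point=int(row.titration_point),
        )
    return df


def shift_records_to_series(df: pd.DataFrame, alpha: float = 0.14) -> TitrationSeries:
    """Combine per-peak H/N shifts into a per-residue CSP TitrationSeries.

    CSPs are measured against titration point 0 with the standard amide
    weighting (see :func:`dynappi.nmr_titration.combined_csp`).
    """
    points = sorted(df["titration_point"].unique())
    if points[0] != 0:
        raise ValueError("titration_point 0 (free protein) is required")
    lt = df.groupby("titration_point")["ligand_total_mM"].first().loc[points].to_numpy()
    pt_vals = df["protein_total_mM"].unique()
    if len(pt_vals) != 1:
        raise ValueError(f"protein_total_mM must be constant, found {pt_vals}")

    residues = sorted(df["residue_number"].unique())
    csp = np.zeros((len(residues), len(points)))
    pivot = df.pivot_table(
        index="residue_number", columns=["titration_point", "atom"], values="shift_ppm"
    )
    for i, res in enumerate(residues):
        h0 = pivot.loc[res].get((0, "H"), np.nan)
        n0 = pivot.loc[res].get((0, "N"), np.nan)
        for j, tp in enumerate(points):
            if tp == 0:
                continue
            dh = pivot.loc[res].get((tp, "H"), np.nan) - h0
            dn = pivot.loc[res].get((tp, "N"), np.nan) - n0
            if np.isnan(dh) or np.isnan(dn):
                raise ValueError(f"residue {res}: missing H or N shift at point {tp}")
            csp[i, j] = combined_csp(dh, dn, alpha)
    return TitrationSeries(
        protein_total=float(pt_vals[0]), ligand_totals=lt, csp=csp, residues=residues
    )


# ---------------------------------------------------------------------------
# Score matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, higher_is_better: bool | Sequence[bool] = True) -> ScoreMatrix:
    """Read a compound x column score CSV (first column ``id``).

    Malformed numeric cells raise with the offending line number
    (1-based, counting the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    cols = list(df.columns[1:])
    if not cols:
        raise ValueError(f"{path}: no score columns")
    scores = np.empty((len(df), len(cols)))
    values = df[cols].to_numpy(dtype=object)
    for i in range(len(df)):
        for j, col in enumerate(cols):
            raw = values[i, j]
            try:
                missing = raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw in ("", "NA")
                scores[i, j] = np.nan if missing else float(raw)
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}, line {i + 2}: bad value {raw!r} in column {col!r}"
                ) from exc
    hib = [higher_is_better] * len(cols) if isinstance(higher_is_better, bool) else list(higher_is_better)
    return ScoreMatrix(
        compounds=df["id"].tolist(), columns=cols, scores=scores, higher_is_better=hib
    )


def write_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.insert(0, "id", matrix.compounds)
    df.to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
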