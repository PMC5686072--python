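"""Pharmacophore models, subset queries and conformer matching.

A pharmacophore abstracts a protein-peptide interface into typed
interaction points (hydrogen-bond acceptor/donor, hydrophobic centroid)
with spherical match tolerances. Conformers whose own feature points can
be rigidly superposed onto a query below an RMSD cutoff are screening
hits. The shipped SxIP preset encodes the Ser-x-Ile-Pro recognition
epitope of the EB1 EBH pocket: two acceptors around the serine hydroxyl,
three hydrophobic centroids over the isoleucine side chain and the
proline ring, one acceptor on the isoleucine backbone amine and donors
on the two backbone carbonyl oxygens.

The correspondence search is exhaustive over kind-compatible injective
assignments (exact for query sizes up to 12), and superposition uses the
closed-form least-squares rotation; reflections are rejected.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._geometry import kabsch
from .structures import CoordinateEnsemble

__all__ = [
    "FEATURE_KINDS",
    "Feature",
    "PharmacophoreModel",
    "SubsetQuery",
    "ConformerFeatures",
    "MatchResult",
    "SXIP_PRESET",
    "build_sxip_model",
    "enumerate_subsets",
    "assign_ligand_features",
    "match_conformer",
    "screen_library",
    "DEFAULT_FEATURE_RULES",
]

FEATURE_KINDS = ("acceptor", "donor", "hydrophobic")

#: Exhaustive correspondence search is exact but factorial; cap the query size.
MAX_QUERY_SIZE = 12


@dataclass(frozen=True)
class Feature:
    """A typed 3-D interaction point with a spherical match tolerance."""

    kind: str
    center: tuple[float, float, float]
    radius: float = 1.0
    direction: tuple[float, float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}")
        if not self.radius > 0:
            raise ValueError("feature radius must be positive")
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = float(np.linalg.norm(d))
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"direction must be a unit vector, |d| = {n:.6g}")
            object.__setattr__(self, "direction", tuple(float(x) for x in d))


@dataclass(frozen=True)
class PharmacophoreModel:
    """Ordered feature list with provenance."""

    features: tuple[Feature, ...]
    name: str = "pharmacophore"
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        if len(self.features) < 1:
            raise ValueError("a pharmacophore model needs at least one feature")
        labels = [f.label for f in self.features]
        if len(set(labels)) != len(labels):
            raise ValueError("feature labels must be unique")

    def __len__(self) -> int:
        return len(self.features)

    def kind_histogram(self) -> dict[str, int]:
        hist = {k: 0 for k in FEATURE_KINDS}
        for f in self.features:
            hist[f.kind] += 1
        return hist

    def centers(self, indices: Sequence[int] | None = None) -> np.ndarray:
        feats = self.features if indices is None else [self.features[i] for i in indices]
        return np.array([f.center for f in feats], dtype=float)


@dataclass(frozen=True)
class SubsetQuery:
    """A strictly increasing index subset of a model's features."""

    model: PharmacophoreModel
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        n = len(self.model)
        if len(idx) < 3:
            raise ValueError("subset queries need at least 3 features")
        if any(i < 0 or i >= n for i in idx):
            raise ValueError(f"indices out of range for a {n}-feature model: {idx}")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("indices must be strictly increasing")

    @property
    def size(self) -> int:
        return len(self.indices)

    @property
    def features(self) -> tuple[Feature, ...]:
        return tuple(self.model.features[i] for i in self.indices)


@dataclass(frozen=True)
class ConformerFeatures:
    """Ligand-side feature points for one conformer of one molecule."""

    molecule_id: str
    conformer_id: str
    points: tuple[Feature, ...]

    def __post_init__(self) -> None:
        if not self.molecule_id or not self.conformer_id:
            raise ValueError("molecule_id and conformer_id must be non-empty")
        object.__setattr__(self, "points", tuple(self.points))

    def coords(self) -> np.ndarray:
        return np.array([p.center for p in self.points], dtype=float).reshape(len(self.points), 3)


@dataclass(frozen=True)
class MatchResult:
    """Best correspondence of a conformer against a subset query."""

    molecule_id: str
    conformer_id: str
    query: SubsetQuery
    correspondence: tuple[tuple[int, int], ...]  # (query feature index, conformer point index)
    rmsd: float
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or not math.isclose(
            float(np.linalg.det(R)), 1.0, abs_tol=1e-6
        ):
            raise ValueError("rotation must be proper orthonormal")
        conf_targets = [j for _, j in self.correspondence]
        if len(set(conf_targets)) != len(conf_targets):
            raise ValueError("correspondence must be injective")


# ---------------------------------------------------------------------------
# SxIP preset
# ---------------------------------------------------------------------------

#: Preset rows: (label, residue_number, residue_type, atom names, kind).
#: Centers are centroids of the named atoms in the supplied structure. The
#: acceptor/donor assignment of the Ile backbone amine and the two carbonyl
#: oxygens follows the published description verbatim; pass
#: ``chemically_corrected=True`` to ``build_sxip_model`` to swap them.
SXIP_PRESET: tuple[tuple[str, int, str, tuple[str, ...], str], ...] = (
    ("Ser5477:OG", 5477, "SER", ("OG",), "acceptor"),
    ("Ser5477:OG/CB", 5477, "SER", ("OG", "CB"), "acceptor"),
    ("Ile5479:sidechain", 5479, "ILE", ("CB", "CG1", "CD1"), "hydrophobic"),
    ("Ile5479:CG2", 5479, "ILE", ("CG2",), "hydrophobic"),
    ("Pro5480:ring", 5480, "PRO", ("CB", "CG", "CD"), "hydrophobic"),
    ("Ile5479:N", 5479, "ILE", ("N",), "acceptor"),
    ("Ile5479:O", 5479, "ILE", ("O",), "donor"),
    ("Pro5480:O", 5480, "PRO", ("O",), "donor"),
)


def build_sxip_model(
    structure: CoordinateEnsemble,
    preset: Sequence[tuple[str, int, str, tuple[str, ...], str]] = SXIP_PRESET,
    *,
    chain: str = "P",
    model_index: int = 0,
    radius: float = 1.0,
    chemically_corrected: bool = False,
    name: str = "sxip",
) -> PharmacophoreModel:
    """Build a pharmacophore model from preset rows over a peptide structure.

    Each preset row contributes one feature whose center is the centroid of
    the named atoms in model ``model_index`` of ``structure``.
    """
    preset = list(preset)
    if not preset:
        raise ValueError("empty preset")
    features = []
    for label, resnum, _restype, atom_names, kind in preset:
        if chemically_corrected:
            # swap the backbone-amine acceptor to donor and carbonyl donors
            # to acceptors; side-chain features untouched
            if label.endswith(":N") and kind == "acceptor":
                kind = "donor"
            elif label.endswith(":O") and kind == "donor":
                kind = "acceptor"
        coords = []
        for atom in atom_names:
            try:
                idx = structure.atom_index(chain, resnum, atom)
            except KeyError as exc:
                raise KeyError(
                    f"preset atom missing from structure: {chain}:{resnum}:{atom}"
                ) from exc
            coords.append(structure.coords[model_index, idx])
        center = np.mean(np.asarray(coords), axis=0)
        features.append(Feature(kind=kind, center=tuple(center), radius=radius, label=label))
    source = f"{structure.name} chain {chain} residues " + ",".join(
        sorted({str(r[1]) for r in preset})
    )
    return PharmacophoreModel(features=tuple(features), name=name, source=source)


# ---------------------------------------------------------------------------
# Subset enumeration
# ---------------------------------------------------------------------------

def enumerate_subsets(
    model: PharmacophoreModel,
    sizes: Iterable[int],
    constraint: Callable[[tuple[int, ...]], bool] | None = None,
) -> list[SubsetQuery]:
    """All feature-index subsets of each requested size, lexicographic order.

    Sizes larger than the model contribute nothing; sizes below 3 are an
    error. ``constraint`` is an optional predicate on index tuples that
    filters the enumeration (ships unconstrained).
    """
    n = len(model)
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 3 for s in sizes):
        raise ValueError("subset sizes must be >= 3")
    out: list[SubsetQuery] = []
    for s in sizes:
        if s > n:
            continue
        for combo in itertools.combinations(range(n), s):
            if constraint is not None and not constraint(combo):
                continue
            out.append(SubsetQuery(model=model, indices=combo))
    return out


# ---------------------------------------------------------------------------
# Ligand feature assignment (SMARTS rules)
# ---------------------------------------------------------------------------

#: Default SMARTS -> kind table. One feature per pattern match, centered on
#: the centroid of the matched heavy atoms. Acceptors: N/O with a lone pair;
#: donors: N-H / O-H; hydrophobic: sp3 or aromatic carbons not bound to N/O.
DEFAULT_FEATURE_RULES: tuple[tuple[str, str], ...] = (
    ("acceptor", "[#7X2,#7X3;!$([#7]~[#6]=[O,S]);!+]"),
    ("acceptor", "[#8;!+]"),
    ("donor", "[#7;!H0]"),
    ("donor", "[#8;!H0]"),
    ("hydrophobic", "[CX4;!$(C~[#7,#8])]"),
    ("hydrophobic", "c"),
)


def assign_ligand_features(
    mol,
    rules: Sequence[tuple[str, str]] = DEFAULT_FEATURE_RULES,
    *,
    molecule_id: str | None = None,
    conformer_id: str = "0",
    conf_index: int = 0,
    radius: float = 1.0,
) -> ConformerFeatures:
    """Assign typed feature points to an RDKit molecule with 3-D coordinates.

    Each SMARTS match contributes one feature at the centroid of its matched
    heavy atoms; a (kind, atom-index-set) pair is emitted only once even when
    several patterns hit it.
    """
    from rdkit import Chem

    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no 3-D coordinates")
    conf = mol.GetConformer(conf_index)
    pos = conf.GetPositions()

    compiled = []
    for kind, smarts in rules:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"unparsable SMARTS pattern: {smarts!r}")
        compiled.append((kind, patt))

    seen: set[tuple[str, frozenset[int]]] = set()
    points: list[Feature] = []
    for kind, patt in compiled:
        for match in mol.GetSubstructMatches(patt):
            heavy = [i for i in match if mol.GetAtomWithIdx(i).GetAtomicNum() > 1]
            if not heavy:
                continue
            key = (kind, frozenset(heavy))
            if key in seen:
                continue
            seen.add(key)
            center = pos[heavy].mean(axis=0)
            points.append(
                Feature(
                    kind=kind,
                    center=tuple(center),
                    radius=radius,
                    label=f"{kind}:{'+'.join(map(str, sorted(heavy)))}",
                )
            )

    if molecule_id is None:
        molecule_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else "mol"
    return ConformerFeatures(molecule_id=molecule_id, conformer_id=conformer_id, points=tuple(points))


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _kind_compatible_injections(
    query_feats: Sequence[Feature], points: Sequence[Feature]
) -> Iterable[tuple[int, ...]]:
    """Yield injective assignments (query position -> conformer point index)
    where every pair has identical kind. Enumerated as a product of per-kind
    permutations, so only kind-compatible candidates are ever generated."""
    by_kind_query: dict[str, list[int]] = {}
    for qi, f in enumerate(query_feats):
        by_kind_query.setdefault(f.kind, []).append(qi)
    by_kind_points: dict[str, list[int]] = {}
    for pi, p in enumerate(points):
        by_kind_points.setdefault(p.kind, []).append(pi)

    kinds = list(by_kind_query)
    per_kind_choices = []
    for kind in kinds:
        q_idx = by_kind_query[kind]
        cand = by_kind_points.get(kind, [])
        if len(cand) < len(q_idx):
            return  # no injection possible
        per_kind_choices.append(list(itertools.permutations(cand, len(q_idx))))

    for choice in itertools.product(*per_kind_choices):
        assignment = [0] * len(query_feats)
        for kind, perm in zip(kinds, choice):
            for qi, pi in zip(by_kind_query[kind], perm):
                assignment[qi] = pi
        yield tuple(assignment)


def _direction_ok(
    query_feats: Sequence[Feature],
    points: Sequence[Feature],
    assignment: tuple[int, ...],
    rotation: np.ndarray,
    angle_tol_deg: float,
) -> bool:
    cos_tol = math.cos(math.radians(angle_tol_deg))
    for qi, pi in enumerate(assignment):
        dq = query_feats[qi].direction
        dp = points[pi].direction
        if dq is None or dp is None:
            continue
        rotated = rotation @ np.asarray(dp)
        if float(np.dot(rotated, dq)) < cos_tol:
            return False
    return True


def match_conformer(
    query: SubsetQuery,
    conf: ConformerFeatures,
    rmsd_max: float,
    *,
    check_directions: bool = False,
    angle_tol_deg: float = 45.0,
) -> MatchResult | None:
    """Best kind-compatible correspondence of a conformer against a query.

    Minimises point RMSD after optimal rigid superposition of the conformer
    points onto the query; returns ``None`` when no kind-compatible injection
    exists or the minimum exceeds ``rmsd_max``.
    """
    if not rmsd_max > 0:
        raise ValueError("rmsd_max must be positive")
    if query.size > MAX_QUERY_SIZE:
        raise ValueError(
            f"query size {query.size} exceeds the exhaustive-search cap "
            f"{MAX_QUERY_SIZE}; lower the subset size"
        )
    qfeats = query.features
    qcoords = np.array([f.center for f in qfeats], dtype=float)
    pts = conf.points
    if len(pts) < query.size:
        return None
    pcoords = conf.coords()

    best: tuple[float, tuple[int, ...], np.ndarray, np.ndarray] | None = None
    for assignment in _kind_compatible_injections(qfeats, pts):
        moving = pcoords[list(assignment)]
        R, t, rmsd = kabsch(moving, qcoords)
        if check_directions and not _direction_ok(qfeats, pts, assignment, R, angle_tol_deg):
            continue
        if best is None or rmsd < best[0]:
            best = (rmsd, assignment, R, t)

    if best is None or best[0] > rmsd_max:
        return None
    rmsd, assignment, R, t = best
    correspondence = tuple((query.indices[qi], pi) for qi, pi in enumerate(assignment))
    return MatchResult(
        molecule_id=conf.molecule_id,
        conformer_id=conf.conformer_id,
        query=query,
        correspondence=correspondence,
        rmsd=rmsd,
        rotation=R,
        translation=t,
    )


def screen_library(
    library: Iterable[ConformerFeatures],
    model: PharmacophoreModel,
    sizes: Iterable[int],
    rmsd_max: float,
    *,
    constraint: Callable[[tuple[int, ...]], bool] | None = None,
    check_directions: bool = False,
) -> pd.DataFrame:
    """Screen a conformer library against all subset queries of a model.

    For every conformer the best match over all queries is kept, then the
    table is deduplicated to one row per ``molecule_id`` (lowest RMSD
    conformer wins) and sorted by RMSD ascending, ties broken by id.

    Returns a DataFrame with columns
    ``molecule_id, conformer_id, query_size, query_indices, rmsd_A``.
    """
    queries = enumerate_subsets(model, sizes, constraint=constraint)
    best_per_molecule: dict[str, dict] = {}
    for conf in library:
        best: MatchResult | None = None
        for q in queries:
            m = match_conformer(q, conf, rmsd_max, check_directions=check_directions)
            if m is not None and (best is None or m.rmsd < best.rmsd):
                best = m
        if best is None:
            continue
        prev = best_per_molecule.get(conf.molecule_id)
        if prev is None or best.rmsd < prev["rmsd_A"]:
            best_per_molecule[conf.molecule_id] = {
                "molecule_id": best.molecule_id,
                "conformer_id": best.conformer_id,
                "query_size": best.query.size,
                "query_indices": ",".join(map(str, best.query.indices)),
                "rmsd_A": best.rmsd,
            }
    df = pd.DataFrame(
        list(best_per_molecule.values()),
        columns=["molecule_id", "conformer_id", "query_size", "query_indices", "rmsd_A"],
    )
    return df.sort_values(["rmsd_A", "molecule_id"], kind="mergesort").reset_index(drop=True)
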