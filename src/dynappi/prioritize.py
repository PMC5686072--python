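"""Compound prioritisation: properties, consensus scoring, Pareto ranking.

Implements the staged selection funnel used after a pharmacophore screen:
docking scores from several scoring functions are intersected (consensus),
compounds are ranked by Pareto non-dominated sorting over docking and
drug-likeness objectives, then filtered on solubility / Lipinski criteria
and docking-pose self-consistency. All filter boundaries are inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "ScoreMatrix",
    "ParetoResult",
    "PoseSet",
    "MONOISOTOPIC_MASS",
    "monoisotopic_mass",
    "parse_formula",
    "ligand_efficiency",
    "lipinski_profile",
    "consensus_top",
    "pareto_rank",
    "solubility_filter",
    "pose_consistency",
    "run_selection",
]

#: Principal-isotope (monoisotopic) atomic masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
}


@dataclass
class CompoundRecord:
    """Property record for one compound; unknown properties stay ``None``."""

    id: str
    formula: dict[str, int] | None = None
    mw: float | None = None
    monoisotopic_mass: float | None = None
    heavy_atoms: int | None = None
    hbd: int | None = None
    hba: int | None = None
    logp: float | None = None
    solubility: float | None = None  # mol/L
    structure: object | None = None  # optional RDKit mol

    def __post_init__(self) -> None:
        for name in ("heavy_atoms", "hbd", "hba"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.solubility is not None and self.solubility < 0:
            raise ValueError("solubility must be >= 0")


@dataclass
class ScoreMatrix:
    """Compounds x scoring-function score table.

    ``higher_is_better`` flags the direction of each column; a failed
    scoring attempt is carried as NaN (the explicit sentinel) and handled
    downstream, never silently imputed.
    """

    compounds: list[str]
    columns: list[str]
    scores: np.ndarray
    higher_is_better: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.compounds), len(self.columns)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.columns)} columns"
            )
        if len(set(self.compounds)) != len(self.compounds):
            raise ValueError("duplicate compound ids")
        if not self.higher_is_better:
            self.higher_is_better = [True] * len(self.columns)
        if len(self.higher_is_better) != len(self.columns):
            raise ValueError("higher_is_better length must match columns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.compounds, columns=self.columns)


@dataclass(frozen=True)
class ParetoResult:
    id: str
    front: int
    tie_key: float

    def __post_init__(self) -> None:
        if self.front < 1:
            raise ValueError("front indices start at 1")


@dataclass
class PoseSet:
    """Docked poses of one compound in a common receptor frame."""

    compound_id: str
    poses: np.ndarray  # (n_poses, n_atoms, 3)

    def __post_init__(self) -> None:
        self.poses = np.asarray(self.poses, dtype=float)
        if self.poses.ndim != 3 or self.poses.shape[2] != 3:
            raise ValueError("poses must be (n_poses, n_atoms, 3)")
        if not np.all(np.isfinite(self.poses)):
            raise ValueError("non-finite pose coordinates")


# ---------------------------------------------------------------------------
# Molecular properties
# ---------------------------------------------------------------------------

def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula string (e.g. ``C18H25NO3``)."""
    import re

    out: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if m.start() != pos or not m.group(1):
            break
        out[m.group(1)] = out.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(formula) or not out:
        raise ValueError(f"unparsable molecular formula: {formula!r}")
    return out


def monoisotopic_mass(formula: Mapping[str, int] | str) -> float:
    """Monoisotopic mass (Da) of an element->count map or formula string."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    total = 0.0
    for element, count in formula.items():
        if element not in MONOISOTOPIC_MASS:
            raise KeyError(f"no monoisotopic mass tabulated for element {element!r}")
        if count < 0:
            raise ValueError(f"negative count for element {element!r}")
        total += count * MONOISOTOPIC_MASS[element]
    return total


def ligand_efficiency(score: float | np.ndarray, heavy_atoms: int | np.ndarray):
    """Score normalised by heavy-atom count (score / N_heavy)."""
    heavy = np.asarray(heavy_atoms)
    if np.any(heavy < 1):
        raise ValueError("heavy_atoms must be >= 1")
    result = np.asarray(score, dtype=float) / heavy
    return float(result) if result.ndim == 0 else result


_LIPINSKI_RULES = {
    "mw": ("mw", 500.0),
    "logp": ("logp", 5.0),
    "hbd": ("hbd", 5.0),
    "hba": ("hba", 10.0),
}


def lipinski_profile(record: CompoundRecord) -> dict:
    """Rule-of-five profile: per-rule pass booleans + violation count.

    Boundary values pass (<=), e.g. MW exactly 500 is compliant.
    """
    missing = [attr for attr, _ in _LIPINSKI_RULES.values() if getattr(record, attr) is None]
    if missing:
        raise ValueError(f"missing properties for Lipinski profile: {missing}")
    profile = {}
    for rule, (attr, limit) in _LIPINSKI_RULES.items():
        profile[rule] = getattr(record, attr) <= limit
    profile["violations"] = sum(1 for rule in _LIPINSKI_RULES if not profile[rule])
    return profile


# ---------------------------------------------------------------------------
# Consensus and Pareto
# ---------------------------------------------------------------------------

def consensus_top(matrix: ScoreMatrix, fraction: float = 0.25) -> set[str]:
    """Ids in the top ``ceil(fraction * n)`` of *every* scoring column.

    Per-column direction follows ``higher_is_better``; ties broken
    deterministically by id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(matrix.compounds)
    if n == 0:
        return set()
    k = math.ceil(fraction * n)
    ids = np.array(matrix.compounds)
    common: set[str] | None = None
    for j, hib in enumerate(matrix.higher_is_better):
        col = matrix.scores[:, j]
        if np.any(np.isnan(col)):
            raise ValueError(f"NaN scores in column {matrix.columns[j]!r}")
        key = -col if hib else col
        order = np.lexsort((ids, key))  # primary: score direction, secondary: id
        top = set(ids[order[:k]])
        common = top if common is None else common & top
    return common or set()


def pareto_rank(
    objectives: np.ndarray | pd.DataFrame,
    directions: Sequence[str],
    ids: Sequence[str] | None = None,
) -> list[ParetoResult]:
    """Non-dominated sorting with deterministic within-front tie keys.

    ``directions`` is one of ``"max"``/``"min"`` per objective. Front 1 is
    the non-dominated set; front k is non-dominated after removing fronts
    < k. The tie key is the normalised rank-sum across objectives (lower is
    better), used to order compounds within a front.
    """
    if isinstance(objectives, pd.DataFrame):
        if ids is None:
            ids = list(objectives.index.astype(str))
        objectives = objectives.to_numpy(dtype=float)
    X = np.asarray(objectives, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("objectives must be a 2-D matrix with >= 1 column")
    if np.any(np.isnan(X)):
        raise ValueError("missing cells in objective matrix")
    if len(directions) != X.shape[1]:
        raise ValueError(
            f"{len(directions)} directions for {X.shape[1]} objectives"
        )
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    ids = list(ids)

    # orient all objectives so larger is better
    sign = np.array([1.0 if d == "max" else -1.0 for d in directions])
    bad = [d for d in directions if d not in ("max", "min")]
    if bad:
        raise ValueError(f"directions must be 'max' or 'min', got {bad}")
    Y = X * sign

    n = X.shape[0]
    # tie key: normalised rank-sum (average ranks on ties), lower = better
    from scipy.stats import rankdata

    ranks = np.column_stack([rankdata(-Y[:, j]) for j in range(Y.shape[1])])
    tie_key = ranks.sum(axis=1) / (Y.shape[1] * max(n, 1))

    # non-dominated sorting (pairwise dominance counts)
    dominated_by = np.zeros(n, dtype=int)
    dominates: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        ge = np.all(Y >= Y[i], axis=1) & np.any(Y > Y[i], axis=1)  # rows dominating i
        for j in np.flatnonzero(ge):
            dominates[j].append(i)
            dominated_by[i] += 1

    front = np.zeros(n, dtype=int)
    current = [i for i in range(n) if dominated_by[i] == 0]
    k = 1
    remaining = dominated_by.copy()
    while current:
        nxt: list[int] = []
        for i in current:
            front[i] = k
            for j in dominates[i]:
                remaining[j] -= 1
                if remaining[j] == 0:
                    nxt.append(j)
        current = sorted(set(nxt))
        k += 1

    return [ParetoResult(id=ids[i], front=int(front[i]), tie_key=float(tie_key[i])) for i in range(n)]


def pareto_top_n(results: Sequence[ParetoResult], n: int) -> list[ParetoResult]:
    """Truncate a Pareto ranking to ``n`` entries, cutting at front
    boundaries and breaking the boundary front by tie_key then id."""
    ordered = sorted(results, key=lambda r: (r.front, r.tie_key, r.id))
    return list(ordered[:n])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def solubility_filter(
    records: Iterable[CompoundRecord], min_molar: float = 1e-4
) -> list[CompoundRecord]:
    """Keep compounds with predicted solubility >= ``min_molar`` (mol/L).

    The boundary value passes; a missing solubility is an error naming the
    compound.
    """
    kept = []
    for rec in records:
        if rec.solubility is None:
            raise ValueError(f"compound {rec.id!r} has no solubility value")
        if rec.solubility >= min_molar:
            kept.append(rec)
    return kept


def pose_consistency(poses: PoseSet) -> tuple[float, np.ndarray]:
    """Mean pairwise RMSD over docked poses, computed in the shared
    receptor frame *without* superposition.

    Returns (mean over unordered pairs, full symmetric pairwise matrix).
    """
    P = poses.poses
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 poses")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = P[i] - P[j]
            rmsd = float(np.sqrt((diff * diff).sum() / P.shape[1]))
            mat[i, j] = mat[j, i] = rmsd
    iu = np.triu_indices(n, k=1)
    return float(mat[iu].mean()), mat


# ---------------------------------------------------------------------------
# Staged selection funnel
# ---------------------------------------------------------------------------

DEFAULT_OBJECTIVES: tuple[tuple[str, str], ...] = (
    ("consensus_score", "max"),
    ("ligand_efficiency", "max"),
    ("mw", "min"),
    ("logp", "min"),
    ("hbd", "min"),
    ("hba", "min"),
    ("solubility", "max"),
)


def run_selection(
    records: Sequence[CompoundRecord],
    matrix: ScoreMatrix,
    *,
    consensus_fraction: float = 0.25,
    objectives: Sequence[tuple[str, str]] | None = None,
    top_n: int | None = 100,
    min_solubility: float | None = 1e-4,
    max_lipinski_violations: int | None = 1,
    pose_sets: Mapping[str, PoseSet] | None = None,
    max_mean_pose_rmsd: float | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Staged compound-selection funnel with a per-stage audit log.

    Stages: consensus scoring -> Pareto ranking (+ top-n cut) -> solubility
    filter -> Lipinski filter -> pose-consistency filter. Stages whose
    parameter is ``None`` pass everything through unchanged. Returns the
    ranked shortlist (ordered by Pareto front then tie key then id) and the
    audit log of per-stage entering/leaving counts.
    """
    audit: list[dict] = []
    by_id = {r.id: r for r in records}
    missing = [c for c in matrix.compounds if c not in by_id]
    if missing:
        raise ValueError(f"score matrix compounds missing property records: {missing[:5]}")

    surviving = list(matrix.compounds)
    audit.append({"stage": "input", "n_in": len(surviving), "n_out": len(surviving)})

    # consensus stage
    n_in = len(surviving)
    if consensus_fraction is not None and n_in:
        common = consensus_top(matrix, consensus_fraction)
        surviving = [c for c in surviving if c in common]
    audit.append({"stage": "consensus", "n_in": n_in, "n_out": len(surviving),
                  "fraction": consensus_fraction})

    # mean consensus score across columns (direction-aligned) per compound
    sign = np.array([1.0 if h else -1.0 for h in matrix.higher_is_better])
    if matrix.scores.size:
        aligned = matrix.scores * sign
        consensus_score = dict(zip(matrix.compounds, aligned.mean(axis=1)))
    else:
        consensus_score = {}

    # assemble objective table
    objectives = tuple(objectives) if objectives is not None else DEFAULT_OBJECTIVES
    rows = {}
    for cid in surviving:
        rec = by_id[cid]
        le = None
        if rec.heavy_atoms:
            le = ligand_efficiency(consensus_score[cid], rec.heavy_atoms)
        candidates = {
            "consensus_score": consensus_score[cid],
            "ligand_efficiency": le,
            "mw": rec.mw,
            "logp": rec.logp,
            "hbd": rec.hbd,
            "hba": rec.hba,
            "solubility": rec.solubility,
        }
        rows[cid] = candidates
    obj_names = [name for name, _ in objectives]
    obj_dirs = [d for _, d in objectives]

    n_in = len(surviving)
    ranked_order: list[str] = []
    pareto_info: dict[str, ParetoResult] = {}
    if surviving:
        table = pd.DataFrame(
            [[rows[cid][name] for name in obj_names] for cid in surviving],
            index=surviving, columns=obj_names, dtype=float,
        )
        if table.isna().any().any():
            bad = table.columns[table.isna().any()].tolist()
            raise ValueError(f"objective columns with missing values: {bad}")
        results = pareto_rank(table, obj_dirs, ids=surviving)
        if top_n is not None:
            results = pareto_top_n(results, top_n)
        results = sorted(results, key=lambda r: (r.front, r.tie_key, r.id))
        ranked_order = [r.id for r in results]
        pareto_info = {r.id: r for r in results}
    surviving = ranked_order
    audit.append({"stage": "pareto", "n_in": n_in, "n_out": len(surviving), "top_n": top_n})

    # solubility
    n_in = len(surviving)
    if min_solubility is not None:
        kept = {r.id for r in solubility_filter([by_id[c] for c in surviving], min_solubility)}
        surviving = [c for c in surviving if c in kept]
    audit.append({"stage": "solubility", "n_in": n_in, "n_out": len(surviving),
                  "min_molar": min_solubility})

    # Lipinski
    n_in = len(surviving)
    if max_lipinski_violations is not None:
        surviving = [
            c for c in surviving
            if lipinski_profile(by_id[c])["violations"] <= max_lipinski_violations
        ]
    audit.append({"stage": "lipinski", "n_in": n_in, "n_out": len(surviving),
                  "max_violations": max_lipinski_violations})

    # pose consistency
    n_in = len(surviving)
    pose_rmsd: dict[str, float] = {}
    if max_mean_pose_rmsd is not None and pose_sets is not None:
        kept_ids = []
        for c in surviving:
            if c in pose_sets:
                mean_rmsd, _ = pose_consistency(pose_sets[c])
                pose_rmsd[c] = mean_rmsd
                if mean_rmsd <= max_mean_pose_rmsd:
                    kept_ids.append(c)
            else:
                kept_ids.append(c)
        surviving = kept_ids
    audit.append({"stage": "pose_consistency", "n_in": n_in, "n_out": len(surviving),
                  "max_mean_rmsd": max_mean_pose_rmsd})

    shortlist = pd.DataFrame(
        {
            "id": surviving,
            "rank": np.arange(1, len(surviving) + 1),
            "front": [pareto_info[c].front for c in surviving],
            "tie_key": [pareto_info[c].tie_key for c in surviving],
            "consensus_score": [consensus_score[c] for c in surviving],
            "mean_pose_rmsd_A": [pose_rmsd.get(c, np.nan) for c in surviving],
        }
    )
    return shortlist, audit
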