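"""Receptor-ensemble score aggregation and binding-pocket dynamics.

Cross-docking against a conformational ensemble (an NMR bundle or MD
snapshots) is summarised per compound by the mean score over receptor
conformations, and the resulting ranking is compared against an
experimental affinity order with rank-correlation statistics. Pocket
dynamics are quantified through "gate" side-chain distances (for the EB1
EBH pocket: Tyr247 Czeta against the Calpha atoms of Leu221 and Leu246),
per-atom RMSF after superposition on a helical core, and open / closed /
bound-like state classification. A small integer-charge utility covers
simulation-box neutralisation arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, spearmanr

from ._geometry import kabsch
from .prioritize import ScoreMatrix
from .structures import CoordinateEnsemble

__all__ = [
    "CoordinateEnsemble",
    "EnsembleScoreTable",
    "PocketMetrics",
    "PocketThresholds",
    "aggregate_ensemble_scores",
    "rank_agreement",
    "distance_series",
    "superpose_rmsf",
    "classify_pocket",
    "formal_charge",
    "neutralizing_ions",
    "state_fractions",
    "import_scores",
    "SoftSphereBackend",
    "EB1_HUMAN_Q15691",
    "eb1c_sequence",
]


@dataclass
class EnsembleScoreTable:
    """Per-compound aggregate of a compounds x conformations score matrix."""

    table: pd.DataFrame  # index: compound id; columns mean, sd, min, max, n_scored
    ranking: list[str]  # by mean desc, ties by id
    n_excluded: int  # sentinel (NaN) cells excluded from aggregates


@dataclass
class PocketMetrics:
    """Per-model gate distances and pocket-state labels."""

    d_gate1: np.ndarray  # Angstrom
    d_gate2: np.ndarray
    states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d_gate1 = np.asarray(self.d_gate1, dtype=float)
        self.d_gate2 = np.asarray(self.d_gate2, dtype=float)
        if np.any(self.d_gate1 <= 0) or np.any(self.d_gate2 <= 0):
            raise ValueError("gate distances must be positive")


def aggregate_ensemble_scores(matrix: ScoreMatrix) -> EnsembleScoreTable:
    """Mean/sd/min/max per compound across receptor conformations.

    NaN cells (failed dockings) are excluded from the aggregates with a
    logged count, never imputed. Ranking is by mean score descending,
    ties broken by compound id.
    """
    if len(matrix.compounds) == 0:
        raise ValueError("empty score matrix")
    S = matrix.scores
    n_excluded = int(np.isnan(S).sum())
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(S, axis=1)
        sd = np.nanstd(S, axis=1, ddof=0)
        mn = np.nanmin(S, axis=1)
        mx = np.nanmax(S, axis=1)
    n_scored = (~np.isnan(S)).sum(axis=1)
    table = pd.DataFrame(
        {"mean": mean, "sd": sd, "min": mn, "max": mx, "n_scored": n_scored},
        index=pd.Index(matrix.compounds, name="compound"),
    )
    order = sorted(matrix.compounds, key=lambda c: (-table.loc[c, "mean"], c))
    return EnsembleScoreTable(table=table, ranking=order, n_excluded=n_excluded)


def rank_agreement(predicted: Mapping[str, float], reference_order: Sequence[str]) -> dict:
    """Kendall tau and Spearman rho between a score-based ranking and a
    reference affinity order (best first). Tie-corrected formulas."""
    pred_ids = set(predicted)
    ref_ids = set(reference_order)
    if pred_ids != ref_ids:
        raise ValueError(
            f"id mismatch: only in predicted {sorted(pred_ids - ref_ids)}, "
            f"only in reference {sorted(ref_ids - pred_ids)}"
        )
    if len(reference_order) < 3:
        raise ValueError("need at least 3 ids")
    # reference rank 1 = best; align directions by scoring reference descending
    ref_rank = {cid: len(reference_order) - i for i, cid in enumerate(reference_order)}
    ids = sorted(reference_order)
    x = [predicted[c] for c in ids]
    y = [ref_rank[c] for c in ids]
    tau, tau_p = kendalltau(x, y)
    rho, rho_p = spearmanr(x, y)
    return {"kendall_tau": float(tau), "spearman_rho": float(rho),
            "tau_pvalue": float(tau_p), "rho_pvalue": float(rho_p)}


def distance_series(
    ensemble: CoordinateEnsemble,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
) -> dict:
    """Per-model Euclidean distance between two named atoms (Angstrom).

    Atom specs are (chain, residue_number, atom_name).
    """
    ia = ensemble.atom_index(*atom_a)
    ib = ensemble.atom_index(*atom_b)
    diff = ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :]
    d = np.linalg.norm(diff, axis=1)
    return {
        "distances": d,
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=0)),
        "min": float(d.min()),
        "max": float(d.max()),
    }


def superpose_rmsf(
    ensemble: CoordinateEnsemble,
    fit_selection: np.ndarray,
    report_selection: np.ndarray | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Per-atom RMSF after iterated superposition onto the ensemble mean.

    Each model is least-squares superposed (on ``fit_selection`` atoms) onto
    the running mean structure; the mean is recomputed and the cycle
    repeated until the mean moves by less than ``tol`` Angstrom (at least 2
    iterations, removing first-model reference bias). RMSF is the RMS
    deviation of each reported atom from the converged mean structure.

    Selections are boolean atom masks. Returns a DataFrame of the reported
    atom table plus an ``rmsf_A`` column and per-residue means available
    via groupby.
    """
    fit_mask = np.asarray(fit_selection, dtype=bool)
    if fit_mask.sum() == 0:
        raise ValueError("empty fit selection")
    if report_selection is None:
        report_mask = np.ones(ensemble.n_atoms, dtype=bool)
    else:
        report_mask = np.asarray(report_selection, dtype=bool)

    coords = ensemble.coords.copy()
    mean = coords.mean(axis=0)
    for it in range(max_iter):
        for m in range(coords.shape[0]):
            R, t, _ = kabsch(coords[m, fit_mask], mean[fit_mask])
            coords[m] = coords[m] @ R.T + t
        new_mean = coords.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if it >= 1 and shift < tol:
            break

    dev = coords - mean[None, :, :]
    rmsf = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    out = ensemble.atoms.loc[report_mask].copy().reset_index(drop=True)
    out["rmsf_A"] = rmsf[report_mask]
    return out


@dataclass(frozen=True)
class PocketThresholds:
    """Distance thresholds defining pocket states (Angstrom).

    ``closed_max`` bounds the closed state from above, ``open_min`` bounds
    the open state from below, and a bound-like window of half-width
    ``bound_tol`` around the reference gate distances (e.g. from the lowest
    energy bound-form structure) takes precedence. Regions must not overlap.
    """

    closed_max: float
    open_min: float
    bound_reference: tuple[float, float] | None = None
    bound_tol: float = 1.5

    def __post_init__(self) -> None:
        if self.closed_max >= self.open_min:
            raise ValueError("closed_max must be below open_min (non-overlapping regions)")


def classify_pocket(metrics: PocketMetrics, thresholds: PocketThresholds) -> PocketMetrics:
    """Label each model open / closed / bound_like / indeterminate.

    A model is bound-like when both gate distances fall within the
    reference window (if a reference is supplied); else closed when both
    distances <= closed_max; open when both >= open_min; otherwise
    indeterminate. Ensemble state fractions are attached to the result.
    """
    states = []
    for d1, d2 in zip(metrics.d_gate1, metrics.d_gate2):
        label = "indeterminate"
        if thresholds.bound_reference is not None:
            r1, r2 = thresholds.bound_reference
            if abs(d1 - r1) <= thresholds.bound_tol and abs(d2 - r2) <= thresholds.bound_tol:
                label = "bound_like"
        if label == "indeterminate":
            if d1 <= thresholds.closed_max and d2 <= thresholds.closed_max:
                label = "closed"
            elif d1 >= thresholds.open_min and d2 >= thresholds.open_min:
                label = "open"
        states.append(label)
    return PocketMetrics(d_gate1=metrics.d_gate1, d_gate2=metrics.d_gate2, states=states)


def state_fractions(metrics: PocketMetrics) -> dict[str, float]:
    n = len(metrics.states)
    if n == 0:
        raise ValueError("no states to summarise")
    return {s: metrics.states.count(s) / n for s in ("open", "closed", "bound_like", "indeterminate")}


# ---------------------------------------------------------------------------
# Charge arithmetic
# ---------------------------------------------------------------------------

#: Integer side-chain charges at pH 7 (His neutral, pKa ~ 6).
_SIDECHAIN_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1, "H": 0}
_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Canonical human EB1 (MAPRE1, UniProt Q15691), 268 residues.
EB1_HUMAN_Q15691 = (
    "MAVNVYSTSVTSDNLSRHDMLAWINESLQLNLTKIEQLCSGAAYCQFMDMLFPGSIALKK"
    "VKFQAKLEHEYIQNFKILQAGFKRMGVDKIIPVDKLVKGKFQDNFEFVQWFKKFFDANYD"
    "GKDYDPVAARQGQETAVAPSLVAPALNKPKKPLTSSSAAPQRPISTQRTAAAPKAGPGVV"
    "RKNPGVGNGDDEAAELMQQVNVLKLTVEDLEKERDFYFGKLRNIELICQENEGENDPVLQ"
    "RIVDILYATDEGFVIPDEGGPQEEQEEY"
)


def eb1c_sequence(start: int = 191, end: int = 260) -> str:
    """EB1c domain segment of human EB1 (1-based inclusive numbering)."""
    return EB1_HUMAN_Q15691[start - 1 : end]


def formal_charge(
    sequence: str,
    ph: float = 7.0,
    *,
    nterm_charge: int = +1,
    cterm_charge: int = -1,
) -> int:
    """Integer formal charge of a protein sequence at pH 7.

    Asp/Glu -1, Lys/Arg +1, His 0 (pKa ~ 6); the default charged termini
    contribute net zero. Only pH 7 is modelled; other values are rejected
    rather than approximated.
    """
    if ph != 7.0:
        raise ValueError("only the pH 7 integer model is implemented")
    seq = sequence.strip().upper()
    bad = sorted(set(seq) - _STANDARD_AA)
    if bad:
        raise ValueError(f"non-standard residue letters: {bad}")
    charge = sum(_SIDECHAIN_CHARGE.get(a, 0) for a in seq)
    return charge + nterm_charge + cterm_charge


def neutralizing_ions(charge_per_monomer: int, n_monomers: int = 1) -> int:
    """Count of monovalent counterions neutralising the assembly
    (cations for a net-negative system, anions for net-positive)."""
    return abs(int(charge_per_monomer) * int(n_monomers))


# ---------------------------------------------------------------------------
# Docking backend contract
# ---------------------------------------------------------------------------

def import_scores(path, higher_is_better: bool = True) -> ScoreMatrix:
    """Import a compound x receptor-conformation score CSV as a ScoreMatrix
    (validated for shape; see :func:`dynappi.io.read_matrix`)."""
    from .io import read_matrix

    return read_matrix(path, higher_is_better=higher_is_better)


class SoftSphereBackend:
    """Deterministic toy docking backend for end-to-end tests.

    Scores a ligand (a point set) against a receptor pocket sphere: each
    ligand point inside the pocket contributes linearly with depth,
    ``score = 10 * sum(max(0, 1 - d_i / radius))``. This is a contact
    surrogate used to exercise the pipeline, not a physical model.
    """

    def __init__(self, pocket_center: Sequence[float], radius: float = 5.0):
        self.pocket_center = np.asarray(pocket_center, dtype=float)
        if radius <= 0:
            raise ValueError("pocket radius must be positive")
        self.radius = float(radius)

    def score(self, receptor_coords: np.ndarray, ligand_points: np.ndarray) -> float:
        pts = np.atleast_2d(np.asarray(ligand_points, dtype=float))
        d = np.linalg.norm(pts - self.pocket_center[None, :], axis=1)
        return float(10.0 * np.clip(1.0 - d / self.radius, 0.0, None).sum())
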