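"""Rigid-body superposition primitives shared across modules.

All coordinates are in Angstrom. Rotations are proper (det = +1);
reflections are never returned.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kabsch", "superpose", "rigid_transform"]


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``target``.

    Parameters
    ----------
    moving, target : (n, 3) arrays of paired points.

    Returns
    -------
    rotation : (3, 3) proper rotation matrix R.
    translation : (3,) vector t, such that ``moving @ R.T + t`` best fits target.
    rmsd : root-mean-square deviation after superposition (Angstrom).
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"paired (n, 3) arrays required, got {P.shape} and {Q.shape}")
    if P.shape[0] < 1:
        raise ValueError("at least one point pair required")

    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    Pc = P - cp
    Qc = Q - cq

    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    t = cq - R @ cp
    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt((diff * diff).sum() / P.shape[0]))
    return R, t, rmsd


def superpose(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Return ``moving`` superposed onto ``target`` and the resulting RMSD."""
    R, t, rmsd = kabsch(moving, target)
    return np.asarray(moving, dtype=float) @ R.T + t, rmsd


def rigid_transform(points: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply a rotation + translation to an (n, 3) point set."""
    return np.asarray(points, dtype=float) @ np.asarray(rotation).T + np.asarray(translation)
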