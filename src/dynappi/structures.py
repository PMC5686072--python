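"""Multi-model coordinate ensembles.

A :class:`CoordinateEnsemble` is the in-memory form of a multi-model PDB
file (an NMR ensemble, MD snapshots, or a toy synthetic ensemble): one
shared atom table plus an ``(n_models, n_atoms, 3)`` coordinate block in
Angstrom. Residue numbers and chain identifiers are preserved exactly as
read; nothing is renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoordinateEnsemble"]

_ATOM_COLUMNS = ["name", "residue_number", "residue_type", "chain"]


@dataclass
class CoordinateEnsemble:
    """Shared atom table + per-model coordinates.

    Parameters
    ----------
    atoms : DataFrame with columns ``name, residue_number, residue_type, chain``.
    coords : float array, shape ``(n_models, n_atoms, 3)``, Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    name: str = field(default="ensemble")

    def __post_init__(self) -> None:
        missing = [c for c in _ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise ValueError(f"atom table missing columns: {missing}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (n_models, n_atoms, 3), got {self.coords.shape}")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords have {self.coords.shape[1]} atoms but table has {len(self.atoms)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, chain: str, residue_number: int, atom_name: str) -> int:
        """Index of a single atom; raises KeyError naming the spec when absent."""
        mask = (
            (self.atoms["chain"] == chain)
            & (self.atoms["residue_number"] == int(residue_number))
            & (self.atoms["name"] == atom_name)
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) == 0:
            raise KeyError(f"atom not found: {chain}:{residue_number}:{atom_name}")
        return int(idx[0])

    def select(self, mask: np.ndarray) -> "CoordinateEnsemble":
        """Sub-ensemble over an atom boolean mask (models preserved)."""
        mask = np.asarray(mask, dtype=bool)
        return CoordinateEnsemble(
            atoms=self.atoms.loc[mask].reset_index(drop=True),
            coords=self.coords[:, mask, :],
            name=self.name,
        )

    def model(self, i: int) -> np.ndarray:
        """Coordinates of model ``i`` as an (n_atoms, 3) array."""
        return self.coords[i]
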