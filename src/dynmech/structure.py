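"""Labeled-atom containers for structures and coordinate trajectories.

The package works on a minimal in-memory representation of a
motor-tubulin complex: flat arrays of (chain role, residue number,
residue name, atom name, element) plus an ``(n_atoms, 3)`` coordinate
array in Angstrom.  Chain roles name the biological unit
(``alpha_tubulin``, ``beta_tubulin``, ``mtbd``, ``stalk``) rather than a
PDB chain letter; the mapping to one-letter chain IDs used for PDB I/O
is :data:`CHAIN_IDS`.

A :class:`StructureModel` may carry a ``labels`` dict mapping short
residue labels (e.g. ``"A3295"``) to ``(chain, resid, atom)`` keys so
that selections used by the geometry code are written once.

A :class:`TrajectoryFrames` is an ordered stack of coordinate arrays
congruent with one structure (identical atom ordering in every frame).
The canonical text format is a long-form CSV with columns
``frame, chain, resid, atom, x, y, z``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "TrajectoryFrames",
    "MissingAtomError",
    "CHAIN_IDS",
    "TUBULIN_ROLES",
    "DYNEIN_ROLES",
]

CHAIN_IDS = {"alpha_tubulin": "A", "beta_tubulin": "B", "mtbd": "M", "stalk": "S"}
_CHAIN_ROLES = {v: k for k, v in CHAIN_IDS.items()}
TUBULIN_ROLES = ("alpha_tubulin", "beta_tubulin")
DYNEIN_ROLES = ("mtbd", "stalk")


class MissingAtomError(KeyError):
    """A requested (chain, resid, atom) key or label is absent."""


@dataclass
class StructureModel:
    """Flat labeled-atom structure; coordinates in Angstrom."""

    chain: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    labels: dict[str, tuple[str, int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype=object)
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = self.chain.size
        for arr, name in [
            (self.resid, "resid"),
            (self.resname, "resname"),
            (self.atom_name, "atom_name"),
            (self.element, "element"),
        ]:
            if arr.size != n:
                raise ValueError(f"{name} length mismatch")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain, self.resid, self.atom_name))
        if len(set(keys)) != n:
            raise ValueError("(chain, resid, atom) keys must be unique")
        self._index = {key: i for i, key in enumerate(keys)}

    @property
    def n_atoms(self) -> int:
        return self.chain.size

    # ------------------------------------------------------------ selections

    def index_of(self, chain: str, resid: int, atom: str) -> int:
        try:
            return self._index[(chain, int(resid), atom)]
        except KeyError:
            raise MissingAtomError(f"atom ({chain}, {resid}, {atom}) not found") from None

    def label_index(self, label: str) -> int:
        """Index of the single atom a short label (e.g. ``'W3395'``) maps to."""
        if label not in self.labels:
            raise MissingAtomError(f"label {label!r} is not mapped on this structure")
        return self.index_of(*self.labels[label])

    def mask(
        self,
        chain: str | Sequence[str] | None = None,
        resid: int | Iterable[int] | None = None,
        atom: str | Sequence[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over atoms matching the given chain/resid/atom sets."""
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            chains = {chain} if isinstance(chain, str) else set(chain)
            m &= np.isin(self.chain, list(chains))
        if resid is not None:
            resids = {int(resid)} if np.isscalar(resid) else {int(r) for r in resid}
            m &= np.isin(self.resid, list(resids))
        if atom is not None:
            atoms = {atom} if isinstance(atom, str) else set(atom)
            m &= np.isin(self.atom_name, list(atoms))
        return m

    def ca_mask(self, chain: str | Sequence[str] | None = None) -> np.ndarray:
        return self.mask(chain=chain, atom="CA")

    def residue_keys(self, mask: np.ndarray | None = None) -> list[tuple[str, int]]:
        """Ordered unique (chain, resid) pairs, optionally restricted to a mask."""
        idx = np.arange(self.n_atoms) if mask is None else np.flatnonzero(mask)
        seen: dict[tuple[str, int], None] = {}
        for i in idx:
            seen.setdefault((self.chain[i], int(self.resid[i])), None)
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        return StructureModel(
            chain=self.chain,
            resid=self.resid,
            resname=self.resname,
            atom_name=self.atom_name,
            element=self.element,
            coords=np.array(coords, dtype=float),
            labels=dict(self.labels),
        )

    # ------------------------------------------------------------------ I/O

    def to_biotite(self):
        import biotite.structure as struc

        arr = struc.AtomArray(self.n_atoms)
        arr.chain_id = np.array(
            [CHAIN_IDS.get(c, str(c)[:1] or "X") for c in self.chain], dtype="U4"
        )
        arr.res_id = self.resid.copy()
        arr.res_name = np.array([str(r)[:5] for r in self.resname], dtype="U5")
        arr.atom_name = np.array([str(a)[:6] for a in self.atom_name], dtype="U6")
        arr.element = np.array([str(e)[:2] for e in self.element], dtype="U2")
        arr.coord = self.coords.astype(np.float32)
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        return arr

    def write_pdb(self, path: str | Path) -> None:
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile()
        pdb.set_structure(self.to_biotite())
        pdb.write(str(path))

    @classmethod
    def read_pdb(
        cls,
        path: str | Path,
        labels: Mapping[str, tuple[str, int, str]] | None = None,
    ) -> "StructureModel":
        from biotite.structure.io.pdb import PDBFile

        arr = PDBFile.read(str(path)).get_structure(model=1)
        chains = np.array(
            [_CHAIN_ROLES.get(c, c) for c in arr.chain_id], dtype=object
        )
        return cls(
            chain=chains,
            resid=arr.res_id.astype(int),
            resname=arr.res_name.astype(object),
            atom_name=arr.atom_name.astype(object),
            element=arr.element.astype(object),
            coords=arr.coord.astype(float),
            labels=dict(labels or {}),
        )


@dataclass
class TrajectoryFrames:
    """Coordinate stack congruent with a :class:`StructureModel`.

    ``coords`` has shape (n_frames, n_atoms, 3).  ``frame_interval`` is
    optional and in ns.  ``realized_contacts`` records, for generated
    trajectories, the realized per-frame frequency of any scheduled
    contacts (see :func:`dynmech.synthetic.generate_trajectory`).
    """

    coords: np.ndarray
    frame_interval: float | None = None
    realized_contacts: dict[Any, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("at least one frame required")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def write_csv(self, path: str | Path, structure: StructureModel) -> None:
        if structure.n_atoms != self.n_atoms:
            raise ValueError("structure does not match trajectory atom count")
        n_f, n_a = self.n_frames, self.n_atoms
        frame = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_f), n_a),
                "chain": np.tile(structure.chain, n_f),
                "resid": np.tile(structure.resid, n_f),
                "atom": np.tile(structure.atom_name, n_f),
                "x": self.coords[:, :, 0].ravel(),
                "y": self.coords[:, :, 1].ravel(),
                "z": self.coords[:, :, 2].ravel(),
            }
        )
        frame.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read_csv(cls, path: str | Path, structure: StructureModel) -> "TrajectoryFrames":
        frame = pd.read_csv(path)
        n_frames = int(frame["frame"].max()) + 1
        coords = np.empty((n_frames, structure.n_atoms, 3), dtype=float)
        for f, sub in frame.groupby("frame", sort=True):
            idx = [
                structure.index_of(c, r, a)
                for c, r, a in zip(sub["chain"], sub["resid"], sub["atom"])
            ]
            coords[int(f), idx, :] = sub[["x", "y", "z"]].to_numpy()
        return cls(coords=coords)
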