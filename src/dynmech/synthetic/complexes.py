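"""Construction of a toy motor-tubulin complex with known geometry.

The generated :class:`~dynmech.structure.StructureModel` stands in for a
microtubule-binding-domain (MTBD) + stalk fragment of the dynein heavy
chain bound to an alpha/beta-tubulin dimer.  It is *not* a physical
model: tubulin is an elongated slab of residues whose longest principal
axis is the +z direction by construction, and the dynein chains are
placed so that every reference vector the geometry code measures is
known analytically:

* tubulin long axis (PA1): ``(0, 0, 1)``, signed from the alpha- to the
  beta-tubulin center;
* MTBD anchor pair (A3295/W3395 C-alpha) midpoint: ``(0, 25, 0)``, so
  the radial axis PA2 is ``(0, 1, 0)``;
* MTBD vector (anchor midpoint -> A3288/Y3402 midpoint): ``(0, 10, 0)``;
* a glutamate (E3306, dynein) / arginine (R402, alpha-tubulin) pair
  whose closest side-chain nitrogen-oxygen distance is ~5.5 Angstrom,
  i.e. just outside the 4 Angstrom salt-bridge cutoff, so that contact
  scheduling can toggle the interaction frame by frame.

Residue numbering mirrors human dynein heavy-chain numbering for the
eight labeled residues so selections written against the toy complex
read identically to selections against a real model.

Principal axes downstream are computed from unit-mass C-alpha atoms;
the tubulin C-alpha grid is exactly symmetric about the x and y axes, so
the construction axes are recovered to machine precision.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ..structure import StructureModel

__all__ = ["ToyComplexSpec", "generate_toy_complex", "toy_reference_geometry"]

_DEFAULT_LABELS: dict[str, tuple[str, int, str]] = {
    "A3295": ("mtbd", 3295, "CA"),
    "W3395": ("mtbd", 3395, "CA"),
    "A3288": ("mtbd", 3288, "CA"),
    "Y3402": ("mtbd", 3402, "CA"),
    "E3306": ("mtbd", 3306, "CA"),
    "R3191": ("stalk", 3191, "CA"),
    "S3501": ("stalk", 3501, "CA"),
    "R402": ("alpha_tubulin", 402, "CA"),
}

_CHAIN_START = {"alpha_tubulin": 370, "beta_tubulin": 1, "mtbd": 3281}
_STALK_ARM_STARTS = (3170, 3480)

# fixed CA positions of the labeled dynein residues (Angstrom)
_NAMED_CA = {
    "A3295": (-2.0, 25.0, 0.0),
    "W3395": (2.0, 25.0, 0.0),
    "A3288": (-2.0, 35.0, 0.0),
    "Y3402": (2.0, 35.0, 0.0),
    "E3306": (0.0, 21.2, -6.0),
}

_LABEL_RESNAME = {
    "A": "ALA", "W": "TRP", "Y": "TYR", "R": "ARG", "S": "SER", "E": "GLU",
}

# backbone/side-chain offsets from CA for a generic residue
_GENERIC_OFFSETS = [
    ("N", "N", (-1.2, 0.3, 0.2)),
    ("C", "C", (1.2, 0.3, -0.2)),
    ("O", "O", (1.9, 1.2, -0.2)),
    ("CB", "C", (0.0, 1.5, 0.4)),
]
_AMIDE_H_OFFSET = (-1.7, -0.5, 0.6)  # relative to CA, ~1 Angstrom from N


@dataclass
class ToyComplexSpec:
    """Layout parameters for :func:`generate_toy_complex`.

    ``chains`` maps chain role to residue count.  The mtbd count must be
    large enough for the contiguous numbering starting at 3281 to reach
    residue 3402, and the stalk count (split into two coiled-coil arms
    starting at residues 3170 and 3480) must cover residues 3191 and
    3501.  ``slab_half_xy`` sets the tubulin slab cross-section
    half-widths; equal second moments in x and y are rejected as a
    degenerate layout.
    """

    chains: dict[str, int] = field(
        default_factory=lambda: {
            "alpha_tubulin": 60,
            "beta_tubulin": 60,
            "mtbd": 125,
            "stalk": 60,
        }
    )
    named_atoms: Mapping[str, tuple[str, int, str]] = field(
        default_factory=lambda: dict(_DEFAULT_LABELS)
    )
    include_hydrogens: bool = True
    slab_half_xy: tuple[float, float] = (10.0, 6.0)

    def __post_init__(self) -> None:
        missing = set(_DEFAULT_LABELS) - set(self.named_atoms)
        if missing:
            raise ValueError(f"named_atoms must map all labels; missing {sorted(missing)}")


def _tubulin_grid(count: int, z_values: np.ndarray, half_xy: tuple[float, float]):
    hx, hy = half_xy
    xs = (-hx, 0.0, hx)
    ys = (-hy, hy)
    points = []
    for z in z_values:
        for x in xs:
            for y in ys:
                points.append((x, y, z))
    return points[:count]


def _residue_atoms(resname: str, ca: np.ndarray, include_h: bool):
    """(atom_name, element, position) records for one generic residue."""
    ca = np.asarray(ca, dtype=float)
    atoms = [("CA", "C", tuple(ca))]
    for name, elem, off in _GENERIC_OFFSETS:
        if resname == "GLY" and name == "CB":
            continue
        atoms.append((name, elem, tuple(ca + off)))
    if include_h:
        atoms.append(("H", "H", tuple(ca + _AMIDE_H_OFFSET)))
    return atoms


def _arg_side_chain(ca: np.ndarray, include_h: bool):
    ca = np.asarray(ca, dtype=float)
    side = [
        ("CB", "C", (0.0, 1.2, 0.0)),
        ("CG", "C", (0.0, 2.3, 0.0)),
        ("CD", "C", (0.0, 3.4, 0.0)),
        ("NE", "N", (0.0, 4.4, 0.0)),
        ("CZ", "C", (0.0, 5.3, 0.0)),
        ("NH1", "N", (-0.8, 6.0, 0.0)),
        ("NH2", "N", (0.8, 6.0, 0.0)),
    ]
    atoms = [(n, e, tuple(ca + off)) for n, e, off in side]
    if include_h:
        atoms.append(("HE", "H", tuple(ca + (0.0, 4.4, 1.0))))
        atoms.append(("HH1", "H", tuple(ca + (-1.3, 6.8, 0.0))))
        atoms.append(("HH2", "H", tuple(ca + (1.3, 6.8, 0.0))))
    return atoms


def _glu_side_chain(ca: np.ndarray):
    ca = np.asarray(ca, dtype=float)
    side = [
        ("CB", "C", (0.0, -1.2, 0.0)),
        ("CG", "C", (0.0, -2.2, 0.0)),
        ("CD", "C", (0.0, -3.0, 0.0)),
        ("OE1", "O", (-0.6, -3.7, 0.0)),
        ("OE2", "O", (0.6, -3.7, 0.0)),
    ]
    return [(n, e, tuple(ca + off)) for n, e, off in side]


def generate_toy_complex(spec: ToyComplexSpec | None = None) -> StructureModel:
    """Build the toy complex; see the module docstring for the geometry."""
    spec = spec or ToyComplexSpec()
    include_h = spec.include_hydrogens

    records: list[tuple[str, int, str, str, str, tuple[float, float, float]]] = []

    def add_residue(chain: str, resid: int, resname: str, atoms) -> None:
        for name, elem, pos in atoms:
            records.append((chain, resid, resname, name, elem, pos))

    # --- tubulin slab -----------------------------------------------------
    n_alpha = spec.chains["alpha_tubulin"]
    n_beta = spec.chains["beta_tubulin"]
    nz_a = int(np.ceil(n_alpha / 6))
    nz_b = int(np.ceil(n_beta / 6))
    z_alpha = -6.0 - 8.0 * np.arange(nz_a)[::-1]  # [-6-8(nz-1) .. -6]
    z_beta = 6.0 + 8.0 * np.arange(nz_b)
    alpha_points = _tubulin_grid(n_alpha, z_alpha, spec.slab_half_xy)
    beta_points = _tubulin_grid(n_beta, z_beta, spec.slab_half_xy)

    alpha_resids = list(range(_CHAIN_START["alpha_tubulin"],
                              _CHAIN_START["alpha_tubulin"] + n_alpha))
    r402_chain, r402_resid, _ = spec.named_atoms["R402"]
    if r402_resid in alpha_resids:
        # give the labeled arginine the slab point nearest the dynein side
        # (+y, z just below the interface) by swapping grid assignments;
        # the CA point set, hence the principal axes, is unchanged
        target = min(
            range(len(alpha_points)),
            key=lambda i: (abs(alpha_points[i][0]), -alpha_points[i][1], abs(alpha_points[i][2] + 6.0)),
        )
        i402 = alpha_resids.index(r402_resid)
        alpha_points[i402], alpha_points[target] = alpha_points[target], alpha_points[i402]
    else:
        raise ValueError("alpha_tubulin chain does not cover the labeled arginine residue")

    for resid, point in zip(alpha_resids, alpha_points):
        if resid == r402_resid:
            ca = np.asarray(point, dtype=float)
            atoms = _residue_atoms("ARG", ca, include_h)
            atoms = [a for a in atoms if a[0] != "CB"] + _arg_side_chain(ca, include_h)
            add_residue("alpha_tubulin", resid, "ARG", atoms)
        else:
            add_residue("alpha_tubulin", resid, "ALA",
                        _residue_atoms("ALA", np.asarray(point), include_h))
    for k, point in enumerate(beta_points):
        add_residue("beta_tubulin", _CHAIN_START["beta_tubulin"] + k, "ALA",
                    _residue_atoms("ALA", np.asarray(point), include_h))

    # --- MTBD -------------------------------------------------------------
    n_mtbd = spec.chains["mtbd"]
    mtbd_resids = list(range(_CHAIN_START["mtbd"], _CHAIN_START["mtbd"] + n_mtbd))
    named_by_resid = {}
    for label, (chain, resid, _atom) in spec.named_atoms.items():
        if chain == "mtbd":
            if resid not in mtbd_resids:
                raise ValueError(f"mtbd chain does not cover labeled residue {label}")
            named_by_resid[resid] = label
    for k, resid in enumerate(mtbd_resids):
        if resid in named_by_resid:
            label = named_by_resid[resid]
            ca = np.asarray(_NAMED_CA[label], dtype=float)
            resname = _LABEL_RESNAME[label[0]]
            atoms = _residue_atoms(resname, ca, include_h)
            if label == "E3306":
                atoms = [a for a in atoms if a[0] != "CB"] + _glu_side_chain(ca)
            add_residue("mtbd", resid, resname, atoms)
        else:
            # compact helical coil around the anchor region
            theta = 0.55 * k
            ca = np.array([
                4.5 * np.cos(theta),
                28.0 + 4.5 * np.sin(theta),
                -4.0 + 8.0 * k / max(n_mtbd - 1, 1),
            ])
            add_residue("mtbd", resid, "ALA", _residue_atoms("ALA", ca, include_h))

    # --- stalk: two coiled-coil arms rising away from the MTBD ------------
    n_stalk = spec.chains["stalk"]
    half = n_stalk // 2
    u = np.array([0.0, np.sin(np.deg2rad(60.0)), np.cos(np.deg2rad(60.0))])
    for arm, (start, count, x_off) in enumerate(
        [(_STALK_ARM_STARTS[0], half, -1.5), (_STALK_ARM_STARTS[1], n_stalk - half, 1.5)]
    ):
        base = np.array([x_off, 35.0, 0.0])
        for k in range(count):
            resid = start + k
            resname = "ARG" if resid == 3191 else ("SER" if resid == 3501 else "ALA")
            ca = base + u * (1.6 * k)
            add_residue("stalk", resid, resname, _residue_atoms(resname, ca, include_h))
    stalk_resids = {r for c, r, *_ in records if c == "stalk"}
    for label in ("R3191", "S3501"):
        if spec.named_atoms[label][1] not in stalk_resids:
            raise ValueError(f"stalk chain does not cover labeled residue {label}")

    chain, resid, resname, name, elem, pos = zip(*records)
    structure = StructureModel(
        chain=np.array(chain, dtype=object),
        resid=np.array(resid, dtype=int),
        resname=np.array(resname, dtype=object),
        atom_name=np.array(name, dtype=object),
        element=np.array(elem, dtype=object),
        coords=np.array(pos, dtype=float),
        labels=dict(spec.named_atoms),
    )
    for label in spec.named_atoms:
        structure.label_index(label)  # raises MissingAtomError if unresolvable

    # reject layouts whose tubulin second moments are (near-)degenerate
    from ..geometry import DegenerateGeometryError, _sorted_gyration_eigen

    evals, _ = _sorted_gyration_eigen(
        structure.coords[structure.ca_mask(("alpha_tubulin", "beta_tubulin"))]
    )
    gaps = np.diff(evals[::-1])  # descending
    if np.any(np.abs(gaps) < 1e-6 * evals.max()):
        raise DegenerateGeometryError(
            "tubulin slab has two (near-)equal principal moments; "
            "choose distinct cross-section half-widths"
        )
    return structure


def toy_reference_geometry(spec: ToyComplexSpec | None = None) -> dict[str, np.ndarray]:
    """Analytic reference vectors of the construction (unperturbed)."""
    anchor = np.array([0.0, 25.0, 0.0])
    tip = np.array([0.0, 35.0, 0.0])
    spec = spec or ToyComplexSpec()
    half = spec.chains["stalk"] // 2
    u = np.array([0.0, np.sin(np.deg2rad(60.0)), np.cos(np.deg2rad(60.0))])
    r3191 = np.array([-1.5, 35.0, 0.0]) + u * (1.6 * (3191 - _STALK_ARM_STARTS[0]))
    s3501 = np.array([1.5, 35.0, 0.0]) + u * (1.6 * (3501 - _STALK_ARM_STARTS[1]))
    return {
        "long_axis": np.array([0.0, 0.0, 1.0]),
        "radial_axis": np.array([0.0, 1.0, 0.0]),
        "anchor_center": anchor,
        "mtbd_vector": tip - anchor,
        "stalk_vector": 0.5 * (r3191 + s3501) - anchor,
    }
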