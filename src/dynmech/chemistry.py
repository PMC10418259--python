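"""Atom chemistry tables and interaction criteria for contact detection.

Interaction definitions:

* salt bridge — any basic side-chain nitrogen within ``salt_bridge_cutoff``
  (default 4 Angstrom) of any acidic side-chain oxygen, between distinct
  residues;
* hydrophobic — any pair of side-chain carbon atoms of distinct residues
  within ``hydrophobic_cutoff`` (default 8 Angstrom);
* hydrogen bond — donor and acceptor heavy atoms within
  ``hbond_distance_cutoff`` (default 3.5 Angstrom) with the angle at the
  donor between the donor's hydrogen and the acceptor at most
  ``hbond_angle_cutoff`` (default 30 degrees).

The residue/atom tables are editable defaults (standard amino-acid
valence); they can be overridden programmatically or loaded from YAML.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "InteractionCriteria",
    "BASIC_NITROGENS",
    "ACIDIC_OXYGENS",
    "HBOND_DONORS",
    "HBOND_ACCEPTORS",
    "BACKBONE_ATOMS",
]

#: Side-chain nitrogens carrying positive charge at physiological pH.
BASIC_NITROGENS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

#: Carboxylate side-chain oxygens.
ACIDIC_OXYGENS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

#: Hydrogen-bond donor heavy atoms per residue; "*" applies to every residue
#: (backbone amide nitrogen).
HBOND_DONORS: dict[str, tuple[str, ...]] = {
    "*": ("N",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
    "CYS": ("SG",),
}

#: Hydrogen-bond acceptor heavy atoms per residue.
HBOND_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}

#: Backbone atoms excluded from the side-chain carbon set.
BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT", "H", "HA")


@dataclass
class InteractionCriteria:
    """Distance/angle cutoffs and atom tables for contact detection."""

    salt_bridge_cutoff: float = 4.0
    hydrophobic_cutoff: float = 8.0
    hbond_distance_cutoff: float = 3.5
    hbond_angle_cutoff: float = 30.0
    basic_nitrogens: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(BASIC_NITROGENS)
    )
    acidic_oxygens: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(ACIDIC_OXYGENS)
    )
    donors: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(HBOND_DONORS))
    acceptors: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(HBOND_ACCEPTORS)
    )

    def __post_init__(self) -> None:
        for name in (
            "salt_bridge_cutoff",
            "hydrophobic_cutoff",
            "hbond_distance_cutoff",
            "hbond_angle_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def atoms_for(self, table: dict[str, tuple[str, ...]], resname: str) -> tuple[str, ...]:
        """Atom names the table assigns to ``resname`` (including wildcards)."""
        return tuple(table.get("*", ())) + tuple(table.get(resname, ()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InteractionCriteria":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        tables = {}
        for key in ("basic_nitrogens", "acidic_oxygens", "donors", "acceptors"):
            if key in data:
                tables[key] = {k: tuple(v) for k, v in data.pop(key).items()}
        return cls(**data, **tables)
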