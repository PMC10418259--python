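"""Shared fixtures and independent brute-force oracles.

The oracles re-implement detection rules with naive loops so the
vectorized implementations can be checked for exact agreement.
"""
from __future__ import annotations

import numpy as np
import pytest

from dynmech.structure import StructureModel
from dynmech.synthetic import ToyComplexSpec, generate_toy_complex
from dynmech.trace import ForceTrace
from dynmech.trap import StallCriteria


@pytest.fixture(scope="session")
def toy():
    return generate_toy_complex(ToyComplexSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------- trap oracle


def brute_force_stalls(trace: ForceTrace, criteria: StallCriteria):
    """Naive exhaustive interval scan with the same criteria.

    Returns (start_idx, end_idx, detached) tuples of maximal candidate
    runs; intentionally loop-based and independent of the vectorized
    detector.
    """
    f = trace.force
    fs = trace.sampling_rate
    n = f.size
    w = int(round(criteria.stationary_window * fs))
    w = max(1, w)
    if w % 2 == 0:
        w += 1
    h = w // 2
    padded = np.concatenate([np.full(h, f[0]), f, np.full(h, f[-1])])
    candidate = np.zeros(n, dtype=bool)
    for i in range(n):
        med = np.median(padded[i : i + w])
        candidate[i] = (f[i] >= criteria.min_force) and (
            abs(f[i] - med) <= criteria.stationary_tolerance
        )
    events = []
    i = 0
    while i < n:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and candidate[j + 1]:
            j += 1
        if (j - i) / fs > criteria.min_duration:
            event_median = float(np.median(f[i : j + 1]))
            lo = j + 1
            hi = min(n, j + 1 + int(round(criteria.snap_back_max_interval * fs)))
            detached = False
            for k in range(lo, hi):
                if (
                    f[k] <= event_median - criteria.snap_back_min_drop
                    or f[k] < criteria.snap_back_floor
                ):
                    detached = True
                    break
            if detached or not criteria.snap_back_required:
                events.append((i, j, detached))
        i = j + 1
    return events


def random_stall_trace(rng: np.random.Generator, n: int = 10_000, fs: float = 250.0):
    """Random piecewise trace with ramps, plateaus, drops and noise."""
    f = np.zeros(n)
    i = 0
    level = 0.0
    while i < n:
        kind = rng.choice(["ramp", "hold", "drop"], p=[0.4, 0.4, 0.2])
        length = int(rng.integers(10, 400))
        j = min(n, i + length)
        if kind == "ramp":
            target = rng.uniform(0.0, 6.0)
            f[i:j] = np.linspace(level, target, j - i)
            level = target
        elif kind == "hold":
            f[i:j] = level
        else:
            f[i:j] = 0.0
            level = 0.0
        i = j
    f = f + rng.normal(0.0, 0.15, n)
    return ForceTrace(
        time=np.arange(n) / fs,
        position=f,  # stiffness 1 => position == force
        force=f,
        sampling_rate=fs,
        trap_stiffness=1.0,
    )


# ------------------------------------------------------------- contact oracle


def brute_force_contacts(structure: StructureModel, criteria, kind: str):
    """All-pairs loop scan for one interaction kind (no vectorization)."""
    out = set()
    n = structure.n_atoms
    coords = structure.coords

    def key(i):
        return (structure.chain[i], int(structure.resid[i]), structure.atom_name[i])

    def same_res(i, j):
        return (
            structure.chain[i] == structure.chain[j]
            and structure.resid[i] == structure.resid[j]
        )

    if kind == "salt_bridge":
        for i in range(n):
            if structure.atom_name[i] not in criteria.atoms_for(
                criteria.basic_nitrogens, structure.resname[i]
            ):
                continue
            for j in range(n):
                if same_res(i, j):
                    continue
                if structure.atom_name[j] not in criteria.atoms_for(
                    criteria.acidic_oxygens, structure.resname[j]
                ):
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= criteria.salt_bridge_cutoff:
                    out.add((key(i), key(j)))
    elif kind == "hydrophobic":
        backbone = {"N", "CA", "C", "O", "OXT", "H", "HA"}
        side_c = [
            i
            for i in range(n)
            if structure.element[i] == "C" and structure.atom_name[i] not in backbone
        ]
        for a, i in enumerate(side_c):
            for j in side_c[a + 1 :]:
                if same_res(i, j):
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= criteria.hydrophobic_cutoff:
                    out.add((key(i), key(j)))
    elif kind == "hbond":
        for i in range(n):
            if structure.atom_name[i] not in criteria.atoms_for(
                criteria.donors, structure.resname[i]
            ):
                continue
            hydrogens = [
                h
                for h in range(n)
                if structure.element[h] == "H"
                and same_res(i, h)
                and np.linalg.norm(coords[h] - coords[i]) <= 1.2
            ]
            if not hydrogens:
                continue
            for j in range(n):
                if same_res(i, j):
                    continue
                if structure.atom_name[j] not in criteria.atoms_for(
                    criteria.acceptors, structure.resname[j]
                ):
                    continue
                d = np.linalg.norm(coords[i] - coords[j])
                if d > criteria.hbond_distance_cutoff or d <= 1e-6:
                    continue
                for h in hydrogens:
                    u = coords[h] - coords[i]
                    v = coords[j] - coords[i]
                    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang <= criteria.hbond_angle_cutoff:
                        out.add((key(i), key(j)))
                        break
    else:
        raise ValueError(kind)
    return out


_RES_ATOMS = {
    "LYS": [("NZ", "N")],
    "ARG": [("NE", "N"), ("NH1", "N"), ("NH2", "N"), ("CZ", "C")],
    "GLU": [("OE1", "O"), ("OE2", "O"), ("CD", "C"), ("CG", "C")],
    "ASP": [("OD1", "O"), ("OD2", "O"), ("CG", "C")],
    "SER": [("OG", "O"), ("CB", "C")],
    "ALA": [("CB", "C")],
}


def random_contact_structure(rng: np.random.Generator, n_residues: int = 8):
    """Small random structure with charged/polar residues in a tight box."""
    resnames = list(_RES_ATOMS)
    chains, resids, rnames, anames, elements, coords = [], [], [], [], [], []
    for r in range(n_residues):
        resname = resnames[rng.integers(len(resnames))]
        chain = "mtbd" if rng.random() < 0.5 else "alpha_tubulin"
        center = rng.uniform(0, 14, 3)
        atoms = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")] + _RES_ATOMS[resname]
        positions = {}
        for name, elem in atoms:
            pos = center + rng.uniform(-2.0, 2.0, 3)
            positions[name] = pos
            chains.append(chain)
            resids.append(r + 1)
            rnames.append(resname)
            anames.append(name)
            elements.append(elem)
            coords.append(pos)
        if rng.random() < 0.8:  # amide hydrogen on the backbone nitrogen
            hpos = positions["N"] + rng.uniform(-0.6, 0.6, 3)
            chains.append(chain)
            resids.append(r + 1)
            rnames.append(resname)
            anames.append("H")
            elements.append("H")
            coords.append(hpos)
    return StructureModel(
        chain=np.array(chains, dtype=object),
        resid=np.array(resids),
        resname=np.array(rnames, dtype=object),
        atom_name=np.array(anames, dtype=object),
        element=np.array(elements, dtype=object),
        coords=np.array(coords),
    )
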