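"""Statistical stand-in trajectories with controlled geometry and contacts.

:func:`generate_trajectory` emulates the *observables* of an all-atom
trajectory of the toy complex without any physics: per frame it

1. samples a tilt angle from a Gaussian mixture and rigidly rotates the
   dynein chains (MTBD + stalk) about ``tilt_axis`` through the MTBD
   anchor midpoint — injecting a known angular distribution that the
   downstream angle pipeline must recover;
2. adds independent Gaussian noise per *residue* (one displacement
   shared by all atoms of the residue), emulating thermal fluctuations
   with a known RMSF (sigma * sqrt(3) per residue);
3. forces or breaks scheduled residue-residue contacts by moving the
   single closest relevant atom radially across the criterion cutoff,
   so that the realized per-frame contact count matches the schedule
   exactly (to the nearest integer frame count).

With zero noise, a zero-mean/zero-sd tilt and no schedule the output is
bitwise identical to the input structure in every frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from ..chemistry import InteractionCriteria
from ..geometry import MTBD_ANCHOR_LABELS, _relevant_sets
from ..structure import DYNEIN_ROLES, StructureModel, TrajectoryFrames

__all__ = ["TrajectorySimParams", "generate_trajectory"]


@dataclass
class TrajectorySimParams:
    """Tilt mixture, per-residue noise and contact schedule for the generator.

    ``contact_schedule`` maps a residue pair ``((chain, resid), (chain,
    resid))`` to a target per-frame frequency in [0, 1]; scheduled
    contacts are evaluated as salt bridges by default (``schedule_kind``).
    """

    n_frames: int = 1000
    tilt_means: tuple[float, ...] = (0.0,)  # degrees
    tilt_sds: tuple[float, ...] = (0.0,)
    tilt_weights: tuple[float, ...] = (1.0,)
    tilt_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    per_residue_noise_sd: float = 0.0  # Angstrom
    contact_schedule: Mapping[tuple, float] = field(default_factory=dict)
    schedule_kind: str = "salt_bridge"
    noise_chains: tuple[str, ...] | None = None  # None = every chain
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        k = len(self.tilt_means)
        if len(self.tilt_sds) != k or len(self.tilt_weights) != k:
            raise ValueError("tilt mixture arrays must have equal length")
        if abs(sum(self.tilt_weights) - 1.0) > 1e-9:
            raise ValueError("tilt_weights must sum to 1")
        for freq in self.contact_schedule.values():
            if not 0.0 <= freq <= 1.0:
                raise ValueError("contact frequencies must lie in [0, 1]")
        if self.per_residue_noise_sd < 0:
            raise ValueError("per_residue_noise_sd must be non-negative")


def _schedule_frames(rng, n_frames: int, frequency: float) -> np.ndarray:
    count = int(round(frequency * n_frames))
    on = np.zeros(n_frames, dtype=bool)
    if count:
        on[rng.choice(n_frames, size=count, replace=False)] = True
    return on


def generate_trajectory(
    structure: StructureModel,
    params: TrajectorySimParams,
    criteria: InteractionCriteria | None = None,
) -> TrajectoryFrames:
    """Generate frames congruent with ``structure`` (see module docstring).

    Realized contact frequencies (exact counts / n_frames) are recorded
    in ``TrajectoryFrames.realized_contacts``.
    """
    criteria = criteria or InteractionCriteria()
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    axis = np.asarray(params.tilt_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pivot = structure.coords[
        [structure.label_index(lab) for lab in MTBD_ANCHOR_LABELS]
    ].mean(axis=0)
    dynein = np.flatnonzero(structure.mask(chain=DYNEIN_ROLES))

    # residue -> atom indices, for shared per-residue noise
    residue_keys = structure.residue_keys()
    key_to_slot = {key: i for i, key in enumerate(residue_keys)}
    atom_slot = np.array(
        [key_to_slot[(c, int(r))] for c, r in zip(structure.chain, structure.resid)]
    )
    if params.noise_chains is None:
        noisy_atoms = np.ones(structure.n_atoms, dtype=bool)
    else:
        noisy_atoms = structure.mask(chain=params.noise_chains)

    # tilt mixture draws
    comp = rng.choice(len(params.tilt_means), size=n, p=np.asarray(params.tilt_weights))
    angles = np.array(
        [rng.normal(params.tilt_means[c], params.tilt_sds[c]) for c in comp]
    )

    # contact schedule bookkeeping
    schedule = []
    cutoff = {
        "salt_bridge": criteria.salt_bridge_cutoff,
        "hydrophobic": criteria.hydrophobic_cutoff,
        "hbond": criteria.hbond_distance_cutoff,
    }[params.schedule_kind]
    realized: dict[tuple, float] = {}
    for pair, freq in params.contact_schedule.items():
        sets = [
            (ia, ib)
            for ia, ib in _relevant_sets(structure, criteria, pair, params.schedule_kind)
            if ia.size and ib.size
        ]
        if not sets:
            raise ValueError(f"no {params.schedule_kind}-relevant atoms for pair {pair}")
        on = _schedule_frames(rng, n, freq)
        schedule.append((pair, sets, on))
        realized[pair] = float(on.sum()) / n

    coords = np.empty((n, structure.n_atoms, 3))
    base = structure.coords
    noise_sd = params.per_residue_noise_sd
    for i in range(n):
        frame = base.copy()
        theta = angles[i]
        if theta != 0.0:
            rot = Rotation.from_rotvec(np.deg2rad(theta) * axis)
            frame[dynein] = rot.apply(frame[dynein] - pivot) + pivot
        if noise_sd > 0.0:
            res_noise = rng.normal(0.0, noise_sd, size=(len(residue_keys), 3))
            frame[noisy_atoms] += res_noise[atom_slot][noisy_atoms]
        for pair, sets, on in schedule:
            _enforce_contact(frame, sets, cutoff, bool(on[i]))
        coords[i] = frame
    traj = TrajectoryFrames(coords=coords)
    traj.realized_contacts = realized
    return traj


def _enforce_contact(
    frame: np.ndarray,
    sets: list[tuple[np.ndarray, np.ndarray]],
    cutoff: float,
    want: bool,
) -> None:
    """Move the closest relevant atom radially so the contact matches ``want``."""
    if want:
        best = None
        for ia, ib in sets:
            d = cdist(frame[ia], frame[ib])
            k = np.unravel_index(np.argmin(d), d.shape)
            if best is None or d[k] < best[0]:
                best = (d[k], int(ia[k[0]]), int(ib[k[1]]))
        dmin, a, b = best
        if dmin > cutoff:
            direction = frame[b] - frame[a]
            direction /= np.linalg.norm(direction)
            frame[a] = frame[b] - direction * (0.9 * cutoff)
    else:
        # iteratively push offending atoms out until no pair qualifies
        for _ in range(32):
            best = None
            for ia, ib in sets:
                d = cdist(frame[ia], frame[ib])
                k = np.unravel_index(np.argmin(d), d.shape)
                if best is None or d[k] < best[0]:
                    best = (d[k], int(ia[k[0]]), int(ib[k[1]]))
            dmin, a, b = best
            if dmin > cutoff:
                return
            direction = frame[a] - frame[b]
            norm = np.linalg.norm(direction)
            direction = direction / norm if norm > 1e-9 else np.array([0.0, 1.0, 0.0])
            frame[a] = frame[b] + direction * (1.25 * cutoff)
        raise RuntimeError("could not break scheduled contact")
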