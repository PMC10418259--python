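"""Structural observables from coordinate trajectories.

This module measures the orientation and flexibility of a dynein
MTBD/stalk fragment relative to the tubulin dimer it is bound to:

* **Principal axes of tubulin.**  PA1 is the longitudinal axis of the
  protofilament (largest spread / smallest moment), signed from the
  alpha- toward the beta-tubulin center of geometry.  PA2 is the radial
  axis: the component, orthogonal to PA1, of the vector from the
  tubulin center to the midpoint of the MTBD anchor C-alpha pair
  (A3295/W3395).  PA3 = PA1 x PA2 completes the right-handed triad.
  Axes are computed from unit-mass C-alpha atoms.

* **MTBD and stalk vectors.**  The MTBD vector runs from the
  A3295/W3395 C-alpha midpoint to the A3288/Y3402 midpoint.  The stalk
  vector runs from the same anchor midpoint to the R3191/S3501 midpoint
  of a full-length reference structure superimposed onto each frame via
  the stalk-base C-alpha atoms.

* **Projected angles.**  A vector is projected onto a chosen
  principal-axes plane and the signed angle to a chosen in-plane
  reference axis is measured; the sign follows the right-hand rule
  about the plane normal.  The default planes are PA2-PA3 (w.r.t. PA2)
  for the around-axis MTBD tilt and PA1-PA2 (w.r.t. PA1) for the
  stalk-vs-longitudinal angle; ``literal_methods=True`` instead
  projects the MTBD vector onto the PA1-PA2 plane and measures against
  PA2.

* **Per-residue fluctuations** (RMSF about the mean aligned position,
  frames aligned on tubulin C-alpha atoms) and **contacts**
  (salt-bridge / hydrophobic / hydrogen-bond criteria, see
  :mod:`dynmech.chemistry`) with per-frame indicator series and
  percentage frequencies.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from ._fitting import GaussianComponent, fit_gaussian_sum
from .chemistry import BACKBONE_ATOMS, InteractionCriteria
from .structure import (
    DYNEIN_ROLES,
    TUBULIN_ROLES,
    MissingAtomError,
    StructureModel,
    TrajectoryFrames,
)

__all__ = [
    "DegenerateGeometryError",
    "PrincipalAxes",
    "AngleSeries",
    "PeakFit",
    "RigidTransform",
    "Contact",
    "ContactRecord",
    "DistanceSeries",
    "FluctuationProfile",
    "principal_axes",
    "mtbd_vector",
    "projected_angle",
    "superimpose",
    "stalk_vector",
    "mtbd_angle_series",
    "stalk_angle_series",
    "angle_histogram_fit",
    "fluctuation_profile",
    "fluctuation_increase",
    "detect_contacts",
    "contact_frequency",
    "distance_series",
]

SIGN_CONVENTION = "positive = right-handed rotation about the plane normal"

MTBD_ANCHOR_LABELS = ("A3295", "W3395")
MTBD_TIP_LABELS = ("A3288", "Y3402")
STALK_TIP_LABELS = ("R3191", "S3501")
STALK_BASE_RANGE = (3288, 3402)


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction is ill-conditioned."""


def _sorted_gyration_eigen(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ascending eigenvalues/vectors of the unit-mass gyration tensor."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    return evals, evecs


@dataclass(frozen=True)
class PrincipalAxes:
    """Orthonormal right-handed tubulin frame; origin at the tubulin center."""

    origin: np.ndarray
    pa1: np.ndarray
    pa2: np.ndarray
    pa3: np.ndarray

    def __post_init__(self) -> None:
        m = np.vstack([self.pa1, self.pa2, self.pa3])
        if np.max(np.abs(m @ m.T - np.eye(3))) > 1e-9:
            raise DegenerateGeometryError("principal axes are not orthonormal")
        if np.dot(np.cross(self.pa1, self.pa2), self.pa3) < 0:
            raise DegenerateGeometryError("principal axes are not right-handed")

    def axis(self, name: str) -> np.ndarray:
        return {"PA1": self.pa1, "PA2": self.pa2, "PA3": self.pa3}[name]


def _coords(structure: StructureModel, coords: np.ndarray | None) -> np.ndarray:
    if coords is None:
        return structure.coords
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (structure.n_atoms, 3):
        raise ValueError("frame coordinates do not match the structure")
    return coords


def _label_point(
    structure: StructureModel, coords: np.ndarray, labels: Sequence[str]
) -> np.ndarray:
    idx = [structure.label_index(lab) for lab in labels]
    return coords[idx].mean(axis=0)


def principal_axes(
    structure: StructureModel,
    coords: np.ndarray | None = None,
    anchor_labels: Sequence[str] = MTBD_ANCHOR_LABELS,
) -> PrincipalAxes:
    """Tubulin principal axes for one frame (see module docstring)."""
    coords = _coords(structure, coords)
    tub = structure.ca_mask(TUBULIN_ROLES)
    if not tub.any():
        raise MissingAtomError("no tubulin C-alpha atoms present")
    tub_coords = coords[tub]
    origin = tub_coords.mean(axis=0)
    evals, evecs = _sorted_gyration_eigen(tub_coords)
    if evals[2] - evals[1] < 1e-8 * max(evals[2], 1.0):
        raise DegenerateGeometryError("tubulin inertia tensor is degenerate")
    pa1 = evecs[:, 2]
    alpha = coords[structure.ca_mask("alpha_tubulin")].mean(axis=0)
    beta = coords[structure.ca_mask("beta_tubulin")].mean(axis=0)
    if np.dot(pa1, beta - alpha) < 0:
        pa1 = -pa1
    radial = _label_point(structure, coords, anchor_labels) - origin
    radial = radial - np.dot(radial, pa1) * pa1
    norm = np.linalg.norm(radial)
    if norm < 1e-9:
        raise DegenerateGeometryError("anchor center lies on the longitudinal axis")
    pa2 = radial / norm
    pa3 = np.cross(pa1, pa2)
    return PrincipalAxes(origin=origin, pa1=pa1, pa2=pa2, pa3=pa3)


def mtbd_vector(
    structure: StructureModel, coords: np.ndarray | None = None
) -> np.ndarray:
    """Anchor-midpoint -> tip-midpoint vector of the MTBD, Angstrom."""
    coords = _coords(structure, coords)
    anchor = _label_point(structure, coords, MTBD_ANCHOR_LABELS)
    tip = _label_point(structure, coords, MTBD_TIP_LABELS)
    return tip - anchor


def projected_angle(
    vector: np.ndarray,
    axes: PrincipalAxes,
    plane: str = "PA2-PA3",
    reference_axis: str = "PA2",
) -> float:
    """Signed in-plane angle (degrees, (-180, 180]) of ``vector``.

    ``plane`` is e.g. ``"PA1-PA2"``; the plane normal is the cross
    product of the two named axes in that order, and the sign of the
    angle follows the right-hand rule about that normal.
    """
    a_name, b_name = plane.split("-")
    a, b = axes.axis(a_name), axes.axis(b_name)
    normal = np.cross(a, b)
    ref = axes.axis(reference_axis)
    if abs(np.dot(ref, normal)) > 1e-9:
        raise ValueError("reference axis must lie in the projection plane")
    v = np.asarray(vector, dtype=float)
    v_proj = v - np.dot(v, normal) * normal
    if np.linalg.norm(v_proj) < 1e-9:
        raise DegenerateGeometryError("vector is (near-)normal to the projection plane")
    angle = np.degrees(
        np.arctan2(np.dot(np.cross(ref, v_proj), normal), np.dot(ref, v_proj))
    )
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


# --------------------------------------------------------------- superposition


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation minimizing least-squares RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def superimpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares (Kabsch) superposition of paired atom sets.

    Returns the transform mapping ``mobile`` onto ``reference``; the
    rotation always has determinant +1 (no reflection).  Collinear or
    too-small atom sets are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be equal-shape (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    mob_com = mobile.mean(axis=0)
    ref_com = reference.mean(axis=0)
    mob_c = mobile - mob_com
    ref_c = reference - ref_com
    svals = np.linalg.svd(mob_c, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise DegenerateGeometryError("mobile atom set is collinear")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref_c, mob_c)
    r = rot.as_matrix()
    translation = ref_com - r @ mob_com
    rmsd = float(np.sqrt(np.mean(np.sum((ref_c - mob_c @ r.T) ** 2, axis=1))))
    return RigidTransform(rotation=r, translation=translation, rmsd=rmsd)


def stalk_vector(
    structure: StructureModel,
    frame_coords: np.ndarray | None,
    reference: StructureModel,
    base_range: tuple[int, int] = STALK_BASE_RANGE,
) -> np.ndarray:
    """Stalk direction via superposition of a full-length reference.

    The reference structure is superimposed onto the frame using the
    stalk-base C-alpha atoms (mtbd-chain residues in ``base_range``
    present in both structures); the returned vector runs from the
    frame's anchor midpoint to the transformed reference's R3191/S3501
    C-alpha midpoint.
    """
    coords = _coords(structure, frame_coords)
    lo, hi = base_range
    keys = [
        (c, r)
        for c, r in structure.residue_keys(structure.ca_mask("mtbd"))
        if lo <= r <= hi
    ]
    pairs = []
    for c, r in keys:
        try:
            pairs.append((structure.index_of(c, r, "CA"), reference.index_of(c, r, "CA")))
        except MissingAtomError:
            continue
    if len(pairs) < 3:
        raise MissingAtomError("fewer than 3 shared stalk-base C-alpha atoms")
    frame_idx, ref_idx = map(list, zip(*pairs))
    transform = superimpose(reference.coords[ref_idx], coords[frame_idx])
    tip_idx = [reference.label_index(lab) for lab in STALK_TIP_LABELS]
    tip = transform.apply(reference.coords[tip_idx]).mean(axis=0)
    anchor = _label_point(structure, coords, MTBD_ANCHOR_LABELS)
    return tip - anchor


# ---------------------------------------------------------------- angle series


@dataclass
class AngleSeries:
    """Per-frame projected angles (degrees) with the projection metadata."""

    angles: np.ndarray
    plane: str
    reference_axis: str
    sign_convention: str = SIGN_CONVENTION

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (
            self.angles.min() <= -180.0 or self.angles.max() > 180.0
        ):
            raise ValueError("angles must lie in (-180, 180]")


@dataclass
class PeakFit:
    """Gaussian peak-fit summary of an angular histogram."""

    n_peaks: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        total = self.weights.sum()
        if total > 0:
            self.weights = self.weights / total


def mtbd_angle_series(
    structure: StructureModel,
    traj: TrajectoryFrames,
    literal_methods: bool = False,
) -> AngleSeries:
    """Around-axis MTBD tilt per frame.

    Default projection: PA2-PA3 plane w.r.t. PA2 (rotation around the
    longitudinal axis).  ``literal_methods=True`` projects onto the
    PA1-PA2 plane and measures against PA2 instead.
    """
    plane, ref = ("PA1-PA2", "PA2") if literal_methods else ("PA2-PA3", "PA2")
    angles = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.coords[i]
        axes = principal_axes(structure, frame)
        angles[i] = projected_angle(mtbd_vector(structure, frame), axes, plane, ref)
    return AngleSeries(angles=angles, plane=plane, reference_axis=ref)


def stalk_angle_series(
    structure: StructureModel,
    traj: TrajectoryFrames,
    reference: StructureModel | None = None,
) -> AngleSeries:
    """Stalk angle relative to the longitudinal axis (PA1-PA2 plane, w.r.t. PA1)."""
    reference = reference or structure
    angles = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.coords[i]
        axes = principal_axes(structure, frame)
        v = stalk_vector(structure, frame, reference)
        angles[i] = projected_angle(v, axes, "PA1-PA2", "PA1")
    return AngleSeries(angles=angles, plane="PA1-PA2", reference_axis="PA1")


def angle_histogram_fit(
    series: AngleSeries | np.ndarray,
    n_peaks: int,
    bin_width: float = 1.0,
) -> PeakFit:
    """Fit ``n_peaks`` Gaussians to the normalized angle histogram."""
    angles = series.angles if isinstance(series, AngleSeries) else np.asarray(series)
    if angles.size < 100:
        raise ValueError("need at least 100 angles for a peak fit")
    lo = np.floor(angles.min() / bin_width) * bin_width - 2 * bin_width
    hi = np.ceil(angles.max() / bin_width) * bin_width + 2 * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    density, edges = np.histogram(angles, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    comps = fit_gaussian_sum(centers, density, n_peaks)
    return PeakFit(
        n_peaks=n_peaks,
        means=np.array([c.mean for c in comps]),
        sds=np.array([abs(c.sd) for c in comps]),
        weights=np.array([c.weight for c in comps]),
    )


# ----------------------------------------------------------------- fluctuations


@dataclass
class FluctuationProfile:
    """Per-residue C-alpha RMSF (Angstrom) after alignment to a reference selection."""

    per_residue_rmsf: dict[tuple[str, int], float]
    aligned_to: str

    def mean_rmsf(
        self,
        chains: Iterable[str] | None = None,
        resid_range: tuple[int, int] | None = None,
    ) -> float:
        values = [
            v
            for (c, r), v in self.per_residue_rmsf.items()
            if (chains is None or c in chains)
            and (resid_range is None or resid_range[0] <= r <= resid_range[1])
        ]
        if not values:
            raise ValueError("selection matches no residues")
        return float(np.mean(values))


def fluctuation_profile(
    traj: TrajectoryFrames,
    structure: StructureModel,
    align_chains: Sequence[str] = TUBULIN_ROLES,
    reference_frame: int = 0,
) -> FluctuationProfile:
    """Per-residue RMSF about the mean aligned position.

    Every frame is superimposed onto ``reference_frame`` using the
    C-alpha atoms of ``align_chains`` (the microtubule), then the RMSF
    of each residue's C-alpha about its across-frame mean is taken.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    align = np.flatnonzero(structure.ca_mask(align_chains))
    ca = np.flatnonzero(structure.ca_mask())
    ref_align = traj.coords[reference_frame][align]
    n = traj.n_frames
    total = np.zeros((ca.size, 3))
    total_sq = np.zeros(ca.size)
    for i in range(n):
        transform = superimpose(traj.coords[i][align], ref_align)
        moved = transform.apply(traj.coords[i][ca])
        total += moved
        total_sq += np.einsum("ij,ij->i", moved, moved)
    mean = total / n
    msd = total_sq / n - np.einsum("ij,ij->i", mean, mean)
    rmsf = np.sqrt(np.clip(msd, 0.0, None))
    per_residue = {
        (structure.chain[a], int(structure.resid[a])): float(r)
        for a, r in zip(ca, rmsf)
    }
    return FluctuationProfile(
        per_residue_rmsf=per_residue,
        aligned_to=f"CA of {'+'.join(align_chains)} (frame {reference_frame})",
    )


def fluctuation_increase(
    baseline: FluctuationProfile,
    variant: FluctuationProfile,
    chains: Iterable[str] | None = DYNEIN_ROLES,
    resid_range: tuple[int, int] | None = None,
) -> float:
    """100 * (mean RMSF_variant / mean RMSF_baseline - 1) over a selection."""
    return 100.0 * (
        variant.mean_rmsf(chains, resid_range) / baseline.mean_rmsf(chains, resid_range)
        - 1.0
    )


# --------------------------------------------------------------------- contacts


@dataclass(frozen=True)
class Contact:
    a: tuple[str, int, str]
    b: tuple[str, int, str]
    distance: float
    kind: str


@dataclass
class ContactRecord:
    """Per-frame contact indicator and percentage frequency for one pair."""

    pair: tuple[tuple[str, int], tuple[str, int]]
    kind: str
    per_frame: np.ndarray
    frequency: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_frame = np.asarray(self.per_frame, dtype=bool)
        self.frequency = 100.0 * float(np.mean(self.per_frame))


def _atom_key(structure: StructureModel, i: int) -> tuple[str, int, str]:
    return (structure.chain[i], int(structure.resid[i]), structure.atom_name[i])


def _table_mask(structure: StructureModel, table: dict, criteria: InteractionCriteria):
    mask = np.zeros(structure.n_atoms, dtype=bool)
    for i in range(structure.n_atoms):
        if structure.atom_name[i] in criteria.atoms_for(table, structure.resname[i]):
            mask[i] = True
    return mask


def _restrict(structure: StructureModel, idx: np.ndarray, residue: tuple[str, int]):
    chain, resid = residue
    keep = (structure.chain[idx] == chain) & (structure.resid[idx] == int(resid))
    return idx[keep]


def _pair_contacts(
    structure: StructureModel,
    coords: np.ndarray,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    cutoff: float,
    kind: str,
    symmetric: bool,
) -> list[Contact]:
    if idx_a.size == 0 or idx_b.size == 0:
        return []
    d = cdist(coords[idx_a], coords[idx_b])
    same_res = (structure.chain[idx_a][:, None] == structure.chain[idx_b][None, :]) & (
        structure.resid[idx_a][:, None] == structure.resid[idx_b][None, :]
    )
    hit = (d <= cutoff) & ~same_res
    out = []
    for ia, ib in zip(*np.nonzero(hit)):
        ga, gb = int(idx_a[ia]), int(idx_b[ib])
        if symmetric and ga >= gb:
            continue
        out.append(
            Contact(
                a=_atom_key(structure, ga),
                b=_atom_key(structure, gb),
                distance=float(d[ia, ib]),
                kind=kind,
            )
        )
    return out


def _hydrogens_by_donor(structure: StructureModel, coords: np.ndarray, donors: np.ndarray):
    """Map donor index -> indices of hydrogens bonded to it (<= 1.2 A, same residue)."""
    h_idx = np.flatnonzero(np.array([e == "H" for e in structure.element]))
    mapping: dict[int, list[int]] = {}
    for d in donors:
        if h_idx.size == 0:
            mapping[int(d)] = []
            continue
        same = (structure.chain[h_idx] == structure.chain[d]) & (
            structure.resid[h_idx] == structure.resid[d]
        )
        cand = h_idx[same]
        if cand.size:
            dist = np.linalg.norm(coords[cand] - coords[d], axis=1)
            cand = cand[dist <= 1.2]
        mapping[int(d)] = [int(c) for c in cand]
    return mapping


def detect_contacts(
    structure: StructureModel,
    coords: np.ndarray | None,
    criteria: InteractionCriteria,
    kind: str,
    pair: tuple[tuple[str, int], tuple[str, int]] | None = None,
    heavy_atom_fallback: bool = False,
) -> list[Contact]:
    """All qualifying atom pairs of one interaction kind in one frame.

    ``pair`` optionally restricts detection to two specific residues
    given as (chain, resid).  Hydrogen-bond detection requires hydrogen
    atoms unless ``heavy_atom_fallback`` is set, in which case the
    donor-acceptor distance plus the antecedent-donor-acceptor angle
    (>= 90 degrees) is used for donors without hydrogens.
    """
    coords = _coords(structure, coords)
    if kind == "salt_bridge":
        basic = np.flatnonzero(_table_mask(structure, criteria.basic_nitrogens, criteria))
        acidic = np.flatnonzero(_table_mask(structure, criteria.acidic_oxygens, criteria))
        if pair is not None:
            res_a, res_b = pair
            contacts = _pair_contacts(
                structure, coords,
                _restrict(structure, basic, res_a), _restrict(structure, acidic, res_b),
                criteria.salt_bridge_cutoff, kind, symmetric=False,
            ) + _pair_contacts(
                structure, coords,
                _restrict(structure, basic, res_b), _restrict(structure, acidic, res_a),
                criteria.salt_bridge_cutoff, kind, symmetric=False,
            )
            return contacts
        return _pair_contacts(
            structure, coords, basic, acidic, criteria.salt_bridge_cutoff, kind, False
        )

    if kind == "hydrophobic":
        side_c = np.flatnonzero(
            np.array(
                [
                    e == "C" and a not in BACKBONE_ATOMS
                    for e, a in zip(structure.element, structure.atom_name)
                ]
            )
        )
        if pair is not None:
            res_a, res_b = pair
            return _pair_contacts(
                structure, coords,
                _restrict(structure, side_c, res_a), _restrict(structure, side_c, res_b),
                criteria.hydrophobic_cutoff, kind, symmetric=False,
            )
        return _pair_contacts(
            structure, coords, side_c, side_c, criteria.hydrophobic_cutoff, kind, True
        )

    if kind == "hbond":
        donors = np.flatnonzero(_table_mask(structure, criteria.donors, criteria))
        acceptors = np.flatnonzero(_table_mask(structure, criteria.acceptors, criteria))
        if pair is not None:
            res_a, res_b = pair
            out = []
            for d_res, a_res in ((res_a, res_b), (res_b, res_a)):
                out.extend(
                    _hbond_contacts(
                        structure, coords, criteria,
                        _restrict(structure, donors, d_res),
                        _restrict(structure, acceptors, a_res),
                        heavy_atom_fallback,
                    )
                )
            return out
        return _hbond_contacts(
            structure, coords, criteria, donors, acceptors, heavy_atom_fallback
        )

    raise ValueError(f"unknown interaction kind {kind!r}")


def _hbond_contacts(
    structure: StructureModel,
    coords: np.ndarray,
    criteria: InteractionCriteria,
    donors: np.ndarray,
    acceptors: np.ndarray,
    heavy_atom_fallback: bool,
) -> list[Contact]:
    if donors.size == 0 or acceptors.size == 0:
        return []
    h_map = _hydrogens_by_donor(structure, coords, donors)
    any_h = any(h_map.values())
    if not any_h and not heavy_atom_fallback:
        raise MissingAtomError(
            "hydrogen-bond detection requires hydrogen atoms; "
            "rebuild the structure with hydrogens or pass heavy_atom_fallback=True"
        )
    out = []
    for d in donors:
        dv = coords[d]
        dist = np.linalg.norm(coords[acceptors] - dv, axis=1)
        near = acceptors[(dist <= criteria.hbond_distance_cutoff) & (dist > 1e-6)]
        for a in near:
            if structure.chain[a] == structure.chain[d] and structure.resid[a] == structure.resid[d]:
                continue
            hydrogens = h_map[int(d)]
            if hydrogens:
                ok = False
                for h in hydrogens:
                    angle = _angle_deg(coords[h] - dv, coords[a] - dv)
                    if angle <= criteria.hbond_angle_cutoff:
                        ok = True
                        break
                if not ok:
                    continue
            elif heavy_atom_fallback:
                ante = _antecedent(structure, coords, int(d))
                if ante is not None:
                    angle = _angle_deg(coords[ante] - dv, coords[a] - dv)
                    if angle < 90.0:
                        continue
            else:
                continue
            out.append(
                Contact(
                    a=_atom_key(structure, int(d)),
                    b=_atom_key(structure, int(a)),
                    distance=float(np.linalg.norm(coords[a] - dv)),
                    kind="hbond",
                )
            )
    return out


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _antecedent(structure: StructureModel, coords: np.ndarray, donor: int) -> int | None:
    """Nearest same-residue heavy atom within 1.8 A of the donor, if any."""
    same = (
        (structure.chain == structure.chain[donor])
        & (structure.resid == structure.resid[donor])
        & (np.arange(structure.n_atoms) != donor)
        & np.array([e != "H" for e in structure.element])
    )
    idx = np.flatnonzero(same)
    if idx.size == 0:
        return None
    dist = np.linalg.norm(coords[idx] - coords[donor], axis=1)
    best = idx[np.argmin(dist)]
    return int(best) if dist.min() <= 1.8 else None


def contact_frequency(
    traj: TrajectoryFrames,
    structure: StructureModel,
    pair: tuple[tuple[str, int], tuple[str, int]],
    criteria: InteractionCriteria | None = None,
    kind: str = "salt_bridge",
    heavy_atom_fallback: bool = False,
) -> ContactRecord:
    """Per-frame indicator and percentage of frames where the contact holds."""
    criteria = criteria or InteractionCriteria()
    per_frame = np.zeros(traj.n_frames, dtype=bool)
    for i in range(traj.n_frames):
        per_frame[i] = bool(
            detect_contacts(
                structure, traj.coords[i], criteria, kind,
                pair=pair, heavy_atom_fallback=heavy_atom_fallback,
            )
        )
    return ContactRecord(pair=pair, kind=kind, per_frame=per_frame)


@dataclass
class DistanceSeries:
    """Per-frame minimum relevant inter-atom distance plus its histogram."""

    distances: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray

    def indicator(self, cutoff: float) -> np.ndarray:
        return self.distances <= cutoff


def _relevant_sets(
    structure: StructureModel,
    criteria: InteractionCriteria,
    pair: tuple[tuple[str, int], tuple[str, int]],
    kind: str,
) -> list[tuple[np.ndarray, np.ndarray]]:
    res_a, res_b = pair
    if kind == "salt_bridge":
        basic = np.flatnonzero(_table_mask(structure, criteria.basic_nitrogens, criteria))
        acidic = np.flatnonzero(_table_mask(structure, criteria.acidic_oxygens, criteria))
        return [
            (_restrict(structure, basic, res_a), _restrict(structure, acidic, res_b)),
            (_restrict(structure, basic, res_b), _restrict(structure, acidic, res_a)),
        ]
    if kind == "hydrophobic":
        side_c = np.flatnonzero(
            np.array(
                [
                    e == "C" and a not in BACKBONE_ATOMS
                    for e, a in zip(structure.element, structure.atom_name)
                ]
            )
        )
        return [(_restrict(structure, side_c, res_a), _restrict(structure, side_c, res_b))]
    if kind == "hbond":
        donors = np.flatnonzero(_table_mask(structure, criteria.donors, criteria))
        acceptors = np.flatnonzero(_table_mask(structure, criteria.acceptors, criteria))
        return [
            (_restrict(structure, donors, res_a), _restrict(structure, acceptors, res_b)),
            (_restrict(structure, donors, res_b), _restrict(structure, acceptors, res_a)),
        ]
    raise ValueError(f"unknown interaction kind {kind!r}")


def distance_series(
    traj: TrajectoryFrames,
    structure: StructureModel,
    pair: tuple[tuple[str, int], tuple[str, int]],
    criteria: InteractionCriteria | None = None,
    kind: str = "salt_bridge",
    bins: int = 40,
) -> DistanceSeries:
    """Minimum kind-relevant inter-atom distance per frame, with histogram."""
    criteria = criteria or InteractionCriteria()
    sets = [
        (ia, ib)
        for ia, ib in _relevant_sets(structure, criteria, pair, kind)
        if ia.size and ib.size
    ]
    if not sets:
        raise MissingAtomError(f"no {kind}-relevant atoms found for pair {pair}")
    distances = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.coords[i]
        distances[i] = min(float(cdist(frame[ia], frame[ib]).min()) for ia, ib in sets)
    density, edges = np.histogram(distances, bins=bins, density=True)
    return DistanceSeries(distances=distances, bin_edges=edges, density=density)
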