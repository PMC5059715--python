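"""Trajectory-geometry observables for pH-gated transporter analysis.

Implements the standard observables used to characterise pH-dependent gating
in membrane transporters: the hydrophobic-gate radius of gyration, first-shell
hydration numbers of carboxylate residues, distance-cutoff ion-binding
indicators, salt-bridge minimum distances, helix bending angles (deviation
from linearity of a Cα triple), donor-acceptor hydrogen-bond checks, water
density maps in bulk-density units, Kabsch superposition and Cα principal
component analysis.

Cutoff conventions are strict inequalities throughout: sodium is *bound*
below 3.0 Å, a water is in the first shell below 3.5 Å, a helix is *bent*
above 28°.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import CARBOXYLATE_OXYGENS, SelectionSpec, StructureFrame

__all__ = [
    "GATE_RESIDUES",
    "gate_rg",
    "hydration_number",
    "sodium_bound",
    "saltbridge_min_distance",
    "bending_angle",
    "bent_occupancy",
    "hbond_present",
    "water_density_map",
    "superpose_kabsch",
    "pca_ca",
]

#: the five hydrophobic sidechains forming the cytoplasmic gate
GATE_RESIDUES = (75, 134, 157, 160, 161)

#: default number density of bulk water at ambient conditions (Å^-3);
#: an external physical constant, overridable in water_density_map
BULK_WATER_DENSITY = 0.0334

SODIUM_CUTOFF = 3.0
HYDRATION_CUTOFF = 3.5
BENT_CUTOFF_DEG = 28.0


def gate_rg(
    frame: StructureFrame,
    gate_selection: SelectionSpec | None = None,
    mass_weighted: bool = False,
    masses: np.ndarray | None = None,
) -> float:
    """Radius of gyration (Å) of the gate sidechain heavy atoms.

    Default selection: sidechain heavy atoms of the five gate residues.
    Unweighted (geometric) by default; pass ``mass_weighted=True`` with
    per-atom ``masses`` for the mass-weighted variant.
    """
    if gate_selection is None:
        gate_selection = SelectionSpec(resids=GATE_RESIDUES, sidechain_heavy=True)
    coords = frame.coords(gate_selection.mask(frame))
    if mass_weighted:
        if masses is None:
            raise ValueError("mass_weighted=True requires per-atom masses")
        w = np.asarray(masses, dtype=float)
        if len(w) != len(coords):
            raise ValueError("masses length does not match selection")
        w = w / w.sum()
    else:
        w = np.full(len(coords), 1.0 / len(coords))
    center = w @ coords
    return float(np.sqrt(np.sum(w * np.sum((coords - center) ** 2, axis=1))))


def _carboxylate_oxygens(frame: StructureFrame, resid: int) -> np.ndarray:
    mask = frame.select(resids=[resid], names=CARBOXYLATE_OXYGENS)
    coords = frame.xyz[mask]
    if len(coords) == 0:
        resnames = set(frame.resnames[frame.resids == resid])
        raise ValueError(
            f"residue {resid} ({resnames or 'absent'}) has no carboxylate oxygens "
            f"({'/'.join(CARBOXYLATE_OXYGENS)})"
        )
    return coords


def hydration_number(
    frame: StructureFrame, residue: int, cutoff: float = HYDRATION_CUTOFF
) -> int:
    """Number of water oxygens within ``cutoff`` (strict) of the residue's
    nearest carboxylate oxygen — the first-solvation-shell count."""
    ox = _carboxylate_oxygens(frame, residue)
    waters = frame.water_oxygens()
    if len(waters) == 0:
        return 0
    dmin = cdist(waters, ox).min(axis=1)
    return int(np.sum(dmin < cutoff))


def sodium_bound(
    frame: StructureFrame,
    targets: Mapping[str, tuple[int, tuple[str, ...]]] | None = None,
    cutoff: float = SODIUM_CUTOFF,
) -> dict[str, bool]:
    """Distance-cutoff sodium-binding indicator per target.

    ``targets`` maps a label to ``(resid, atom_names)``; the default is the
    core triad convention: carboxylate oxygens of residues 163 and 164 and
    the backbone carbonyl oxygen of residue 132.  A target is *bound* when
    any sodium is strictly below ``cutoff`` from its nearest listed atom.
    Returns the per-target booleans plus ``"any"``.  With no sodium present
    all targets are False.
    """
    if targets is None:
        targets = {
            "Asp163": (163, CARBOXYLATE_OXYGENS),
            "Asp164": (164, CARBOXYLATE_OXYGENS),
            "Thr132": (132, ("O",)),
        }
    na = frame.sodium_positions()
    out: dict[str, bool] = {}
    for label, spec in targets.items():
        try:
            resid, atom_names = spec
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"target {label!r} must be (resid, atom_names), got {spec!r}"
            ) from exc
        mask = frame.select(resids=[int(resid)], names=tuple(atom_names))
        if not mask.any():
            raise ValueError(f"target {label!r}: no atoms {atom_names} in residue {resid}")
        if len(na) == 0:
            out[label] = False
        else:
            out[label] = bool(cdist(na, frame.xyz[mask]).min() < cutoff)
    out["any"] = any(out.values())
    return out


def sodium_binding_probability(
    frames: Sequence[StructureFrame],
    targets: Mapping[str, tuple[int, tuple[str, ...]]] | None = None,
    cutoff: float = SODIUM_CUTOFF,
) -> dict[str, float]:
    """Fraction of frames with sodium bound, per target (frame counting)."""
    counts: dict[str, int] = {}
    n = 0
    for fr in frames:
        flags = sodium_bound(fr, targets, cutoff)
        for k, v in flags.items():
            counts[k] = counts.get(k, 0) + int(v)
        n += 1
    if n == 0:
        raise ValueError("no frames given")
    return {k: c / n for k, c in counts.items()}


def saltbridge_min_distance(
    frame: StructureFrame, lys_residue: int = 300, asp_residue: int = 163
) -> float:
    """Minimum distance (Å) between the lysine amine nitrogen (NZ) and the
    aspartate carboxylate oxygens."""
    nz_mask = frame.select(resids=[lys_residue], names=["NZ"])
    if not nz_mask.any():
        raise ValueError(f"residue {lys_residue} has no NZ atom")
    ox = _carboxylate_oxygens(frame, asp_residue)
    return float(cdist(frame.xyz[nz_mask], ox).min())


def saltbridge_distance_series(
    frames: Sequence[StructureFrame],
    lys_residue: int = 300,
    asp_residue: int = 163,
    condition: Sequence[bool] | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-frame salt-bridge distances, optionally split by a per-frame
    condition; returns (distances_where_true, distances_where_false) or
    (all, None)."""
    d = np.array([saltbridge_min_distance(fr, lys_residue, asp_residue) for fr in frames])
    if condition is None:
        return d, None
    cond = np.asarray(condition, dtype=bool)
    if len(cond) != len(d):
        raise ValueError("condition length does not match frame count")
    return d[cond], d[~cond]


def bending_angle(
    frame: StructureFrame, res_a: int = 152, res_b: int = 163, res_c: int = 174
) -> float:
    """Helix bending angle in degrees: deviation from linearity (180° minus
    the internal angle) of the Cα atoms of three residues; 0° = straight."""
    points = []
    for r in (res_a, res_b, res_c):
        mask = frame.select(resids=[r], names=["CA"])
        if not mask.any():
            raise ValueError(f"residue {r} has no CA atom")
        points.append(frame.xyz[mask][0])
    a, b, c = points
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("coincident Cα positions; bending angle undefined")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(180.0 - np.degrees(np.arccos(cosang)))


def bent_occupancy(angles_deg: Iterable[float], cutoff: float = BENT_CUTOFF_DEG) -> float:
    """Fraction of frames with bending angle strictly above ``cutoff``."""
    angles = np.asarray(list(angles_deg), dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle series")
    return float(np.mean(angles > cutoff))


def hbond_present(
    frame: StructureFrame,
    donor: tuple[int, str] = (132, "N"),
    acceptor_residue: int = 163,
    acceptor_names: tuple[str, ...] = CARBOXYLATE_OXYGENS,
    d_cut: float = 3.5,
    angle_cut: float = 150.0,
    hydrogen_name: str | None = None,
) -> bool:
    """Donor-acceptor hydrogen-bond check.

    True iff the donor heavy atom is strictly within ``d_cut`` of the nearest
    acceptor atom and, when a donor hydrogen is present (``hydrogen_name`` or
    an 'H'/'HN' atom in the donor residue), the D-H···A angle exceeds
    ``angle_cut``.  Without a hydrogen the check is heavy-atom-only.
    """
    don_resid, don_name = donor
    dmask = frame.select(resids=[don_resid], names=[don_name])
    if not dmask.any():
        raise ValueError(f"donor atom {don_name} of residue {don_resid} not found")
    amask = frame.select(resids=[acceptor_residue], names=acceptor_names)
    if not amask.any():
        raise ValueError(
            f"acceptor atoms {acceptor_names} of residue {acceptor_residue} not found"
        )
    d_pos = frame.xyz[dmask][0]
    acc = frame.xyz[amask]
    dists = np.linalg.norm(acc - d_pos, axis=1)
    if dists.min() >= d_cut:
        return False
    h_names = [hydrogen_name] if hydrogen_name else ["H", "HN", "H1"]
    hmask = frame.select(resids=[don_resid], names=h_names)
    if not hmask.any():
        return True
    h_pos = frame.xyz[hmask][0]
    a_pos = acc[np.argmin(dists)]
    v1 = d_pos - h_pos
    v2 = a_pos - h_pos
    cosang = np.clip(
        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-30), -1.0, 1.0
    )
    return bool(np.degrees(np.arccos(cosang)) > angle_cut)


@dataclass(frozen=True)
class DensityMap:
    """Water-oxygen density on a regular grid, in bulk-density units."""

    grid: np.ndarray        # (nx, ny, nz) occupancy / (frames * voxel * bulk)
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    n_frames: int
    bulk_density: float
    n_observations: int     # water oxygens inside the mapped region

    @property
    def voxel_volume(self) -> float:
        return float(np.prod([e[1] - e[0] for e in self.edges]))

    def slab(self, normal: str = "z", center: float | None = None, thickness: float = 5.0):
        """2D average over a slab perpendicular to ``normal``."""
        axis = "xyz".index(normal)
        centers = 0.5 * (self.edges[axis][:-1] + self.edges[axis][1:])
        if center is None:
            sel = np.ones(len(centers), dtype=bool)
        else:
            sel = np.abs(centers - center) <= thickness / 2.0
        if not sel.any():
            raise ValueError("slab selects no grid layers")
        return self.grid.take(np.where(sel)[0], axis=axis).mean(axis=axis)


def water_density_map(
    frames: Sequence[StructureFrame],
    grid_spacing: float = 1.0,
    bounds: tuple[tuple[float, float], ...] | None = None,
    bulk_density: float = BULK_WATER_DENSITY,
) -> DensityMap:
    """Time-averaged water-oxygen density map in units of bulk water density.

    ``grid[v] = count_v / (n_frames * voxel_volume * bulk_density)``, so that
    ``sum(grid) * voxel_volume * bulk_density * n_frames`` equals the total
    number of water-oxygen observations inside the mapped region (count
    conservation).  ``bounds`` default to the data extent padded by one
    voxel; an empty region yields an all-zero grid.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    coords = [fr.water_oxygens() for fr in frames]
    allw = np.concatenate([c for c in coords if len(c)], axis=0) if any(
        len(c) for c in coords
    ) else np.empty((0, 3))
    if bounds is None:
        if len(allw) == 0:
            bounds = tuple((0.0, grid_spacing) for _ in range(3))
        else:
            bounds = tuple(
                (float(allw[:, k].min() - grid_spacing), float(allw[:, k].max() + grid_spacing))
                for k in range(3)
            )
    edges = tuple(
        np.arange(lo, hi + grid_spacing * 0.5, grid_spacing) for lo, hi in bounds
    )
    shape = tuple(len(e) - 1 for e in edges)
    hist = np.zeros(shape)
    n_obs = 0
    for c in coords:
        if len(c) == 0:
            continue
        h, _ = np.histogramdd(c, bins=edges)
        hist += h
        n_obs += int(h.sum())
    voxel = float(np.prod([e[1] - e[0] for e in edges]))
    grid = hist / (len(frames) * voxel * bulk_density)
    return DensityMap(grid=grid, edges=edges, n_frames=len(frames),
                      bulk_density=bulk_density, n_observations=n_obs)


def write_opendx(density: DensityMap, path) -> None:
    """Write a density map as OpenDX-style scalar grid text."""
    nx, ny, nz = density.grid.shape
    ox, oy, oz = (float(e[0] + 0.5 * (e[1] - e[0])) for e in density.edges)
    dx, dy, dz = (float(e[1] - e[0]) for e in density.edges)
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {dx:.6f} 0 0\ndelta 0 {dy:.6f} 0\ndelta 0 0 {dz:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = density.grid.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


# ------------------------------------------------------------ superposition
def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids aligning mobile onto reference
    (least-squares rigid superposition)."""
    if mobile.shape != reference.shape:
        raise ValueError(
            f"atom count mismatch: mobile {mobile.shape[0]} vs reference {reference.shape[0]}"
        )
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - cr, mobile - cm)
    return rot.as_matrix(), cm, cr


def superpose_kabsch(
    mobile_frames: Sequence[StructureFrame],
    reference: StructureFrame,
    selection: SelectionSpec | np.ndarray | None = None,
) -> tuple[list[StructureFrame], np.ndarray]:
    """Least-squares superpose each frame onto the reference.

    The rotation is computed on ``selection`` (mask or spec; all atoms by
    default) and applied to all atoms.  Returns aligned frames and the
    per-frame RMSD (Å) over the selection after alignment.
    """
    if selection is None:
        mask = np.ones(reference.n_atoms, dtype=bool)
    elif isinstance(selection, SelectionSpec):
        mask = selection.mask(reference)
    else:
        mask = np.asarray(selection, dtype=bool)
    ref_sel = reference.xyz[mask]
    aligned = []
    rmsds = []
    for fr in mobile_frames:
        mob_sel = fr.xyz[mask]
        R, cm, cr = kabsch_rotation(mob_sel, ref_sel)
        new = fr.transformed(R, cr - R @ cm)
        aligned.append(new)
        diff = new.xyz[mask] - ref_sel
        rmsds.append(float(np.sqrt(np.mean(np.sum(diff**2, axis=1)))))
    return aligned, np.asarray(rmsds)


@dataclass(frozen=True)
class PCAResult:
    """Cα principal components: orthonormal modes (rows, length 3N),
    non-negative descending eigenvalues, variance fractions summing to 1,
    per-frame projections, and the converged mean structure."""

    modes: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    projections: np.ndarray
    mean_coords: np.ndarray

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Centred coordinates rebuilt from the first k modes (all by default)."""
        k = len(self.eigenvalues) if k is None else k
        return self.projections[:, :k] @ self.modes[:k]


def pca_ca(
    frames: Sequence[StructureFrame],
    selection: SelectionSpec | np.ndarray | None = None,
    align: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PCAResult:
    """Principal component analysis of Cα coordinates.

    Frames are iteratively superposed onto their mean structure until the
    mean moves less than ``tol`` Å (RMS), then the covariance of the
    flattened coordinates is diagonalised.  Needs at least 3 frames and a
    non-degenerate (non-constant) trajectory.
    """
    if len(frames) < 3:
        raise ValueError(f"PCA needs at least 3 frames, got {len(frames)}")
    ref = frames[0]
    if selection is None:
        mask = ref.select(names=["CA"])
        if not mask.any():
            mask = np.ones(ref.n_atoms, dtype=bool)
    elif isinstance(selection, SelectionSpec):
        mask = selection.mask(ref)
    else:
        mask = np.asarray(selection, dtype=bool)

    X = np.stack([fr.xyz[mask] for fr in frames])  # (T, N, 3)
    if align:
        mean = X[0].copy()
        for _ in range(max_iter):
            for t in range(len(X)):
                R, cm, cr = kabsch_rotation(X[t], mean)
                X[t] = (X[t] - cm) @ R.T + cr
            new_mean = X.mean(axis=0)
            shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
            mean = new_mean
            if shift < tol:
                break
    else:
        mean = X.mean(axis=0)

    flat = X.reshape(len(X), -1)
    centred = flat - flat.mean(axis=0)
    total_var = float(np.sum(centred**2) / len(X))
    if total_var < 1e-20:
        raise ValueError("degenerate trajectory: zero total variance, PCA undefined")
    cov = centred.T @ centred / len(X)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    modes = evecs[:, order].T
    fractions = evals / evals.sum()
    projections = centred @ modes.T
    return PCAResult(
        modes=modes, eigenvalues=evals, variance_fractions=fractions,
        projections=projections, mean_coords=mean,
    )
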