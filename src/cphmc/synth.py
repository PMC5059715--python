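"""Synthetic-data generators with machine-readable ground truth.

Every generator returns ``(object, manifest)`` where the manifest is a
JSON-serializable record of the planted truth (curve parameters, geometric
targets, seeds), enabling generator → analysis → truth round-trip tests.
Generators that emit structures write standard PDB through the package's own
writer, so downstream tests exercise the real readers.

What is emulated: Bernoulli protonation series with prescribed titration
curves (optionally a two-population mixture conditioned on an ion-binding
indicator), idealized bent helices, a hydrophobic-gate scene with placed
shell waters and a placed sodium ion, and trajectories with planted
principal-component variances.  What is *not* emulated: realistic protein
packing, lipids, or correlated protonation dynamics — frames are independent
draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ProtonationEnsemble
from .structure import StructureFrame
from .titration import hill_curve

__all__ = [
    "gen_protonation_series",
    "gen_helix",
    "gen_gate_fixture",
    "gen_pca_trajectory",
    "MixtureSpec",
]

#: default helix geometry: rise per residue (Å), Cα radius (Å) and twist.
#: The twist default, 1080/11 ≈ 98.18°/residue (3.667 residues/turn), is an
#: idealization chosen so the canonical probe residues spaced 11 apart share
#: helical phase: a straight helix then measures a bending angle of exactly
#: 0° on the Cα triple.  Pass twist=100.0 for the textbook α-helix value.
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST = 1080.0 / 11.0


@dataclass(frozen=True)
class MixtureSpec:
    """Two-population microscopic titration mixture for one site.

    ``freq_by_ph`` gives the probability that a frame satisfies the
    condition (e.g. sodium bound) at each ladder pH; conditioned frames
    deprotonate along ``(pka_given, hill_given)``, the rest along
    ``(pka_not, hill_not)``.
    """

    pka_given: float
    pka_not: float
    freq_by_ph: Mapping[float, float]
    hill_given: float = 1.0
    hill_not: float = 1.0
    condition_label: str = "occ:Na_bound"

    def __post_init__(self):
        for ph, f in self.freq_by_ph.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"condition frequency at pH {ph} outside [0, 1]: {f}")


def gen_protonation_series(
    ph_ladder: Sequence[float],
    sites: Mapping[str, tuple[float, float]],
    frames_per_ph: int = 1000,
    seed: int = 0,
    mixture: Mapping[str, MixtureSpec] | None = None,
) -> tuple[ProtonationEnsemble, dict]:
    """Draw independent Bernoulli protonation series with known titration.

    ``sites`` maps a site name to its true (pKa, Hill n); per pH, each
    frame's deprotonation bit is Bernoulli(S*(pH)).  Sites listed in
    ``mixture`` additionally get a per-frame condition bit with the
    prescribed per-pH frequency and condition-specific microscopic curves.
    Returns an ensemble (same table layout as the sampler's) plus the truth
    manifest.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ladder = tuple(float(p) for p in ph_ladder)
    mixture = dict(mixture or {})
    for name in mixture:
        if name not in sites:
            raise ValueError(f"mixture refers to unknown site {name!r}")

    cond_labels = {name: spec.condition_label for name, spec in mixture.items()}
    rows = []
    for ph in ladder:
        block: dict[str, np.ndarray] = {
            "pH": np.full(frames_per_ph, ph),
            "sweep": np.arange(frames_per_ph),
        }
        for name, (pka, n) in sites.items():
            if name in mixture:
                spec = mixture[name]
                if ph not in spec.freq_by_ph:
                    raise ValueError(f"mixture for {name!r} lacks a frequency at pH {ph}")
                cond = rng.random(frames_per_ph) < spec.freq_by_ph[ph]
                s_given = hill_curve(ph, spec.pka_given, spec.hill_given)
                s_not = hill_curve(ph, spec.pka_not, spec.hill_not)
                p = np.where(cond, s_given, s_not)
                block[f"site:{name}"] = (rng.random(frames_per_ph) < p).astype(np.int8)
                block[spec.condition_label] = cond.astype(np.int8)
            else:
                s = hill_curve(ph, pka, n)
                block[f"site:{name}"] = (rng.random(frames_per_ph) < s).astype(np.int8)
        rows.append(pd.DataFrame(block))
    data = pd.concat(rows, ignore_index=True)
    bit_labels = tuple(c for c in data.columns if c not in ("pH", "sweep"))
    ensemble = ProtonationEnsemble(
        ph_values=ladder, bit_labels=bit_labels, data=data, seed=seed,
        config_hash="synthetic",
    )
    manifest = {
        "generator": "gen_protonation_series",
        "seed": seed,
        "frames_per_ph": frames_per_ph,
        "ph_ladder": list(ladder),
        "sites": {k: {"pka": v[0], "hill_n": v[1]} for k, v in sites.items()},
        "mixture": {
            k: {
                "pka_given": m.pka_given, "pka_not": m.pka_not,
                "hill_given": m.hill_given, "hill_not": m.hill_not,
                "freq_by_ph": {str(p): f for p, f in m.freq_by_ph.items()},
                "condition_label": m.condition_label,
            }
            for k, m in mixture.items()
        },
    }
    return ensemble, manifest


def _helix_ca(n_res: int, rise: float, radius: float, twist_deg: float) -> np.ndarray:
    i = np.arange(n_res)
    phi = np.radians(twist_deg) * i
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi), rise * i])


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()


def gen_helix(
    n_res: int = 23,
    bend_angle: float | Sequence[float] = 0.0,
    bend_residue: int = 163,
    jitter: float = 0.0,
    start_resid: int = 152,
    n_frames: int | None = None,
    seed: int = 0,
    rise: float = HELIX_RISE,
    radius: float = HELIX_RADIUS,
    twist: float = HELIX_TWIST,
) -> tuple[list[StructureFrame], dict]:
    """Idealized Cα helix with a planted kink at ``bend_residue``.

    The chain is numbered ``start_resid .. start_resid + n_res - 1``; the
    part downstream of the bend residue is rigidly rotated by the bend angle
    about an axis through the bend Cα perpendicular to the helix axis, so the
    deviation-from-linearity measured on equal-phase probe residues equals
    the planted angle exactly at zero jitter.  ``bend_angle`` may be a
    sequence (one angle per frame) to build bimodal angle series; Gaussian
    ``jitter`` (Å, per coordinate) is added independently per frame.
    """
    b = bend_residue - start_resid
    if not (0 < b < n_res - 1):
        raise ValueError(
            f"bend residue {bend_residue} not interior to chain "
            f"{start_resid}..{start_resid + n_res - 1}"
        )
    angles = np.atleast_1d(np.asarray(bend_angle, dtype=float))
    if n_frames is None:
        n_frames = len(angles)
    if len(angles) == 1:
        angles = np.repeat(angles, n_frames)
    if len(angles) != n_frames:
        raise ValueError("bend_angle sequence length must equal n_frames")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = _helix_ca(n_res, rise, radius, twist)
    phi_b = np.radians(twist) * b
    axis = np.array([-np.sin(phi_b), np.cos(phi_b), 0.0])  # ⊥ helix axis
    names = np.array(["CA"] * n_res, dtype=object)
    resnames = np.array(["ALA"] * n_res, dtype=object)
    resnames[b] = "ASP"
    resids = np.arange(start_resid, start_resid + n_res)
    chains = np.array(["A"] * n_res, dtype=object)
    elements = np.array(["C"] * n_res, dtype=object)

    frames = []
    for t in range(n_frames):
        xyz = base.copy()
        R = _rotation_about(axis, angles[t])
        pivot = base[b]
        xyz[b + 1 :] = (xyz[b + 1 :] - pivot) @ R.T + pivot
        if jitter > 0:
            xyz = xyz + rng.normal(0.0, jitter, xyz.shape)
        frames.append(
            StructureFrame(names=names, resnames=resnames, resids=resids,
                           chains=chains, elements=elements, xyz=xyz, frame_index=t)
        )
    manifest = {
        "generator": "gen_helix",
        "seed": seed,
        "n_res": n_res,
        "start_resid": int(start_resid),
        "bend_residue": int(bend_residue),
        "bend_angles": angles.tolist(),
        "jitter": jitter,
        "rise": rise,
        "radius": radius,
        "twist": twist,
        "probe_residues": [int(start_resid), int(bend_residue),
                           int(start_resid + n_res - 1)],
    }
    return frames, manifest


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def gen_gate_fixture(
    target_rg: float = 4.6,
    shell_waters: int = 5,
    ion_distances: Mapping[str, float] | None = None,
    water_distances: Sequence[float] | None = None,
    lys_nz_distance: float | None = None,
    hydration_residue: int = 164,
    seed: int = 0,
) -> tuple[StructureFrame, dict]:
    """A single-frame scene with exact, planted geometric observables.

    Builds five gate residues whose single sidechain heavy atoms sit on a
    ring of radius ``target_rg`` (so the gate radius of gyration equals the
    target to machine precision), two core aspartates with carboxylate
    oxygens, a threonine backbone carbonyl, ``shell_waters`` water oxygens
    at prescribed distances from the hydration residue's OD1 (defaults
    evenly spaced in 3.0-3.4 Å), one placed sodium ion per entry of
    ``ion_distances`` (label -> distance from that target's reference atom),
    and optionally a lysine NZ at ``lys_nz_distance`` from Asp163 OD1.
    """
    if target_rg <= 0:
        raise ValueError("target_rg must be positive")
    if shell_waters < 0:
        raise ValueError("shell_waters must be >= 0")
    ion_distances = dict(ion_distances or {})
    if water_distances is None:
        water_distances = list(np.linspace(3.0, 3.4, shell_waters)) if shell_waters else []
    elif len(water_distances) != shell_waters:
        raise ValueError("water_distances length must equal shell_waters")

    names, resnames, resids, chains, elements, xyz = [], [], [], [], [], []

    def add(name, resname, resid, pos, element=None):
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        chains.append("A")
        elements.append(element or name[0])
        xyz.append(np.asarray(pos, dtype=float))

    # gate: 5 sidechain atoms on a ring of radius target_rg around origin
    gate = [("VAL", 75, "CB"), ("ILE", 134, "CB"), ("MET", 157, "CB"),
            ("ALA", 160, "CB"), ("ILE", 161, "CB")]
    for k, (rn, ri, an) in enumerate(gate):
        ang = 2 * np.pi * k / 5
        add(an, rn, ri, [target_rg * np.cos(ang), target_rg * np.sin(ang), 0.0])
        # backbone CA slightly outside; excluded from sidechain-heavy masks
        add("CA", rn, ri, [(target_rg + 1.5) * np.cos(ang), (target_rg + 1.5) * np.sin(ang), 0.5])

    # core aspartates below the gate plane, well separated (> 8 Å)
    asp_centres = {163: np.array([-6.0, 0.0, -6.0]), 164: np.array([6.0, 0.0, -6.0])}
    for resid, c in asp_centres.items():
        add("CB", "ASP", resid, c + [0.0, 0.0, 1.8])
        add("CG", "ASP", resid, c + [0.0, 0.0, 0.6])
        add("OD1", "ASP", resid, c)
        add("OD2", "ASP", resid, c + [0.0, 1.2, 0.8])

    # threonine backbone carbonyl, off to the side
    thr_o = np.array([0.0, 8.0, -6.0])
    add("N", "THR", 132, thr_o + [1.2, 0.8, 0.0])
    add("CA", "THR", 132, thr_o + [2.0, 0.0, 0.8])
    add("C", "THR", 132, thr_o + [0.9, -0.6, 0.4])
    add("O", "THR", 132, thr_o)

    ref_atoms = {"Asp163": asp_centres[163], "Asp164": asp_centres[164], "Thr132": thr_o}

    if lys_nz_distance is not None:
        add("NZ", "LYS", 300, asp_centres[163] + lys_nz_distance * _unit([-1.0, 0.3, -0.2]), "N")

    # shell waters: placed off OD1 of the hydration residue, pointing away
    # from OD2 so OD1 stays the nearest carboxylate oxygen
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    od1 = ref_atoms[f"Asp{hydration_residue}"] if hydration_residue in (163, 164) else None
    if od1 is None:
        raise ValueError("hydration_residue must be 163 or 164")
    wid = 1
    for d in water_distances:
        theta = rng.uniform(0, 2 * np.pi)
        direction = _unit([0.4 * np.cos(theta), -1.0, -0.4 * np.sin(theta)])
        add("O", "HOH", 400 + wid, od1 + d * direction)
        wid += 1

    for label, d in ion_distances.items():
        if label not in ref_atoms:
            raise ValueError(f"unknown ion target {label!r}; valid: {sorted(ref_atoms)}")
        add("NA", "NA", 500 + len(ion_distances), ref_atoms[label] + d * _unit([0.2, -0.9, -0.3]), "Na")

    frame = StructureFrame(
        names=np.array(names, dtype=object), resnames=np.array(resnames, dtype=object),
        resids=np.array(resids), chains=np.array(chains, dtype=object),
        elements=np.array(elements, dtype=object), xyz=np.array(xyz),
    )
    manifest = {
        "generator": "gen_gate_fixture",
        "seed": seed,
        "target_rg": target_rg,
        "shell_waters": shell_waters,
        "water_distances": list(map(float, water_distances)),
        "ion_distances": {k: float(v) for k, v in ion_distances.items()},
        "lys_nz_distance": lys_nz_distance,
        "hydration_residue": hydration_residue,
    }
    return frame, manifest


def gen_pca_trajectory(
    n_atoms: int = 30,
    mode_variances: Sequence[float] = (1.0,),
    n_frames: int = 500,
    background_variance: float = 0.0,
    seed: int = 0,
) -> tuple[list[StructureFrame], dict]:
    """Trajectory with planted principal-component variances.

    Frames are ``mean + sum_k sqrt(v_k) z_k m_k + background`` with random
    orthonormal modes m_k and iid N(0,1) amplitudes z_k; the background adds
    ``background_variance`` per Cartesian coordinate.  Frames carry no
    rigid-body motion, so they are analysable as-is (no superposition
    required).  The manifest records the exact expected variance fractions
    ``(v_k + b) / (sum v + 3 N b)``.
    """
    if any(v < 0 for v in mode_variances):
        raise ValueError("mode variances must be >= 0")
    if background_variance < 0:
        raise ValueError("background variance must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dim = 3 * n_atoms
    k = len(mode_variances)
    if k > dim:
        raise ValueError("more planted modes than coordinate dimensions")
    mean = rng.normal(0.0, 5.0, size=dim)
    modes, _ = np.linalg.qr(rng.normal(size=(dim, k)))
    modes = modes.T  # (k, dim)

    amps = rng.normal(size=(n_frames, k)) * np.sqrt(np.asarray(mode_variances))
    X = mean + amps @ modes
    if background_variance > 0:
        X = X + rng.normal(0.0, np.sqrt(background_variance), size=(n_frames, dim))

    names = np.array(["CA"] * n_atoms, dtype=object)
    resnames = np.array(["GLY"] * n_atoms, dtype=object)
    resids = np.arange(1, n_atoms + 1)
    chains = np.array(["A"] * n_atoms, dtype=object)
    elements = np.array(["C"] * n_atoms, dtype=object)
    frames = [
        StructureFrame(names=names, resnames=resnames, resids=resids, chains=chains,
                       elements=elements, xyz=X[t].reshape(n_atoms, 3), frame_index=t)
        for t in range(n_frames)
    ]
    total = float(np.sum(mode_variances) + dim * background_variance)
    fractions = (
        [(v + background_variance) / total for v in mode_variances] if total > 0 else []
    )
    manifest = {
        "generator": "gen_pca_trajectory",
        "seed": seed,
        "n_atoms": n_atoms,
        "n_frames": n_frames,
        "mode_variances": list(map(float, mode_variances)),
        "background_variance": background_variance,
        "expected_fractions": fractions,
    }
    return frames, manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
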