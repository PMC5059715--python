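"""Structure frames and PDB/XYZ input/output (MDAnalysis-backed).

A :class:`StructureFrame` is a flat, numpy-backed snapshot of a structure:
atom and residue names, 1-based residue numbers as they appear in the source
file, chain identifiers, elements and Å coordinates.  Multi-MODEL PDB files
become lists of frames (0-based frame index).  Alternate locations keep the
highest occupancy (ties broken toward altloc 'A'); insertion codes are
preserved in ``icodes``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: residue-name dialects recognized as water
WATER_RESNAMES = frozenset({"HOH", "TIP3", "TIP3P", "WAT", "SOL", "SPC", "T3P", "TP3"})
#: residue/atom names recognized as sodium ions
SODIUM_RESNAMES = frozenset({"NA", "SOD", "NA+"})

#: backbone heavy-atom names (used to pick out sidechain heavy atoms)
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "OT1", "OT2"})

#: sidechain carboxylate oxygens of Asp/Glu
CARBOXYLATE_OXYGENS = ("OD1", "OD2", "OE1", "OE2")


@dataclass
class StructureFrame:
    """One structural snapshot with per-atom annotation arrays."""

    names: np.ndarray      # atom names
    resnames: np.ndarray
    resids: np.ndarray     # residue numbers (file numbering, 1-based)
    chains: np.ndarray
    elements: np.ndarray
    xyz: np.ndarray        # (N, 3) Å
    icodes: np.ndarray | None = None
    frame_index: int = 0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = len(self.xyz)
        for attr in ("names", "resnames", "resids", "chains", "elements"):
            arr = np.asarray(getattr(self, attr))
            if len(arr) != n:
                raise ValueError(f"{attr} has length {len(arr)}, expected {n}")
            setattr(self, attr, arr)
        if not np.isfinite(self.xyz).all():
            raise ValueError("coordinates must be finite")
        if self.icodes is None:
            self.icodes = np.full(n, "", dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    # ------------------------------------------------------------- selection
    def select(
        self,
        resids: Iterable[int] | None = None,
        names: Iterable[str] | None = None,
        resnames: Iterable[str] | None = None,
        chain: str | None = None,
        sidechain_heavy: bool = False,
    ) -> np.ndarray:
        """Boolean mask of atoms matching all given criteria.

        ``sidechain_heavy`` excludes backbone heavy atoms and hydrogens.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if resids is not None:
            mask &= np.isin(self.resids.astype(int), list(resids))
        if names is not None:
            mask &= np.isin(self.names, list(names))
        if resnames is not None:
            mask &= np.isin(self.resnames, list(resnames))
        if chain is not None:
            mask &= self.chains == chain
        if sidechain_heavy:
            mask &= ~np.isin(self.names, list(BACKBONE_ATOMS))
            mask &= ~np.char.startswith(self.names.astype(str), "H")
            mask &= self.elements.astype(str) != "H"
        return mask

    def coords(self, mask: np.ndarray) -> np.ndarray:
        return self.xyz[mask]

    def water_oxygens(self) -> np.ndarray:
        """Coordinates of water oxygen atoms (by residue-name dialect)."""
        mask = np.isin(self.resnames, list(WATER_RESNAMES)) & (
            np.char.startswith(self.names.astype(str), "O")
        )
        return self.xyz[mask]

    def sodium_positions(self) -> np.ndarray:
        mask = np.isin(self.resnames, list(SODIUM_RESNAMES)) | np.isin(
            self.names, ["NA", "SOD"]
        )
        return self.xyz[mask]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureFrame":
        """A copy with coordinates mapped through x -> R x + t."""
        new = StructureFrame(
            names=self.names.copy(), resnames=self.resnames.copy(),
            resids=self.resids.copy(), chains=self.chains.copy(),
            elements=self.elements.copy(),
            xyz=self.xyz @ np.asarray(rotation).T + np.asarray(translation),
            icodes=None if self.icodes is None else self.icodes.copy(),
            frame_index=self.frame_index,
        )
        return new


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection: residue numbers plus atom-name patterns.

    ``sidechain_heavy`` selects all non-backbone heavy atoms of the listed
    residues (the convention for gate radius-of-gyration calculations).
    """

    resids: tuple[int, ...]
    atom_names: tuple[str, ...] = ()
    sidechain_heavy: bool = False
    chain: str | None = None

    def mask(self, frame: StructureFrame) -> np.ndarray:
        m = frame.select(
            resids=self.resids,
            names=self.atom_names or None,
            chain=self.chain,
            sidechain_heavy=self.sidechain_heavy,
        )
        if not m.any():
            raise ValueError(
                f"selection resolves to no atoms (resids={self.resids}, "
                f"names={self.atom_names}, chain={self.chain})"
            )
        return m


def _frames_from_universe(u) -> list[StructureFrame]:
    atoms = u.atoms
    names = atoms.names.astype(object)
    try:
        resnames = atoms.resnames.astype(object)
    except Exception:
        resnames = np.full(len(atoms), "UNK", dtype=object)
    try:
        resids = atoms.resids.astype(int)
    except Exception:
        resids = np.arange(1, len(atoms) + 1)
    try:
        chains = atoms.chainIDs.astype(object)
    except AttributeError:
        try:
            chains = atoms.segids.astype(object)
        except AttributeError:
            chains = np.full(len(atoms), "", dtype=object)
    try:
        elements = atoms.elements.astype(object)
    except AttributeError:
        elements = np.array([_guess_element(n) for n in names], dtype=object)
    try:
        icodes = atoms.icodes.astype(object)
    except AttributeError:
        icodes = None
    frames = []
    for i, _ in enumerate(u.trajectory):
        frames.append(
            StructureFrame(
                names=names, resnames=resnames, resids=resids, chains=chains,
                elements=elements, xyz=atoms.positions.astype(float).copy(),
                icodes=icodes, frame_index=i,
            )
        )
    return frames


def _guess_element(name: str) -> str:
    name = str(name).strip()
    if not name:
        return ""
    if name[:2].upper() in ("NA", "CL", "MG", "ZN", "FE", "CA") and len(name) <= 2:
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _dedupe_altloc(u):
    """Keep one altloc per atom: highest occupancy, ties toward 'A'/''."""
    try:
        altlocs = u.atoms.altLocs
        occupancies = u.atoms.occupancies
    except AttributeError:
        return u.atoms
    if all(a in ("", " ") for a in altlocs):
        return u.atoms
    keep = np.ones(len(u.atoms), dtype=bool)
    import collections

    groups = collections.defaultdict(list)
    for i, a in enumerate(u.atoms):
        groups[(a.segid, a.resid, getattr(a, "icode", ""), a.resname, a.name)].append(i)
    for idxs in groups.values():
        if len(idxs) > 1:
            best = max(idxs, key=lambda i: (occupancies[i], altlocs[i] in ("A", "", " ")))
            for i in idxs:
                keep[i] = i == best
    return u.atoms[keep]


def read_pdb(path) -> list[StructureFrame]:
    """Read a single- or multi-MODEL PDB into a list of frames."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        ag = _dedupe_altloc(u)
        if len(ag) != len(u.atoms):
            u = mda.Merge(ag)
        return _frames_from_universe(u)


def read_xyz(path) -> list[StructureFrame]:
    """Read an XYZ trajectory; atoms get placeholder residue annotation."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="XYZ", topology_format="XYZ")
        return _frames_from_universe(u)


def _universe_from_frames(frames: Sequence[StructureFrame]):
    """Build an in-memory MDAnalysis Universe from frames (shared topology)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    ref = frames[0]
    for fr in frames[1:]:
        if fr.n_atoms != ref.n_atoms:
            raise ValueError("all frames must have the same atom count")

    # group consecutive atoms into residues on (chain, resid, resname, icode)
    keys = list(zip(ref.chains, ref.resids, ref.resnames,
                    ref.icodes if ref.icodes is not None else [""] * ref.n_atoms))
    atom_resindex = np.empty(ref.n_atoms, dtype=int)
    res_keys: list = []
    for i, key in enumerate(keys):
        if not res_keys or key != res_keys[-1]:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1

    u = mda.Universe.empty(
        n_atoms=ref.n_atoms, n_residues=len(res_keys),
        atom_resindex=atom_resindex, trajectory=True,
    )
    u.add_TopologyAttr("names", ref.names.astype(str))
    u.add_TopologyAttr("elements", ref.elements.astype(str))
    u.add_TopologyAttr("chainIDs", [(str(c) or "A")[0] for c in ref.chains])
    u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
    u.add_TopologyAttr("resids", [int(k[1]) for k in res_keys])
    u.add_TopologyAttr("icodes", [str(k[3]) for k in res_keys])
    u.add_TopologyAttr("occupancies", np.ones(ref.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(ref.n_atoms))
    u.load_new(np.stack([fr.xyz for fr in frames]).astype(np.float32), format=MemoryReader)
    return u


def write_pdb(frames: StructureFrame | Sequence[StructureFrame], path) -> None:
    """Write one or more frames as a (multi-MODEL) PDB file."""
    import MDAnalysis as mda

    if isinstance(frames, StructureFrame):
        frames = [frames]
    u = _universe_from_frames(frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=len(frames) > 1, n_atoms=u.atoms.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
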