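"""Structures, trajectories and named residue-range selections.

This module holds the lightweight in-memory containers the rest of the
package operates on (:class:`StructureModel`, :class:`TrajectoryEnsemble`)
together with readers/writers for the standard formats (PDB, mmCIF, DCD,
XTC, multi-model PDB) and the receptor geometry dictionary shipped with the
package (TM helix ranges, domain anchors, TM6 kink quadruplets for the FSH
and LHCG receptors).

Residue numbers are always author numbers as they appear in the file; they
are never renumbered, so residue labels such as Y303 or L460 can be used
directly.
"""

from __future__ import annotations

import dataclasses
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "StructureModel",
    "TrajectoryEnsemble",
    "SelectionSpec",
    "DomainAnchors",
    "KinkSpec",
    "ReceptorGeometry",
    "FormatError",
    "SelectionError",
    "read_structure",
    "read_trajectory",
    "resolve_selection",
    "write_pdb",
    "write_trajectory",
    "load_receptor_geometry",
    "static_ensemble",
]

#: Frame interval used when a trajectory format carries no time information.
DEFAULT_FRAME_INTERVAL_PS = 10.0

# Atomic masses (amu) for elements that occur in protein/membrane systems.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "FE": 55.845,
    "ZN": 65.38, "MN": 54.938, "CU": 63.546, "SE": 78.971,
}


class FormatError(ValueError):
    """Raised when a structure or trajectory file cannot be interpreted."""


class SelectionError(ValueError):
    """Raised when a selection resolves to no atoms on the target model."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StructureModel:
    """Atoms of a single structure: identity columns plus Angstrom coordinates.

    All fields are parallel numpy arrays of length ``n_atoms``. ``mass`` is
    in amu; atoms whose element could not be identified carry mass 0 (a
    warning is emitted at parse time).
    """

    serial: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    chain_id: np.ndarray
    xyz: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_atoms, 3)")
        n = self.xyz.shape[0]
        for field in ("serial", "atom_name", "element", "residue_number",
                      "residue_name", "chain_id", "mass"):
            arr = np.asarray(getattr(self, field))
            if arr.shape != (n,):
                raise ValueError(f"{field} must have length {n}")
            setattr(self, field, arr)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def __len__(self) -> int:
        return self.n_atoms

    def subset(self, indices: np.ndarray) -> "StructureModel":
        """New model holding only ``indices`` (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return StructureModel(
            serial=self.serial[idx], atom_name=self.atom_name[idx],
            element=self.element[idx], residue_number=self.residue_number[idx],
            residue_name=self.residue_name[idx], chain_id=self.chain_id[idx],
            xyz=self.xyz[idx], mass=self.mass[idx],
        )

    def with_coordinates(self, xyz: np.ndarray) -> "StructureModel":
        return dataclasses.replace(self, xyz=np.asarray(xyz, dtype=float))


@dataclasses.dataclass
class TrajectoryEnsemble:
    """Frames x atoms x 3 coordinate stack with per-frame times and boxes.

    ``coordinates`` are Angstrom, ``times`` picoseconds (strictly
    increasing), ``box`` per-frame orthorhombic (x, y, z) edge lengths in
    Angstrom or ``None``. ``atom_table`` refers to the topology
    :class:`StructureModel`; its atom order defines the coordinate columns.
    """

    coordinates: np.ndarray
    times: np.ndarray
    atom_table: StructureModel
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.atom_table.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology atom count {self.atom_table.n_atoms}")
        if self.times.shape != (self.coordinates.shape[0],):
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates in trajectory")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def slice_frames(self, frame_indices: Sequence[int]) -> "TrajectoryEnsemble":
        idx = np.asarray(frame_indices, dtype=int)
        return TrajectoryEnsemble(
            coordinates=self.coordinates[idx],
            times=self.times[idx],
            atom_table=self.atom_table,
            box=None if self.box is None else self.box[idx],
        )


def static_ensemble(model: StructureModel) -> TrajectoryEnsemble:
    """Wrap a static structure as a single-frame trajectory."""
    return TrajectoryEnsemble(
        coordinates=model.xyz[None, :, :],
        times=np.array([0.0]),
        atom_table=model,
    )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SelectionSpec:
    """Named residue-range selection (inclusive ranges, author numbering)."""

    name: str
    residue_ranges: tuple[tuple[int, int], ...]
    chain_id: str | None = None
    atom_names: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_ranges",
                           tuple((int(a), int(b)) for a, b in self.residue_ranges))
        object.__setattr__(self, "atom_names", tuple(self.atom_names))
        for start, end in self.residue_ranges:
            if start > end:
                raise ValueError(f"range start {start} > end {end} in {self.name!r}")


@dataclasses.dataclass(frozen=True)
class DomainAnchors:
    """One anchor residue per domain (LRR, hinge region, TM bundle).

    Each anchor is ``(chain_id or None, residue_number, atom_name)`` and must
    resolve to exactly one atom. ``tm_hr_anchor`` optionally names a second
    TM anchor used for the TM-HR distance when it differs from the one used
    for LRR-TM (the LHCG receptor table prints I431 and L452 respectively).
    """

    lrr_anchor: tuple[str | None, int, str]
    hr_anchor: tuple[str | None, int, str]
    tm_anchor: tuple[str | None, int, str]
    tm_hr_anchor: tuple[str | None, int, str] | None = None

    def __post_init__(self) -> None:
        residues = {(a[0], a[1]) for a in (self.lrr_anchor, self.hr_anchor, self.tm_anchor)}
        if len(residues) != 3:
            raise ValueError("domain anchors must be three distinct residues")
        if self.tm_hr_anchor is not None and self.tm_hr_anchor != self.tm_anchor:
            warnings.warn(
                "TM anchor for the TM-HR distance differs from the LRR-TM one "
                f"({self.tm_hr_anchor[1]} vs {self.tm_anchor[1]}); both are used "
                "as configured", stacklevel=2)


@dataclasses.dataclass(frozen=True)
class KinkSpec:
    """Four-Calpha definition of a helix kink angle.

    ``upper_pair`` and ``lower_pair`` each hold two ``(chain_id, residue)``
    entries; the axis vectors run from the second member of each pair to the
    first, both pointing up the helix, so an unbent helix reads ~0 deg.
    ``reference_angle`` is the angle in the experimental structure, in
    degrees, against which relative kinks are reported.
    """

    upper_pair: tuple[tuple[str | None, int], tuple[str | None, int]]
    lower_pair: tuple[tuple[str | None, int], tuple[str | None, int]]
    reference_angle: float = 0.0

    def __post_init__(self) -> None:
        residues = {*self.upper_pair, *self.lower_pair}
        if len(residues) != 4:
            raise ValueError("kink quadruplet must name four distinct residues")
        if not 0.0 <= self.reference_angle < 180.0:
            raise ValueError("reference angle must lie in [0, 180)")


def resolve_selection(model: StructureModel, spec: SelectionSpec) -> np.ndarray:
    """Resolve ``spec`` against ``model`` to an ordered, de-duplicated index list.

    Indices are ordered by (residue_number, atom_name) and the result is
    deterministic for identical inputs. Raises :class:`SelectionError`
    listing the residue ranges that resolved to nothing.
    """
    name_mask = np.isin(model.atom_name, spec.atom_names)
    if spec.chain_id is not None:
        name_mask &= model.chain_id == spec.chain_id
    mask = np.zeros(model.n_atoms, dtype=bool)
    missing = []
    for start, end in spec.residue_ranges:
        rng = name_mask & (model.residue_number >= start) & (model.residue_number <= end)
        if not rng.any():
            missing.append((start, end))
        mask |= rng
    if missing:
        raise SelectionError(
            f"selection {spec.name!r}: residue ranges {missing} resolve to no "
            f"{'/'.join(spec.atom_names)} atoms"
            + (f" on chain {spec.chain_id}" if spec.chain_id else ""))
    idx = np.nonzero(mask)[0]
    order = np.lexsort((model.atom_name[idx], model.residue_number[idx]))
    return idx[order]


def resolve_anchor(model: StructureModel,
                   anchor: tuple[str | None, int, str]) -> int:
    """Resolve a single-atom anchor ``(chain, residue, atom_name)``."""
    chain, resid, atom = anchor
    mask = (model.residue_number == resid) & (model.atom_name == atom)
    if chain is not None:
        mask &= model.chain_id == chain
    idx = np.nonzero(mask)[0]
    if idx.size != 1:
        raise SelectionError(
            f"anchor {atom} of residue {resid}"
            + (f" chain {chain}" if chain else "")
            + f" resolves to {idx.size} atoms (need exactly 1)")
    return int(idx[0])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    """PDB-style element guess: first alphabetic character of the atom name.

    Correct for organic/protein atoms (CA -> C); two-letter ions must carry
    an explicit element column to be recognised.
    """
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _masses_for(elements: np.ndarray) -> np.ndarray:
    masses = np.zeros(len(elements))
    unknown = set()
    for i, el in enumerate(elements):
        m = ELEMENT_MASSES.get(str(el).upper())
        if m is None:
            unknown.add(str(el))
        else:
            masses[i] = m
    if unknown:
        warnings.warn(f"unknown element(s) {sorted(unknown)}: mass set to 0",
                      stacklevel=3)
    return masses


def _dedupe_altlocs(records: list[tuple], occupancies: np.ndarray) -> list[int]:
    """Keep only the highest-occupancy record per (chain, resid, name)."""
    best: dict[tuple, int] = {}
    for i, key in enumerate(records):
        j = best.get(key)
        if j is None or occupancies[i] > occupancies[j]:
            best[key] = i
    return sorted(best.values())


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    return {"cif": "mmcif", "mmcif": "mmcif", "pdb": "pdb", "ent": "pdb",
            "dcd": "dcd", "xtc": "xtc"}.get(suffix, suffix)


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ATOM and HETATM records are both kept; author residue numbering is
    preserved; element-derived masses are assigned (mass 0 + warning for
    unknown elements). For altloc duplicates only the highest-occupancy
    record is retained.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mmcif":
        return _read_mmcif(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise FormatError(f"unsupported structure format {fmt!r}")


def _read_pdb(path: Path) -> StructureModel:
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - reported as a format error
        raise FormatError(f"could not parse {path} as PDB: {exc}") from exc
    atoms = u.atoms
    names = atoms.names.astype(str)
    if hasattr(atoms, "elements") and any(atoms.elements):
        elements = np.array([el if el else _element_from_name(nm)
                             for el, nm in zip(atoms.elements, names)])
    else:
        elements = np.array([_element_from_name(nm) for nm in names])
    elements = np.char.upper(elements.astype(str))
    chain = (atoms.chainIDs.astype(str) if hasattr(atoms, "chainIDs")
             else atoms.segids.astype(str))
    occ = (np.asarray(atoms.occupancies, dtype=float)
           if hasattr(atoms, "occupancies") else np.ones(len(atoms)))
    altloc = (atoms.altLocs.astype(str) if hasattr(atoms, "altLocs")
              else np.full(len(atoms), ""))
    keys = list(zip(chain, atoms.resids, names))
    keep = (_dedupe_altlocs(keys, occ) if any(a.strip() for a in altloc)
            else list(range(len(atoms))))
    keep = np.asarray(keep, dtype=int)
    return StructureModel(
        serial=np.asarray(atoms.ids, dtype=int)[keep],
        atom_name=names[keep],
        element=elements[keep],
        residue_number=np.asarray(atoms.resids, dtype=int)[keep],
        residue_name=atoms.resnames.astype(str)[keep],
        chain_id=chain[keep],
        xyz=np.asarray(atoms.positions, dtype=float)[keep],
        mass=_masses_for(elements[keep]),
    )


def _read_mmcif(path: Path) -> StructureModel:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse {path} as mmCIF: {exc}") from exc
    st.setup_entities()
    model = st[0]
    rows = []
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append((atom.serial, atom.name, atom.element.name.upper(),
                             res.seqid.num, res.name, chain.name,
                             (atom.pos.x, atom.pos.y, atom.pos.z),
                             atom.element.weight, atom.occ))
    if not rows:
        raise FormatError(f"no atoms found in {path}")
    occ = np.array([r[8] for r in rows])
    keys = [(r[5], r[3], r[1]) for r in rows]
    keep = _dedupe_altlocs(keys, occ)
    rows = [rows[i] for i in keep]
    return StructureModel(
        serial=np.array([r[0] for r in rows], dtype=int),
        atom_name=np.array([r[1] for r in rows]),
        element=np.array([r[2] for r in rows]),
        residue_number=np.array([r[3] for r in rows], dtype=int),
        residue_name=np.array([r[4] for r in rows]),
        chain_id=np.array([r[5] for r in rows]),
        xyz=np.array([r[6] for r in rows], dtype=float),
        mass=np.array([r[7] for r in rows], dtype=float),
    )


def read_trajectory(topology: StructureModel, path: str | Path,
                    fmt: str | None = None, stride: int = 1,
                    frame_interval_ps: float = DEFAULT_FRAME_INTERVAL_PS,
                    use_file_times: bool | None = None) -> TrajectoryEnsemble:
    """Read a DCD/XTC/multi-model-PDB trajectory against ``topology``.

    Frame times come from the file when the format records them (XTC) and
    ``use_file_times`` is not False; otherwise each frame is assigned
    ``original_frame_index * frame_interval_ps`` (default 10 ps, the
    trajectory storage interval of the study this package reproduces).
    Atom-count mismatches raise a hard error naming both counts.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.core import get_reader_for

    path = Path(path)
    fmt = _infer_format(path, fmt)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    mda_fmt = {"multi-pdb": "pdb"}.get(fmt, fmt)
    try:
        Reader = get_reader_for(str(path), format=mda_fmt.upper())
        reader = Reader(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not open {path} as {fmt}: {exc}") from exc
    if reader.n_atoms != topology.n_atoms:
        raise ValueError(
            f"trajectory {path} has {reader.n_atoms} atoms but the topology "
            f"has {topology.n_atoms}")
    if use_file_times is None:
        use_file_times = fmt == "xtc"
    coords, times, boxes = [], [], []
    for k, ts in enumerate(reader):
        if k % stride:
            continue
        coords.append(ts.positions.astype(float).copy())
        times.append(float(ts.time) if use_file_times else k * frame_interval_ps)
        dims = ts.dimensions
        boxes.append(None if dims is None or not np.any(dims[:3])
                     else np.asarray(dims[:3], dtype=float))
    reader.close()
    box = (np.stack(boxes) if boxes and all(b is not None for b in boxes)
           else None)
    times = np.asarray(times)
    if use_file_times and times.size > 1 and not np.all(np.diff(times) > 0):
        # degenerate or missing time stamps: fall back to the frame interval
        times = np.arange(0, len(times)) * stride * frame_interval_ps
    return TrajectoryEnsemble(coordinates=np.stack(coords),
                              times=times, atom_table=topology,
                              box=box)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _to_universe(model: StructureModel, n_frames: int = 1):
    import MDAnalysis as mda

    res_keys = list(zip(model.chain_id, model.residue_number))
    resindex = np.empty(model.n_atoms, dtype=int)
    seen: dict[tuple, int] = {}
    res_order = []
    for i, key in enumerate(res_keys):
        if key not in seen:
            seen[key] = len(seen)
            res_order.append(i)
        resindex[i] = seen[key]
    n_res = len(seen)
    u = mda.Universe.empty(model.n_atoms, n_residues=n_res,
                           atom_resindex=resindex,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", model.atom_name.astype(str))
    u.add_TopologyAttr("elements", model.element.astype(str))
    u.add_TopologyAttr("resids", model.residue_number[res_order])
    u.add_TopologyAttr("resnames", model.residue_name[res_order].astype(str))
    u.add_TopologyAttr("chainIDs", model.chain_id.astype(str))
    u.add_TopologyAttr("occupancies", np.ones(model.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(model.n_atoms))
    return u


def write_pdb(model: StructureModel, path: str | Path,
              coordinates: np.ndarray | None = None) -> None:
    """Write ``model`` as a PDB file; ``coordinates`` of shape (frames, n, 3)
    produce a multi-model PDB."""
    import MDAnalysis as mda

    u = _to_universe(model)
    frames = (model.xyz[None] if coordinates is None
              else np.asarray(coordinates, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=model.n_atoms, multiframe=len(frames) > 1) as w:
            for frame in frames:
                u.atoms.positions = frame
                w.write(u.atoms)


def write_trajectory(ensemble: TrajectoryEnsemble, path: str | Path,
                     fmt: str | None = None) -> None:
    """Write an ensemble as DCD, XTC or multi-model PDB."""
    import MDAnalysis as mda

    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt in ("pdb", "multi-pdb"):
        write_pdb(ensemble.atom_table, path, ensemble.coordinates)
        return
    u = _to_universe(ensemble.atom_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=ensemble.n_atoms) as w:
            for i in range(ensemble.n_frames):
                u.atoms.positions = ensemble.coordinates[i]
                u.trajectory.ts.frame = i
                u.trajectory.ts.time = float(ensemble.times[i])
                if ensemble.box is not None:
                    u.dimensions = [*ensemble.box[i], 90.0, 90.0, 90.0]
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# receptor geometry dictionary
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ReceptorGeometry:
    """Per-receptor analysis geometry: TM selection, anchors, kink spec."""

    name: str
    chain: str | None
    helices: dict[str, tuple[int, int]]
    tm_selection: SelectionSpec
    anchors: DomainAnchors
    kink: KinkSpec

    def helix_selection(self, helix: str) -> SelectionSpec:
        return SelectionSpec(name=f"{self.name}_{helix}",
                             residue_ranges=(self.helices[helix],),
                             chain_id=self.chain)


def load_receptor_geometry(name: str,
                           config_path: str | Path | None = None) -> ReceptorGeometry:
    """Load a receptor's geometry ('fshr' or 'lhcgr', or from a user YAML)."""
    if config_path is None:
        text = resources.files("confland.data").joinpath("receptors.yaml").read_text()
    else:
        text = Path(config_path).read_text()
    table = yaml.safe_load(text)
    key = name.lower()
    if key not in table:
        raise KeyError(f"unknown receptor {name!r}; known: {sorted(table)}")
    entry = table[key]
    chain = entry.get("chain")
    helices = {h: tuple(r) for h, r in entry["tm_helices"].items()}
    tm_sel = SelectionSpec(name=f"{key}_tm",
                           residue_ranges=tuple(helices[h] for h in sorted(helices)),
                           chain_id=chain)
    a = entry["anchors"]
    anchors = DomainAnchors(
        lrr_anchor=(chain, int(a["lrr"]), "CA"),
        hr_anchor=(chain, int(a["hr"]), "CA"),
        tm_anchor=(chain, int(a["tm"]), "CA"),
        tm_hr_anchor=(chain, int(a["tm_hr"]), "CA") if "tm_hr" in a else None,
    )
    k = entry["kink"]
    kink = KinkSpec(
        upper_pair=((chain, int(k["upper_pair"][0])), (chain, int(k["upper_pair"][1]))),
        lower_pair=((chain, int(k["lower_pair"][0])), (chain, int(k["lower_pair"][1]))),
        reference_angle=float(k["reference_angle_deg"]),
    )
    return ReceptorGeometry(name=key, chain=chain, helices=helices,
                            tm_selection=tm_sel, anchors=anchors, kink=kink)
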