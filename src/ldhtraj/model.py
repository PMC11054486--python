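"""Data model for slab trajectories: atoms, topologies, frames, and file I/O.

Coordinates are in Å, times in fs, boxes are orthorhombic edge lengths in Å.
Atom order is stable: index ``i`` refers to the same atom in every frame and
in every operation of the package.

Trajectory files carry coordinates only; charges, molecule membership and
atom roles live in a separate :class:`Topology`, serialized as a small YAML
document (XYZ and DCD carry neither charges nor roles).
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "ROLES",
    "ATOMIC_MASSES",
    "Atom",
    "AnionRecord",
    "Topology",
    "Frame",
    "Trajectory",
    "SlabGeometry",
    "FormatError",
    "GeometryError",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
    "detect_slab_geometry",
]

#: Recognized atom roles. ``layer_*`` roles belong to the inorganic sheets;
#: the rest live in the interlayer galleries.
ROLES = frozenset(
    {
        "carboxylate_C",
        "carboxylate_O",
        "amino_N",
        "water_O",
        "water_H",
        "layer_Mg",
        "layer_Al",
        "layer_OH_O",
        "layer_OH_H",
        "other",
    }
)

#: Standard atomic masses (u) for the elements this package handles.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Mg": 24.305,
    "Al": 26.982,
}


class FormatError(ValueError):
    """Raised when a trajectory or topology file violates its format."""


class GeometryError(ValueError):
    """Raised when slab geometry cannot be established."""


@dataclass(frozen=True)
class Atom:
    """One atom: element, fixed partial charge (e), molecule id and role."""

    element: str
    partial_charge: float
    molecule_id: int
    role: str = "other"

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")
        if self.molecule_id < 0:
            raise ValueError("molecule_id must be >= 0")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES[self.element]


@dataclass(frozen=True)
class AnionRecord:
    """Named atom indices of one intercalated anion.

    ``carboxylate_carbons`` are the two carbons whose connecting vector
    defines the orientation angle θ against the surface normal;
    ``dihedral`` is the four-atom quadruple defining the classifying torsion
    χ (C-C-C-C for succinate, C-Cα-Cβ-Cγ for the amino acids);
    ``amino_n`` is the amino nitrogen (absent for succinate).
    """

    molecule_id: int
    carboxylate_carbons: tuple[int, int]
    dihedral: tuple[int, int, int, int]
    amino_n: Optional[int] = None

    def __post_init__(self) -> None:
        idx = list(self.carboxylate_carbons) + list(self.dihedral)
        if self.amino_n is not None:
            idx.append(self.amino_n)
        if len(self.carboxylate_carbons) != 2 or len(self.dihedral) != 4:
            raise ValueError("need 2 carboxylate carbons and a 4-atom dihedral")
        if len(set(self.carboxylate_carbons)) != 2 or len(set(self.dihedral)) != 4:
            raise ValueError("record indices must be mutually distinct")
        if any(i < 0 for i in idx):
            raise ValueError("indices must be non-negative")


ANION_TYPES = ("ASP", "GLU", "SUC")


@dataclass
class Topology:
    """Static description of every atom plus per-anion named indices."""

    atoms: list[Atom]
    anion_records: list[AnionRecord] = field(default_factory=list)
    anion_type: Optional[str] = None
    n_layers: Optional[int] = None  # metadata used by detect_slab_geometry

    def __post_init__(self) -> None:
        if self.anion_type is not None and self.anion_type not in ANION_TYPES:
            raise ValueError(f"anion_type must be one of {ANION_TYPES}")
        n = len(self.atoms)
        for rec in self.anion_records:
            idx = list(rec.carboxylate_carbons) + list(rec.dihedral)
            if rec.amino_n is not None:
                idx.append(rec.amino_n)
            if any(i >= n for i in idx):
                raise ValueError(f"anion record for molecule {rec.molecule_id} indexes out of range")
            if self.anion_type == "SUC" and rec.amino_n is not None:
                raise ValueError("SUC records must not carry an amino N")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def indices_by_role(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return np.array([i for i, a in enumerate(self.atoms) if a.role == role], dtype=int)

    def molecule_indices(self, molecule_id: int) -> np.ndarray:
        idx = np.array(
            [i for i, a in enumerate(self.atoms) if a.molecule_id == molecule_id], dtype=int
        )
        if idx.size == 0:
            raise KeyError(f"no atoms with molecule_id {molecule_id}")
        return idx

    def validate_anion_charges(self, expected: float = -2.0, tol: float = 1e-6) -> None:
        """Check that every anion's partial charges sum to ``expected``."""
        for rec in self.anion_records:
            q = sum(
                a.partial_charge for a in self.atoms if a.molecule_id == rec.molecule_id
            )
            if abs(q - expected) > tol:
                raise ValueError(
                    f"anion molecule {rec.molecule_id} net charge {q:.6f} != {expected}"
                )


@dataclass
class Frame:
    """Coordinates (Å) of every atom at one instant, with box and time."""

    coordinates: np.ndarray  # (n_atoms, 3), Å
    box: np.ndarray  # (3,) orthorhombic edges, Å
    time: float = 0.0  # fs
    velocities: Optional[np.ndarray] = None  # (n_atoms, 3), Å/fs

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive edge lengths")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise ValueError("velocities must match coordinates shape")


@dataclass
class Trajectory:
    """An ordered sequence of frames over one topology, saved every ``dt`` fs."""

    topology: Topology
    frames: list[Frame]
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = self.topology.n_atoms
        for i, fr in enumerate(self.frames):
            if fr.coordinates.shape[0] != n:
                raise FormatError(
                    f"frame {i} has {fr.coordinates.shape[0]} atoms, topology has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def coordinate_array(self) -> np.ndarray:
        """Stack coordinates into an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])

    def velocity_array(self) -> Optional[np.ndarray]:
        if any(f.velocities is None for f in self.frames):
            return None
        return np.stack([f.velocities for f in self.frames])


@dataclass
class SlabGeometry:
    """Positions of the inorganic sheets and the interlayer galleries."""

    layer_z_centers: np.ndarray  # Å, sorted ascending
    interlayer_bounds: list[tuple[float, float]]  # (z_lo, z_hi) pairs, Å
    spacing_d: float  # Å, mean adjacent-layer separation

    def __post_init__(self) -> None:
        self.layer_z_centers = np.asarray(self.layer_z_centers, dtype=float)
        if np.any(np.diff(self.layer_z_centers) <= 0):
            raise GeometryError("layer centers must be strictly increasing")
        if self.spacing_d <= 0:
            raise GeometryError("spacing_d must be > 0")

    @property
    def n_layers(self) -> int:
        return int(self.layer_z_centers.size)

    def midplanes(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.interlayer_bounds])


# ---------------------------------------------------------------------------
# Topology serialization (YAML)
# ---------------------------------------------------------------------------

def write_topology(top: Topology, path: str | Path) -> None:
    """Write a topology as a YAML document (documented key-value format)."""
    doc = {
        "anion_type": top.anion_type,
        "n_layers": top.n_layers,
        "atoms": [
            {
                "element": a.element,
                "charge": float(a.partial_charge),
                "molecule_id": int(a.molecule_id),
                "role": a.role,
            }
            for a in top.atoms
        ],
        "anion_records": [
            {
                "molecule_id": int(r.molecule_id),
                "carboxylate_carbons": [int(i) for i in r.carboxylate_carbons],
                "dihedral": [int(i) for i in r.dihedral],
                "amino_n": None if r.amino_n is None else int(r.amino_n),
            }
            for r in top.anion_records
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_topology(path: str | Path) -> Topology:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        atoms = [
            Atom(d["element"], float(d["charge"]), int(d["molecule_id"]), d.get("role", "other"))
            for d in doc["atoms"]
        ]
        records = [
            AnionRecord(
                molecule_id=int(d["molecule_id"]),
                carboxylate_carbons=tuple(d["carboxylate_carbons"]),
                dihedral=tuple(d["dihedral"]),
                amino_n=d.get("amino_n"),
            )
            for d in doc.get("anion_records", [])
        ]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed topology file {path}: {exc}") from exc
    return Topology(
        atoms=atoms,
        anion_records=records,
        anion_type=doc.get("anion_type"),
        n_layers=doc.get("n_layers"),
    )


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

_FORMATS = ("XYZ", "PDB", "DCD")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        f = fmt.upper()
        if f not in _FORMATS:
            raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return f
    suffix = path.suffix.lstrip(".").upper()
    if suffix in _FORMATS:
        return suffix
    raise FormatError(f"cannot infer format from suffix of {path}")


def read_trajectory(
    path: str | Path,
    topology: Topology,
    format: Optional[str] = None,
    dt: Optional[float] = None,
) -> Trajectory:
    """Read a trajectory from XYZ, PDB or DCD.

    XYZ comment lines of the form ``box: Lx Ly Lz time: t`` supply box and
    time per frame; for PDB the CRYST1 record supplies the box; for DCD the
    unit cell is taken from the file. ``dt`` overrides (or supplies, when the
    file carries no time information) the frame interval in fs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "XYZ":
        frames = _read_xyz(path, topology.n_atoms)
    else:
        frames = _read_with_mdanalysis(path, fmt, topology.n_atoms)
    if not frames:
        raise FormatError(f"{path} contains no frames")
    if dt is None:
        times = [f.time for f in frames]
        dt = times[1] - times[0] if len(times) >= 2 and times[1] > times[0] else 1.0
    return Trajectory(topology=topology, frames=frames, dt=dt)


def write_trajectory(traj: Trajectory, path: str | Path, format: Optional[str] = None) -> None:
    """Write a trajectory to XYZ, PDB or DCD; re-readable by read_trajectory."""
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "XYZ":
        _write_xyz(traj, path)
    else:
        _write_with_mdanalysis(traj, path, fmt)


def _read_xyz(path: Path, n_atoms_expected: int) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"frame {frame_no}: bad atom-count line {lines[i]!r}") from exc
        if n != n_atoms_expected:
            raise FormatError(
                f"frame {frame_no}: file declares {n} atoms, topology has {n_atoms_expected}"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box, time = _parse_xyz_comment(comment, frame_no)
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise FormatError(f"frame {frame_no}: truncated (expected {n} atom lines)")
        coords = np.empty((n, 3))
        for j, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise FormatError(f"frame {frame_no}: unparsable atom line {ln!r}")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(coordinates=coords, box=box, time=time))
        i += 2 + n
        frame_no += 1
    return frames


def _parse_xyz_comment(comment: str, frame_no: int) -> tuple[np.ndarray, float]:
    toks = comment.split()
    box = np.array([1.0, 1.0, 1.0])
    time = float(frame_no)
    if "box:" in toks:
        k = toks.index("box:")
        try:
            box = np.array([float(toks[k + 1]), float(toks[k + 2]), float(toks[k + 3])])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"frame {frame_no}: bad box in comment {comment!r}") from exc
    if "time:" in toks:
        k = toks.index("time:")
        try:
            time = float(toks[k + 1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"frame {frame_no}: bad time in comment {comment!r}") from exc
    return box, time


def _write_xyz(traj: Trajectory, path: Path) -> None:
    elements = traj.topology.elements
    with open(path, "w") as fh:
        for fr in traj.frames:
            fh.write(f"{traj.n_atoms}\n")
            bx = fr.box
            fh.write(f"box: {bx[0]:.6f} {bx[1]:.6f} {bx[2]:.6f} time: {fr.time:.6f}\n")
            for el, (x, y, z) in zip(elements, fr.coordinates):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def _read_with_mdanalysis(path: Path, fmt: str, n_atoms_expected: int) -> list[Frame]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "PDB":
            u = mda.Universe(str(path))
        else:  # DCD needs an atom count, not a topology file
            u = mda.Universe.empty(n_atoms_expected, trajectory=True)
            u.load_new(str(path))
        if len(u.atoms) != n_atoms_expected:
            raise FormatError(
                f"{path}: file has {len(u.atoms)} atoms, topology has {n_atoms_expected}"
            )
        frames = []
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                box = np.array([1.0, 1.0, 1.0])
            else:
                box = np.array(dims[:3], dtype=float)
            frames.append(
                Frame(
                    coordinates=np.array(ts.positions, dtype=float),
                    box=box,
                    time=float(ts.time),
                )
            )
    return frames


def _write_with_mdanalysis(traj: Trajectory, path: Path, fmt: str) -> None:
    import MDAnalysis as mda

    n = traj.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=1, atom_resindex=np.zeros(n, dtype=int),
                               trajectory=True)
        u.add_TopologyAttr("names", [a.element for a in traj.topology.atoms])
        u.add_TopologyAttr("elements", [a.element for a in traj.topology.atoms])
        with mda.Writer(str(path), n_atoms=n) as w:
            for fr in traj.frames:
                u.atoms.positions = fr.coordinates
                u.dimensions = [fr.box[0], fr.box[1], fr.box[2], 90.0, 90.0, 90.0]
                u.trajectory.ts.time = fr.time
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Slab geometry detection
# ---------------------------------------------------------------------------

def _kmeans_1d(values: np.ndarray, k: int, n_iter: int = 50) -> np.ndarray:
    """Deterministic 1-D k-means: gap-split initialisation + Lloyd updates.

    Initial centers come from splitting the sorted values at the k-1 largest
    gaps (ties broken by sorted z), which for well-separated sheets is
    already the fixed point.
    """
    v = np.sort(values)
    if k == 1:
        return np.array([v.mean()])
    gaps = np.diff(v)
    # k-1 largest gaps; stable order so equal gaps break by position (sorted z)
    split_at = np.sort(np.argsort(-gaps, kind="stable")[: k - 1])
    groups = np.split(v, split_at + 1)
    centers = np.array([g.mean() for g in groups])
    for _ in range(n_iter):
        labels = np.argmin(np.abs(v[:, None] - centers[None, :]), axis=1)
        new = np.array([v[labels == j].mean() if np.any(labels == j) else centers[j]
                        for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    return np.sort(centers)


def detect_slab_geometry(traj: Trajectory, n_layers: Optional[int] = None) -> SlabGeometry:
    """Locate the inorganic sheets from the Mg z-coordinates.

    Layer centers are the 1-D k-means cluster means of Mg z averaged over
    frames; ``spacing_d`` is the mean difference of adjacent centers;
    interlayer bounds span between adjacent centers, plus the periodic
    gallery above the top sheet (wrapping to the bottom sheet through the
    box) when the box accommodates it.
    """
    mg = traj.topology.indices_by_role("layer_Mg")
    if mg.size == 0:
        raise GeometryError("topology contains no layer_Mg atoms")
    k = n_layers if n_layers is not None else traj.topology.n_layers
    zs = np.concatenate([fr.coordinates[mg, 2] for fr in traj.frames])
    if k is None:
        # estimate layer count from gaps larger than 3 Å in the pooled z values
        v = np.sort(np.unique(np.round(zs, 6)))
        k = 1 + int(np.sum(np.diff(v) > 3.0))
    if k < 2:
        raise GeometryError("need at least 2 layers to define an interlayer")
    centers = _kmeans_1d(zs, k)
    if np.any(np.diff(centers) <= 0.5):
        raise GeometryError("Mg z-clusters are not distinct layers")
    spacing = float(np.mean(np.diff(centers)))
    bounds = [(float(centers[i]), float(centers[i + 1])) for i in range(k - 1)]
    # periodic gallery above the top sheet if the box spans beyond it
    lz = float(np.median([fr.box[2] for fr in traj.frames]))
    if centers[-1] + spacing <= lz + 1e-6:
        bounds.append((float(centers[-1]), float(centers[-1] + spacing)))
    return SlabGeometry(layer_z_centers=centers, interlayer_bounds=bounds, spacing_d=spacing)
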