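"""Geometric descriptors of the interlayer galleries.

Implements the structural analyses used to characterize confined
carboxylate anions:

* the orientation angle θ between the vector joining an anion's two
  carboxylate carbons and the surface normal (z), folded to [0°, 90°];
  anions with θ strictly above a threshold (default 80.0°) count as
  *parallel* to the sheets, the rest as intermediate/perpendicular;
* the classifying torsion χ (C-C-C-C for succinate, C-Cα-Cβ-Cγ for the
  amino acids) with conformer windows centred on the known wells:
  anti for |χ| > 120°, gauche+ for 0° < χ ≤ 120°, gauche− for
  −120° ≤ χ ≤ 0°;
* number-density profiles along z, folded per interlayer around the
  gallery midplane and pooled over galleries and frames;
* radial distribution functions under the minimum-image convention,
  normalized with the full-box ideal-gas expectation and read only out to
  the size of one gallery (default 5 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import AnionRecord, Frame, GeometryError, SlabGeometry, Trajectory

__all__ = [
    "OrientationResult",
    "ConformerResult",
    "DensityProfile",
    "RDFResult",
    "orientation_angle",
    "classify_orientation",
    "orientation_populations",
    "dihedral_angle",
    "conformer_fractions",
    "number_density_z",
    "rdf",
]

PARALLEL_THRESHOLD = 80.0  # degrees; strict inequality
CONFORMER_BOUNDARY = 120.0  # degrees


@dataclass
class OrientationResult:
    per_sample_theta: np.ndarray  # (n_frames, n_anions), degrees in [0, 90]
    threshold: float = PARALLEL_THRESHOLD

    @property
    def parallel_fraction(self) -> float:
        """Percent of (frame, anion) samples with θ strictly above threshold."""
        return 100.0 * float(np.mean(self.per_sample_theta > self.threshold))


@dataclass
class ConformerResult:
    per_sample_chi: np.ndarray  # (n_frames, n_anions), degrees in (-180, 180]
    bin_edges: np.ndarray  # histogram edges over (-180, 180]
    counts: np.ndarray

    @property
    def fractions(self) -> dict[str, float]:
        """Conformer populations in percent; sums to 100."""
        chi = self.per_sample_chi.ravel()
        n = chi.size
        anti = np.abs(chi) > CONFORMER_BOUNDARY
        gp = (chi > 0) & (chi <= CONFORMER_BOUNDARY)
        gm = ~anti & ~gp
        return {
            "anti": 100.0 * anti.sum() / n,
            "gauche_plus": 100.0 * gp.sum() / n,
            "gauche_minus": 100.0 * gm.sum() / n,
        }


@dataclass
class DensityProfile:
    z_centers: np.ndarray  # Å, relative to the gallery midplane
    density: np.ndarray  # counts per Å per frame, pooled over galleries
    role: str
    bin_width: float
    n_frames: int
    mirrored: bool = True

    def integral(self) -> float:
        """∫ density dz; times n_frames this equals the observation count."""
        return float(np.sum(self.density) * self.bin_width)


@dataclass
class RDFResult:
    r_centers: np.ndarray  # Å
    g: np.ndarray  # dimensionless, >= 0
    pair: tuple[str, str]
    r_max: float
    counts: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def _theta_from_vectors(v: np.ndarray) -> np.ndarray:
    """θ = arccos(|v_z| / |v|) in degrees; v may be (..., 3)."""
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm < 1e-10):
        raise GeometryError("coincident carboxylate carbons (zero θ vector)")
    cos = np.abs(v[..., 2]) / norm
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def orientation_angle(frame: Frame, record: AnionRecord) -> float:
    """Orientation angle θ (degrees) of one anion in one frame.

    θ is the angle between the carboxylate-carbon vector and the surface
    normal, folded to [0°, 90°] via |v_z| so the carbon order is irrelevant.
    """
    i, j = record.carboxylate_carbons
    v = frame.coordinates[i] - frame.coordinates[j]
    return float(_theta_from_vectors(v))


def classify_orientation(theta: float, threshold: float = PARALLEL_THRESHOLD) -> str:
    """'parallel' iff θ > threshold (strict); else 'intermediate_perpendicular'."""
    if not (0.0 <= theta <= 90.0):
        raise ValueError(f"theta {theta} outside [0, 90] degrees")
    return "parallel" if theta > threshold else "intermediate_perpendicular"


def orientation_populations(
    traj: Trajectory, threshold: float = PARALLEL_THRESHOLD
) -> OrientationResult:
    """θ for every (frame, anion) sample and the parallel population.

    The population is the fraction over all frame × anion samples, in
    percent.
    """
    records = traj.topology.anion_records
    if not records:
        raise ValueError("topology has no anion records")
    coords = traj.coordinate_array()
    i1 = np.array([r.carboxylate_carbons[0] for r in records])
    i2 = np.array([r.carboxylate_carbons[1] for r in records])
    v = coords[:, i1, :] - coords[:, i2, :]
    theta = _theta_from_vectors(v)
    return OrientationResult(per_sample_theta=theta, threshold=threshold)


# ---------------------------------------------------------------------------
# Dihedrals / conformers
# ---------------------------------------------------------------------------

def _torsion_array(p0, p1, p2, p3) -> np.ndarray:
    """Signed IUPAC torsion (degrees, (-180, 180]) for (..., 3) arrays."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    if np.any(norm1 < 1e-10) or np.any(norm2 < 1e-10):
        raise GeometryError("collinear atoms in dihedral quadruple")
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m = np.cross(n1, b1u)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m, n2)
    ang = np.degrees(np.arctan2(-y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def dihedral_angle(frame: Frame, quadruple: Sequence[int]) -> float:
    """Signed IUPAC torsion of four atoms, degrees in (−180, 180]."""
    i, j, k, l = quadruple
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral atoms must be distinct")
    c = frame.coordinates
    return float(_torsion_array(c[i], c[j], c[k], c[l]))


def conformer_fractions(traj: Trajectory, bin_width: float = 5.0) -> ConformerResult:
    """χ for every (frame, anion) sample, histogram, and conformer percents."""
    records = traj.topology.anion_records
    if not records:
        raise ValueError("topology has no anion records")
    coords = traj.coordinate_array()
    quads = np.array([r.dihedral for r in records])  # (n_anions, 4)
    chi = _torsion_array(
        coords[:, quads[:, 0], :],
        coords[:, quads[:, 1], :],
        coords[:, quads[:, 2], :],
        coords[:, quads[:, 3], :],
    )
    edges = np.arange(-180.0, 180.0 + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(chi.ravel(), bins=edges)
    return ConformerResult(per_sample_chi=chi, bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# Density profiles along z
# ---------------------------------------------------------------------------

def number_density_z(
    traj: Trajectory,
    role: str,
    geometry: SlabGeometry,
    bin_width: float = 0.1,
    mirror: bool = True,
) -> DensityProfile:
    """Number density of a species along z, folded around gallery midplanes.

    Each selected atom is assigned to its enclosing interlayer (z wrapped
    into the periodic stack), re-expressed relative to that gallery's
    midplane, and pooled over galleries and frames. Density is in counts
    per Å per frame, so ``integral() * n_frames`` equals the number of
    assigned observations. With ``mirror`` the profile is symmetrized
    across the midplane (slab symmetry); the integral is unchanged.
    """
    idx = traj.topology.indices_by_role(role)
    if idx.size == 0:
        raise ValueError(f"no atoms with role {role!r}")
    c0 = geometry.layer_z_centers[0]
    span = geometry.interlayer_bounds[-1][1] - c0
    half = 0.5 * max(hi - lo for lo, hi in geometry.interlayer_bounds)
    edges = np.arange(-half, half + 0.5 * bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    n_frames = traj.n_frames
    bounds = np.array(geometry.interlayer_bounds)
    for fr in traj.frames:
        z = fr.coordinates[idx, 2]
        zw = np.mod(z - c0, span) + c0
        for lo, hi in bounds:
            sel = (zw >= lo) & (zw < hi)
            if not np.any(sel):
                continue
            rel = zw[sel] - 0.5 * (lo + hi)
            h, _ = np.histogram(rel, bins=edges)
            counts += h
    density = counts / (n_frames * bin_width)
    if mirror:
        density = 0.5 * (density + density[::-1])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(
        z_centers=centers,
        density=density,
        role=role,
        bin_width=bin_width,
        n_frames=n_frames,
        mirrored=mirror,
    )


# ---------------------------------------------------------------------------
# Radial distribution functions
# ---------------------------------------------------------------------------

def _min_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def rdf(
    traj: Trajectory,
    pair: tuple[str, str],
    r_max: float = 5.0,
    bin_width: float = 0.05,
) -> RDFResult:
    """Radial distribution function g(r) for a role pair, out to ``r_max``.

    Distances use the orthorhombic minimum-image convention; normalization
    uses the full-box ideal-gas shell expectation (the confined geometry
    makes the absolute scale qualitative beyond one gallery, hence the
    short default range). Self-pairs are excluded for identical roles.
    """
    role_a, role_b = pair
    ia = traj.topology.indices_by_role(role_a)
    ib = traj.topology.indices_by_role(role_b)
    same = role_a == role_b
    if ia.size == 0 or ib.size == 0:
        raise ValueError(f"roles {pair} not both present")
    if same and ia.size < 2:
        raise ValueError(f"role {role_a!r} has a single atom: no pairs")
    box0 = traj.frames[0].box
    if r_max > 0.5 * float(np.min(box0)) + 1e-9:
        raise ValueError(
            f"r_max {r_max} Å exceeds half the smallest box edge {np.min(box0) / 2:.3f} Å"
        )
    edges = np.arange(0.0, r_max + 0.5 * bin_width, bin_width)
    counts = np.zeros(edges.size - 1)
    for fr in traj.frames:
        ra = fr.coordinates[ia]
        rb = fr.coordinates[ib]
        diff = ra[:, None, :] - rb[None, :, :]
        diff = _min_image(diff, fr.box)
        dist = np.linalg.norm(diff, axis=-1)
        if same:
            iu = np.triu_indices(ia.size, k=1)
            d = dist[iu]
        else:
            d = dist.ravel()
        h, _ = np.histogram(d, bins=edges)
        counts += h
    vol = float(np.prod(box0))
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if same:
        n_ideal = ia.size * (ia.size - 1) / 2.0 * shell / vol
    else:
        n_ideal = ia.size * ib.size * shell / vol
    g = counts / (traj.n_frames * n_ideal)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r_centers=centers, g=g, pair=pair, r_max=r_max, counts=counts)
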