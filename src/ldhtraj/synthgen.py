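"""Synthetic slab-trajectory generator.

Emulates the statistical structure of MD trajectories of hydrotalcite-like
layered double hydroxides (LDHs), [Mg4Al2(OH)12]A2-.XH2O, intercalating
succinate (SUC), L-alpha-aspartate (ASP) or L-alpha-glutamate (GLU) dianions:

* three rigid metal-hydroxide sheets stacked along z at spacing ``d``;
* one anion per formula unit, each holding an orientation state (parallel
  to the sheets, or intermediate/perpendicular) and a conformer state
  (anti / gauche+ / gauche-) that switch by a Markov chain with a
  configurable mean dwell, so frames are autocorrelated like real MD;
* carboxylate oxygens oscillating along the C->O bonds as two
  noise-driven underdamped modes: in-phase (symmetric stretch, near
  1400 cm^-1) and out-of-phase (antisymmetric stretch, near 1600 cm^-1);
* water molecules anchored in the surface hydration shell of carboxylate
  oxygens, with a configurable fraction placed at the gallery midplane
  (populated only at high hydration in the real systems);
* Gaussian thermal jitter on all interlayer atoms.

Initial orientation/conformer states are allocated across anions by a
largest-remainder (stratified) scheme so the ensemble cross-section matches
the prescribed populations exactly up to integer rounding; the Markov
dynamics then preserves those populations in distribution.

Everything is reproducible from a single seed through named substreams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .model import AnionRecord, Atom, Frame, Topology, Trajectory

__all__ = [
    "SyntheticConfig",
    "GenerationError",
    "PRESETS",
    "UNDEFINED_PRESETS",
    "preset",
    "preset_names",
    "build_topology",
    "generate_trajectory",
    "anion_template",
]

#: speed of light in cm/fs; nu[cm^-1] * C_CM_FS * dt[fs] = cycles per frame
C_CM_FS = 2.99792458e-5


class GenerationError(RuntimeError):
    """Raised when a configuration cannot be realized geometrically."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticConfig:
    """All knobs of the generator. Units: Å, fs, cm^-1, elementary charges."""

    anion_type: str = "ASP"
    n_formula_units: int = 8
    waters_per_anion_X: float = 0.0
    spacing_d: float = 12.10
    n_layers: int = 3
    p_parallel: float = 0.5
    conformer_fractions: dict = field(
        default_factory=lambda: {"anti": 1.0, "gauche_plus": 0.0, "gauche_minus": 0.0}
    )
    nu_S: float = 1400.0
    nu_AS: float = 1600.0
    mode_amplitude: float = 0.10
    damping_time: float = 500.0
    thermal_sigma: float = 0.05
    midplane_water_fraction: float = 0.0
    dt: float = 0.5
    n_frames: int = 4096
    seed: int = 0
    state_dwell_frames: float = 100.0
    lattice_a: float = 3.05

    def __post_init__(self) -> None:
        if self.anion_type not in ("ASP", "GLU", "SUC"):
            raise ValueError(f"unknown anion_type {self.anion_type!r}")
        cf = self.conformer_fractions
        missing = {"anti", "gauche_plus", "gauche_minus"} - set(cf)
        if missing:
            raise ValueError(f"conformer_fractions missing keys {sorted(missing)}")
        if abs(sum(cf.values()) - 1.0) > 1e-9:
            raise ValueError("conformer_fractions must sum to 1")
        if any(v < 0 for v in cf.values()):
            raise ValueError("conformer_fractions must be non-negative")
        if not (0.0 <= self.p_parallel <= 1.0):
            raise ValueError("p_parallel must be in [0, 1]")
        if not (0.0 <= self.midplane_water_fraction <= 1.0):
            raise ValueError("midplane_water_fraction must be in [0, 1]")
        if self.nu_AS <= self.nu_S:
            raise ValueError("nu_AS must exceed nu_S")
        for name in ("n_formula_units", "spacing_d", "n_layers", "dt", "n_frames",
                     "mode_amplitude", "damping_time", "state_dwell_frames", "lattice_a"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.waters_per_anion_X < 0 or self.thermal_sigma < 0:
            raise ValueError("waters_per_anion_X and thermal_sigma must be >= 0")

    # -- serialization ------------------------------------------------------

    def to_file(self, path: str | Path) -> None:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)


# ---------------------------------------------------------------------------
# Presets: the simulated systems (hydration X, interlamellar spacing d),
# their orientational populations, and band positions chosen so the
# generated S/AS splitting matches the computed band gaps of the source
# systems (symmetric stretch fixed near 1400 cm^-1).
# ---------------------------------------------------------------------------

def _cf(anti: float, gp: float, gm: float) -> dict:
    return {"anti": anti, "gauche_plus": gp, "gauche_minus": gm}


# name: (anion, X, d, p_parallel, gap_cm1, conformer_fractions, midplane_fraction)
_PRESET_TABLE = {
    "ASP_0_WAT":    ("ASP", 0.0, 9.06, 0.55, 210.0, _cf(0.60, 0.00, 0.40), 0.00),
    "ASP_1_WAT":    ("ASP", 1.0, 9.21, 0.39, 209.0, _cf(0.60, 0.00, 0.40), 0.00),
    "ASP_3.5_WAT":  ("ASP", 3.5, 11.21, 0.09, 197.0, _cf(0.55, 0.00, 0.45), 0.00),
    "ASP_6.5_WAT":  ("ASP", 6.5, 12.10, 0.32, 197.0, _cf(0.55, 0.00, 0.45), 0.25),
    "GLU_0_WAT":    ("GLU", 0.0, 9.08, 0.86, 213.0, _cf(1.00, 0.00, 0.00), 0.00),
    "GLU_1_WAT":    ("GLU", 1.0, 11.57, 0.04, 185.0, _cf(0.60, 0.20, 0.20), 0.00),
    "GLU_4.25_WAT": ("GLU", 4.25, 12.35, 0.15, 192.0, _cf(0.60, 0.20, 0.20), 0.25),
    "GLU_6.5_WAT":  ("GLU", 6.5, 12.35, 0.16, 187.0, _cf(0.60, 0.20, 0.20), 0.25),
    "SUC_0_WAT":    ("SUC", 0.0, 8.87, 1.00, 257.0, _cf(1.00, 0.00, 0.00), 0.00),
    "SUC_2_WAT":    ("SUC", 2.0, 11.38, 0.00, 210.0, _cf(1.00, 0.00, 0.00), 0.00),
    "SUC_6.5_WAT":  ("SUC", 6.5, 11.98, 0.15, 200.0, _cf(0.80, 0.10, 0.10), 0.25),
}

#: systems reported in derived tables but with no defined interlamellar
#: spacing; requesting them raises rather than guessing a geometry.
UNDEFINED_PRESETS = ("SUC_8_WAT",)

PRESETS = tuple(_PRESET_TABLE)


def preset_names() -> tuple[str, ...]:
    return PRESETS


def preset(name: str, **overrides) -> SyntheticConfig:
    """Return the SyntheticConfig for a named system, e.g. ``ASP_6.5_WAT``.

    Keyword overrides replace preset fields (seed, n_frames, ...).
    """
    if name in UNDEFINED_PRESETS:
        raise LookupError(
            f"{name} is reported in derived tables but has no defined interlamellar "
            f"spacing; it cannot be generated. Defined presets: {', '.join(PRESETS)}"
        )
    if name not in _PRESET_TABLE:
        raise LookupError(
            f"unknown preset {name!r}; available presets: {', '.join(PRESETS)}"
        )
    anion, x, d, p_par, gap, conf, midfrac = _PRESET_TABLE[name]
    cfg = SyntheticConfig(
        anion_type=anion,
        waters_per_anion_X=x,
        spacing_d=d,
        p_parallel=p_par,
        conformer_fractions=dict(conf),
        nu_S=1400.0,
        nu_AS=1400.0 + gap,
        midplane_water_fraction=midfrac,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Anion templates (rigid ideal geometry, one free torsion chi)
# ---------------------------------------------------------------------------

_BOND_CC = 1.53
_BOND_CO = 1.26
_BOND_CH = 1.09
_BOND_CN = 1.47
_BOND_NH = 1.01
_ANGLE_CCC = 111.0
_ANGLE_CCO = 117.0

# per anion type: ordered atom spec (element, role, charge, name)
_ANION_ATOMS = {
    "SUC": [
        ("C", "carboxylate_C", 0.70, "C1"),
        ("O", "carboxylate_O", -0.80, "O1a"),
        ("O", "carboxylate_O", -0.80, "O1b"),
        ("C", "other", -0.20, "C2"),
        ("H", "other", 0.05, "H2a"),
        ("H", "other", 0.05, "H2b"),
        ("C", "other", -0.20, "C3"),
        ("H", "other", 0.05, "H3a"),
        ("H", "other", 0.05, "H3b"),
        ("C", "carboxylate_C", 0.70, "C4"),
        ("O", "carboxylate_O", -0.80, "O4a"),
        ("O", "carboxylate_O", -0.80, "O4b"),
    ],
    "ASP": [
        ("C", "carboxylate_C", 0.70, "C1"),
        ("O", "carboxylate_O", -0.80, "O1a"),
        ("O", "carboxylate_O", -0.80, "O1b"),
        ("C", "other", -0.10, "CA"),
        ("H", "other", 0.10, "HA"),
        ("N", "amino_N", -0.90, "N"),
        ("H", "other", 0.35, "HN1"),
        ("H", "other", 0.35, "HN2"),
        ("C", "other", -0.20, "CB"),
        ("H", "other", 0.10, "HB1"),
        ("H", "other", 0.10, "HB2"),
        ("C", "carboxylate_C", 0.70, "CG"),
        ("O", "carboxylate_O", -0.80, "OGa"),
        ("O", "carboxylate_O", -0.80, "OGb"),
    ],
    "GLU": [
        ("C", "carboxylate_C", 0.70, "C1"),
        ("O", "carboxylate_O", -0.80, "O1a"),
        ("O", "carboxylate_O", -0.80, "O1b"),
        ("C", "other", -0.10, "CA"),
        ("H", "other", 0.10, "HA"),
        ("N", "amino_N", -0.90, "N"),
        ("H", "other", 0.35, "HN1"),
        ("H", "other", 0.35, "HN2"),
        ("C", "other", -0.20, "CB"),
        ("H", "other", 0.10, "HB1"),
        ("H", "other", 0.10, "HB2"),
        ("C", "other", -0.20, "CG"),
        ("H", "other", 0.10, "HG1"),
        ("H", "other", 0.10, "HG2"),
        ("C", "carboxylate_C", 0.70, "CD"),
        ("O", "carboxylate_O", -0.80, "ODa"),
        ("O", "carboxylate_O", -0.80, "ODb"),
    ],
}


def _name_index(atype: str) -> dict[str, int]:
    return {name: i for i, (_, _, _, name) in enumerate(_ANION_ATOMS[atype])}


#: per type: the theta-defining carboxylate carbons, the classifying torsion
#: quadruple, the amino N name, and the two carboxylate groups (C, O, O).
_ANION_NAMED = {
    "SUC": {
        "carboxylate_carbons": ("C1", "C4"),
        "dihedral": ("C1", "C2", "C3", "C4"),
        "amino_n": None,
        "groups": [("C1", "O1a", "O1b"), ("C4", "O4a", "O4b")],
        "chain": ("C1", "C2", "C3", "C4"),
    },
    "ASP": {
        "carboxylate_carbons": ("C1", "CG"),
        "dihedral": ("C1", "CA", "CB", "CG"),
        "amino_n": "N",
        "groups": [("C1", "O1a", "O1b"), ("CG", "OGa", "OGb")],
        "chain": ("C1", "CA", "CB", "CG"),
    },
    "GLU": {
        "carboxylate_carbons": ("C1", "CD"),
        "dihedral": ("C1", "CA", "CB", "CG"),
        "amino_n": "N",
        "groups": [("C1", "O1a", "O1b"), ("CD", "ODa", "ODb")],
        "chain": ("C1", "CA", "CB", "CG", "CD"),
    },
}


def _torsion(p0, p1, p2, p3) -> float:
    """Signed IUPAC torsion in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = math.degrees(math.atan2(-y, x))
    return 180.0 if ang <= -180.0 else ang


def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, angle(b,c,d)=angle and
    IUPAC torsion(a,b,c,d)=torsion."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d2 = np.array(
        [-bond * math.cos(ang),
         bond * math.sin(ang) * math.cos(tor),
         bond * math.sin(ang) * math.sin(tor)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def anion_template(anion_type: str, chi_deg: float) -> np.ndarray:
    """Ideal-geometry coordinates (Å) of one anion with classifying torsion chi.

    The quadruple named in ``_ANION_NAMED[anion_type]['dihedral']`` has the
    IUPAC torsion ``chi_deg`` exactly (ideal bond lengths and angles
    elsewhere); the molecule is centered at its centroid.
    """
    spec = _ANION_ATOMS[anion_type]
    named = _ANION_NAMED[anion_type]
    ni = _name_index(anion_type)
    coords = np.zeros((len(spec), 3))
    chain = named["chain"]

    # main chain: first three atoms fix the frame, the fourth carries chi
    coords[ni[chain[0]]] = [0.0, 0.0, 0.0]
    coords[ni[chain[1]]] = [_BOND_CC, 0.0, 0.0]
    ang = math.radians(180.0 - _ANGLE_CCC)
    coords[ni[chain[2]]] = coords[ni[chain[1]]] + _BOND_CC * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )
    torsions = {3: chi_deg, 4: 180.0}
    for k in range(3, len(chain)):
        coords[ni[chain[k]]] = _place(
            coords[ni[chain[k - 3]]],
            coords[ni[chain[k - 2]]],
            coords[ni[chain[k - 1]]],
            _BOND_CC, _ANGLE_CCC, torsions[k],
        )

    # carboxylate oxygens on both terminal carbons (sp2, in/out of plane)
    for (cname, o1, o2) in named["groups"]:
        ci = ni[cname]
        if cname == chain[0]:
            a, b = ni[chain[2]], ni[chain[1]]
        else:
            a, b = ni[chain[-3]], ni[chain[-2]]
        coords[ni[o1]] = _place(coords[a], coords[b], coords[ci], _BOND_CO, _ANGLE_CCO, 0.0)
        coords[ni[o2]] = _place(coords[a], coords[b], coords[ci], _BOND_CO, _ANGLE_CCO, 180.0)

    # substituents on interior chain carbons (H, and N+H2 on the alpha carbon)
    for k in range(1, len(chain) - 1):
        ci = ni[chain[k]]
        prev_i = ni[chain[k - 1]]
        ref_i = ni[chain[k - 3]] if k >= 3 else ni["O1a"]
        t_next = _torsion(coords[ref_i], coords[prev_i], coords[ci], coords[ni[chain[k + 1]]])
        subs = [nm for nm in _sub_names(anion_type, chain[k])]
        offsets = (120.0, -120.0)
        for nm, off in zip(subs, offsets):
            bond = _BOND_CN if nm == "N" else _BOND_CH
            coords[ni[nm]] = _place(
                coords[ref_i], coords[prev_i], coords[ci], bond, 109.5, t_next + off
            )

    # amino hydrogens
    if named["amino_n"] is not None:
        n_i = ni[named["amino_n"]]
        ca_i = ni["CA"]
        c1_i = ni["C1"]
        for nm, tor in (("HN1", 60.0), ("HN2", 300.0)):
            coords[ni[nm]] = _place(coords[c1_i], coords[ca_i], coords[n_i],
                                    _BOND_NH, 107.0, tor)

    return coords - coords.mean(axis=0)


def _sub_names(anion_type: str, chain_atom: str) -> list[str]:
    """Non-chain substituents bonded to an interior chain carbon, in order."""
    if anion_type == "SUC":
        return {"C2": ["H2a", "H2b"], "C3": ["H3a", "H3b"]}[chain_atom]
    if chain_atom == "CA":
        return ["N", "HA"]
    if chain_atom == "CB":
        return ["HB1", "HB2"]
    return ["HG1", "HG2"]  # GLU CG


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

_LAYER_CHARGES = {"layer_Mg": 2.0, "layer_Al": 3.0, "layer_OH_O": -1.42, "layer_OH_H": 0.42}
_WATER_CHARGES = {"O": -0.8476, "H": 0.4238}


def _water_counts(n_fu: int, x: float) -> list[int]:
    """Total waters = round(n_fu * X), distributed largest-first by unit index."""
    total = math.floor(n_fu * x + 0.5)
    base, rem = divmod(total, n_fu)
    return [base + (1 if f < rem else 0) for f in range(n_fu)]


def build_topology(config: SyntheticConfig) -> Topology:
    """Assemble the Topology for a configuration.

    Per formula unit: 4 layer Mg, 2 layer Al, 12 hydroxyl O-H pairs (all on
    one sheet, assigned round-robin across layers), one anion, and its share
    of round(n_fu * X) three-site waters. Layer atoms of sheet ``l`` share
    molecule id ``l``; anion ``f`` has molecule id ``n_layers + f``; waters
    follow with one id per molecule.
    """
    n_fu = config.n_formula_units
    nl = config.n_layers
    atoms: list[Atom] = []
    for f in range(n_fu):
        sheet = f % nl
        for _ in range(4):
            atoms.append(Atom("Mg", _LAYER_CHARGES["layer_Mg"], sheet, "layer_Mg"))
        for _ in range(2):
            atoms.append(Atom("Al", _LAYER_CHARGES["layer_Al"], sheet, "layer_Al"))
        for _ in range(12):
            atoms.append(Atom("O", _LAYER_CHARGES["layer_OH_O"], sheet, "layer_OH_O"))
            atoms.append(Atom("H", _LAYER_CHARGES["layer_OH_H"], sheet, "layer_OH_H"))

    records: list[AnionRecord] = []
    named = _ANION_NAMED[config.anion_type]
    spec = _ANION_ATOMS[config.anion_type]
    ni = _name_index(config.anion_type)
    for f in range(n_fu):
        mol = nl + f
        offset = len(atoms)
        for el, role, q, _name in spec:
            atoms.append(Atom(el, q, mol, role))
        records.append(
            AnionRecord(
                molecule_id=mol,
                carboxylate_carbons=tuple(offset + ni[n] for n in named["carboxylate_carbons"]),
                dihedral=tuple(offset + ni[n] for n in named["dihedral"]),
                amino_n=None if named["amino_n"] is None else offset + ni[named["amino_n"]],
            )
        )

    mol = nl + n_fu
    for f, nw in enumerate(_water_counts(n_fu, config.waters_per_anion_X)):
        for _ in range(nw):
            atoms.append(Atom("O", _WATER_CHARGES["O"], mol, "water_O"))
            atoms.append(Atom("H", _WATER_CHARGES["H"], mol, "water_H"))
            atoms.append(Atom("H", _WATER_CHARGES["H"], mol, "water_H"))
            mol += 1

    top = Topology(atoms=atoms, anion_records=records, anion_type=config.anion_type,
                   n_layers=nl)
    top.validate_anion_charges()
    return top


# ---------------------------------------------------------------------------
# Trajectory generation
# ---------------------------------------------------------------------------

#: window half-widths (deg) for the state draws; boundaries of the analysis
#: windows (80 deg for theta, +-120 deg for chi) are kept well away.
_CHI_HALF_WIDTH = 25.0
_CHI_CENTERS = {"anti": 180.0, "gauche_plus": 60.0, "gauche_minus": -60.0}
_CONFORMER_ORDER = ("anti", "gauche_plus", "gauche_minus")
_THETA_PARALLEL = (81.0, 90.0)
_THETA_OTHER = (0.0, 70.0)
#: minimum clearance (Å) between any anion atom and a sheet plane
_Z_MARGIN = 1.2


def _largest_remainder(fracs: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n items proportional to fracs (sums to n)."""
    quota = fracs * n
    counts = np.floor(quota).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def _rotation_to(u: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector u onto unit vector t (Rodrigues)."""
    c = float(np.dot(u, t))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        return np.eye(3) + 2.0 * (k @ k)
    v = np.cross(u, t)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + (k @ k) / (1.0 + c)


def _markov_segments(rng: np.random.Generator, n_frames: int, dwell: float) -> list[int]:
    """Frame indices at which the state is (re)drawn; always includes 0."""
    switches = rng.random(n_frames) < (1.0 / dwell)
    switches[0] = True
    return list(np.flatnonzero(switches))


def _mode_series(rng: np.random.Generator, n_modes: int, n_frames: int,
                 nu_cm1: float, dt: float, amplitude: float, damping_time: float) -> np.ndarray:
    """Stationary underdamped noise-driven oscillators, shape (n_frames, n_modes).

    Exact deterministic propagator of x'' + gamma x' + w0^2 x = 0 plus a
    per-step velocity kick scaled so the stationary displacement RMS equals
    ``amplitude``; the power spectrum is a Lorentzian-like band of FWHM
    ~ gamma/(2 pi c) centered at the damped frequency.
    """
    w0 = 2.0 * math.pi * C_CM_FS * nu_cm1
    gamma = 1.0 / damping_time
    wd = math.sqrt(max(w0 * w0 - 0.25 * gamma * gamma, 1e-12))
    e = math.exp(-0.5 * gamma * dt)
    cwd, swd = math.cos(wd * dt), math.sin(wd * dt)
    m11 = e * (cwd + 0.5 * gamma * swd / wd)
    m12 = e * swd / wd
    m21 = -e * w0 * w0 * swd / wd
    m22 = e * (cwd - 0.5 * gamma * swd / wd)
    q = 2.0 * gamma * w0 * w0 * amplitude * amplitude
    kick = math.sqrt(q * dt)

    x = rng.normal(0.0, amplitude, n_modes)
    v = rng.normal(0.0, amplitude * w0, n_modes)
    noise = rng.normal(0.0, kick, (n_frames, n_modes))
    out = np.empty((n_frames, n_modes))
    for t in range(n_frames):
        out[t] = x
        x, v = m11 * x + m12 * v, m21 * x + m22 * v + noise[t]
    return out


def generate_trajectory(config: SyntheticConfig) -> Trajectory:
    """Generate a synthetic slab trajectory realizing ``config``.

    See the module docstring for the statistical model. Fully reproducible:
    two calls with equal configs return bit-identical trajectories.
    """
    top = build_topology(config)
    n_fu = config.n_formula_units
    nl = config.n_layers
    d = config.spacing_d
    nf = config.n_frames
    atype = config.anion_type
    ss = np.random.SeedSequence(config.seed)
    rng_states, rng_modes, rng_place, rng_jitter = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # ---- static sheets ----------------------------------------------------
    fu_per_sheet = [sum(1 for f in range(n_fu) if f % nl == sheet) for sheet in range(nl)]
    m_grid = max(1, math.ceil(math.sqrt(6 * max(fu_per_sheet))))
    a = config.lattice_a
    lx = ly = m_grid * a
    lz = nl * d
    box = np.array([lx, ly, lz])

    coords0 = np.zeros((top.n_atoms, 3))
    i = 0
    sheet_slot = [0] * nl
    for f in range(n_fu):
        sheet = f % nl
        z0 = sheet * d
        for k in range(6):
            slot = sheet_slot[sheet]
            sheet_slot[sheet] += 1
            gx, gy = divmod(slot, m_grid)
            pos = np.array([(gx % m_grid + 0.5) * a, (gy + 0.5) * a, z0])
            coords0[i] = pos
            i += 1
        # hydroxyls: one above and one below each of the 6 cation sites
        base = i - 6
        for k in range(6):
            cx, cy, _ = coords0[base + k]
            for sgn in (+1.0, -1.0):
                coords0[i] = [cx + 0.8, cy + 0.8, z0 + sgn * 1.0]
                i += 1
                coords0[i] = [cx + 0.8, cy + 0.8, z0 + sgn * 1.96]
                i += 1

    n_layer_atoms = i

    # ---- anion state machinery -------------------------------------------
    templates = {}  # cache per (state) chi draw handled per segment

    anion_offsets = []
    for rec in top.anion_records:
        mol_idx = top.molecule_indices(rec.molecule_id)
        anion_offsets.append(int(mol_idx[0]))
    n_anion_atoms = len(_ANION_ATOMS[atype])
    named = _ANION_NAMED[atype]
    ni = _name_index(atype)
    cc_local = [ni[n] for n in named["carboxylate_carbons"]]

    # geometric feasibility probe: the longest (anti) template; anions in a
    # too-narrow gallery tilt toward the sheets (theta grows) until they fit,
    # and generation fails only if even the maximal tilt does not fit
    probe = anion_template(atype, 180.0)
    axis = probe[cc_local[1]] - probe[cc_local[0]]
    axis /= np.linalg.norm(axis)
    proj = probe @ axis
    l_max = float(proj.max() - proj.min())

    # stratified initial states across anions
    p = config.p_parallel
    orient_counts = _largest_remainder(np.array([p, 1.0 - p]), n_fu)
    orient_init = np.array([0] * orient_counts[0] + [1] * orient_counts[1])
    rng_states.shuffle(orient_init)
    cfr = np.array([config.conformer_fractions[k] for k in _CONFORMER_ORDER])
    conf_counts = _largest_remainder(cfr, n_fu)
    conf_init = np.repeat(np.arange(3), conf_counts)
    rng_states.shuffle(conf_init)

    # gallery assignment and xy sites
    gallery_of = [f % nl for f in range(n_fu)]
    per_gallery: dict[int, list[int]] = {}
    for f, g in enumerate(gallery_of):
        per_gallery.setdefault(g, []).append(f)
    site_xy = np.zeros((n_fu, 2))
    for g, members in per_gallery.items():
        gm = max(1, math.ceil(math.sqrt(len(members))))
        for j, f in enumerate(members):
            site_xy[f] = [((j % gm) + 0.5) * lx / gm, ((j // gm) + 0.5) * ly / gm]

    def draw_theta(state: int) -> float:
        lo, hi = _THETA_PARALLEL if state == 0 else _THETA_OTHER
        return float(rng_states.uniform(lo, hi))

    def draw_chi(state: int) -> float:
        c = _CHI_CENTERS[_CONFORMER_ORDER[state]]
        chi = c + float(rng_states.uniform(-_CHI_HALF_WIDTH, _CHI_HALF_WIDTH))
        return chi - 360.0 if chi > 180.0 else chi

    # per anion: combined segments of (orientation, conformer) states
    anion_base = np.zeros((nf, n_fu, n_anion_atoms, 3))
    group_u = np.zeros((nf, n_fu, 2, 2, 3))  # frame, anion, group, oxygen, unit vec
    orient_state_per_frame = np.zeros((nf, n_fu), dtype=int)
    chi_per_frame = np.zeros((nf, n_fu))

    groups_local = [
        (ni[c], ni[o1], ni[o2]) for (c, o1, o2) in named["groups"]
    ]

    for f in range(n_fu):
        g = gallery_of[f]
        z_lo, z_hi = g * d, (g + 1) * d
        mid = 0.5 * (z_lo + z_hi)
        o_switch = set(_markov_segments(rng_states, nf, config.state_dwell_frames))
        c_switch = set(_markov_segments(rng_states, nf, config.state_dwell_frames))
        breaks = sorted(o_switch | c_switch)
        ostate, cstate = int(orient_init[f]), int(conf_init[f])
        theta = draw_theta(ostate)
        chi = draw_chi(cstate)
        first = True
        for bi, start in enumerate(breaks):
            end = breaks[bi + 1] if bi + 1 < len(breaks) else nf
            if not first:
                if start in o_switch:
                    ostate = 0 if rng_states.random() < p else 1
                    theta = draw_theta(ostate)
                if start in c_switch:
                    cstate = int(rng_states.choice(3, p=cfr))
                    chi = draw_chi(cstate)
            first = False

            tmpl = anion_template(atype, chi)
            u = tmpl[cc_local[1]] - tmpl[cc_local[0]]
            u /= np.linalg.norm(u)
            phi = rng_states.uniform(0.0, 2.0 * math.pi)
            usable_half = 0.5 * (d - 2 * _Z_MARGIN)

            def _placed_at(theta_deg: float) -> np.ndarray:
                th = math.radians(theta_deg)
                target = np.array([math.sin(th) * math.cos(phi),
                                   math.sin(th) * math.sin(phi),
                                   math.cos(th)])
                return tmpl @ _rotation_to(u, target).T

            placed = _placed_at(theta)
            if ostate != 0:
                # tilt up (toward the sheets) until the anion fits the gallery
                theta_fit = theta
                while (np.max(np.abs(placed[:, 2])) + 0.3 > usable_half
                       and theta_fit < _THETA_OTHER[1]):
                    theta_fit = min(theta_fit + 0.5, _THETA_OTHER[1])
                    placed = _placed_at(theta_fit)
                if np.max(np.abs(placed[:, 2])) + 0.3 > usable_half:
                    raise GenerationError(
                        f"{atype} anion (length {l_max:.2f} Å) exceeds the interlayer "
                        f"clearance {d - 2 * _Z_MARGIN:.2f} Å at spacing_d={d} Å even "
                        f"at the maximal tilt of {_THETA_OTHER[1]:.0f} deg"
                    )
                theta = theta_fit
            h = float(np.max(np.abs(placed[:, 2]))) + 0.3
            if ostate == 0:
                side = 1.0 if rng_states.random() < 0.5 else -1.0
                zc = (z_lo + _Z_MARGIN + h) if side > 0 else (z_hi - _Z_MARGIN - h)
                zc = min(max(zc, z_lo + _Z_MARGIN + h), z_hi - _Z_MARGIN - h)
                if 2 * h > d - 2 * _Z_MARGIN:
                    raise GenerationError(
                        f"{atype} anion does not fit the interlayer even lying "
                        f"parallel: width {2 * h:.2f} Å vs clearance "
                        f"{d - 2 * _Z_MARGIN:.2f} Å at spacing_d={d} Å"
                    )
            else:
                zc = mid
            placed = placed + np.array([site_xy[f, 0], site_xy[f, 1], zc])
            anion_base[start:end, f] = placed
            orient_state_per_frame[start:end, f] = ostate
            chi_per_frame[start:end, f] = chi
            for gi, (ci, o1, o2) in enumerate(groups_local):
                for oi, o in enumerate((o1, o2)):
                    uv = placed[o] - placed[ci]
                    uv /= np.linalg.norm(uv)
                    group_u[start:end, f, gi, oi] = uv

    # ---- carboxylate stretch modes ---------------------------------------
    s_series = _mode_series(rng_modes, 2 * n_fu, nf, config.nu_S, config.dt,
                            config.mode_amplitude, config.damping_time)
    a_series = _mode_series(rng_modes, 2 * n_fu, nf, config.nu_AS, config.dt,
                            config.mode_amplitude, config.damping_time)
    s_series = s_series.reshape(nf, n_fu, 2)
    a_series = a_series.reshape(nf, n_fu, 2)

    # the in-phase (S) displacement is scaled by |u1-u2|/|u1+u2| so both
    # bands carry comparable dipole strength, as carboxylate S/AS bands do
    u_sum = np.linalg.norm(group_u[:, :, :, 0] + group_u[:, :, :, 1], axis=-1)
    u_dif = np.linalg.norm(group_u[:, :, :, 0] - group_u[:, :, :, 1], axis=-1)
    beta = u_dif / np.maximum(u_sum, 1e-9)
    anion_coords = anion_base.copy()
    for gi in range(2):
        for oi, sign in ((0, 1.0), (1, -1.0)):
            o_local = groups_local[gi][1 + oi]
            disp = (beta[:, :, gi] * s_series[:, :, gi]
                    + sign * a_series[:, :, gi])[:, :, None] * group_u[:, :, gi, oi]
            anion_coords[:, :, o_local, :] += disp

    # ---- waters -----------------------------------------------------------
    water_rows = []  # (anchor_anion or None, static offset/static position)
    wcounts = _water_counts(n_fu, config.waters_per_anion_X)
    o_locals = [groups_local[gi][1 + oi] for gi in range(2) for oi in range(2)]
    water_base = None
    n_waters = sum(wcounts)
    if n_waters:
        water_base = np.zeros((nf, n_waters, 3, 3))
        w = 0
        for f in range(n_fu):
            g = gallery_of[f]
            z_lo, z_hi = g * d, (g + 1) * d
            mid = 0.5 * (z_lo + z_hi)
            for _ in range(wcounts[f]):
                # rigid water: O at origin, H's at fixed geometry, random tilt
                hv1 = rng_place.normal(size=3)
                hv1 /= np.linalg.norm(hv1)
                hv2 = rng_place.normal(size=3)
                hv2 -= hv1 * np.dot(hv1, hv2)
                hv2 /= np.linalg.norm(hv2)
                h1 = 0.9572 * hv1
                h2 = 0.9572 * (math.cos(math.radians(104.52)) * hv1
                               + math.sin(math.radians(104.52)) * hv2)
                if rng_place.random() < config.midplane_water_fraction:
                    o_pos = np.array([
                        rng_place.uniform(0, lx),
                        rng_place.uniform(0, ly),
                        mid + rng_place.uniform(-0.75, 0.75),
                    ])
                    pos = np.broadcast_to(o_pos, (nf, 3))
                else:
                    # hydration shell of a carboxylate O, on its surface side
                    o_local = o_locals[int(rng_place.integers(len(o_locals)))]
                    r = rng_place.uniform(2.4, 3.0)
                    dz = rng_place.uniform(0.0, 2.0)
                    rho = math.sqrt(max(r * r - dz * dz, 0.0))
                    az = rng_place.uniform(0.0, 2.0 * math.pi)
                    anchor = anion_base[:, f, o_local, :]
                    toward = np.where(anchor[:, 2] < mid, -1.0, 1.0)
                    off_xy = np.array([rho * math.cos(az), rho * math.sin(az)])
                    pos = np.empty((nf, 3))
                    pos[:, :2] = anchor[:, :2] + off_xy
                    pos[:, 2] = np.clip(anchor[:, 2] + toward * dz,
                                        z_lo + 1.0, z_hi - 1.0)
                water_base[:, w, 0, :] = pos
                water_base[:, w, 1, :] = pos + h1
                water_base[:, w, 2, :] = pos + h2
                w += 1

    # ---- assemble and jitter ---------------------------------------------
    all_coords = np.empty((nf, top.n_atoms, 3))
    all_coords[:, :n_layer_atoms, :] = coords0[:n_layer_atoms]
    for f, off in enumerate(anion_offsets):
        all_coords[:, off:off + n_anion_atoms, :] = anion_coords[:, f]
    if n_waters:
        w_off = n_layer_atoms + n_fu * n_anion_atoms
        all_coords[:, w_off:, :] = water_base.reshape(nf, 3 * n_waters, 3)

    if config.thermal_sigma > 0:
        n_mobile = top.n_atoms - n_layer_atoms
        jit = rng_jitter.normal(0.0, config.thermal_sigma, (nf, n_mobile, 3))
        # the two theta-defining carbons of each anion share one jitter draw,
        # so the orientation state survives thermal noise exactly
        for f, off in enumerate(anion_offsets):
            j0 = off - n_layer_atoms
            c1, c2 = (j0 + cc_local[0], j0 + cc_local[1])
            jit[:, c2, :] = jit[:, c1, :]
        all_coords[:, n_layer_atoms:, :] += jit

    frames = [
        Frame(coordinates=all_coords[t], box=box.copy(), time=t * config.dt)
        for t in range(nf)
    ]
    return Trajectory(topology=top, frames=frames, dt=config.dt)
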