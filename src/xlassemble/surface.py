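"""Solvent-accessible surface area (Shrake-Rupley), interface buried area,
and polar-contact detection.

SASA uses the point-sampling construction of Shrake & Rupley: each atom's
solvent-expanded sphere (van der Waals radius + probe radius) is covered
with a deterministic golden-spiral point set, and the accessible area is
the unoccluded point fraction times the sphere area.  No RNG is involved,
so results are bit-reproducible at a given point count.

The buried area of an interface between atom groups A and B is computed
from SASA differences:

    dSASA = SASA(A alone) + SASA(B alone) - SASA(A u B)

where "alone" means the group's atoms extracted with everything else
removed.  Both reporting conventions are available: the PISA-like
"interface area" dSASA/2 (default) and the un-halved dSASA, since
published buried areas use either.

Hydrogen bonds are detected as N/O...N/O heavy-atom pairs across the two
groups within a distance cap (default 3.5 A, no angle term — appropriate
for models without hydrogens); salt bridges as basic-nitrogen
(Lys NZ, Arg NH1/NH2/NE, His ND1/NE2) to carboxylate-oxygen
(Asp OD1/OD2, Glu OE1/OE2) pairs within 4.0 A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structio import StructureModel

logger = logging.getLogger(__name__)

#: van der Waals radii (A) used for the solvent-expanded spheres.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.80
PROBE_RADIUS = 1.4

_MAIN_CHAIN = {"N", "CA", "C", "O", "OXT"}

_BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
                ("HIS", "ND1"), ("HIS", "NE2")}
_ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points from the golden spiral."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom: np.ndarray              # A^2, aligned with the model's atom order
    per_residue: dict                 # (chain, res_seq, ins_code) -> A^2
    total: float
    probe_radius: float
    n_sphere_points: int


def _atom_radii(model: StructureModel, radii: dict | None,
                strict: bool) -> np.ndarray:
    table = VDW_RADII if radii is None else radii
    out = np.empty(model.n_atoms)
    for i, a in enumerate(model.atoms):
        r = table.get(a.element)
        if r is None:
            if strict:
                raise ValueError(f"no vdW radius for element {a.element!r}")
            r = DEFAULT_RADIUS
        out[i] = r
    return out


def sasa(model: StructureModel, probe_radius: float = PROBE_RADIUS,
         n_points: int = 960, radii: dict | None = None,
         strict: bool = False) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area of a model."""
    if model.n_atoms == 0:
        raise ValueError("empty model")
    coords = model.coords
    rad = _atom_radii(model, radii, strict) + probe_radius
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = rad.max()
    per_atom = np.empty(model.n_atoms)
    for i in range(model.n_atoms):
        surface = coords[i] + rad[i] * pts
        neighbors = tree.query_ball_point(coords[i], rad[i] + rmax)
        free = np.ones(n_points, dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            free &= d2 > rad[j] ** 2
        per_atom[i] = free.sum() / n_points * 4.0 * np.pi * rad[i] ** 2
    per_residue: dict = {}
    for i, a in enumerate(model.atoms):
        key = a.residue_address
        per_residue[key] = per_residue.get(key, 0.0) + per_atom[i]
    return SasaResult(per_atom=per_atom, per_residue=per_residue,
                      total=float(per_atom.sum()), probe_radius=probe_radius,
                      n_sphere_points=n_points)


# ---------------------------------------------------------------------------
# Buried area
# ---------------------------------------------------------------------------

def _check_groups(group_a, group_b):
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("interface groups must be non-empty")
    if np.intersect1d(ga, gb).size:
        raise ValueError("interface groups overlap")
    return ga, gb


def buried_area(model: StructureModel, group_a: Sequence[int],
                group_b: Sequence[int], halve: bool = True,
                probe_radius: float = PROBE_RADIUS,
                n_points: int = 960) -> float:
    """Interface buried area (A^2) between two disjoint atom-index groups.

    ``halve=True`` gives the PISA-like interface area dSASA/2;
    ``halve=False`` gives the raw SASA loss dSASA.
    """
    ga, gb = _check_groups(group_a, group_b)
    sub_a = model.subset(ga)
    sub_b = model.subset(gb)
    sub_ab = model.subset(np.concatenate([ga, gb]))
    kw = dict(probe_radius=probe_radius, n_points=n_points)
    dsasa = sasa(sub_a, **kw).total + sasa(sub_b, **kw).total \
        - sasa(sub_ab, **kw).total
    dsasa = max(dsasa, 0.0)
    return dsasa / 2.0 if halve else dsasa


# ---------------------------------------------------------------------------
# Polar contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contact:
    atom_a: tuple           # (chain, res_seq, ins, res_name, atom_name)
    atom_b: tuple
    distance: float         # A
    role_a: str = ""        # "side_chain" / "main_chain"
    role_b: str = ""


def _atom_tag(a):
    return (a.chain_id, a.res_seq, a.ins_code, a.res_name, a.atom_name)


def _role(atom_name: str) -> str:
    return "main_chain" if atom_name in _MAIN_CHAIN else "side_chain"


def detect_hbonds(model: StructureModel, group_a: Sequence[int],
                  group_b: Sequence[int], d_max: float = 3.5) -> list[Contact]:
    """All N/O...N/O heavy-atom pairs across the interface within ``d_max``.

    Donor/acceptor assignment is not attempted (no hydrogens); each atom is
    annotated side-chain vs main-chain by its name instead.
    """
    ga, gb = _check_groups(group_a, group_b)
    polar_a = [i for i in ga if model.atoms[i].element in ("N", "O")]
    polar_b = [i for i in gb if model.atoms[i].element in ("N", "O")]
    return _cross_contacts(model, polar_a, polar_b, d_max)


def detect_salt_bridges(model: StructureModel, group_a: Sequence[int],
                        group_b: Sequence[int],
                        d_max: float = 4.0) -> list[Contact]:
    """Basic-to-acidic charged-group atom pairs across the interface.

    Lys NZ / Arg NH1,NH2,NE / His ND1,NE2 against Asp OD1,OD2 / Glu OE1,OE2,
    in either group order, any atom pair within ``d_max``.
    """
    ga, gb = _check_groups(group_a, group_b)

    def pick(indices, table):
        return [i for i in indices
                if (model.atoms[i].res_name, model.atoms[i].atom_name) in table]

    out = _cross_contacts(model, pick(ga, _BASIC_ATOMS), pick(gb, _ACIDIC_ATOMS),
                          d_max)
    out += _cross_contacts(model, pick(ga, _ACIDIC_ATOMS), pick(gb, _BASIC_ATOMS),
                           d_max)
    return sorted(out, key=lambda c: c.distance)


def _cross_contacts(model, idx_a, idx_b, d_max) -> list[Contact]:
    if not idx_a or not idx_b:
        return []
    coords = model.coords
    pa = coords[idx_a]
    pb = coords[idx_b]
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    out = []
    for ii, jj in zip(*np.nonzero(d <= d_max)):
        a = model.atoms[idx_a[ii]]
        b = model.atoms[idx_b[jj]]
        out.append(Contact(_atom_tag(a), _atom_tag(b), float(d[ii, jj]),
                           _role(a.atom_name), _role(b.atom_name)))
    return sorted(out, key=lambda c: (c.atom_a, c.atom_b))


# ---------------------------------------------------------------------------
# Interface reports
# ---------------------------------------------------------------------------

@dataclass
class InterfaceReport:
    interface_id: str
    buried_area: float          # dSASA/2, A^2
    delta_sasa: float           # un-halved, A^2
    hbonds: list[Contact]
    salt_bridges: list[Contact]
    n_atoms_a: int = 0
    n_atoms_b: int = 0


def interface_report(model: StructureModel, interface_id: str,
                     group_a: Sequence[int], group_b: Sequence[int],
                     hbond_d_max: float = 3.5, salt_d_max: float = 4.0,
                     n_points: int = 960) -> InterfaceReport:
    """Full characterization of one declared interface."""
    ga, gb = _check_groups(group_a, group_b)
    dsasa = buried_area(model, ga, gb, halve=False, n_points=n_points)
    return InterfaceReport(
        interface_id=interface_id,
        buried_area=dsasa / 2.0,
        delta_sasa=dsasa,
        hbonds=detect_hbonds(model, ga, gb, d_max=hbond_d_max),
        salt_bridges=detect_salt_bridges(model, ga, gb, d_max=salt_d_max),
        n_atoms_a=len(ga), n_atoms_b=len(gb))
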