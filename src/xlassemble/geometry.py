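"""Rigid-body transforms, least-squares superposition, and shape descriptors.

The superposition here is the classic Kabsch algorithm: given two paired
point sets it finds the proper rotation + translation minimizing the RMSD,
with the SVD sign correction that excludes reflections.  Principal
dimensions are the coordinate extents along the eigenvectors of the Calpha
covariance matrix, the usual way an elongated assembly's "~a x b x c"
dimensions are quoted.  The bend angle measures the kink between two helix
segments as the angle between their principal axes, each oriented along the
chain's N-to-C progression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation followed by a translation: ``x -> R @ x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 1.0 - 1e-6:
            raise ValueError("rotation matrix must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_point(cls, rotation: np.ndarray, center: np.ndarray,
                    translation: np.ndarray | None = None) -> "RigidTransform":
        """Rotation about ``center`` plus an optional extra translation.

        ``x -> R (x - c) + c + t`` collapsed to global (R, T) form.
        """
        R = np.asarray(rotation, dtype=float)
        c = np.asarray(center, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return cls(R, c + t - R @ c)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) coordinate array (or a single 3-vector)."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def almost_equal(self, other: "RigidTransform", atol: float = 1e-6) -> bool:
        return (np.allclose(self.rotation, other.rotation, atol=atol)
                and np.allclose(self.translation, other.translation, atol=atol))


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid alignment of a mobile point set onto a reference."""

    transform: RigidTransform
    rmsd: float
    n_atoms: int
    pairing: tuple = field(default=())


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    k = axis / n
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via the unit-quaternion method."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def coord_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (un-superposed) RMSD between two equal-length coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(coords_mobile: np.ndarray, coords_ref: np.ndarray,
                     pairing: Sequence | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_mobile`` onto ``coords_ref``.

    Returns the proper rotation + translation minimizing the RMSD over all
    rigid transforms (reflections excluded by the determinant sign
    correction), together with the minimized RMSD.

    Parameters
    ----------
    coords_mobile, coords_ref : (N, 3) arrays, N >= 3
        Paired coordinates; row i of one corresponds to row i of the other.
    pairing : optional sequence of residue-address pairs, stored in the result.
    """
    P = np.asarray(coords_mobile, dtype=float)
    Q = np.asarray(coords_ref, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("expected (N, 3) coordinate arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    tr = RigidTransform(R, t)
    rmsd = coord_rmsd(tr.apply(P), Q)
    return SuperpositionResult(tr, rmsd, n, tuple(pairing) if pairing else ())


def pair_common_ca(model_a, model_b, chain_pairing):
    """Pair Calpha atoms of two models over residues present in both.

    ``chain_pairing`` is either a list of ``(chain_in_a, chain_in_b)`` tuples
    (one assignment), or a list of such lists (alternative assignments, e.g.
    the two ways of matching the copies of a homodimer).  Residues are
    matched by author residue number; pairing order is deterministic
    (ascending chain pair, then residue number).  With alternatives, each is
    superposed and the lower-RMSD assignment kept (logged).

    Returns ``(coords_a, coords_b, pairing)`` where pairing lists
    ``((chain_a, res), (chain_b, res))`` tuples.
    """
    alternatives = _normalize_pairing(chain_pairing)
    best = None
    for alt in alternatives:
        ca, cb, pairing = _pair_one(model_a, model_b, alt)
        if len(pairing) == 0:
            continue
        if len(pairing) >= 3:
            rmsd = kabsch_superpose(ca, cb).rmsd
        else:
            rmsd = coord_rmsd(ca, cb)
        if best is None or rmsd < best[0]:
            best = (rmsd, ca, cb, pairing, alt)
    if best is None:
        raise ValueError("no common Calpha residues under any chain assignment")
    if len(alternatives) > 1:
        logger.info("kept chain assignment %s (superposition RMSD %.2f A)",
                    best[4], best[0])
    return best[1], best[2], best[3]


def _normalize_pairing(chain_pairing):
    chain_pairing = list(chain_pairing)
    if not chain_pairing:
        raise ValueError("empty chain pairing")
    first = chain_pairing[0]
    if isinstance(first, (list, tuple)) and len(first) == 2 \
            and isinstance(first[0], str):
        return [chain_pairing]
    return [list(alt) for alt in chain_pairing]


def _pair_one(model_a, model_b, assignment):
    coords_a, coords_b, pairing = [], [], []
    for chain_a, chain_b in assignment:
        res_a = model_a.ca_residues(chain_a)
        res_b = model_b.ca_residues(chain_b)
        for r in sorted(set(res_a) & set(res_b)):
            coords_a.append(res_a[r])
            coords_b.append(res_b[r])
            pairing.append(((chain_a, r), (chain_b, r)))
    if not coords_a:
        return np.empty((0, 3)), np.empty((0, 3)), []
    return np.array(coords_a), np.array(coords_b), pairing


def principal_dimensions(coords: np.ndarray) -> np.ndarray:
    """Extents along the principal axes of the coordinate covariance.

    Returns the three (max - min) extents projected onto the covariance
    eigenvectors, sorted descending — the usual "~a x b x c A" description
    of an assembly's overall dimensions.  Degenerate (coplanar/collinear)
    input is allowed; trailing extents may be ~0.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected (N, 3) coordinates")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 atoms")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / X.shape[0]
    _, vecs = np.linalg.eigh(cov)
    proj = Xc @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    return np.sort(extents)[::-1]


def _window_direction(coords: np.ndarray) -> np.ndarray:
    """Principal axis of a Calpha window, oriented N-terminal to C-terminal."""
    Xc = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(Xc.T @ Xc)
    axis = vecs[:, -1]
    if np.dot(axis, coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


def bend_angle(model, chain: str, residue_window_n: tuple[int, int],
               residue_window_c: tuple[int, int]) -> float:
    """Kink angle (degrees) between two helix segments of one chain.

    Each window is a consecutive author-numbered residue range ``(first,
    last)`` with at least 7 Calpha atoms.  The angle between the two
    windows' principal axes (each pointed along the chain direction) is
    returned; 0 means straight, 30 means a 30-degree bend at the hinge.
    """
    dirs = []
    for lo, hi in (residue_window_n, residue_window_c):
        ca = model.ca_residues(chain)
        coords = []
        for r in range(lo, hi + 1):
            if r not in ca:
                raise ValueError(f"residue {chain}/{r} missing Calpha")
            coords.append(ca[r])
        if len(coords) < 7:
            raise ValueError("bend windows need >= 7 consecutive Calpha")
        dirs.append(_window_direction(np.array(coords)))
    cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))
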