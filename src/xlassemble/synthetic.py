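"""Ground-truth toy assemblies and simulated crosslink sets.

The generator emulates the geometric situation the analysis assumes: a
multi-chain rigid assembly of helical folds (ideal alpha-helix, helix
hairpin, or alpha-solenoid-like arc) with lysine-like anchor sites at
regular spacing, crosslinks sampled from anchor pairs that are genuinely
within reach of the crosslinker in the true assembly, decoy (geometrically
violated) links mimicking false identifications, and a synthetic FDR score
column.  Everything is deterministic from the seed, and every generation
parameter is recorded so a run can be reproduced exactly.

Chain traces are Calpha-only: an ideal alpha-helix has a 1.5 A rise,
2.3 A radius and 100 degrees of turn per residue.  Anchors ("lysine-like"
residues, written as LYS) are every k-th residue (default k=7) — crosslink
geometry depends on anchor spacing, not on sequence identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import RigidTransform, random_rotation, rotation_about_axis
from .structio import AtomRecord, ChainMap, ChainSpan, StructureModel
from .xlinks import Crosslink, CrosslinkSet, DEFAULT_CUTOFF

logger = logging.getLogger(__name__)

FOLDS = ("helix", "helix_hairpin", "solenoid")
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

HELIX_RISE = 1.5      # A per residue
HELIX_RADIUS = 2.3    # A
HELIX_TURN = 100.0    # degrees per residue
ANCHOR_EVERY = 7      # residue spacing of lysine-like anchors
MIN_CHAIN_SEP = 4.5   # A, minimum interchain Calpha distance at placement


@dataclass
class SyntheticAssembly:
    """A generated assembly plus everything needed to test recovery."""

    model: StructureModel
    cmap: ChainMap
    anchors: list[tuple[str, int]]          # (chain, res_seq)
    links: CrosslinkSet | None
    truth_transform: RigidTransform | None  # pose applied to the mobile chains
    gen_params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Chain traces
# ---------------------------------------------------------------------------

def _helix_trace(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    ang = np.deg2rad(HELIX_TURN) * i
    return np.column_stack([HELIX_RADIUS * np.cos(ang),
                            HELIX_RADIUS * np.sin(ang),
                            HELIX_RISE * i])


def _hairpin_trace(n: int) -> np.ndarray:
    """Two antiparallel helices joined at the top, ~10.5 A apart."""
    n1 = n // 2
    n2 = n - n1
    up = _helix_trace(n1)
    down = _helix_trace(n2)
    down = down * np.array([1.0, 1.0, -1.0])          # descending
    down += np.array([10.5, 0.0, HELIX_RISE * (n1 - 1)])
    return np.vstack([up, down])


def _solenoid_trace(n: int, super_radius: float = 9.0,
                    super_pitch: float = 15.0) -> np.ndarray:
    """Helix of helices: a local alpha-helix wound on a superhelical path.

    The superhelical path is a wide helix (radius ``super_radius``, pitch
    ``super_pitch`` A per superhelical turn) traversed at the local helix's
    1.5 A/residue rise; the Calpha trace spirals around that path at the
    local helical radius.  The result is a thick tube (~2x(super_radius +
    2.3) A across), the toy analog of a stacked-repeat alpha-solenoid.
    """
    s = HELIX_RISE * np.arange(n, dtype=float)      # arc length along path
    circ = np.sqrt((2 * np.pi * super_radius) ** 2 + super_pitch ** 2)
    phi = 2 * np.pi * s / circ                       # superhelical angle
    path = np.column_stack([super_radius * np.cos(phi),
                            super_radius * np.sin(phi),
                            super_pitch * phi / (2 * np.pi)])
    # local frame: tangent T, inward normal N, binormal B
    T = np.column_stack([-super_radius * np.sin(phi),
                         super_radius * np.cos(phi),
                         np.full(n, super_pitch / (2 * np.pi))])
    T /= np.linalg.norm(T, axis=1)[:, None]
    N = np.column_stack([-np.cos(phi), -np.sin(phi), np.zeros(n)])
    B = np.cross(T, N)
    theta = np.deg2rad(HELIX_TURN) * np.arange(n, dtype=float)
    return path + HELIX_RADIUS * (np.cos(theta)[:, None] * N
                                  + np.sin(theta)[:, None] * B)


_TRACES = {"helix": _helix_trace, "helix_hairpin": _hairpin_trace,
           "solenoid": _solenoid_trace}


def _chain_atoms(chain_id: str, coords: np.ndarray,
                 anchor_every: int) -> list[AtomRecord]:
    atoms = []
    for i, p in enumerate(coords):
        res_seq = i + 1
        is_anchor = (i % anchor_every) == 0
        atoms.append(AtomRecord(
            chain_id=chain_id, res_seq=res_seq, ins_code="",
            res_name="LYS" if is_anchor else "ALA", atom_name="CA",
            element="C", pos=(float(p[0]), float(p[1]), float(p[2]))))
    return atoms


def _perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, w)
    return p / np.linalg.norm(p)


def generate_assembly(n_chains: int = 2, chain_length: int = 60,
                      fold: str = "helix_hairpin", seed: int = 0,
                      anchor_every: int = ANCHOR_EVERY,
                      min_separation: float = MIN_CHAIN_SEP,
                      max_tilt_deg: float = 10.0) -> StructureModel:
    """Generate an ``n_chains`` rigid assembly of identical folds.

    The first chain sits centered at the origin.  Each further chain packs
    side-by-side against the existing assembly, the way elongated helical
    subunits pack in coiled-coil / solenoid complexes: its long axis stays
    aligned with the first chain's principal axis up to a random tilt
    (<= ``max_tilt_deg``), with a random roll about its own axis, a random
    flip (parallel/antiparallel), and a random axial offset, then it is
    pushed outward along a random perpendicular direction to the closest
    position where all interchain Calpha distances are >=
    ``min_separation``.  The resulting contact runs along the chains, so
    crosslinkable anchor pairs are spread over an extended interface —
    the geometry under which crosslinks can localize a subunit at all.
    """
    if chain_length < 20:
        raise ValueError("chain_length must be >= 20")
    if fold not in _TRACES:
        raise ValueError(f"unknown fold {fold!r}; choose from {FOLDS}")
    if n_chains < 1 or n_chains > len(_CHAIN_IDS):
        raise ValueError("n_chains out of range")
    rng = np.random.default_rng(seed)
    base = _TRACES[fold](chain_length)
    base = base - base.mean(axis=0)
    cov = base.T @ base
    long_axis = np.linalg.eigh(cov)[1][:, -1]
    axial_len = float(np.ptp(base @ long_axis))
    perp0 = _perpendicular(long_axis)

    placed: list[np.ndarray] = []
    atoms: list[AtomRecord] = []
    for k in range(n_chains):
        if k == 0:
            coords = base.copy()
        else:
            coords = None
            for _attempt in range(50):
                R = rotation_about_axis(long_axis, rng.uniform(0.0, 2 * np.pi))
                if rng.random() < 0.5:  # antiparallel copy
                    R = rotation_about_axis(perp0, np.pi) @ R
                tilt_axis = rotation_about_axis(
                    long_axis, rng.uniform(0.0, 2 * np.pi)) @ perp0
                R = rotation_about_axis(
                    tilt_axis, np.deg2rad(rng.uniform(0.0, max_tilt_deg))) @ R
                rotated = base @ R.T
                rotated = rotated + long_axis * rng.uniform(-0.15, 0.15) * axial_len
                d = rotation_about_axis(long_axis,
                                        rng.uniform(0.0, 2 * np.pi)) @ perp0
                existing = np.vstack(placed)
                for s in np.arange(0.0, 300.0, 0.5):
                    trial = rotated + s * d
                    if cdist(trial, existing).min() >= min_separation:
                        coords = trial
                        break
                if coords is not None:
                    break
            if coords is None:
                raise RuntimeError("could not place chain without clashes")
        placed.append(coords)
        atoms.extend(_chain_atoms(_CHAIN_IDS[k], coords, anchor_every))
    return StructureModel(atoms, title=f"synthetic-{fold}",
                          source_format="pdb")


def build_chainmap(model: StructureModel,
                   protein_names: Sequence[str] | None = None) -> ChainMap:
    """One protein per chain, offset 0, full observed residue range."""
    ranges = model.residue_ranges()
    chains = model.chain_ids
    if protein_names is None:
        protein_names = [f"P{i + 1}" for i in range(len(chains))]
    spans = []
    for name, cid in zip(protein_names, chains):
        lo, hi = ranges[cid]
        spans.append(ChainSpan(protein=name, chain_id=cid, offset=0,
                               first=lo, last=hi))
    return ChainMap(spans)


def anchor_sites(model: StructureModel) -> list[tuple[str, int]]:
    """All lysine-like (LYS) Calpha residues, file order."""
    return [(a.chain_id, a.res_seq) for a in model.atoms
            if a.res_name == "LYS" and a.atom_name == "CA"]


# ---------------------------------------------------------------------------
# Crosslink simulation
# ---------------------------------------------------------------------------

def simulate_crosslinks(model: StructureModel, n_true: int = 10,
                        decoy_rate: float = 0.0, noise_sd: float = 0.0,
                        cutoff: float = DEFAULT_CUTOFF, margin: float = 2.0,
                        seed: int = 0, cmap: ChainMap | None = None,
                        include_intra: bool = False,
                        fdr_threshold: float = 0.05) -> CrosslinkSet:
    """Sample crosslinks from anchor pairs of a ground-truth assembly.

    True links come uniformly without replacement from anchor pairs whose
    true Calpha-Calpha distance is <= cutoff - margin (with optional
    Gaussian jitter of ``noise_sd`` blurring that acceptance boundary);
    decoys from pairs with distance > cutoff + margin, sized so decoys form
    a ``decoy_rate`` fraction of the whole set:
    ``n_decoy = round(n_true * decoy_rate / (1 - decoy_rate))``.
    True links get fdr ~ U[0, 0.01]; decoys fdr ~ U[0, fdr_threshold].
    Only the residue pairs are recorded — distances stay hidden, as in a
    real identification table.
    """
    if not 0.0 <= decoy_rate < 1.0:
        raise ValueError("decoy_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if cmap is None:
        cmap = build_chainmap(model)
    chain_to_protein = {s.chain_id: s.protein for s in cmap.spans}
    offsets = {s.chain_id: s.offset for s in cmap.spans}

    anchors = anchor_sites(model)
    coords = np.array([model.ca_coord(c, r) for c, r in anchors])
    pairs = []
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            inter = anchors[i][0] != anchors[j][0]
            if not inter and not include_intra:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            pairs.append((anchors[i], anchors[j], d))

    jitter = rng.normal(0.0, noise_sd, size=len(pairs)) if noise_sd > 0 \
        else np.zeros(len(pairs))
    true_pool = [p for p, dj in zip(pairs, jitter)
                 if p[2] + dj <= cutoff - margin]
    decoy_pool = [p for p in pairs if p[2] > cutoff + margin]
    if len(true_pool) < n_true:
        raise ValueError(
            f"only {len(true_pool)} candidate anchor pairs within "
            f"{cutoff - margin:.1f} A; need {n_true}")
    n_decoy = int(round(n_true * decoy_rate / (1.0 - decoy_rate)))
    if len(decoy_pool) < n_decoy:
        raise ValueError(
            f"only {len(decoy_pool)} decoy candidates beyond "
            f"{cutoff + margin:.1f} A; need {n_decoy}")

    chosen_true = [true_pool[i] for i in
                   rng.choice(len(true_pool), size=n_true, replace=False)]
    chosen_decoy = [decoy_pool[i] for i in
                    rng.choice(len(decoy_pool), size=n_decoy, replace=False)] \
        if n_decoy else []

    links = []
    for (ca, cb, _d) in chosen_true:
        links.append(_make_link(ca, cb, chain_to_protein, offsets,
                                fdr=float(rng.uniform(0.0, 0.01))))
    for (ca, cb, _d) in chosen_decoy:
        links.append(_make_link(ca, cb, chain_to_protein, offsets,
                                fdr=float(rng.uniform(0.0, fdr_threshold))))
    order = rng.permutation(len(links))
    links = [links[i] for i in order]
    logger.info("simulated %d true + %d decoy crosslinks (seed %d)",
                n_true, n_decoy, seed)
    return CrosslinkSet(links, fdr_threshold=fdr_threshold,
                        provenance=f"synthetic(seed={seed})")


def _make_link(addr_a, addr_b, chain_to_protein, offsets, fdr) -> Crosslink:
    (ca, ra), (cb, rb) = addr_a, addr_b
    pa, pb = chain_to_protein[ca], chain_to_protein[cb]
    kind = "intra_subunit" if pa == pb else "inter_subunit"
    return Crosslink(pa, ra - offsets[ca], pb, rb - offsets[cb],
                     fdr=fdr, spectra_count=1, kind=kind)


# ---------------------------------------------------------------------------
# Pose perturbation
# ---------------------------------------------------------------------------

def perturb_pose(model: StructureModel, chains: Sequence[str],
                 max_rot_deg: float = 60.0, max_trans: float = 20.0,
                 seed: int = 0) -> tuple[StructureModel, RigidTransform]:
    """Apply a seeded random rigid transform to the named chains.

    Rotation: random axis, angle uniform in [0, max_rot_deg], about the
    selected chains' Calpha centroid.  Translation: uniform in a ball of
    radius ``max_trans``.  Returns the perturbed model and the global
    transform that was applied (its inverse restores the input exactly).
    """
    missing = [c for c in chains if c not in model.chain_ids]
    if missing:
        raise KeyError(f"unknown chain(s) {missing}")
    rng = np.random.default_rng(seed)
    if max_rot_deg > 0:
        axis = rng.normal(size=3)
        angle = np.deg2rad(rng.uniform(0.0, max_rot_deg))
        R = rotation_about_axis(axis, angle)
    else:
        rng.normal(size=3)  # keep stream layout stable
        rng.uniform(0.0, 1.0)
        R = np.eye(3)
    if max_trans > 0:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        t = d * max_trans * rng.uniform(0.0, 1.0) ** (1.0 / 3.0)
    else:
        t = np.zeros(3)
    center = model.ca_coords(chains=chains).mean(axis=0)
    tr = RigidTransform.about_point(R, center, t)
    return model.transformed(tr.rotation, tr.translation, chains=chains), tr


# ---------------------------------------------------------------------------
# Full docking problem
# ---------------------------------------------------------------------------

@dataclass
class DockingProblem:
    """A self-contained pose-recovery instance with known ground truth."""

    fixed: StructureModel        # scaffold chain(s), true coordinates
    mobile_true: StructureModel  # mobile chain(s) at the true pose
    mobile_start: StructureModel  # mobile chain(s) at a perturbed pose
    links: CrosslinkSet
    cmap: ChainMap
    perturbation: RigidTransform  # maps true -> start
    gen_params: dict


def make_docking_problem(seed: int = 0, n_chains: int = 2,
                         chain_length: int = 60, fold: str = "helix_hairpin",
                         n_true: int = 10, decoy_rate: float = 0.0,
                         noise_sd: float = 0.0, cutoff: float = DEFAULT_CUTOFF,
                         margin: float = 2.0, max_rot_deg: float = 60.0,
                         max_trans: float = 20.0) -> DockingProblem:
    """Generate assembly + links, then displace the last chain set.

    The first chain is the fixed scaffold; the remaining chains form the
    mobile rigid body, displaced by a seeded random pose.  Recovering the
    mobile body's true pose from the crosslinks is the benchmark task.
    """
    ss = np.random.SeedSequence(seed)
    s_asm, s_links, s_pert = [int(c.generate_state(1)[0] % (2 ** 31))
                              for c in ss.spawn(3)]
    model = generate_assembly(n_chains=n_chains, chain_length=chain_length,
                              fold=fold, seed=s_asm)
    cmap = build_chainmap(model)
    links = simulate_crosslinks(model, n_true=n_true, decoy_rate=decoy_rate,
                                noise_sd=noise_sd, cutoff=cutoff,
                                margin=margin, seed=s_links, cmap=cmap)
    chains = model.chain_ids
    fixed_chains, mobile_chains = chains[:1], chains[1:]
    perturbed, tr = perturb_pose(model, mobile_chains,
                                 max_rot_deg=max_rot_deg,
                                 max_trans=max_trans, seed=s_pert)
    gen_params = dict(seed=seed, n_chains=n_chains, chain_length=chain_length,
                      fold=fold, n_true=n_true, decoy_rate=decoy_rate,
                      noise_sd=noise_sd, cutoff=cutoff, margin=margin,
                      max_rot_deg=max_rot_deg, max_trans=max_trans,
                      stage_seeds=dict(assembly=s_asm, links=s_links,
                                       perturb=s_pert))
    return DockingProblem(
        fixed=model.select(chains=fixed_chains),
        mobile_true=model.select(chains=mobile_chains),
        mobile_start=perturbed.select(chains=mobile_chains),
        links=links, cmap=cmap, perturbation=tr, gen_params=gen_params)
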