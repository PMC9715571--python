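"""Rigid-body assembly under crosslink distance restraints.

A mobile subunit (treated as one rigid body) is placed against a fixed
scaffold by minimizing a flat-bottom restraint score

    score = sum_links  w_viol * max(0, d_link - cutoff)^2  +  n_clashes * w_clash

where d_link is the Calpha-Calpha distance of a crosslinked residue pair
(shortest assignment for copy-ambiguous links) and a clash is a
fixed-mobile Calpha pair closer than the clash distance.  The score is
zero exactly when every mappable link is within the cutoff and no clash
exists — the "accounts for all crosslinks" condition used to select an
integrative model.

The search runs independent restarts: a uniform random orientation and a
random placement of the mobile centroid in a shell around the centroid of
the fixed-side crosslink anchors, refined by simulated annealing over the
6 rigid-body degrees of freedom (geometric cooling) and finished with
greedy coordinate descent.  Near-duplicate poses (pairwise Calpha RMSD
within 2 A) are merged keeping the better score; ranking is by score
ascending with ties broken by restart index.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, random_rotation, rotation_about_axis
from .structio import ChainMap, StructureModel
from .xlinks import CrosslinkSet, link_distances, DEFAULT_CUTOFF

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RestraintScoreParams:
    cutoff: float = DEFAULT_CUTOFF      # A, flat-bottom edge
    violation_weight: float = 1.0       # per A^2 beyond the cutoff
    clash_distance: float = 3.0         # A, Calpha-Calpha
    clash_weight: float = 100.0         # per clashing pair
    unmappable_policy: str = "ignore"   # or "count"

    def __post_init__(self) -> None:
        if self.violation_weight < 0 or self.clash_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.cutoff <= self.clash_distance:
            raise ValueError("cutoff must exceed clash_distance")
        if self.unmappable_policy not in ("ignore", "count"):
            raise ValueError("unmappable_policy must be 'ignore' or 'count'")


@dataclass(frozen=True)
class ScoreCounts:
    n_satisfied: int
    n_violated: int
    n_clashes: int
    n_unmappable: int = 0


@dataclass(frozen=True)
class DockResult:
    transform: RigidTransform   # global: applied to the mobile model's input coords
    score: float
    n_satisfied: int
    n_violated: int
    n_clashes: int
    seed: int                   # restart index within the run
    rank: int


class _ScoreContext:
    """Precomputed link geometry for fast repeated pose evaluation."""

    def __init__(self, fixed: StructureModel, mobile: StructureModel,
                 links: CrosslinkSet, cmap: ChainMap,
                 params: RestraintScoreParams):
        self.params = params
        fixed_chains = set(fixed.chain_ids)
        mobile_chains = set(mobile.chain_ids)
        self.fixed_ca = fixed.ca_coords()
        self.mobile_ca = mobile.ca_coords()
        self.tree = cKDTree(self.fixed_ca)

        fixed_pts: list[list[np.ndarray]] = []
        mobile_pts: list[list[np.ndarray]] = []
        n_unmappable = 0
        for ln in links:
            fa, ma = self._side(fixed, mobile, fixed_chains, mobile_chains,
                                cmap, ln.protein_a, ln.residue_a)
            fb, mb = self._side(fixed, mobile, fixed_chains, mobile_chains,
                                cmap, ln.protein_b, ln.residue_b)
            if fa and mb:
                fixed_pts.append(fa)
                mobile_pts.append(mb)
            elif fb and ma:
                fixed_pts.append(fb)
                mobile_pts.append(ma)
            else:
                n_unmappable += 1
        if not fixed_pts:
            raise ValueError("no usable inter-unit crosslinks between the "
                             "fixed and mobile models")
        self.n_links = len(fixed_pts)
        self.n_unmappable = n_unmappable
        self.simple = all(len(f) == 1 and len(m) == 1
                          for f, m in zip(fixed_pts, mobile_pts))
        if self.simple:
            self.F = np.array([f[0] for f in fixed_pts])
            self.M0 = np.array([m[0] for m in mobile_pts])
        else:
            self.fixed_pts = [np.array(f) for f in fixed_pts]
            self.mobile_pts = [np.array(m) for m in mobile_pts]
            self.F = np.array([f[0] for f in fixed_pts])  # for anchor centroid

    @staticmethod
    def _side(fixed, mobile, fixed_chains, mobile_chains, cmap, protein, residue):
        fixed_hits, mobile_hits = [], []
        for chain, res in cmap.map_residue(protein, residue):
            if chain in fixed_chains:
                p = fixed.ca_coord(chain, res)
                if p is not None:
                    fixed_hits.append(p)
            if chain in mobile_chains:
                p = mobile.ca_coord(chain, res)
                if p is not None:
                    mobile_hits.append(p)
        return fixed_hits, mobile_hits

    @property
    def anchor_centroid(self) -> np.ndarray:
        """Centroid of the fixed-side crosslink anchors."""
        return self.F.mean(axis=0)

    def link_distances(self, R: np.ndarray, T: np.ndarray) -> np.ndarray:
        if self.simple:
            mob = self.M0 @ R.T + T
            return np.sqrt(np.sum((self.F - mob) ** 2, axis=1))
        out = np.empty(self.n_links)
        for i, (f, m) in enumerate(zip(self.fixed_pts, self.mobile_pts)):
            mob = m @ R.T + T
            d = np.sqrt(((f[:, None, :] - mob[None, :, :]) ** 2).sum(axis=2))
            out[i] = d.min()
        return out

    def evaluate(self, R: np.ndarray, T: np.ndarray) -> tuple[float, ScoreCounts]:
        p = self.params
        d = self.link_distances(R, T)
        excess = np.maximum(0.0, d - p.cutoff)
        score = p.violation_weight * float(np.sum(excess ** 2))
        mob_ca = self.mobile_ca @ R.T + T
        n_clashes = int(sum(len(hits) for hits in self.tree.query_ball_point(
            mob_ca, p.clash_distance)))
        score += p.clash_weight * n_clashes
        n_sat = int(np.sum(d <= p.cutoff))
        n_unmap = self.n_unmappable if p.unmappable_policy == "count" else 0
        return score, ScoreCounts(n_sat, self.n_links - n_sat, n_clashes,
                                  n_unmap)

    def objective(self, R: np.ndarray, T: np.ndarray,
                  centering_weight: float = 0.0) -> float:
        """Search objective: the restraint score plus, optionally, a weak
        quadratic pull on all link distances.

        The flat-bottom score is exactly zero on a whole region of poses
        (every restraint is a one-sided bound), so a search guided by it
        alone stalls anywhere on that plateau.  The centering term,
        ``centering_weight * sum(d^2)``, acts like the distance-decreasing
        part of a crosslink likelihood and selects a unique pose within the
        feasible region; its weight is kept small enough that it can never
        trade a real violation away.  Reported scores never include it.
        """
        p = self.params
        d = self.link_distances(R, T)
        excess = np.maximum(0.0, d - p.cutoff)
        score = p.violation_weight * float(np.sum(excess ** 2))
        mob_ca = self.mobile_ca @ R.T + T
        n_clashes = int(sum(len(hits) for hits in self.tree.query_ball_point(
            mob_ca, p.clash_distance)))
        score += p.clash_weight * n_clashes
        if centering_weight:
            score += centering_weight * float(np.sum(d ** 2))
        return score


def restraint_score(fixed_model: StructureModel, mobile_model: StructureModel,
                    transform: RigidTransform, links: CrosslinkSet,
                    cmap: ChainMap,
                    params: RestraintScoreParams | None = None
                    ) -> tuple[float, ScoreCounts]:
    """Flat-bottom crosslink restraint score of one candidate pose.

    ``transform`` is applied to the mobile model's coordinates; the fixed
    model stays put.  Deterministic for fixed inputs.
    """
    params = params or RestraintScoreParams()
    ctx = _ScoreContext(fixed_model, mobile_model, links, cmap, params)
    return ctx.evaluate(transform.rotation, transform.translation)


# ---------------------------------------------------------------------------
# Stochastic rigid-body search
# ---------------------------------------------------------------------------

def _pose_to_global(R: np.ndarray, t: np.ndarray,
                    c0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(rotation about centroid c0, centroid shift t) -> global (R, T)."""
    return R, c0 + t - R @ c0


def _anneal(ctx: _ScoreContext, c0: np.ndarray, R: np.ndarray, t: np.ndarray,
            rng: np.random.Generator, n_steps: int,
            centering: float = 0.0) -> tuple:
    score = ctx.objective(*_pose_to_global(R, t, c0), centering)
    best = (score, R.copy(), t.copy())
    T0 = max(score * 0.1, 10.0)
    alpha = (1e-3) ** (1.0 / max(n_steps, 1))
    temp = T0
    for step in range(n_steps):
        frac = 1.0 - step / n_steps
        rot_scale = np.deg2rad(2.0 + 18.0 * frac)
        trans_scale = 0.5 + 4.5 * frac
        if rng.random() < 0.5:
            axis = rng.normal(size=3)
            dR = rotation_about_axis(axis, rng.normal(0.0, rot_scale))
            R_new, t_new = dR @ R, t
        else:
            R_new, t_new = R, t + rng.normal(0.0, trans_scale, size=3)
        s_new = ctx.objective(*_pose_to_global(R_new, t_new, c0), centering)
        delta = s_new - score
        if delta <= 0 or rng.random() < np.exp(-delta / temp):
            R, t, score = R_new, t_new, s_new
            if score < best[0]:
                best = (score, R.copy(), t.copy())
        temp *= alpha
    return best


_AXES = np.eye(3)


def _coordinate_descent(ctx: _ScoreContext, c0: np.ndarray, R: np.ndarray,
                        t: np.ndarray, centering: float = 0.0,
                        tol: float = 1e-6, max_sweeps: int = 200) -> tuple:
    score = ctx.objective(*_pose_to_global(R, t, c0), centering)
    rot_step = np.deg2rad(4.0)
    trans_step = 1.5
    for _sweep in range(max_sweeps):
        improved = False
        for axis in _AXES:
            for sign in (1.0, -1.0):
                dR = rotation_about_axis(axis, sign * rot_step)
                s_new = ctx.objective(*_pose_to_global(dR @ R, t, c0), centering)
                if s_new < score - tol:
                    R, score, improved = dR @ R, s_new, True
        for axis in _AXES:
            for sign in (1.0, -1.0):
                t_new = t + sign * trans_step * axis
                s_new = ctx.objective(*_pose_to_global(R, t_new, c0), centering)
                if s_new < score - tol:
                    t, score, improved = t_new, s_new, True
        if not improved:
            rot_step *= 0.5
            trans_step *= 0.5
            if rot_step < np.deg2rad(0.05) and trans_step < 0.02:
                break
    return score, R, t


def dock_rigid(fixed_model: StructureModel, mobile_model: StructureModel,
               links: CrosslinkSet, cmap: ChainMap,
               params: RestraintScoreParams | None = None,
               n_restarts: int = 50, seed: int = 0, sa_steps: int = 300,
               dedup_rmsd: float = 2.0, centering_weight: float = 0.0,
               shell_radius: float | None = None) -> list[DockResult]:
    """Restart-based rigid-body docking of ``mobile_model`` onto the scaffold.

    Each restart draws a uniform random orientation (quaternion method) and
    places the mobile centroid uniformly in a ball of radius
    ``shell_radius`` (default: the restraint cutoff) around the fixed-side
    crosslink-anchor centroid, then refines by simulated annealing and
    greedy coordinate descent on the centering-regularized objective (see
    :meth:`_ScoreContext.objective`), with a final descent on the pure
    restraint score.  Results are deduplicated at ``dedup_rmsd`` and ranked
    by (reported score, restart index).  Bit-reproducible from ``seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    params = params or RestraintScoreParams()
    ctx = _ScoreContext(fixed_model, mobile_model, links, cmap, params)
    c0 = ctx.mobile_ca.mean(axis=0)
    target = ctx.anchor_centroid
    if shell_radius is None:
        shell_radius = params.cutoff

    children = np.random.SeedSequence(seed).spawn(n_restarts)
    raw: list[tuple[float, np.ndarray, np.ndarray, int]] = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        R0 = random_rotation(rng)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = shell_radius * rng.uniform(0.0, 1.0) ** (1.0 / 3.0)
        t0 = target + radius * direction - c0
        _, R1, t1 = _anneal(ctx, c0, R0, t0, rng, sa_steps, centering_weight)
        if centering_weight:
            _, R1, t1 = _coordinate_descent(ctx, c0, R1, t1, centering_weight)
        score, R2, t2 = _coordinate_descent(ctx, c0, R1, t1)
        raw.append((score, R2, t2, k))

    raw.sort(key=lambda r: (r[0], r[3]))
    kept: list[tuple[float, np.ndarray, np.ndarray, int, np.ndarray]] = []
    for score, R, t, k in raw:
        Rg, Tg = _pose_to_global(R, t, c0)
        mob_ca = ctx.mobile_ca @ Rg.T + Tg
        dup = any(np.sqrt(np.mean(np.sum((mob_ca - prev[4]) ** 2, axis=1)))
                  <= dedup_rmsd for prev in kept)
        if not dup:
            kept.append((score, Rg, Tg, k, mob_ca))

    results = []
    for rank, (score, Rg, Tg, k, _ca) in enumerate(kept, start=1):
        _, counts = ctx.evaluate(Rg, Tg)
        results.append(DockResult(
            transform=RigidTransform(Rg, Tg), score=float(score),
            n_satisfied=counts.n_satisfied, n_violated=counts.n_violated,
            n_clashes=counts.n_clashes, seed=k, rank=rank))
    logger.info("docking: %d restarts -> %d distinct poses; best score %.4g",
                n_restarts, len(results), results[0].score)
    return results


def refine_pose(fixed_model: StructureModel, mobile_model: StructureModel,
                transform: RigidTransform, links: CrosslinkSet,
                cmap: ChainMap, params: RestraintScoreParams | None = None,
                sa_steps: int = 0, seed: int = 0
                ) -> tuple[RigidTransform, float, ScoreCounts]:
    """Refine a single supplied pose (optionally with annealing first).

    With ``sa_steps=0`` this is pure greedy coordinate descent from the
    given transform — e.g. to polish a pose that is already believed
    near-optimal.  Returns the refined global transform, score and counts.
    """
    params = params or RestraintScoreParams()
    ctx = _ScoreContext(fixed_model, mobile_model, links, cmap, params)
    c0 = ctx.mobile_ca.mean(axis=0)
    # convert global (R, T) to centroid-relative (R, t)
    R = transform.rotation
    t = transform.translation + R @ c0 - c0
    if sa_steps > 0:
        rng = np.random.default_rng(seed)
        _, R, t = _anneal(ctx, c0, R, t, rng, sa_steps)
    score, R, t = _coordinate_descent(ctx, c0, R, t)
    Rg, Tg = _pose_to_global(R, t, c0)
    _, counts = ctx.evaluate(Rg, Tg)
    return RigidTransform(Rg, Tg), float(score), counts


# ---------------------------------------------------------------------------
# Candidate-model ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedModel:
    label: str
    score: float
    counts: ScoreCounts
    violated: tuple  # LinkDistance records with d > cutoff
    rank: int


def rank_models(candidates: Sequence, links: CrosslinkSet, cmap: ChainMap,
                params: RestraintScoreParams | None = None) -> list[RankedModel]:
    """Score complete candidate assemblies in place and rank them.

    ``candidates`` is a sequence of models or ``(label, model)`` pairs.
    Each candidate is scored with the identity transform: flat-bottom
    violation penalties over all mappable links plus the inter-chain clash
    penalty.  Output is sorted ascending by (score, input order) and keeps
    the per-candidate violated-link report.
    """
    params = params or RestraintScoreParams()
    if len(candidates) == 0:
        raise ValueError("need at least one candidate model")
    scored = []
    for idx, cand in enumerate(candidates):
        if isinstance(cand, tuple):
            label, model = cand
        else:
            label, model = f"model_{idx + 1}", cand
        dists = link_distances(model, links, cmap, cutoff=params.cutoff)
        mappable = [d for d in dists if d.mappable]
        if not mappable:
            raise ValueError(f"candidate {label!r} is missing all linked chains")
        excess = np.array([max(0.0, d.distance - params.cutoff)
                           for d in mappable])
        n_clashes = _interchain_clashes(model, params.clash_distance)
        score = params.violation_weight * float(np.sum(excess ** 2)) \
            + params.clash_weight * n_clashes
        n_sat = int(sum(d.satisfied for d in mappable))
        n_unmap = (len(dists) - len(mappable)
                   if params.unmappable_policy == "count" else 0)
        counts = ScoreCounts(n_sat, len(mappable) - n_sat, n_clashes, n_unmap)
        violated = tuple(d for d in mappable if not d.satisfied)
        scored.append((score, idx, label, counts, violated))
    scored.sort(key=lambda s: (s[0], s[1]))
    return [RankedModel(label=label, score=float(score), counts=counts,
                        violated=violated, rank=rank)
            for rank, (score, _idx, label, counts, violated)
            in enumerate(scored, start=1)]


def _interchain_clashes(model: StructureModel, clash_distance: float) -> int:
    ca = [(a.chain_id, np.asarray(a.pos)) for a in model.atoms
          if a.atom_name == "CA"]
    if len(ca) < 2:
        return 0
    coords = np.array([p for _c, p in ca])
    chains = np.array([c for c, _p in ca])
    tree = cKDTree(coords)
    n = 0
    for i, j in tree.query_pairs(clash_distance):
        if chains[i] != chains[j]:
            n += 1
    return n
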