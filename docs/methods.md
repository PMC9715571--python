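# Methods

## Restraint model

A BS3 crosslink between two lysines is treated as an upper bound on their
Cα–Cα Euclidean distance. The default bound is **30 Å**, inclusive at the
boundary: the 11.4 Å spacer plus two lysine side chains plus backbone
flexibility. Solvent-accessible surface distance is deliberately not used
(no pathing convention is standard, and Euclidean distance is the
conservative, reproducible choice). Crosslink tables are filtered at
FDR ≤ 0.05 (inclusive), deduplicated over unordered residue pairs (max
spectra count, min FDR kept), and classified inter-/intra-subunit from the
protein names. Residues outside every mapped range — disordered regions,
absent subunits — make a link *unmapped*: it is counted and reported but
never scored, so the accounting `total = inter + intra + ambiguous` holds
through every stage. A protein mapped to two chains (homodimer) makes a
link copy-ambiguous; it resolves to the assignment with the shorter
distance, the standard permissive convention, and the choice is logged.

## Docking score and search

A candidate pose of a mobile rigid body against a fixed scaffold is scored

    score = Σ_links  w_viol · max(0, d − cutoff)²  +  n_clashes · w_clash

with `w_viol = 1` per Å², `cutoff = 30 Å`, a clash being a fixed–mobile
Cα pair closer than 3.0 Å, and `w_clash = 100` per pair (large enough that
one clash always outweighs sub-Å restraint violations, small enough to
leave the annealer a gradient). The score is zero exactly when every
mappable link is within the cutoff and no clash exists. Scoring is
deterministic and frame-independent (invariant under a joint rigid
transform of fixed, mobile and pose).

The search runs `n_restarts` independent trajectories. Each draws a
uniform random orientation (quaternion method) and places the mobile
centroid uniformly in a ball (radius = cutoff) around the centroid of the
fixed-side link anchors, then refines by simulated annealing over the six
rigid-body degrees of freedom — Metropolis acceptance, geometric cooling
over three decades, move scales shrinking linearly from 20°/5 Å to
2°/0.5 Å — followed by greedy coordinate descent (per-axis rotations and
translations, step-halving, convergence when improvements fall below 1e-6
or steps below 0.05°/0.02 Å). Poses within 2 Å pairwise Cα RMSD are
merged keeping the better score; ranking is by (score, restart index).
Everything is reproducible bit-for-bit from the run seed, which fans out
to per-restart seeds via `numpy.random.SeedSequence.spawn`.

An optional `centering_weight` adds `w_c · Σ d²` to the *search* objective
only (reported scores never include it). It mimics the
distance-decreasing part of likelihood-based crosslink scores and selects
a unique, compact contact pose inside the otherwise flat zero-score
region. It is off by default because it biases the selected pose toward
shorter-than-observed link distances; see "information content" below.

Candidate-assembly ranking (`rank_models`) applies the same score with the
identity transform to complete models, using inter-chain Cα clashes, and
reports each candidate's violated links by name and distance — the
"accounts for all crosslinks except …" accounting used to select an
integrative model.

## Superposition, dimensions, bend angles

Superposition is the Kabsch algorithm (SVD with determinant sign
correction; reflections excluded), unweighted over an explicit Cα pairing
by author residue number — no outlier trimming, so the quoted RMSD covers
the stated atom count. For homodimers both chain assignments are evaluated
and the lower-RMSD one kept (logged). Principal dimensions are the
max-minus-min extents along the eigenvectors of the Cα covariance matrix,
sorted descending — reproducible on coordinates alone, unlike map-derived
measurements. Helix bend angles are measured between the principal axes of
two user-specified Cα windows (≥ 7 residues each), each axis oriented
along the N→C progression; the hinge is an input, not auto-detected.

## Surface areas and contacts

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å; van der Waals radii C 1.70, N 1.55,
O 1.52, S 1.80, others 1.80 Å). There is no RNG anywhere in the surface
code, so areas are bit-reproducible; at 960 points the two-sphere case
agrees with the closed-form spherical-cap area to better than 1%, and
rigid motions change totals by < 0.5%.

Interface buried area is computed from extracted groups:
`ΔSASA = SASA(A) + SASA(B) − SASA(A∪B)`, with "alone" meaning all other
atoms removed. Both conventions are always reported — the PISA-like
interface area ΔSASA/2 and the raw ΔSASA — because published buried areas
use either and rarely say which.

Hydrogen bonds are N/O⋯N/O heavy-atom pairs across the interface within
3.5 Å, annotated side-chain/main-chain by atom name; no angle term and no
hydrogen placement, appropriate for models without hydrogens. Salt bridges
are Lys NZ / Arg NH1, NH2, NE / His ND1, NE2 against Asp OD1, OD2 /
Glu OE1, OE2 within 4.0 Å, in either group order.

## Synthetic benchmark generator

The generator emulates the geometry the analysis assumes, not sequence or
spectra. Chains are Cα traces of three folds: an ideal α-helix (rise
1.5 Å/residue, radius 2.3 Å, 100°/residue), a helix hairpin (two
antiparallel helices 10.5 Å apart), and an α-solenoid (the same local
helix wound on a superhelical path, default radius 9 Å, pitch 15 Å — a
thick tube, the toy analog of stacked ARM-like repeats). Chains pack
side-by-side along a shared long axis with a random roll, flip, tilt
(≤ 10°) and axial offset, pushed apart to the closest non-clashing
position (min Cα separation 4.5 Å): elongated helical subunits in real
complexes of this class pack along extended interfaces, and only such
interfaces produce crosslink sets spread widely enough to be worth
benchmarking (a point contact localizes nothing).

Every 7th residue is a lysine-like anchor — crosslink geometry depends on
anchor spacing, not identity. True links are drawn uniformly without
replacement from anchor pairs with true distance ≤ cutoff − margin
(margin 2 Å by default; optional Gaussian jitter of `noise_sd` blurs the
acceptance boundary); decoys, mimicking false identifications, come from
pairs with distance > cutoff + margin, sized so they form a `decoy_rate`
fraction of the set. True links get synthetic FDR ~ U[0, 0.01], decoys
~ U[0, 0.05]. Only the residue pairs are recorded, as in a real
identification table. Pose-recovery problems displace the mobile chain
set by a random rotation (≤ 60°) and translation (≤ 20 Å ball) and record
the exact transform. All stages are deterministic from one seed, and every
generation parameter is serialized with the output.

What the generator does **not** emulate: side chains (Cα-only models, so
clash detection and buried areas are coarser than all-atom values),
realistic MS score distributions, under-crosslinking of buried lysines,
chain flexibility. Tests passing on these fixtures certify the geometry,
accounting and search machinery — not performance on real, sparse,
heterogeneous CXMS data.

## Information content of sparse crosslink restraints

The flat-bottom score is zero on a *region* of pose space, not at a point:
each restraint is a one-sided bound, so any pose keeping all links under
the cutoff and avoiding clashes scores exactly zero. Measuring this region
directly (a random walk confined to the zero-score set, started at the
ground-truth pose) shows that with 10 links sampled at ≤ 28 Å the region
extends 23–40 Å Cα RMSD from the truth for every fold and size tried:
poses can slide along the contact (lengthening perpendicular links only to
second order), pivot, or even flip while keeping every distance under
30 Å. No scoring of the same information can do better — the likelihood
of the sampling model is maximized by "taut" poses at the outer feasible
boundary, and a centering term prefers compact poses at the inner boundary,
both 10–30 Å from the truth — so rank-1 pose error of order 10–30 Å is the
*correct* outcome for such data, consistent with the ~10–25 Å localization
reported for sparse crosslink-driven docking generally. The benchmark
therefore certifies that the search finds zero-score poses, that scoring,
ranking and accounting behave exactly as specified, and that recovery
tightens as restraints tighten — not that 10 crosslinks determine a pose
to a few Å, which they cannot.

## Numerical and policy choices

* Author (deposited) numbering is canonical internally; full-length
  numbering exists only at the chain-map boundary.
* Satisfaction and FDR boundaries are inclusive (≤), fixed for
  testability.
* Hydrogens and waters are ignored everywhere (models at these
  resolutions have no reliable H positions).
* Multi-model files: first model, logged. Alternate locations: highest
  occupancy, first-seen on ties.
* PDB output carries 3 decimals (format limit); round-tripping is a fixed
  point after one pass.
* Ties in ranking break by restart index, then insertion order —
  deterministic everywhere.
* Problem sizes in tests and the acceptance script (chains of 60
  residues, 10–30 links, 50 restarts, 20 replicates) are desk-scale
  choices that exercise every code path at comfortable interactive
  runtimes.
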