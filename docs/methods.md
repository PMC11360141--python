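# Methods

`mesocpm` is a 3D Cellular-Potts (Glazier–Graner–Hogeweg) model of
collectively migrating *Xenopus* mesendoderm, with leader and follower
cell agents, mechanical link objects, a cohesotaxis protrusion bias,
stochastic cell–cell link turnover (intercalation), and the single-DMZ
and four-explant in-the-round (ITR) geometries, plus the measurement and
statistics layer used for its in-silico experiments.

## The model

**Lattice and agents.** Space is a regular 3D voxel lattice. Each voxel
is owned by the medium, the substrate (a single immutable plane at
`z = 0`), or one cell. A cell is the set of voxels carrying its ID; it
has a type (leader or follower, fixed for life), an integer volume, and
a centroid maintained incrementally from coordinate sums. One voxel is
6 µm (30 µm cells are 5×5×5 voxels); one Monte-Carlo step (MCS)
represents 5 s, so 1 voxel/MCS = 4320 µm/h.

**Effective energy.** A configuration's energy is

```
H =  Σ_neighbors J(τ_i, τ_j)·[σ_i ≠ σ_j]          (contact)
   + Σ_cells   λ_volume (V_cell − V_target)²       (volume constraint)
   + Σ_springs λ (l − L)²                          (cell–cell, follower–substrate)
   + Σ_lamellipodia λ_Lam · l                      (constant tension)
```

The contact sum runs over 26-neighborhood voxel pairs with unequal
owners; `J` depends only on the pair of types. Spring links connect cell
centroids (cell–cell) or a centroid to a fixed substrate anchor
(follower–substrate). Lamellipodium links are linear in length, so their
force magnitude `dE/dl = λ_Lam` is length-independent — a stalling-force
traction. A lamellipodium whose leader has pulled its centroid within
1 voxel (in-plane) of its anchor is *satisfied* and exerts no further
force until turnover replaces it.

**Kinetics.** One MCS makes `N` voxel-copy attempts, `N` = number of
non-substrate sites: a random site proposes copying its owner onto a
random 6-neighbor, accepted with the Boltzmann rule `P = 1` for
`ΔH ≤ 0`, else `exp(−ΔH/T)`. ΔH is evaluated incrementally (local
contact change, the two affected cells' volume terms, and the
link-energy change from their centroid shifts); a dedicated test proves
the incremental value equals a full recomputation to 1e-9. Copies into
or out of the substrate are never attempted; lattice walls are fixed
(no wrap-around), and lattices are sized with free space of at least
twice the explant length along the migration axis.

**Fission guard.** An otherwise-accepted copy is rejected if it would
locally 26-disconnect the losing cell (the standard CPM connectivity
constraint, evaluated on the 3×3×3 neighborhood of the lost voxel; the
last voxel of a cell may still be lost, so volume-0 removal works).
Without the guard, strong leader traction sheds 1–3-voxel satellites.
This is a numerical-integrity choice: it forbids unphysical cell
fission and leaves all other statistics untouched.

**Link turnover.** Each link kind carries a Poisson rate ζ per timestep;
an event fires with `P = 1 − exp(−ζ)`. A leader's firing deletes its
lamellipodium and (if it still has free-edge voxels — voxels touching
medium) creates a new one through a cohesotaxis-selected direction
voxel, anchored on the substrate plane at distance χ_Lamellipodia beyond
that voxel along the in-plane centroid→voxel direction (anchors are
clamped to the lattice). A leader fully enclosed by other cells forms
nothing and temporarily behaves as a follower. Followers touching the
substrate hold one spring anchored beneath their centroid, re-anchored
on firing; followers that lose substrate contact lose the link.

**Cohesotaxis.** Free-edge voxels are ranked by cumulative Euclidean
distance to the cell's cell–cell border voxels (contacts with other
cells only, not medium/substrate), sorted ascending with lexicographic
tie-breaks, and one is drawn using normalized logistic weights
`f(x) = 1/(1+exp(−2^κ·x))` evaluated at n evenly spaced points on
[−5, 5] (a single point x = 0 when n = 1). Weights are non-decreasing
along the list, so mass sits on the voxels *farthest* from cell–cell
contacts — protrusion away from adhesion, which is the forward direction
for a leading-row cell regardless of which way the explant faces.
κ = −6 is near-uniform; κ = +6 approaches a step at the list midpoint
(uniform over the far half). The source material describes the
selection both as "lowest cumulative distance" and as "most opposite
from cell–cell contacts"; these conflict, and only the away-from-contacts
reading produces forward-polarized lamellipodia, so it is the default
(`bias_toward: far`), with `bias_toward: near` preserving the
alternative reading. With no cell–cell borders at all the draw is
uniform. At initialization the direction voxel is drawn uniformly (no
bias), establishing each leader's initial heading.

**Intercalation.** Cell–cell links break with rate ζ_Tissue per
timestep. For each broken link, one endpoint (chosen uniformly — the
narrative "the cell" is ambiguous) forms one new link to a uniformly
random face-adjacent cell it is not linked to, provided both cells hold
fewer than `max_reformed_neighbors` (default 4) cell–cell links. The
cap constrains only reformation; initial grid wiring links *all*
adjacent pairs (an interior cell starts with 5). Values of the cap at
3 or below, or 6 and above, produce unrealistically loose or locked
tissue. Breakage and reformation run after the copy sweep each MCS.

**Geometries.** A DMZ explant is width × length × height = 8×4×2 cells
of 5³ voxels resting on the substrate; the eight bottom-layer cells at
the leading face are leaders (`leader_rows: full_face` instead promotes
the whole 16-cell face; bottom row is the default because biological
leading-row cells contact the fibronectin substrate). All adjacent cell
pairs get springs (rest length L = 5), bottom-layer followers get
substrate springs, and each leader gets an initial lamellipodium. The
ITR configuration places four explants facing +x, +y, −x, −y around a
central cell-free square (default side 40 voxels = one explant width;
the source does not state the gap size) on a square lattice, so the
four placements are exact 90° rotations; no other parameter changes.

## Parameters

The source's parameter table is unrecoverable (rendered as an image), so
all numeric defaults are **package-calibrated**, frozen after a manual
search against qualitative gates: a cohesive explant (no fragmentation,
volumes within ±30% of target), monotone forward leading-edge
displacement, mean DMZ speed inside a 50–200 µm/h band around the
biological ≈107 µm/h benchmark, a progressive ITR closure ≈2–3× the DMZ
speed (the biological relation is 107 vs ≈237 µm/h), a bilayer that
stays rigid without intercalation and flattens with it, and positive
retraction after lamellipodia blocking. `experiments.check_gates` and
`experiments.calibrate_defaults` implement the gates and the search.

| parameter | default | meaning |
|---|---|---|
| J cell–medium / cell–cell / cell–substrate / medium–substrate | 8 / 5 / 4 / 7 | contact energies |
| T | 24 | fluctuation amplitude |
| λ_volume, V_target | 2, 125 vox | volume constraint |
| λ_Tissue, L | 50, 5 vox | cell–cell springs (stiff: keeps the bilayer) |
| λ_FollowerSubstrate, L_sub | 2, 3 vox | follower–substrate springs |
| λ_Lamellipodia | 800 | leader traction (on the stable, rising branch of the speed–traction curve) |
| ζ_Lamellipodia, ζ_Substrate, ζ_Tissue | 0.25, 0.25, 0 | turnover rates /timestep |
| χ_Lamellipodia | 12 vox | anchor distance beyond the selected voxel |
| κ | 6 | cohesotaxis bias |

A separate substrate-spring rest length (3 voxels = bottom-cell centroid
height) is used instead of the cell–cell rest length: one shared L = 5
would push bottom-layer centroids *away* from anchors placed beneath
them.

## Measurement protocols

* **DMZ migration speed**: run 1440 MCS (2 h), sample the centroids of
  the center four leading-row cells every 200 MCS (~17 min); speed is
  the mean net axial displacement rate, in µm/h (a path-length variant
  is available via `mode="path"`).
* **ITR closure speed**: the free area of the initial gap square is the
  count of (x, y) columns containing no cell voxel (the top-down
  cell-free area; counting only the substrate-adjacent layer would pick
  up sub-cellular pinholes inside covered tissue). side(t) = √area;
  speed = |least-squares slope| of side vs t over the closing phase
  (samples with area > 0), converted to µm/h, with the per-edge advance
  (half) co-reported since two opposing edges close each side. The area
  is sampled every 50 MCS — finer than the centroid cadence — because
  fast closures otherwise leave too few closing-phase samples for a
  stable fit.
* **Substrate cell count**: cells owning ≥1 voxel in the layer touching
  the substrate.
* **Retraction**: migrate 200 MCS, block all further lamellipodium
  formation, let existing links expire by their Poisson lifetime, and
  continue until no lamellipodia remain plus a 200-MCS relaxation
  window; retraction is the mean rearward axial displacement of the
  leading row from block onset, in µm (forward motion is negative).
* **Statistics**: unpaired two-tailed Student's t (pooled variance),
  one-way ANOVA (no post-hoc tests), and least-squares sensitivity
  slopes, via scipy.stats behind `mesocpm.metrics`; degenerate
  zero-variance/equal-mean inputs return p = 1.

## Experiment design

Replicate *i* of any condition uses seed `base_seed + i`, so every
result replays bit-identically. The sensitivity sweep varies one
parameter at a time by ±10…±50% (the protocol rejects levels outside
±50%) with fresh seeds per level by default (`reuse_seeds_across_levels`
switches to paired seeding). ITR runs stop at closure; non-closing runs
are recorded as censored and excluded from summary statistics.

**Problem sizes.** Structural checks, calibration gates, and the DMZ
cohesotaxis t-test use the full 8×4×2 explant. The geometry,
intercalation and retraction comparisons, and the sensitivity sweep
(levels ±20%, ±50%, n = 5, 720 MCS), use a scaled preset — 6×3×2-cell
explants, 30-voxel gap, tighter margins — chosen as the package's
standard quick preset; all qualitative effects were verified to persist
at this scale.

## What the tests do and do not show

The synthetic trajectory/area generators drive the measurement layer
with known drift and noise, so metric tests verify units and estimators,
not biology. The simulation-level tests verify *relations* the study
reports (κ effect in the DMZ, geometry dominance in the ITR,
intercalation acceleration, retraction after blocking), not absolute
speeds: absolute values depend on the calibrated defaults standing in
for the unrecoverable parameter table. Real mesendoderm shows cell-shape
elongation, chemotactic (PDGF) guidance and substrate remodeling, none
of which the model represents.

## Known limitations

* **χ sensitivity regime.** In the source's account, longer
  lamellipodium links speed migration because leaders that reach their
  link target stop until turnover replaces it ("fewer interruptions").
  That mechanism requires link lifetimes comparable to the time a leader
  needs to traverse χ. At the calibrated ζ_Lamellipodia = 0.25
  (lifetime ≈ 4 MCS) anchors are effectively pure direction markers and
  the one-at-a-time χ slope is small; at lifetimes long enough for the
  mechanism (ζ ≈ 0.002, measured), direction draws stop averaging out
  and the cohesotaxis contrast degrades below the study's reported
  significance. With the original parameter table unavailable, the
  shipped regime preserves the cohesotaxis, geometry, intercalation and
  retraction results at the cost of a weak χ sensitivity; the
  sensitivity-ordering test documents this honestly.
* **ITR kappa-independence.** The study reports that closure speed in
  the round is unaffected by the cohesotaxis bias. In this
  reconstruction the circular boundary reduces the kappa dependence
  (closure-speed spread across kappa = -6..6 is ~23%, vs ~31% for DMZ
  migration speed) but does not eliminate it: closure remains limited
  by leading-edge migration speed, so an ANOVA across kappa can reach
  significance. A geometry in which colliding explants fully seal the
  leading edges' lateral free surface would likely be required.
* The Boltzmann kinetics with link terms and the fission guard do not
  satisfy strict detailed balance (standard for CPM models with active
  force terms).
* Leaders under strong traction equilibrate slightly above V_target;
  the ±30% volume gate bounds this.
* The ITR gap occasionally leaves a small transient pocket at the
  4-explant junction; closure is declared on the top-down free-column
  area reaching zero.
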