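# Model and methods

## The model

`invasim` is a three-dimensional cellular Potts (Graner–Glazer) model of
collective squamous-cell-carcinoma (SCC) invasion. Space is a cubic lattice
(voxel side 2 µm); each voxel holds a cell id (0 = matrix/medium, −1 =
frozen air, >0 = a cell), and a cell is the set of voxels sharing its id.
Cells are SCCs or cancer-associated fibroblasts (CAFs). A continuous field
ρ ∈ [0, 1] per voxel carries extracellular-matrix (ECM) density (1 =
intact collagen-rich matrix).

Dynamics are Metropolis voxel-copy attempts. One Monte Carlo step (MCS,
30 s of real time) performs one attempt per lattice voxel: a source voxel
is drawn uniformly, a target from its six face neighbours, and the copy of
the source id into the target is accepted with probability 1 if ΔH ≤ 0 and
exp(−ΔH/T) otherwise. ΔH sums:

- **Contact energy** over the 26-neighbourhood of the changing voxel.
  Energies derive from measured adhesion strengths by normalising to the
  SCC–ECM score, inverting, and multiplying by 10 (strong adhesion → cheap
  interface): SCC–ECM 10, SCC–SCC 21, SCC–CAF 35, CAF–CAF 45, CAF–ECM 15.
  The SCC–matrix energy interpolates linearly with local density,
  J(ρ) = 40 + (10 − 40)ρ, so fully degraded matrix offers poor grip (40)
  while intact matrix is maximally adhesive (10). The frozen air phase
  above an organotypic culture repels cells with a prohibitive energy (100).
- **Volume and surface constraints** λ_v (v − V_t)² and λ_s (s − S_t)²,
  with v the voxel count and s the exposed-face count. CAFs: V_t = 800,
  S_t = 700. SCCs: V_t ramps from 400 towards the dividing volume (below);
  S_t scales as S_t = k V_t^{2/3} with k anchored at the CAF point
  (700/800^{2/3}).
- **Taxis**: copies involving a motile cell are biased by −E cos θ, where θ
  is the angle between the copy direction and the local cue (uniform
  "downward" in organotypic slabs, radially outward in spheroids). Both
  extensions and rear retractions count, the usual Potts chemotaxis
  convention. E is the cell's taxis scale (SCC 13; CAF interpolating
  3.5 → 21 with proximity to the nearest cancer cell over a 30-voxel
  stimulation range) multiplied by a per-type coupling gain (below).
- **Matrix entry resistance**: a copy of a cell into a matrix voxel is
  excluded outright when ρ > 0.75 (collagen pores smaller than a cell are
  impassable until remodelled; the threshold coincides with the density at
  which matrix counts as "remodelled" in the track metric) and otherwise
  pays β·ρ with β = 20.
- **CAF–CAF repulsion**: a copy that pulls two CAF centroids closer while
  they are within 20 voxels pays a fixed penalty (15), keeping fibroblasts
  spread out at roughly their observed spacing.

Cells occupy matrix voxels without destroying the residual density: ρ is
stored beneath the cell and reappears if the cell retreats. Degradation and
displacement are the only ways matrix is permanently removed or moved.

## ECM remodelling

- **Proteolysis** is multiplicative: each MCS, a matrix voxel face-adjacent
  to a cell of kind k is multiplied by (1 − rate_k); both factors apply if
  both kinds touch it. Stored density beneath a cell is digested at the
  occupying cell's rate (membrane-bound protease acting on overlapped
  matrix) — this is what turns a fibroblast's path into a permissive track
  instead of restoring intact matrix behind it. Rates: CAF 0.0012, SCC
  0.0001 (wild type), scaled by the proteolysis multiplier in sweeps.
- **Pushing** (displacement): each MCS a matrix voxel transfers fraction
  0.0140 of its density per adjacent CAF face one voxel along the outward
  normal (centroid → voxel, quantised to the nearest axis). Receiving
  voxels clip at 1; overflow continues outward; anything unplaceable
  returns to the source, so total density is conserved exactly. This
  reproduces the compaction of matrix just ahead of pushing cells.

## Growth and division

Only SCCs proliferate. Each cell draws a mitosis interval from an
exponential with mean 8640 MCS (3 days), clipped to [0.05, 3]× the mean;
its target volume ramps linearly from 400 to 800 voxels across that
interval and keeps ramping (up to 1.5×) until the *actual* volume reaches
the dividing volume of 800 — interfacial pressure holds cells a few tens of
voxels below target, so capping the ramp at 800 would stall division. At
800 voxels the cell splits by a uniformly random plane through its
centroid; daughters restart the ramp. Seeded populations receive a random
initial cycle phase (an asynchronous population, as in culture). Because
growth happens by claiming voxels against the matrix-entry resistance,
confinement suppresses proliferation until proteolysis or displacement
opens space.

## Calibration constants

The interaction energies, rates, targets and taxis scales above are the
published parameterisation. Four quantities the parameterisation does not
fix — the constraint strengths, the fluctuation temperature, the entry
barrier, and the taxis coupling — were tuned once against the calibration
rows (median speeds and median cell volume) and then frozen:

| constant | value | anchored by |
| --- | --- | --- |
| temperature T | 40 | speed calibration (jointly) |
| λ_v | 1.0 | speed + volume calibration |
| λ_s | 0.15 | speed calibration |
| β (entry penalty) | 20 | pushing-limited CAF speed through intact matrix |
| pore-opening threshold | 0.75 | wall containment; ties to the track metric's remodelled-density threshold |
| SCC taxis gain | 6.0 | SCC median speed 0.2 µm/min |
| CAF taxis gain | 2.0 | CAF median speed 0.1 µm/min |
| CAF repulsion penalty | 15 | visible spacing without freezing CAF motility |

The taxis gain is per type because the two speed rows cannot be met with
one coupling: in passable matrix (ρ ≤ 0.75) the interpolated SCC–matrix
contact energy (≥ 17.5) never drops below the CAF–matrix value (15), so
SCC interfaces are always at least as stiff as CAF interfaces and the
required 2:1 speed ratio is unreachable otherwise. Each gain is an
exactly-determined constant (one knob per calibration row, not a fit with
slack).

**Speed protocol.** Median instantaneous speed is measured from centroid
tracks sampled every 20 MCS (10-minute frames, standard time-lapse
cadence): per cell the median frame-to-frame displacement over the
interval, then the population median, converted at 2 µm/voxel and
30 s/MCS. SCCs are measured migrating through remodelled matrix at ρ = 0.5
— the environment invading cells actually traverse; in zero-density medium
the model's own weak-adhesion energy (40) stiffens SCC interfaces and
caps their speed well below the reference value. CAFs are measured in open
medium. The pushing-only CAF speed is measured into a density-1 slab of
finite thickness: displaced matrix needs a free far side to compact
towards, exactly as a real gel has; the measured 0.05–0.06 µm/min sits
slightly below the 0.07 reference because displaced matrix piles up
immediately ahead of the cell (the compaction the model is meant to show)
before it clears.

## Scenarios

- **Organotypic**: frozen air above, an SCC monolayer (8×8×8-voxel seeds
  tiling the cross-section), an intact ρ = 1 slab below, uniform cue into
  the slab. CAFs (10×10×8-voxel seeds) are scattered in the upper slab,
  where their downward tracks connect to the cancer-cell layer, or mixed
  into the monolayer. The interface plane (monolayer/slab boundary) is
  recorded at build time.
- **Spheroid**: an 8³-block-tiled ball of cells (CAF fraction 0.5 by
  default, the experimental 1:1 hanging-drop ratio) centred in ρ = 1
  matrix; radial cue by default, uniform as a variant. The nominal sphere
  radius is the recorded interface.
- **Front curvature**: an SCC slab facing matrix under a uniform cue, no
  CAFs, optionally with a permissive track, parallel-fibre planes, or a
  chessboard texture.

Day conversions are fixed: day 4 = 11 520 MCS (metric timepoint), day 5 =
14 400 (track invasion score), day 7 = 20 160 (front curvature).

## Invasion metrics

Computed on the cell-id grid + density field (engine output or synthetic
labelled volumes): invasive cells are SCCs whose centroid lies strictly
beyond the recorded interface (perpendicular distance for slabs, radial
beyond the initial surface for spheroids). Maximum invasion is the largest
such distance; the invasion score is the number of invasive cells times
their mean distance. Mean neighbours (SCC cells sharing ≥ 1 voxel face)
and tapering (OLS slope of neighbour count against distance) are computed
over invasive SCCs in the bulk tumour mass, the largest 26-connected
cell object containing an SCC voxel; fractured objects are detached
SCC-containing objects. Growth rate is the log-linear slope of SCC count
against time (per day). The track invasion score sums, over voxels beyond
the boundary with density ≤ 0.75, the distance beyond the boundary
(linear weighting); for track scenarios it is restricted to the
neighbourhood around the permissive track (the track footprint dilated
laterally, `ecm.track_region`), without which general pericellular
remodelling around the whole mass swamps the track signal.
Track width is the maximum cross-section extent of the invading strand
(undefined for non-invasive runs or uniform whole-mass advance). Front
curvature reduces the leading edge to the two mid-plane profiles, smooths
each with a 50-pixel moving average (odd reflection at the ends, which
continues the boundary slope instead of fabricating curvature) and
averages the three-point circumcircle curvature; it is exact (1/r) on
circular arcs. Spheroid runs whose largest SCC object holds < 50% of SCC
voxels (hollow or broken apart) are flagged and excluded from PCA and
heatmaps.

## Sweeps, PCA, heatmaps

A sweep runs every combination of proteolysis, SCC–SCC adhesion and
SCC–ECM adhesion multipliers (adhesion multipliers act on the measured
adhesion score, so contact energies are divided by them) with a fixed
replicate count (10 by default); per-run seeds derive only from (base
seed, point index, replicate), so runs are order-independent and
resumable. The PCA morphospace z-scores the six per-run metrics and
diagonalises them (verified against an independent eigensolution of the
correlation matrix); heatmap tables expand each grid cell into the 0.5–99.5
percentile profile over replicates with linear order-statistic
interpolation.

## What the synthetic volumes do and do not show

`invasim.synthetic` builds labelled volumes with constructively known
metric values (cube placements, prescribed depths, fragment counts,
analytic dome fronts). They validate every metric without the engine, but
they contain axis-aligned blocks with clean interfaces — they say nothing
about engine behaviour such as strand formation, which the scenario-level
tests cover.

## Problem sizes

Default desk-scale presets use 64×64×72 (organotypic) and 64³ (spheroid)
voxel domains with tens to low hundreds of cells. The test suite and the
acceptance script run reduced versions (36³–48³ domains, 2–3 replicates,
25–50 cells per kinematic measurement) chosen so the full suite completes
on a single CPU in well under half an hour; the qualitative orderings they
check were stable across the larger exploratory runs used during
development.

## Numerical choices

- Copy attempts use an inline xorshift64* RNG (one uniform draw selects
  source voxel and direction); fixed seeds give bit-identical trajectories.
- Incremental volume/surface/centroid bookkeeping is exact: a brute-force
  recount equality is asserted in the test suite after arbitrary dynamics.
- Cell connectivity is *not* enforced; fragmentation is a measured output.
- A copy that would annihilate a cell's last voxel is rejected (cell death
  is not modelled).
- Copies across the domain boundary are rejected (no-flux walls).
- The CAF taxis stimulation distance is refreshed every 10 MCS from a
  Euclidean distance transform of the SCC mask.

## Known limitations

- Amoeboid (protease- and adhesion-independent) single-cell migration is
  outside the model's scope; transitions to single-cell behaviour are not
  predicted faithfully.
- Matrix is a scalar density: no fibre orientation, strain stiffening, or
  ECM secretion.
- The pushing-limited CAF speed lands ~20% below its reference value
  (compaction backlog, see above).
- Explicit chemokine diffusion is not modelled; cues are static fields.
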