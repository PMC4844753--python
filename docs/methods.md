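# Methods

## Coordinate conventions

All volumes are `(z, y, x)` arrays with 0-based indices and the origin at
the array corner.  Physical calibration is a `VoxelSpacing` in micrometres
per voxel step; every length- or volume-valued parameter is physical and is
converted to voxel units through the spacing, so one parameter set behaves
identically on isotropic and anisotropic grids.  Volumes are reported in
μm³.  Connectivity is 6-neighbour (face) everywhere: components, seed
maxima, watershed flooding.

## Synthetic alveoli

A scene is one alveolus: a spherical shell between `lumen_radius` and
`alveolus_radius` whose cells are the Voronoi regions of `n_cells`
quasi-uniform seed points (golden-angle lattice, randomly rotated per seed)
on the mid-shell sphere, computed in physical coordinates and clipped to
the shell.  For seeds on a common sphere the Euclidean nearest seed is also
the angularly (geodesically) nearest, so the partition is the geodesic one.
Each cell draws one nucleus, or two with probability `p_binucleated`,
placed symmetrically about the cell centroid along the cell's longest
shell-tangent axis at a centre separation of 2.1 nucleus radii (nuclei
never overlap; a packing check rejects specs whose expected cell diameter
cannot hold two nuclei and says which constraint failed).  With
`lipid_droplet` on, a central droplet displaces nuclei toward the cell
periphery — the late-pregnancy morphology; off, nuclei sit centrally as in
lactation.

Channels are rendered as anti-aliased indicators before optics and noise:

- **membrane** — interface voxels are marked on one side of every
  cell–cell wall and on the cell side of the apical/basal surfaces (one
  voxel at base), then broadened to `membrane_thickness` by thresholding
  the distance to this set, with the digitization offset (a quarter voxel)
  subtracted so the rendered band is the nominal thickness overall.
  Rendering the band wider than nominal makes dense monolayers
  unsegmentable at any threshold, because a wall of 2–3 μm consumes a
  large fraction of a 15 μm cell.
- **nuclear** — union of nucleus spheres, clipped to the parent cell.
- **markers** (`marker:<name>`) — nuclear-localised intensity in the
  nuclei of marker-positive cells; positivity is drawn per cell with
  class-specific probabilities `(p_mono, p_bi)`, and all nuclei of a
  positive cell carry signal (an S-phase label incorporated before a
  failed cytokinesis marks both daughter nuclei).
- **reporters** (`reporter:<i>`) — each cell uniformly expresses exactly
  one of `reporter_colors` mutually exclusive colours over its whole
  region, emulating a stochastic multi-colour lineage label.

Each channel is blurred with an anisotropic Gaussian PSF and corrupted as
`Normal(Poisson(signal·photons)/photons, read_noise_sd)`, a two-knob
confocal approximation.  Defaults: spacing `(1.0, 0.5, 0.5)` μm,
alveolus 40 μm / lumen 25 μm, 40 cells, nucleus radius 4 μm, membrane
1 μm, PSF σ `(0.5, 0.2, 0.2)` μm (typical confocal axial/lateral
resolution at this pixel size), `photons = 100`, read noise 0.01 — cells
of ~5·10³ μm³ on a ~90×177×177 grid, generated in a few seconds.
Identical spec + seed give bit-identical scenes.

What the generator does **not** emulate: ducts and branching geometry, the
myoepithelial sheath, intensity inhomogeneity and depth-dependent
attenuation, chromatin texture, debris and segmentation-hostile artefacts.
Passing tests therefore demonstrate correctness of the measurement chain
on geometry-faithful, optics-simplified data — not robustness to every
failure mode of real tissue imaging.

## Cell segmentation

`membrane_mask` smooths with `smooth_sigma` (default `(0.5, 0.25, 0.25)`
μm) and thresholds globally (Otsu by default; a constant image is refused
with a pointer to the fixed threshold).  `interior_distance` is the
anisotropy-aware Euclidean distance to the nearest membrane voxel, with
the grid boundary treated as membrane (one spacing step beyond the last
voxel), which keeps seeds away from the arbitrary field-of-view edge.
`find_seeds` takes the distance maxima surviving h-maxima suppression
(default depth 2 μm) and a greedy mutual-separation filter (default 6 μm;
deeper maxima win, exact ties go to the lexicographically smaller
`(z, y, x)`; a plateau yields its lexicographically smallest voxel).
`watershed_cells` floods the negated distance field from the seeds,
restricted to non-membrane voxels; membrane voxels stay background.
Flooding priority is depth-based, so results are traversal-order
independent except at exact ties, where the flooding queue is
deterministic.  `size_filter` removes labels outside
`[size_min, size_max]` = [200, 20 000] μm³ and, by default, labels
touching an array face (flagged `border` rather than `size`); this
removes the lumen and exterior basins that inevitably receive seeds.

The seed-suppression and smoothing defaults were set so that the default
fixture scene segments correctly (95–97.5% of cells matched one-to-one at
IoU ≥ 0.7 across seeds); they are all exposed in config and recorded in
the run manifest.

## Slice curation

Verdicts arrive as a CSV of `(cell_label, z_index, verdict)` with unlisted
pairs valid.  A rejected slice of a cell is rebuilt from its nearest valid,
non-empty cross-sections above and below: both are converted to 2-D signed
Euclidean distance fields (negative inside, physical units), blended
linearly with weight `(z−z1)/(z2−z1)`, and the sub-zero level set is the
rebuilt section.  Contested voxels go to the cell with the more negative
blended distance (ties to the smaller label); voxels of cells valid at
that slice are never overwritten; a rejected terminal slice with no
flanking valid section is left empty and logged.  The operation is
idempotent, leaves untouched cells bit-identical, and preserves the
partition property.  Blending signed distances reproduces closed forms
exactly up to voxel quantization: the midpoint between concentric disks of
radius 4 and 8 μm is the disk of radius 6 μm.

## Nuclei, classes, markers

`segment_nuclei` reuses the smooth→threshold→distance→seeds→watershed
chain at nucleus scale (h-maxima 0.5 μm, separation 3 μm, size bounds
30–800 μm³, border exclusion off).  `assign_nuclei` gives each nucleus to
the cell owning the plurality of its voxels; background plurality leaves
it unassigned; a winner below 50% is kept but flagged ambiguous — the only
genuinely ambiguous geometry.  `classify_nucleation` maps counts 0/1/2/≥3
to anucleate / mononucleated / binucleated / multinucleated; the latter
two extremes are logged, never re-binned, because a >2-nuclei cell is a
biological anomaly worth surfacing rather than hiding.

Marker scoring is per-nucleus mean intensity against a per-channel
threshold (Otsu over the channel, or fixed); a cell is positive iff at
least one nucleus is.  Reporter colours are scored per cell; the Otsu
threshold over per-cell means is re-centred between the two class means,
because with two tight clusters Otsu's criterion is flat across the gap
and the bin-argmax can sit at the edge of the low cluster, mislabelling
cells that receive blur bleed-through from coloured neighbours.  Cells
expressing ≥2 colours are fusion candidates; on faithful single-colour
scenes the expected output is the empty list.

## Morphometry

Volumes are voxel counts × voxel volume — exact, additive (label + background
volumes sum to the grid volume identically) and axis-permutation invariant.
This is deliberately not a smoothed-surface (marching-cubes) volume as a
commercial surface module computes; voxel counting overestimates a convex
body slightly (≪1% at radius 8 μm on the default grid), a known systematic
difference.  Group comparison defaults to Welch's two-sample two-sided
*t*-test with the zero-variance cases defined by continuity (equal
constant groups → t = 0, p = 1); Mann–Whitney U is available.  The choice
of Welch is this package's convention, appropriate for unequal group
variances at modest n.  `binucleation_fraction` reports per-unit
(per-alveolus) fractions — excluding anucleate records, which carry no
nucleation information — with a minimum-cells-per-unit filter (default 5)
and an across-unit mean ± s.e.m.

## DNA-content cytometry

Each simulated cell is G0/G1 (content 2), S (Uniform(2, 4)), G2/M (4) or
binucleated (two diploid nuclei, total 4).  Binucleated content is
modelled identically to G2/M deliberately: total DNA fluorescence cannot
distinguish them, which is precisely why an imaging-derived binucleation
fraction is needed to decompose a 4N peak.  Binucleated cells survive
dissociation with probability `1 − p_loss_binucleated`; survivors'
fluorescence is content × mean-corrected LogNormal noise with
σ² = ln(1 + cv²) so the multiplicative CV equals `stain_cv` (default
0.05, standard for stoichiometric DNA dyes).  The surviving binucleated
fraction `b(1−ℓ) / (1 − bℓ)` is strictly below the in-tissue fraction
whenever ℓ > 0 — the model's account of why imaging counts exceed
cytometry counts.

Gating: the `midpoint` method histograms fluorescence (256 bins,
Gaussian-smoothed), finds the two dominant modes, places the 2N/4N
boundary at the minimum-density point between them and outer bounds at
mode ± 3 peak-widths; it requires ≥100 samples, mode separation ≥1.3× and
a valley below half the lower peak, otherwise it raises and advises fixed
windows.  The `fixed` method uses configured windows (default [1.5, 2.5]
and [3.5, 4.5]), leaving S-phase cells in `frac_other`.
Exact gate placement is a convention of this package, not a measured
protocol.  The 2N/4N conservation property (`frac_4N → p_G2M +
p_binucleated`) holds exactly only without S-phase cells, whose contents
straddle any boundary; conservation tests therefore run at `p_S = 0`.
Doublets/aggregates are not modelled (live single-cell gating is assumed
upstream).

## Problem sizes and numerical choices

Statistical tests run at desk scale: the fixture alveolus is ~40 cells on
a ~90×177×177 grid; fraction-recovery studies use 25 alveoli × 50 cells
(alveolus 30 μm, nuclei 3 μm, so 50-cell packing is feasible) and 8
marker-scored alveoli (~400 cells); the type-I calibration uses 200
geometry-only scenes of 40 cells at alveolus radius 22 μm, where the
Welch comparison of ~20 vs ~20 volumes rejects at the nominal 1% within
Monte-Carlo tolerance (with only ~6 cells per class the small-sample
approximation visibly inflates the rate).  Cytometry runs at n = 10⁵.
`generate_scene(…, render=False)` skips channel rendering for studies
that need many scenes but no imagery.

Known limitations: watershed tie-voxels between equally deep basins follow
the deterministic flooding queue rather than an explicit smaller-label
rule; nucleus spheres are clipped to their parent cell, so nuclei of
tightly packed binucleated cells can be truncated by a cell wall (measured
nuclear volumes of mono- and binucleated cells still agree within 5% at
the defaults); the marker scorer assumes some positive signal exists in
the channel when using Otsu — an all-negative noisy channel is better
scored with a fixed threshold.
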