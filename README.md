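# alveoquant

3-D quantification of alveolar epithelium from multi-channel confocal
stacks: membrane-seeded watershed segmentation of secretory cells,
file-driven slice curation, nucleus-per-cell counting (mono- vs
binucleated), cell and nucleus volumetry, marker scoring (EdU-like labels,
multi-colour lineage reporters), and an in-silico DNA-content cytometry
model with 2N/4N gating.

## The problem

Secretory alveoli of the lactating mammary gland are spherical monolayers
of luminal cells, most of which carry **two nuclei** — the product of
mitosis without cytokinesis.  Quantifying this state from intact-tissue 3-D
imaging needs several measurements that 2-D microscopy cannot provide:

- **cell segmentation** from a membrane stain (E-cadherin / F-actin):
  smooth → threshold → invert, then a marker-controlled watershed seeded at
  the points furthest from all membranes, followed by a physical-volume
  size filter;
- **slice curation**: human verdicts on a per-cell, per-slice basis, with
  rejected slices rebuilt by shape-based (signed-distance) interpolation
  between the two nearest accepted slices;
- **nucleation counting**: nuclei segmented from the DAPI-like channel,
  assigned to cells by voxel-overlap plurality, and classified as
  anucleate / mononucleated / binucleated / multinucleated;
- **volumetry**: per-object volumes as voxel count × voxel volume on the
  anisotropic grid (μm³), compared between groups with Welch's *t*;
- **ploidy by flow cytometry, in silico**: total DNA fluorescence cannot
  distinguish a single 4N (G2/M) nucleus from two 2N nuclei, so a 4N peak
  is the sum of cycling and binucleated cells; an imaging-derived
  binucleation fraction decomposes it.  A fragility parameter models the
  selective loss of large binucleated cells during tissue dissociation,
  which biases cytometry fractions below in-tissue imaging counts.

Every stage is testable without any data download: the `synthetic` module
renders confocal-like alveoli (Voronoi cells on a spherical shell, PSF
blur, Poisson + read noise) with exact per-cell ground truth.

## Worked example

```python
import alveoquant as aq

spec = aq.SceneSpec(seed=42, p_binucleated=0.5)
channels, truth = aq.generate_scene(spec)

params = aq.SegmentationParams()
membrane = channels[0]
mask = aq.membrane_mask(membrane, params)
distance = aq.interior_distance(mask, membrane.spacing)
seeds = aq.find_seeds(distance, params, membrane.spacing)
cells, removed = aq.size_filter(
    aq.watershed_cells(membrane, mask, seeds, params), params
)
match = aq.match_labels(truth.cell_labels, cells)
print(f"segmented {len(cells.label_ids())} cells "
      f"({100*match.recovery(0.7):.1f}% of truth at IoU>=0.7)")

nuclei = aq.segment_nuclei(channels[1])
records = aq.assign_nuclei(nuclei, cells)
cell_records = aq.classify_nucleation(cells, records)
summaries, t, p = aq.compare_volumes(cell_records)
for cls, s in summaries.items():
    print(f"{cls}: n={s.n}, volume {s.mean:.0f} +/- {s.sem:.0f} um^3")
print(f"Welch t = {t:.2f}, p = {p:.2f}")

pop = aq.PopulationSpec(n_cells=100_000, p_G0G1=0.83, p_S=0.0,
                        p_G2M=0.05, p_binucleated=0.12, stain_cv=0.05, seed=1)
gate = aq.gate_2n_4n(aq.sample_dna_contents(pop), method="midpoint")
est_g2m, bi_of_4n = aq.decompose_4n(gate, 0.12)
print(f"4N fraction {100*gate.frac_4N:.1f}%, "
      f"estimated G2/M {100*est_g2m:.1f}% of all cells")
```

Output:

```
segmented 40 cells (97.5% of truth at IoU>=0.7)
mononucleated: n=19, volume 3820 +/- 48 um^3
binucleated: n=21, volume 3835 +/- 23 um^3
Welch t = -0.29, p = 0.77
4N fraction 17.0%, estimated G2/M 5.0% of all cells
```

The segmentation recovers 39 of 40 ground-truth cells one-to-one at
IoU ≥ 0.7.  By default the generator draws cell volume independently of
nucleation, so the mono/bi volume comparison is correctly non-significant
(set `bi_volume_scale > 1` to build in the enlarged-binucleated phenotype).
The 4N peak (17.0%) decomposes into the known 12% binucleated contribution
plus an estimated 5.0% G2/M, matching the generator.

## Command line

The same pipeline as shell subcommands exchanging OME-TIFF / CSV / JSON:

```sh
alveoquant simulate -o scene --seed 42
alveoquant segment scene/channels.ome.tif -o seg
alveoquant curate seg/cells.ome.tif verdicts.csv -o curated
alveoquant nuclei scene/channels.ome.tif curated/cells.ome.tif -o nuc
alveoquant quantify nuc/cells.csv -o quant
alveoquant ploidy --seed 42 --confocal-fraction 0.12 -o ploidy
alveoquant report quant -o report.txt
```

Every tunable lives in a YAML config (`--config`); flags override config
keys; a manifest with the config hash and seed is written beside each
output.

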