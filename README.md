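# nestkin

Quantification of spermatogonial stem-cell (SSC) pool establishment in the
neonatal mouse testis: 3D germ-cell **nest** statistics from whole-testis
fluorescence volumes, flow-cytometry **gating and developmental kinetics**,
and **scRNA-seq** QC/clustering/annotation — with seeded synthetic-data
generators so every stage can be validated against ground truth without
animal data.

The package is aimed at germline/stem-cell labs quantifying reporter-mouse
imaging and cytometry (e.g. ID4-eGFP × tdTomato lineage-label systems) and
at anyone who needs a tested reference implementation of the underlying
measurements.

## The core computations

**Nest calling.** Detected fluorescent objects (centroid, volume, mean
intensity, in physical µm) are clustered by single linkage on their
surface-to-surface distances, d(i, j) = ‖cᵢ − cⱼ‖ − rᵢ − rⱼ with
equivalent-sphere radii rᵢ = (3Vᵢ/4π)^⅓, cut at 10 µm. A cluster is a
nest when its summed estimated cell count — round(V / V₂₀), the object
volume over a reference 20 µm cell sphere — reaches 3. Per intensity
class (Bright/Mid) the pipeline reports percent of cells in nests,
average nest size, and total nests, optionally rescaled for partial
imaging by observed × FCA_total / imaged_cells.

**Gating and kinetics.** Germ cells are gated as tdTomato⁺ above the
99.5th percentile of an unstained control; each sample's eGFP⁺ range is
split into equal log10 thirds (Bright/Mid/Dim); DNA-content histograms
give S/G2/M fractions via a 1.5 × 2N-mode threshold; per-age counts become
fold-changes and plateau flags.

**Transcriptomes.** Strict per-library QC (">n genes", "<25%" mito), germ
selection on Dazl/Ddx4, normalisation/scaling, dispersion-based variable
genes, PCA → KNN → modularity clustering, and a resolution criterion that
requires a reference population (the ~10% SSC pool) to be enriched within
a single cluster. Cluster identities are scored on marker panels
(dotplot-style scaled expression and detection fractions), and replicate
libraries are compared by the modified RV matrix correlation.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

Simulate a testis volume with planted nests, detect objects, and call
nests:

```python
from nestkin.simulate import (VolumeSimConfig, simulate_testis_volume,
                              default_class_boundaries)
from nestkin.volumes import DetectionConfig, classify_intensity, segment_objects
from nestkin.nests import (NestConfig, call_nests_from_objects,
                           summarize_nests, summaries_to_dataframe)

config = VolumeSimConfig()          # 400x400x200 um, 8 Bright + 3 Mid nests
sim = simulate_testis_volume(config, seed=7)
objects = segment_objects(sim.egfp, DetectionConfig(), cochannel=sim.tdtomato)
classify_intensity(objects, default_class_boundaries(config))

summaries = []
for cls in ("Bright", "Mid"):
    cls_objects = [o for o in objects if o.label == cls]
    nests, singletons = call_nests_from_objects(cls_objects, NestConfig())
    summaries.append(summarize_nests(nests, cls_objects, NestConfig(), cls))
print(summaries_to_dataframe(summaries).to_string(index=False))
```

```
 class  percent_of_cells_in_nests  average_nest_size  total_nests  n_cells_total  n_cells_in_nests scaled_total_nests  undefined
Bright                  92.105263           4.375000            8             38                35               None      False
   Mid                  81.250000           4.333333            3             16                13               None      False
```

All 8 planted Bright nests and 3 Mid nests are recovered; 92.1% of the 38
Bright cells sit in nests averaging 4.4 cells, with the remaining cells
being planted singletons — the per-class statistics a developmental
time-course is built from.

The same stages are available from the shell:

```sh
nestkin simulate --config sim.yaml --seed 7 --out data/
nestkin detect --egfp data/egfp.tiff --tdtomato data/tdtomato.tiff \
        --boundaries 32,141 --out objects.csv
nestkin nests --objects objects.csv --cutoff 10 --min-cells 3 --out nests/
nestkin run --config run.yaml --seed 7 --out results/   # full pipeline
```

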