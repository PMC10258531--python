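# prlcortex

Analysis pipeline for studying cortical structure after central vision loss:
it defines visual-field regions of interest from microperimetry (the preferred
retinal locus and an eccentricity-matched control region), projects them onto
retinotopically annotated V1 surface meshes, extracts normalised cortical
thickness and NODDI metrics (neurite density, orientation dispersion) per
region, and runs the group statistics (Welch t-tests, three-way mixed
ANOVA/ANCOVA with Mauchly/Huynh–Feldt sphericity handling, and FDR-corrected
post-hocs). A synthetic-data generator produces every input the pipeline
consumes, so the whole stack is testable without imaging data.

## Modules

| module | purpose |
| --- | --- |
| `prlcortex.synthetic` | fixation clouds, radial sensitivity grids with central scotomas, magnification-weighted retinotopic meshes, per-vertex metric maps with injected group effects, full cohort bundles |
| `prlcortex.fixation` | PRL centre, bivariate contour ellipse area (BCEA), binocular map fusion, scotoma trimming, URL placement |
| `prlcortex.transfer` | field-to-surface vertex matching, mesh dilation to a minimum ROI size, lesion-projection-zone and eccentricity-band ROIs |
| `prlcortex.metrics` | hemisphere-mean thickness normalisation, per-ROI metric aggregation |
| `prlcortex.stats` | Welch t, split-plot mixed ANOVA/ANCOVA (Type III, sum-to-zero), Mauchly's W, Greenhouse–Geisser / Huynh–Feldt epsilons, Benjamini–Hochberg post-hocs |
| `prlcortex.pipeline`, `prlcortex.io`, `prlcortex.cli` | orchestration, plain-CSV I/O, validation, command line |

## CLI

```bash
# generate a synthetic study (CSV bundle)
prlcortex simulate --config cohort.yaml --out data/ --seed 7

# validate a bundle directory (exit 2 on violations)
prlcortex validate --in data/

# define PRL/URL for one participant
prlcortex roi define --fixations data/fixations.csv \
    --sensitivity data/sensitivity.csv --participant MD001 --out roi.json

# run every stage and write ROI labels, the metric table and effect tables
prlcortex run --in data/ --out results/

# statistics on an extracted metric table
prlcortex stats anova --metrics results/metrics.csv --design data/design.csv \
    --dv thickness_norm
prlcortex stats ttest --metrics results/metrics.csv --design data/design.csv \
    --roi LPZ
```

Exit codes: 0 success, 2 validation failure, 3 computation error.

## Conventions

All planar coordinates are visual-field degrees with the fovea at the origin;
polar angle is counter-clockwise from the right horizontal meridian. The right
visual hemifield projects to the left cortical hemisphere and vice versa.
Surfaces are per-participant vertex tables (id, hemisphere, eccentricity,
polar angle, V1 flag, metrics) plus a triangle list; all I/O is plain CSV.
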