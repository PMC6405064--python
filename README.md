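# calciscan

Micro-CT densitometry and stable-isotope statistics for calcareous
microfossil shells (planktic foraminifera and similar microscale
biomineral specimens).

The package implements a complete desk-scale analysis workflow:

* **Calcite CT number (CCN)** — per-scan calibration of reconstructed
  grayscale against a standard-calcite block and surrounding air, mapping
  air to 0 and pure calcite (2.71 g/cm³) to 1000. Because both references
  come from the same scan, the mapping cancels scan-to-scan X-ray
  spectrum/gain drift exactly.
* **Scan simulation** — trochospiral shell phantoms with known density and
  wall thickness, polychromatic parallel-beam projection with beam
  hardening (two-term attenuation model, optional 0.2 mm aluminium
  pre-filter), Poisson noise, and ramp-filtered back projection.
* **Wall thickness** — Hildebrand local-thickness maps (largest inscribed
  sphere) on segmented shell masks.
* **Statistics** — paired t-test, Shapiro–Wilk + Lilliefors-KS normality
  gate, one-way ANOVA, tie-corrected Kruskal–Wallis, Tukey HSD, and OLS
  with 95% mean-response bands.
* **Packaged tables** — per-specimen paired CT measurements (20 specimens)
  and individual isotope measurements (49 specimens across treatment
  groups A/B/C with genetic-type labels), with loaders, writers and the
  paired-difference arithmetic used in the analyses.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (table
arithmetic, inference thresholds, CCN identities, simulation properties,
thickness recovery, statistical calibration).

## CLI

```sh
calciscan reproduce --out report.json          # all packaged-table numbers
calciscan physical --out phys.json             # paired pre/post comparison
calciscan isotopes-groups --out groups.json    # treatment-group tests
calciscan isotopes-genotypes --out types.json  # genotype tests + regressions
calciscan simulate --specimens 3 --out simdir  # simulated polychromatic scan
calciscan ccn --volume simdir/reconstruction.tif --out ccn.json
calciscan thickness --mask mask.tif --voxel-size 0.8 --out tmap.tif
calciscan slices --volume simdir/reconstruction.tif --out slicedir
calciscan fixtures export --table ct --out table1.csv
```

Global flags: `--config FILE` (flat `key = value` overrides, see
`calciscan/config.py` for keys), `--seed N`, `--log-level LEVEL`.

## Notes

* Volumes are written as float32 multi-page TIFF with voxel size in
  metadata plus a JSON label sidecar (no NRRD dependency).
* The scan simulator is 2D parallel-beam by design; the instrument's
  cone-beam geometry is out of scope because all downstream claims
  concern relative density, which the parallel geometry reproduces.
* Published per-genotype regression values (R² 0.643/0.755, slopes
  0.0853/0.1281) are not reproducible from the printed table (its typed
  sample sizes differ from the figure captions); the pipeline reports the
  values computed from the packaged table instead.
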