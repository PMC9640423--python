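# ripaq — riparian strip quality from VHR multispectral imagery

`ripaq` turns very-high-resolution satellite imagery (an 8-band 2-m
multispectral stack plus a 0.5-m panchromatic band, WorldView-2-style)
into per-station scores of riparian vegetation quality. It is aimed at
river-basin managers and remote-sensing ecologists who need to rank
100-m stretches of riverbank for conservation, recovery or restoration
without walking the whole river.

The chain is classic object-based image analysis:

1. **Pansharpen** the multispectral stack to the panchromatic grid
   (least-squares component substitution, spectrally consistent in the
   Wald sense).
2. **Composite**: red-edge NDVI, RE-NDVI = (NIR − RE)/(NIR + RE), plus
   the first three principal components of the 8 bands — a standardised
   4-band analysis raster.
3. **Segment** the composite inside a 50-m stream buffer with
   multiresolution region merging (Baatz–Schäpe cost; scale 25, shape
   0.1, compactness 0.1).
4. **Classify** objects into water / forest / crops / urban with a
   hierarchical threshold cascade, and validate with a stratified object
   sample, confusion matrix, overall accuracy and Cohen's kappa.
5. **Score** each 100-m, per-bank station with the riparian strip
   quality index,

       RSQI = Σᵢ (%LUᵢ · Wᵢ) / 10,

   weights forest 10.0, crops 1.9, bare soil 1.7, infrastructure 1.9
   (range 17–100), categorised very low / low / moderate / high; field
   QBR scores (four 0–25 blocks) can be joined for agreement statistics
   (Shapiro–Wilk, Levene, Pearson) and restoration triage.

Because such imagery is commercial, the package ships a seeded synthetic
scene generator — a meandering river with a degraded riparian forest
strip, class-specific spectra and sensor noise, with per-pixel ground
truth — so the entire chain is testable end to end. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a 256 × 512 m corridor, run every stage, and inspect the
results (about half a minute):

```python
import json
import pandas as pd
import ripaq
from ripaq.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="example_out",
    scene=ripaq.SceneSpec(width_px=128, height_px=256, seed=7),
    n_stations=2,          # 2 centres x 2 banks = 4 scored units
    validation_n=30,
)
manifest = run_pipeline(cfg)
print("stages:", [s["name"] for s in manifest["stages"]])

metrics = json.load(open("example_out/validation.json"))
print(f"objects: {metrics['n_objects']}  "
      f"overall accuracy: {metrics['overall_accuracy']:.3f}  "
      f"kappa: {metrics['cohens_kappa']:.3f}")

stations = pd.read_csv("example_out/stations.csv")
print(stations[["station_id", "bank", "rsqi", "rsqi_category",
                "pct_forest", "pct_crops", "pct_urban"]]
      .round(1).to_string(index=False))
```

which prints:

```
stages: ['simulate', 'preprocess', 'segment', 'classify', 'validate', 'score']
objects: 56  overall accuracy: 0.933  kappa: 0.910
station_id  bank  rsqi rsqi_category  pct_forest  pct_crops  pct_urban
      S01L  left  37.9      very_low        23.4       31.4       45.2
      S01R right  22.9      very_low         4.8       52.0       43.2
      S02L  left  74.7      moderate        68.7       31.1        0.2
      S02R right  33.8      very_low        18.2       62.5       19.3
```

Reading this: the classifier recovered the simulated land cover with
kappa 0.91 against ground truth; station S02L keeps 68.7 % forest in its
strip and scores a moderate 74.7, while the other three banks are
dominated by crop and built-up intrusions and fall into the very-low
band — the stretches a manager would flag first. The run manifest
(`example_out/manifest.json`) records parameters and output hashes;
rerunning with the same seed reproduces the hashes exactly.

The same stages are available on the command line (`ripaq simulate`,
`preprocess`, `segment`, `score`, `report`, `run-all`); configuration
comes from a single YAML file.

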