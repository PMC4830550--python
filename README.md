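# cropsense

Participatory-sensing crop height assessment: can laypeople with
smartphones and handheld GPS units map the height variation of a crop
field well enough to be useful? `cropsense` implements the full analysis
chain for answering that question on a maize field:

* **Reference surface (TLS-style):** derive a crop height model (CHM)
  from terrain and canopy point clouds — ground filtering, moving-planes
  DTM interpolation, a 99th-percentile crop surface model (CSM),
  CHM = CSM − DTM, local-maximum filtering at plant (15 cm) and row
  (80 cm) scale, a 10 cm between-kernel difference filter, and a
  gap-filling Gaussian smoother. The result, CHMREF, is the benchmark.
* **Direct participant measurements:** ruler readings (M2, cm) and
  human-figure category estimates (M1, 1–10; category *k* maps to
  *k*·body height/10). GPS positions are co-registered onto the four
  predefined measurement rows with a 2-D similarity transform
  (scale *s*, rotation *θ*, translation *t*) fitted by iterative closest
  point, and interpolated to an area-wide surface (CHMPS) by ordinary
  kriging with a WLS-fitted variogram.
* **Image-based heights:** a 200 cm marker bar with a 15 cm reference
  band stands in the crop; pixels of a photograph are classified
  (random forest over multi-scale color/edge/texture/orientation
  features) into background / marker / reference / circle, masks are
  cleaned morphologically and clipped to the participant-drawn circle,
  and crop height = 200 − 15·(marker extent / reference extent).
* **Evaluation:** R² between participant and reference heights after
  dropping pairs above the 95th percentile of absolute differences,
  plus RMSE / mean / SD difference rasters (study area and the buried
  Roman-road strip; instruction regimes I1 vs I1+I2), and per-class
  precision / recall for the pixel segmentation.

A first-class synthetic-data module generates the whole study: a
150 m × 30 m field with heights 30–180 cm, a ~5 m wide road strip
~40 cm lower, laser-scanning-style point clouds, participant surveys
with GPS noise and a hidden datum offset, and rendered marker-bar
photographs with exact ground truth — so every stage is testable
without any field data.

## Worked example

```python
from cropsense.evaluation import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
print(round(report["chm"]["truth_rmse_cm"], 2))          # 3.26
print(round(report["chm"]["road_depression_cm"], 1))     # 40.1
print(round(report["groups"]["GPS"]["r2"], 3))           # 0.982
print(round(report["groups"]["SP"]["r2"], 3))            # 0.598
```

Reading: the derived reference CHM matches the generator's true height
surface to 3.26 cm RMSE (50 cm cells, field interior); the buried-road
strip is recovered 40.1 cm lower than its surroundings; and after
co-registration and kriging, the GPS-group heights (σ ≈ 1.2 m position
noise) explain 98% of the reference variance while the noisier
smartphone group (σ ≈ 5 m) explains 60% — positional accuracy, not
height-reading accuracy, is what limits the participatory surface.

The same pipeline is exposed on the command line:

```bash
cropsense simulate --seed 1 --outdir fixture/   # write a full fixture
cropsense chm --terrain fixture/terrain.xyz --canopy fixture/canopy.xyz \
          --out chmref.asc
cropsense run --seed 1 --out report.json        # end-to-end report
```

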