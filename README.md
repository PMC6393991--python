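# ecmorph

Computer-aided morphometry of the collagenic extracellular matrix (ECM) in
PicroSirius-red-stained pancreas histology, for researchers quantifying
desmoplasia in chronic pancreatitis and pancreatic ductal adenocarcinoma
(PDAC). Given digitized regions of interest (ROIs), the package measures, per
ROI:

- **Sirius-red-stained ECM surface (%)** — collagen pixels are classified by
  a colour rule (a wrapping red/magenta hue band in HSV space by default),
  grouped into connected components ("collagen islets"), and their summed
  area is expressed as a percentage of the tissue surface, excluding
  near-white tissue-free space;
- **2-D box-counting fractal dimension (D)** — the frame is covered by grids
  of ε-sided boxes and N(ε), the number of boxes containing collagen, is
  fitted on the log–log plot: D = d, the slope of log N(ε) against
  log(1/ε), taken over the most linear contiguous segment (selected by
  least-squares R²) with the slope computed by Tukey's iterated three-group
  resistant line. 0 ≤ D ≤ 2; the closer to 2, the more space-filling the
  collagen conformation;
- **degradation simulation** — the collagen mask is eroded to extinction by
  iterated 3×3 binary morphological erosion; the **number of cycles** until
  the ECM surface reaches 0 % and the **mean degradation velocity**
  (initial surface % ÷ cycles) summarize the trace.

Per-ROI measurements are pooled per group (normal pancreas *nPA*,
pancreatitis *iPA*, *PDAC*) and compared with two-sided pooled-variance
Student t-tests.

No image data ships with the method, so a seeded synthetic-fixture module
generates Sirius-red-like ROIs (pale-yellow tissue, white background,
red collagen islets of controllable area fraction and boundary roughness)
with exact ground-truth masks, reference shapes for fractal calibration, and
cohort-level measurement samples.

## Worked example

Generate four synthetic ROIs (two low-collagen "nPA", two high-collagen
"PDAC"), write a manifest CSV with columns `path,roi_id,case_id,group`, and
run the pipeline:

```sh
ecmorph analyze --manifest manifest.csv --out-dir out
# analyzed 4 ROI(s); 0 failure(s); wrote out/measurements.csv
cat out/measurements.csv
```

```text
roi_id,case_id,group,ecm_percent,fractal_dimension,n_cycles,velocity
roi0,case0,nPA,2.9992201010477775,1.0140670549116866,5.0,0.5998440202095555
roi1,case0,nPA,2.9992201010477775,1.1907200732292498,6.0,0.4998700168412962
roi2,case1,PDAC,19.999321826998067,1.501205595864211,15.0,1.333288121799871
roi3,case1,PDAC,19.999321826998067,1.6481708844463028,15.0,1.333288121799871
```

Each row is one ROI: the ECM occupies ~3 % of the tissue in the normal-like
fields versus ~20 % in the tumour-like fields; the fractal dimension and the
erosion cycle count rise with the amount and spatial complexity of the
collagen, and the velocity is the initial surface divided by the cycles.
The `out/audit/` directory holds the per-ROI fractal fit (JSON) and erosion
trace (CSV).

Group comparison on a synthetic cohort (library call; the `compare` command
does the same from a measurements CSV):

```python
from ecmorph import table2_cohort_spec, generate_cohort_measurements, build_results_table
ms = generate_cohort_measurements(table2_cohort_spec(seed=1))
t = build_results_table(ms, [("nPA", "iPA"), ("nPA", "PDAC"), ("iPA", "PDAC")])
print(t.to_text())
```

```text
Group summaries (mean ± SD):
  nPA (n=50): ecm_percent=2.220±0.249, fractal_dimension=1.358±0.017, n_cycles=12.849±0.881, velocity=0.149±0.011
  iPA (n=60): ecm_percent=14.034±1.072, fractal_dimension=1.699±0.010, n_cycles=21.222±1.314, velocity=0.671±0.036
  PDAC (n=70): ecm_percent=22.705±1.875, fractal_dimension=1.741±0.011, n_cycles=27.493±1.624, velocity=0.718±0.046
Pairwise unpaired Student t-tests (two-sided):
  nPA vs iPA [ecm_percent]: t=-76.168, df=108, p=1.07e-95 *
  ...
  iPA vs PDAC [velocity]: t=-6.371, df=128, p=3.1e-09 *
```

A `*` flags p < 0.05. Other commands: `ecmorph synth` (write fixture
images/masks/cohorts from a TOML spec) and `ecmorph simulate` (degradation
trace for a single image).

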