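# fragmetrics

Morphometry of residual rectal tumor after neoadjuvant chemoradiotherapy
(CRT), for researchers evaluating imaging techniques for response
assessment.

## The problem

After CRT, rectal tumors regress in one of two patterns: **shrinkage**
(the tumor recedes concentrically as a single bulk) or **fragmentation**
(the bulk disintegrates into scattered clusters of tumor cells embedded in
fibrosis, conventionally called fragmentation when clusters are at least
3 mm apart). Whether any imaging technique can distinguish a *good*
clinical response from a *complete* one depends on two geometric
quantities measurable on histopathology:

* the **short-axis width** `w` of the widest residual fragment per
  patient — a technique with spatial resolution `r` can only detect a
  patient's residual tumor if `w ≥ r` (a 3 mm × 0.05 mm sliver is
  invisible at 1 mm resolution, so the short axis is what matters);
* the **minimum depth** `d` of vital tumor below the luminal surface — a
  technique with imaging depth `z` only reaches it if `d ≤ z`.

Over a cohort, the pair `(min_patients w, max_patients d)` is the
resolution/imaging-depth specification a technique would have needed to
detect residual tumor in *every* patient.

`fragmetrics` computes all of this from per-slide tissue **label masks**
(integer rasters with classes background/tumor/mucosa/other, as produced
by tissue classifiers such as HALO): it extracts 8-connected tumor
fragments, measures each fragment's width as the **diameter of the
largest inscribed disk** (an exact Euclidean distance transform;
minimum-Feret caliper width available as an alternative), measures
shortest distances to the luminal surface, classifies the regression
pattern by single-linkage clustering with the 3 mm rule, aggregates
per-patient summaries (widest fragment, shallowest depth, central-slide
area, volume = Σ slide area × slide spacing), compares TRG 2 vs TRG 3
groups (Shapiro–Wilk-gated t-test / Mann–Whitney, p ≤ 0.05), and reports
per-modality detectable fractions.

Because no such cohort is publicly deposited, the package ships a
synthetic cohort generator (`fragmetrics.synthetic`) that renders label
masks with exactly known geometry — capsule-shaped fragments with widths
spanning 0.06–14.9 mm and depths 0.001–8.9 mm, serial slides, both
response patterns — so every stage of the pipeline can be validated
against ground truth.

## Worked example

```python
from fragmetrics import (GeneratorConfig, PipelineConfig, generate_cohort,
                         cohort_requirements, fraction_below)
from fragmetrics.pipeline import measure_patient

cohort, truths = generate_cohort(GeneratorConfig(n_patients=6, seed=7))
cfg = PipelineConfig()
summaries = [measure_patient(rec, cfg)[1] for rec in cohort.patients]
for s, t in zip(summaries, truths):
    print(f"{s.patient_id} TRG{s.trg} {s.pattern:13s} "
          f"width {s.max_width_mm:6.2f} mm (true {t.max_width_mm:6.2f}) "
          f"depth {s.min_depth_mm:5.3f} mm (true {t.min_depth_mm:5.3f}) "
          f"volume {s.volume_mm3:8.2f} mm^3")
res, depth = cohort_requirements(summaries)
print(f"required resolution {res:.2f} mm, required imaging depth {depth:.2f} mm")
```

prints

```
P000 TRG2 shrinkage     width   8.46 mm (true   8.45) depth 0.020 mm (true 0.015) volume  1374.24 mm^3
P001 TRG3 shrinkage     width   0.11 mm (true   0.11) depth 0.060 mm (true 0.051) volume     0.15 mm^3
P002 TRG2 fragmentation width  10.35 mm (true  10.34) depth 0.020 mm (true 0.002) volume  1183.36 mm^3
P003 TRG3 shrinkage     width   7.88 mm (true   7.88) depth 0.040 mm (true 0.040) volume   312.39 mm^3
P004 TRG2 fragmentation width   1.05 mm (true   1.04) depth 0.020 mm (true 0.003) volume    17.85 mm^3
P005 TRG3 fragmentation width   2.33 mm (true   2.33) depth 0.020 mm (true 0.002) volume   230.23 mm^3
required resolution 0.11 mm, required imaging depth 0.06 mm
```

Each row is one patient: the measured pattern, the widest fragment (vs
the generator's true capsule width — agreement is within the 0.02 mm
pixel), the shallowest tumor depth below the luminal surface, and the
tumor volume over all serial slides. The final line is the cohort-level
requirement pair: any technique with ≥ 0.11 mm resolution would miss
patient P001 entirely, and one imaging shallower than 0.06 mm would miss
P001's tumor as well.

The same pipeline runs from the shell on a cohort directory of PNG/TIFF
masks plus a `cohort.json` manifest:

```bash
fragmetrics run-all --out results/ --seed 42 --n-patients 30
fragmetrics summarize --cohort results/cohort --out results/ --plot
```

writing per-fragment and per-patient CSV tables, the per-TRG summary JSON
(median and range of widths, depths, areas, volumes, with p-values),
ECDF tables, and the per-modality detectability report. Re-running with
the same seed reproduces every output byte for byte.

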