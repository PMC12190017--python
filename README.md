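# her2ish

Automated quantification of **HER2 dual-probe bright-field in-situ
hybridization (Dual BF ISH)** in breast carcinoma, built as a deterministic,
fully testable pipeline with a synthetic slide simulator in place of patient
material.

## Who this is for

Determining HER2 (*ERBB2*) status guides therapy in 15–20% of breast
cancers.  In the bright-field dual-probe assay, HER2 copies appear as black
silver-precipitate dots and the chromosome-17 centromere (CEP17) as red Fast
Red dots inside hematoxylin-counterstained nuclei.  A reader counts both
signals in ≥20 nuclei and reports the HER2/CEP17 ratio, the mean HER2 copies
per cell, and the ASCO/CAP ISH group.  This package re-implements that whole
workflow for people studying *the workflow itself*: how nucleus detection,
signal counting, inclusion rules, ROI selection and — above all — scanner
and scanning-protocol choice propagate into the final clinical call.

Because no public Dual BF ISH image sets exist at controlled quality levels,
the package ships a **generator**: tiles with exact per-nucleus ground truth
(`her2ish.synth`), plus scanning-protocol degradation models (resolution,
optical blur, stain fading, patchy focus instability, extended-focus
compositing) for six named protocols (A1, A2, B1, B2, B3, C1).

## The quantification core

For reportable nuclei (by default ≥2 HER2 **and** ≥2 CEP17 signals each,
i.e. two complete chromosomes 17; thresholds adjustable for
monosomy/polysomy), over the first n ∈ [20, 200] nuclei:

```
ratio = mean(HER2 signals/nucleus) / mean(CEP17 signals/nucleus)
```

ASCO/CAP ISH group (boundaries inclusive):

| group | ratio  | mean HER2 copies/cell | status        |
|-------|--------|-----------------------|---------------|
| 1     | ≥ 2.0  | ≥ 4.0                 | Amplified     |
| 2     | ≥ 2.0  | < 4.0                 | Non-amplified |
| 3     | < 2.0  | ≥ 6.0                 | Non-amplified |
| 4     | < 2.0  | 4.0 – <6.0            | Non-amplified |
| 5     | < 2.0  | < 4.0                 | Non-amplified |

Borderline results (groups 2–4, or ratio within [1.8, 2.2]) are re-counted
at 40 nuclei, pooling additional non-overlapping ROIs as needed.

## Worked example

```python
from her2ish import (sample_case_profile, render_roi, analyze_roi_image,
                     rectangle_roi, run_case)

profile = sample_case_profile(target_group=1, seed=7)   # an amplified tumour
rois = [rectangle_roi(f"r{j}", j * 130.0, 0.0, 120.0, 120.0, 0.2)
        for j in range(3)]                              # 120x120 um ROIs

def analyze(roi):
    j = int(roi.id[1:])
    image, _ = render_roi(profile, 600, 600, 0.2, seed=7 + j)
    return analyze_roi_image(image, 0.2, roi_id=roi.id).nuclei

report = run_case(rois, analyze, case_id="demo")
r = report.result
print(f"n={r.n_reported}  HER2/cell={r.mean_her2_per_cell:.2f}  "
      f"CEP17/cell={r.mean_cep17_per_cell:.2f}  ratio={r.ratio:.2f}  "
      f"group={r.ish_group}  {r.status}")
```

prints

```
n=20  HER2/cell=11.40  CEP17/cell=4.40  ratio=2.59  group=1  Amplified
```

i.e. the first 20 reportable nuclei averaged 11.40 HER2 and 4.40 CEP17
signals, a ratio of 2.59 — group 1, HER2 amplified, matching the profile the
generator was asked for.

The same flow is available on the command line:

```sh
her2ish simulate --seed 5 --out sim --n-cases 2 --group 1 --group 5
her2ish analyze sim/*.png --out reports        # exit 3 signals an n/a case
her2ish compare --protocol A1 --protocol C1 --seed 5 --out cmp
```

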