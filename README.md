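# ceboost

Contrast-enhancement boost (**CE-boost**) post-processing for CT
angiography, with digital vessel phantoms, objective image-quality
metrics, and reader-agreement statistics.

## The problem

Head and neck CT angiography must resolve small posterior-circulation
arteries (posterior cerebral artery, basilar artery, vertebral arteries;
calibers ≈2–4 mm) whose opacification is limited by how much iodinated
contrast can safely be injected.  CE-boost amplifies vascular enhancement
in software, using the pre-contrast acquisition that is usually scanned
anyway:

```
iodine  = enhanced − rigid_align(pre)        # subtraction isolates iodine
boosted = denoise(enhanced) + w · denoise(iodine)
```

Subtraction doubles the noise variance, so the iodine map is denoised
(3-D non-local means by default) before being added back with weight
`w` (default 1).  With the denoiser disabled and `w = 1` the pipeline is
exactly `boosted = 2·enhanced − pre`.

The package is aimed at imaging researchers who want to study this class
of post-processing quantitatively: it ships a phantom generator with full
ground truth (true iodine map, compartment masks, applied misalignment),
the standard CTA quality metrics — ROI attenuation, image noise (SD in a
100 mm² subcutaneous-fat ROI), SNR = attenuation/noise,
CNR = (attenuation − muscle)/noise, voxelwise SNR maps, and vessel
sharpness as the full width at half maximum (FWHM) of an attenuation line
profile — and the statistical layer used in reader studies (paired t,
Wilcoxon signed-rank with an exact small-sample tail, Cohen's kappa with
interpretation bins).

## Worked example

```python
from ceboost import (BoostParams, ce_boost_pipeline, default_head_neck_spec,
                     make_phantom, evaluate_case, records_to_dataframe)
from ceboost.batch import default_plan

spec = default_head_neck_spec(seed=42)          # 3 vessels, 10 HU noise
pre, enhanced, truth = make_phantom(spec)
boosted, iodine, _ = ce_boost_pipeline(pre, enhanced,
                                       BoostParams(registration="none"))
records = evaluate_case(enhanced, boosted, default_plan(spec))
print(records_to_dataframe(records).round(2).to_string(index=False))
```

```
segment      variant  attenuation_hu  noise_hu    snr    cnr  fwhm_mm
    PCA conventional          377.87     10.04  37.65  31.70     2.09
     BA conventional          413.75     10.04  41.22  35.27     3.07
     VA conventional          442.70     10.04  44.11  38.15     3.64
    PCA      boosted          709.66      0.95 745.81 677.27     2.08
     BA      boosted          782.30      0.95 822.14 753.61     3.12
     VA      boosted          836.75      0.95 879.37 810.84     3.62
```

Boosting roughly doubles vessel attenuation (the added iodine signal,
450 → 45 HU contrast, comes back on top of the enhanced image) while the
denoising step cuts the fat-ROI noise, so SNR and CNR rise sharply.
Per-case FWHM jitters with the noise (here BA moved up, the other two
down); the batch report over many seeds is what shows the systematic
sharpening.  `ceboost.batch.run_phantom_batch` +
`ceboost.stats_report.compare_report` produce that per-segment
mean ± SD table with routed p-values.

The same steps are available from the shell:

```
ceboost phantom --seed 42 --out phantom/
ceboost boost --pre phantom/pre.nii.gz --enhanced phantom/enhanced.nii.gz \
              --out boosted.nii.gz --register none
ceboost qa --conventional phantom/enhanced.nii.gz --boosted boosted.nii.gz \
           --plan plan.yaml --out qa.csv
ceboost report --qa qa_batch.csv --ratings ratings.csv --out report/
```

## Layout

| module | contents |
|---|---|
| `ceboost.volume_io` | `CTVolume`, NIfTI/DICOM readers, NIfTI writer, mm↔voxel |
| `ceboost.phantom` | phantom spec/truth types, supersampled rasterizer |
| `ceboost.boost` | registration, subtraction, denoisers, recombination |
| `ceboost.qa` | ROI stats, noise, SNR/CNR, SNR map, profiles, FWHM |
| `ceboost.stats_report` | normality, paired tests, exact Wilcoxon, kappa, report tables |
| `ceboost.batch` | phantom-replicate driver feeding the report |
| `ceboost.cli` | `ceboost phantom/boost/qa/report` |

See `docs/methods.md` for the model details, parameter defaults and
their rationale, and known limitations.
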