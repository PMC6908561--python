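# attenquant

Quantification of soft-tissue attenuation artifacts in myocardial
perfusion SPECT, from paired attenuation-corrected (AC) and
non-attenuation-corrected (NAC) short-axis volumes.

Attenuation by the diaphragm, breasts and lateral chest wall removes
counts from NAC images in patterns that mimic true perfusion defects,
and the pattern differs between camera designs (multi-pinhole CZT
cameras vs conventional rotating NaI cameras). For physicists and
physicians who need those patterns characterized — and for anyone
validating perfusion-quantification software — `attenquant` measures
the artifact instead of eyeballing it, and ships a digital cardiac
phantom so the whole pipeline is verifiable without clinical data.

## Method

The LV is reduced to an `n_slices × 12` grid of normalized counts
(20 slices at 4 mm voxels for the `czt` profile, 12 at 6.4 mm for the
conventional `ventri` profile; twelve 30° sectors per slice, 0° =
anterior, 90° = lateral). With `r_ij` the per-segment ratio of
normalized NAC to normalized AC counts, the artifact mask is
`M = {(i,j) : r_ij < τ}` at the per-camera threshold `τ` (0.90 czt,
0.85 ventri), and

```
extent       = |M| / n_segments
localization = circular mean of sector-centre angles over M   [deg]
depth        = mean(NAC over M) / mean(NAC over top 30% segments)
```

Depth is the surviving count level inside the artifact (73% = a 27%
reduction). A true perfusion defect scales NAC and AC identically, so
it cancels in `r` — the pipeline sees attenuation, not disease.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

Simulate a CZT acquisition of a uniform myocardial shell with an
inferolateral attenuation artifact (transmission 0.70 over sectors
90–150°, 0.76 over 150–210°, on the 17 most basal of 20 slices), then
quantify it:

```python
from attenquant import (CZT, LVGeometry, ArtifactSpec, AttenuationZone,
                        generate_study, quantify_study)

zones = (
    AttenuationZone(90.0, 150.0, slice_first=1, slice_last=17, transmission=0.70),
    AttenuationZone(150.0, 210.0, slice_first=1, slice_last=17, transmission=0.76),
)
study = generate_study(geometry=LVGeometry(), artifact=ArtifactSpec(zones),
                       profile=CZT, noise=False)
m = quantify_study(study)
print(f"extent       {m.extent_pct}%  ({m.n_artifact_segments} of {m.n_total_segments} segments)")
print(f"localization {m.localization_deg:.0f} deg")
print(f"depth        {m.depth_pct}%  (threshold {m.threshold_used})")
```

```
extent       28%  (68 of 240 segments)
localization 150 deg
depth        73%  (threshold 0.9)
```

28% of the 240 segments are attenuated; the artifact centre sits at
150° (inferolateral wall); counts inside it run at 73% of the
brightest-segment level. The same artifact measured at the conventional
profile is narrower, deeper and more inferior — the built-in reference
phantoms capture exactly that contrast:

```
$ attenquant fixtures --out demo/
phantom_czt: extent 28%  localization 150  depth 73%
phantom_ventri: extent 19%  localization 165  depth 67%
```

The CLI also exposes `simulate`, `quantify`, `cohort` and `compare`
(`attenquant --help`), reading/writing NIfTI volumes with JSON
sidecars, CSV sector tables and JSON metric reports.

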