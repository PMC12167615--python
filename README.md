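# psma-sink

Quantification of radioligand uptake in organs at risk on PSMA PET, and
analysis of the *tumour sink effect* — the hypothesis that a large tumour
burden sequesters enough tracer to depress uptake in healthy organs
(kidneys, liver, parotid glands, spleen), which would matter for
individualized radionuclide-therapy dosing.

The package is aimed at nuclear-medicine image analysts. It provides:

* **SUV conversion** — activity concentration `Ac` (kBq/mL) to the unitless
  standardized uptake value `SUV = Ac / (Ai / w)`, with the administered
  activity `Ai` decay-corrected to the start of imaging
  (`Ai' = Ai · 2^(−Δt/T½)`, F-18 `T½ = 109.77` min) and `w` the body weight
  (density 1 g/cm³).
* **Automatic measurement-sphere placement** in an organ mask (30 mm sphere
  for the liver, 15 mm otherwise): compute SUVpeak (mean SUV in a 1 cm³
  sphere) for every organ voxel; keep candidate centres whose sphere stays
  ≥ 5 mm from the organ edge (Euclidean distance transform); score each
  candidate by max + SD of SUVpeak inside its sphere; place the sphere where
  the score is closest to the median score. Hot metastases get extreme
  scores and are avoided; the organ SUVmean is read out in the chosen
  sphere.
* **Tumour-burden metrics** — total lesion volume `TLV` (cm³), total lesion
  uptake `TLU = TLV · SUVmean(lesions)`, and the percentage of injected
  activity in tumour, `100 · TLU / (w·1000)`.
* **Cohort statistics** — median/IQR summaries, tie-corrected Spearman
  correlations of TLV/TLU against organ SUVmean with a two-tailed test,
  six-group TLV stratification (0, >0–25, >25–189, >189–532, >532–1355,
  >1355 cm³), and scatter data with `log10(x+1)` burden axes.
* **Digital phantoms** — single-patient phantoms (ellipsoidal organs,
  spherical lesions, voxel noise) with exact ground truth, and synthetic
  cohorts with a parameterized sink coupling
  `SUV_o = B_o · (1 − β·TLU/(TLU+K)) · ε_o`, so every stage is testable
  without patient data.

## Worked example

```python
from psma_sink import to_suv
from psma_sink.phantom import default_phantom_config, generate_patient
from psma_sink.voi_placement import OrganRegion, place_and_measure

ph = generate_patient(default_phantom_config(seed=1, noise_sd_frac=0.05))
suv = to_suv(ph.pet, ph.meta)
for organ, mask in ph.organ_masks.items():
    r = place_and_measure(suv, OrganRegion(organ, mask))
    t = ph.truth["organ_suv_target"][organ]
    print(f"{organ:15s} SUVmean={r.suv_mean:6.2f}  (true {t:5.1f})  "
          f"candidates={r.n_candidates:4d}  flagged={r.flagged}")
```

prints

```
liver           SUVmean= 11.80  (true  11.8)  candidates= 775  flagged=False
spleen          SUVmean= 11.30  (true  11.3)  candidates= 293  flagged=False
kidneys         SUVmean= 13.09  (true  13.1)  candidates=  76  flagged=False
parotid_glands  SUVmean= 18.54  (true  18.6)  candidates=  38  flagged=False
```

i.e. with 5% voxel noise the automatically placed spheres recover each
organ's true uptake to well within 1%; `candidates` is the number of
admissible sphere centres after the edge-margin filter, and `flagged` marks
placements whose sphere max exceeds twice the organ median (review flag for
high-burden patients).

The same works from the shell:

```bash
psma-sink simulate-patient --seed 1 --out patient/
psma-sink measure --pet patient/pet.nii.gz --organs patient/organs.nii.gz \
    --labels patient/labels.yaml --meta patient/meta.yaml \
    --lesions patient/lesions.nii.gz --out patient.csv
psma-sink end-to-end --n 500 --beta 0.6 --seed 1 --out run/
```

`end-to-end` simulates a 500-patient cohort with sink coupling β = 0.6,
K = 500 SUV·cm³ and writes the report bundle (correlations table, TLV-strata
summary, organ summaries, scatter data, manifest).

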