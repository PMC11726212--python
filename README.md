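# adattn

Multi-label prediction of Alzheimer's disease (AD) subtypes and severity
from routine tabular clinical data, using per-group scaled dot-product
self-attention.

Binary AD/not-AD classifiers discard the structure clinicians actually act
on: *which* presentation a patient has and *how severe* it is. `adattn`
targets three recognized AD subtypes simultaneously — Logopenic Variant
(language), Posterior Cortical Atrophy (visual processing) and Frontal
Variant (behaviour/executive) — each as a continuous severity in [0, 1].
Overall severity is the mean of the three, binned into
asymptomatic/mild/moderate/severe at thresholds 0.25/0.5/0.75/1.0; a
subtype is called present when its severity is ≥ 0.5.

The model routes an 81-variable clinical panel (hematology, biochemistry,
endocrine/immune markers, lifestyle and demographics) through four group
modules. Each module embeds its features as tokens X (one token per
feature) and applies self-attention

    Attention(X) = softmax(X Xᵀ / √d_k) X

so the network learns which markers within a group to emphasize per
patient. Pooled group context vectors concatenate with two directly fed
neurological markers (serum β2-microglobulin and the MMSE cognitive score)
and pass through a fully connected trunk with three logistic outputs. The
package also provides the complete surrounding protocol: mean imputation,
clinical-reference-range min-max normalization, a 70/15/15 split, SMOTE
oversampling of the training set (with label interpolation), a
parameter-matched fully connected baseline, the evaluation conventions
(per-subtype confusion metrics, class-conditional severity accuracy), and a
seeded synthetic-cohort generator standing in for the private clinical
dataset. It is aimed at methods researchers who want to stress this model
family on data whose generative structure they control.

## Worked example

```python
import adattn as ad

schema = ad.default_schema()                      # 81-variable clinical panel
cfg = ad.GeneratorConfig(n=430, beta=5.0, seed=7) # study-sized synthetic cohort
table, truth = ad.generate_cohort(cfg, schema)

data = ad.preprocess(table, truth.severities, schema, split=ad.SplitSpec(seed=7))
model = ad.build_model(schema, ad.ModelConfig(seed=7))
model, hist = ad.train(model, data.train_X, data.train_y,
                       data.val.values, data.val_y,
                       ad.TrainConfig(max_epochs=150, patience=15, seed=7))

preds = model.forward(data.test.values)
import pandas as pd
report = ad.make_report(
    pd.DataFrame(preds, columns=["lv", "pca", "fv"]).assign(patient_id=data.test.patient_ids),
    pd.DataFrame(data.test_y, columns=["lv", "pca", "fv"]).assign(patient_id=data.test.patient_ids),
)
print(report.subtype_frame().to_string(index=False))
print(report.severity_frame().to_string(index=False))
```

Output:

```
                   subtype  accuracy  precision  recall   f1
         Logopenic Variant      96.9       94.6   100.0 97.2
Posterior Cortical Atrophy      93.8       87.5   100.0 93.3
           Frontal Variant      92.2       90.9    93.8 92.3
 asymptomatic  mild  moderate  severe  overall
         95.2  81.8      84.6    89.5     87.8
```

Read: on the held-out test split of 64 synthetic patients, the model calls
each subtype's presence with ~92–97% accuracy (precision/recall/F1 are the
usual 2×2 quantities at threshold 0.5), and places 87.8% of patients in
their correct severity level on average across the four levels
(class-conditional, unweighted mean).

The same pipeline is available as a CLI:

```bash
adattn generate --n 430 --seed 7 --out cohort/
adattn preprocess --cohort cohort/cohort.csv --labels cohort/labels.csv --seed 7 --out prep/
adattn train --train prep/train.csv --train-labels prep/train_labels.csv \
             --val prep/val.csv --val-labels prep/val_labels.csv \
             --seed 7 --out model.json
adattn predict --model model.json --cohort prep/test.csv --out preds.csv \
               --dump-attention attn/
adattn evaluate --pred preds.csv --truth prep/test_labels.csv --out report/
```

`--dump-attention` exports each patient's per-group attention-weight rows,
the model's account of which markers it weighted.

See `docs/methods.md` for the model, the generator's assumptions, and all
numerical conventions.

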