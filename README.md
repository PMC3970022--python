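# mtai — the Medial Temporal Atrophy index from single-slice planimetry

`mtai` quantifies medial temporal lobe (MTL) atrophy relative to global
brain atrophy from a single coronal MRI slice, for clinicians and
researchers who want an objective MTL-atrophy measure without volumetric
segmentation. Three regions are traced per hemisphere on the coronal slice
at the level of the interpeduncular fossa:

- **A** — the MTL region (bounded by the tentorium cerebelli, cerebral
  peduncles, roof of the temporal horn, and collateral sulcus);
- **B** — the parenchyma within A (hippocampus + parahippocampal gyrus,
  excluding fimbria taenia and choroid plexus);
- **C** — the body of the ipsilateral lateral ventricle.

The index, computed per hemisphere, is

```
MTAi = (A − B) × 10 / C
```

A − B is the CSF-filled portion of the MTL region (parenchyma already
lost); dividing by C normalizes it against unspecific global atrophy, so
the ratio needs no intracranial-volume or age correction. Two hemispheric
values are summarized by their median (the mean of the two) and the Index
of Asymmetry

```
IA = (lMTAi − rMTAi) / (lMTAi + rMTAi) × 100   [percent]
```

with |IA| ≥ 3% flagging significant hemispheric asymmetry, in which case
the per-hemisphere values — not the median alone — should be reported.
Between two dated studies the yearly (relative) atrophy rates are

```
yrMTA  = [(A2 − B2) − (A1 − B1)] × 120 / months
yrMTAr = [(A2 − B2) − (A1 − B1)] × 120 / [(C2 − C1) × months]
```

The package converts traced polygon ROIs (its own ROI JSON format, or
ImageJ `.roi` files) into physical areas, accepts pre-measured areas as a
CSV, extracts coronal slices from NIfTI volumes or DICOM series, and ships
a geometric phantom with analytically exact areas for validation.

## Worked example

The bilateral mild-AD case with areas (mm²) right A=326.5, B=201.4,
C=189.7 and left A=326.5, B=224.0, C=175.2:

```python
from mtai import RegionAreas, summarize_bilateral

res = summarize_bilateral(
    RegionAreas("LEFT",  A=326.5, B=224.0, C=175.2),
    RegionAreas("RIGHT", A=326.5, B=201.4, C=189.7),
)
print(res.as_dict())
```

prints

```
{'left_mtai': 5.85, 'right_mtai': 6.59, 'median_mtai': 6.22,
 'ia_percent': -5.98, 'asymmetric': True,
 'asymmetry_threshold_percent': 3.0}
```

Right MTAi 6.59 exceeds left 5.85; the IA (−5.98% unrounded, −5.95% when
computed from the 2-decimal presentation values) is beyond the ±3% band,
so the case is asymmetric and the median 6.22 should not be reported
alone. The same numbers come out of the CLI:

```sh
mtai compute areas.csv            # per-subject MTAi/median/IA report
mtai longitudinal areas.csv       # yrMTA / yrMTAr from dated studies
mtai phantom --out-dir fixtures   # synthetic slice + analytic truth
```

where `areas.csv` has columns
`subject_id, study_date, hemisphere, A_mm2, B_mm2, C_mm2`.

An illustrative, non-normative reference table of group means (healthy
controls through dementia subtypes) is available via
`mtai.reference_table()`; it carries an explicit disclaimer and is not a
set of diagnostic cut-offs.

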