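# gliohab

Voxel-wise habitat imaging of diffuse gliomas from multiparametric MRI, and
prediction of IDH mutation status from the resulting habitat composition.

## The problem

IDH (isocitrate dehydrogenase) mutation status splits diffuse gliomas into
prognostically distinct groups, and a noninvasive imaging read-out of that
status is clinically valuable. Single quantitative maps (ADC, pH-weighted
CEST) separate the groups only moderately well; this package implements a
*habitat imaging* approach that combines four co-registered channels —
contrast-enhanced T1-weighted imaging (CE-T1WI), FLAIR, the amine CEST
asymmetry MTR<sub>asym</sub>(3.0 ppm), and the apparent diffusion
coefficient (ADC) — and partitions tumor voxels into data-driven habitats
whose per-tumor mixture predicts IDH status.

It is aimed at quantitative-imaging researchers who want an end-to-end,
fully testable re-implementation of this pipeline that runs on synthetic
phantoms with known ground truth (the generator is a first-class module),
and that accepts real co-registered NIfTI volumes with the same interfaces.

## The method

1. **CEST mapping.** From a sampled z-spectrum S(ω) (29 offsets in three
   bands: −3.5…−2.5, −0.3…+0.3, +2.5…+3.5 ppm at 0.1 ppm spacing) and the
   unsaturated reference S₀, the pH-weighted asymmetry is

   MTR<sub>asym</sub>(3.0 ppm) = S(−3.0 ppm)/S₀ − S(+3.0 ppm)/S₀,

   with each band value taken as a width-0.4 ppm integral (band average
   over ±0.2 ppm). SAGE acquisitions average gradient echoes 1–2 first.
   B₀ inhomogeneity is removed by a two-stage correction: k-means
   clustering of normalized z-spectra, an inverted-Lorentzian fit
   1 − AΓ²/(Γ² + (ω−δ)²) to each cluster-mean spectrum near water, and
   per-voxel re-sampling of the spectrum at ω + δ.
2. **Features.** Channels are z-scored per subject within the brain mask;
   one voxel per 4×4×4 = 64-voxel cell is sampled.
3. **Two-level clustering.** A 20×20 batch-learning self-organizing map
   (N = k²_max = 400 protoclusters, Gaussian neighborhood, linear radius
   schedule) quantizes the feature cloud; K-means partitions the 400
   prototype vectors into K classes (K ∈ {4,6,8,10,12,16,20}, working
   default K = 10); each tumor voxel inherits the class of its nearest
   prototype.
4. **Classification.** Per tumor, the label composition p (percentages)
   becomes log₁₀(p + 10⁻²); a linear SVM with a two-step grid search over
   the cost C (nested in each fold) is evaluated by leave-one-out
   cross-validation, reporting AUC/accuracy/sensitivity/specificity/
   precision/recall/F1 with wild-type as the positive class. Candidate K
   values are compared with class-stratified bootstrap resampling followed
   by one-way ANOVA + Tukey HSD.
5. **Group statistics.** Each label is categorized M / N / W according to
   whether its log-ratio is significantly higher in mutant, not different,
   or higher in wild-type tumors (Mann–Whitney U + Benjamini–Hochberg,
   α = 0.05); spherical biopsy targets take the majority category; marker
   tables are compared with Kruskal–Wallis + Dunn and within-category
   Mann–Whitney U + BH.

## Worked example

```python
import gliohab as gh
from gliohab.classify import compositions_to_table

spec = gh.HabitatSpec()                      # 4 planted habitats, 48^3 volumes
cohort = gh.generate_cohort(spec, n_mutant=30, n_wildtype=30, seed=0)
features = gh.sample_features(cohort.stacks, stride=4)
model = gh.TwoLevelHabitatClustering(n_clusters=10, random_state=0).fit(features.X)

comps = [gh.composition(model.label_volume(s), idh_status=s.idh_status)
         for s in cohort.stacks]
X, y, ids = compositions_to_table(comps)
cv = gh.svm_loocv(X, y, subject_ids=ids, seed=0)
print({k: round(v, 3) for k, v in cv.metrics.items()})
print(gh.categorize_labels(comps).categories)
```

prints

```
{'auc': 0.994, 'accuracy': 0.95, 'sensitivity': 0.967, 'specificity': 0.933,
 'precision': 0.935, 'recall': 0.967, 'f1': 0.951}
{1: 'W', 2: 'W', 3: 'N', 4: 'W', 5: 'M', 6: 'M', 7: 'N', 8: 'M', 9: 'N', 10: 'M'}
```

i.e. on this phantom cohort the leave-one-out SVM separates the IDH classes
almost perfectly (AUC 0.994), and the categorization recovers both
mutant-like (M) and wild-type-like (W) habitat labels. (Labels are numbered
by ascending ADC, so the low-ADC wild-type-like habitats take the low label
numbers here.)

The same stages are exposed on the command line:

```bash
gliohab simulate --out sim --n-mutant 4 --n-wildtype 4 --shape 32 --seed 0
gliohab extract --cohort sim/cohort.csv --volume-root sim --out features.csv
gliohab train --features features.csv --k 10 --out model.json
gliohab run --out-dir run_default          # full pipeline on a phantom cohort
```

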