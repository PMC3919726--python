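# adherit

Twin-design heritability analysis for plate-based leukocyte–endothelial
adhesion assays.

Leukocyte adhesion to the vascular endothelium drives pathology in
atherosclerosis, multiple sclerosis, diabetic retinopathy and other
inflammatory disease. A cell-based screen measures it by loading
Calcein-labelled lymphoblastoid cell lines (LCLs) onto an endothelial
monolayer (EA.hy926) in 96-well plates, washing three times, and reading
fluorescence before and after washing. Assaying LCLs from monozygotic (MZ)
twin pairs against full-sibling pairs turns the screen into a genetics
experiment: excess MZ resemblance estimates the trait's heritability.

`adherit` implements that pipeline for analysts working with plate-reader
exports and a pair manifest:

1. **plate_io** — tidy-CSV readers/writers and cross-table validation for
   well readings, plate layouts, standard-curve points and pair manifests.
2. **qc** — replicate CV, Z′-factor, signal-to-noise, composite Z′ and
   plate pass/fail gating.
3. **quantify** — % input RFU (`100 · RFU_wash3 / RFU_pre`), four-parameter
   logistic (4PL) standard curves `y = d + (a−d)/(1+(x/c)^b)` with exact
   inversion to % adherent cells, positive-control standardization that
   cancels plate-wide gain, and a cross-plate consistency ANOVA.
4. **heritability** — one-way ANOVA intraclass correlation (ICC) per
   zygosity group, Falconer's estimate `h² = 2(r_MZ − r_DZ)`, a permutation
   null for the empirical p-value, confounder screening (age, sex,
   ethnicity, growth class, transformation time) and a variance-equality
   F-test.
5. **simulate** — a generator of complete synthetic studies (additive
   genetic model → phenotypes → plates → CSVs) with known ground truth.

The central objects follow the model/results convention:

```python
from adherit import TwinHeritabilityModel

model = TwinHeritabilityModel.from_pairs(pairs)   # or .from_dataframe(df)
res = model.fit(estimator="icc_anova", n_perm=10_000, seed=7)
print(res.summary())
res.to_json("heritability.json")
```

## Worked example

Generate a synthetic study of 23 MZ and 23 sibling pairs at generative
heritability h² = 0.6966 and run the whole pipeline:

```
adherit simulate --out-dir study --seed 2
adherit run-all --config config.yaml        # paths to the study/ CSVs
```

prints (this run excluded one plate that failed its QC gate, dropping four
sibling pairs):

```
Twin heritability of leukocyte-endothelial adhesion
=======================================================
Pairs:              23 MZ, 19 sibling
Estimator:          icc_anova
r_MZ:                 0.6660
r_SIB:                0.2918
h2 = 2(r_MZ-r_SIB):   0.7484  (74.84%)
Permutation p:        0.1179  (10000 permutations, scheme=pool_individuals, seed=2)
Null h2:            mean 0.0065, sd 0.6226, 95% [-1.216, 1.242]
```

`r_MZ` and `r_SIB` are the intra-pair ICCs; their doubled difference is the
Falconer heritability — here 0.75 against a generative truth of 0.70, well
inside the estimator's sampling error at ~20 pairs per group (sd ≈ 0.37).
The permutation p is the tail probability of the observed h² under pooled
re-dealing of all individuals into pseudo-pairs. The QC report for the same
run gave a composite Z′ of 0.674 and per-sample replicate CVs averaging
8.2 %, and the confounder screen found no covariate associated with
adhesion after Bonferroni adjustment.

Intermediate artifacts (`qc_report.json`, `phenotypes.tsv`,
`confounder_screen.tsv`, `heritability.json`, `run_log.json`) all embed the
config hash and seed.

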