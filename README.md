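# pheoscan

Multi-locus genetic analysis of hair-coat **pheomelanin intensity** in
dogs — the cream-to-deep-red axis of coat color. Pheomelanin intensity is
an ordinal phenotype (a six-point scale anchored at cream, tan and red
swatches) with a multigenic architecture: a handful of biallelic SNPs, each
with its own dominance behavior and pairwise epistatic interactions,
jointly explain most of the variation across breeds. `pheoscan` implements
the complete analysis chain for this kind of study, for geneticists who
want to run it on their own panels or probe its statistical behavior on
simulated ones:

1. **Color scale** — piecewise-linear interpolation of *n* equally spaced
   swatches through anchor colors, plus nearest-swatch assignment of an
   observed RGB color and z-standardization of phenotype vectors.
2. **Genotype I/O + QC** — PLINK bed/bim/fam and a plain-TSV dialect;
   marker missingness (> 5% removed), sample missingness (> 3%),
   method-of-moments IBD relatedness with π̂ ≥ 0.45 pruning, MAF ≥ 0.001
   filtering, breed-modal phenotype imputation.
3. **Mixed-model GWAS** — per marker, y = Xα + xβ + u + ε with
   u ~ N(0, σ²_g K) over the centered genomic relationship matrix
   K = WWᵀ/p; the variance ratio λ = σ²_g/σ²_e is estimated per marker by
   REML after a single eigendecomposition of K, β is tested by Wald t, and
   PVE = β̂²·Var(x)/Var(y). Quantitative and cream-vs-red case-control
   modes; Bonferroni genome-wide significance.
4. **Genetic architecture** — dominance deviation d = ȳ_het − (ȳ₀+ȳ₂)/2
   with a Student-t CI test, and pairwise epistasis regressions
   Y = β₀ + β₁g_A + β₂g_B + β₃g_Ag_B with a χ²(1) Wald test on β₃.
5. **Model search** — per-locus genotype encodings (additive 0/1/2,
   red-dominant, red-recessive, het/hom indicator split), exhaustive
   enumeration of encoding × interaction combinations (31 models for five
   loci; 4,095 with seven candidate interactions), ranking by adjusted R²,
   per-term proportional reduction of error (PRE), PRE-threshold pruning,
   and likelihood-ratio comparison of nested fits.
6. **Prediction + validation** — stratified 70:30 breed × phenotype
   cohort split, frozen-coefficient prediction, out-of-sample adjusted R²
   and the fraction of dogs predicted within one point, overall and per
   breed.
7. **Simulator** — a breed-structured generator (Balding–Nichols
   per-breed allele frequencies around ancestral values with divergence
   F_ST, Hardy–Weinberg within breed, a five-locus generative model with
   dominance encodings, Gaussian residual noise calibrated to a target R²,
   1–6 discretization and rater error), so the entire chain runs and is
   testable with no external data.

## Worked example

```python
from pheoscan.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_breeds=20, dogs_per_breed=25,
                     n_background_markers=300, seed=3)
manifest = run_pipeline(cfg, "out/")
print(manifest["stages"]["model_search"]["best_dominance_encodings"])
print(manifest["stages"]["validate"])
```

prints (seed 3):

```
{'CFA2': 'additive', 'CFA15': 'red_recessive', 'CFA18': 'red_dominant',
 'CFA20': 'additive', 'CFA21': 'red_dominant'}
{'n': 151, 'r2': 0.76955, 'adj_r2': 0.761603, 'within1_overall': 0.880795}
```

Reading: on a 500-dog simulated panel the search stage recovered the
generative dominance modes of all five loci (the two strong loci additive,
CFA15 recessive, CFA18/CFA21 dominant for the red allele), and the reduced
model predicted held-out dogs with adjusted R² ≈ 0.76, 88% of them within
one point of their observed six-point value.

The same chain is scriptable from the shell:

```sh
pheoscan scale                      # print the six-swatch color scale
pheoscan simulate --out-prefix p --n-breeds 20 --dogs-per-breed 25 --markers 300
pheoscan qc --geno p --out-prefix p.qc
pheoscan gwas --geno p.qc --pheno p.pheno.tsv --out gwas.tsv
pheoscan epistasis --geno p.qc --pheno p.pheno.tsv --loci CFA2,CFA15,CFA18,CFA20,CFA21
pheoscan select --geno p.qc --pheno p.pheno.tsv --loci CFA2,CFA15,CFA18,CFA20,CFA21 \
        --model-out model.json
pheoscan predict --model model.json --geno p.qc --pheno p.pheno.tsv --out pred.tsv
pheoscan validate --predictions pred.tsv --model-df 5
pheoscan run --out out/            # the whole pipeline from one config
```

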