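# eaccd

Censoring-aware consensus clustering of cancer patient cohorts into ordered
prognostic groups, with machinery to compare the result against AJCC
8th-edition TNM staging.

## What problem this solves

Staging systems map a patient's anatomic factors (primary tumor T, nodes N,
metastasis M) to an ordered stage. Adding further prognostic factors — age,
histology, eventually biomarkers — by committee is slow; this package does it
by clustering. Every *combination* of factor levels (all `T1bN1M0` patients,
say) becomes one object whose censored survival distribution is estimated by
Kaplan–Meier. The pipeline then:

1. scores every pair of combinations by the **Mann–Whitney parameter**
   θ̂ ≈ P(T_i < T_j), turned into a dissimilarity d = 2|θ̂ − ½|;
2. **learns a consensus dissimilarity** δ(i,j): the fraction of many
   deterministic PAM (k-medoids) runs, with k varied across runs, that
   separate i from j;
3. builds a **minimax-linkage dendrogram** on δ (each cluster summarized by
   a member prototype whose covering radius is the merge height);
4. **cuts** the tree where the **Harrell C-index** of the induced patient
   stratification stops improving (the knee of the C-vs-k curve), and
   numbers the groups by decreasing five-year survival, so risk increases
   with group number.

Audience: biostatisticians and registry analysts stratifying censored
cohort data (the design target is SEER-like lung-cancer case listings, but
nothing is lung-specific except the bundled AJCC stage table).

## Worked example

Simulate a registry-like cohort with three planted hazard tiers across 30
TNM combinations (hazard ratio 3 between adjacent tiers, 500 patients per
combination, administrative censoring at 60–96 months), fit, and inspect:

```python
from eaccd import EACCDModel, generate_cases, planted_tiers_config

cfg = planted_tiers_config(n_combinations=30, k_true=3, hazard_ratio=3.0,
                           cohort_size=500, seed=7)
cases, truth = generate_cases(cfg)
model = EACCDModel(cases, active_factors=("T", "N", "M"), min_cases=50)
res = model.fit(runs=200, seed=7)
print(res.summary())
```

```
Consensus-clustering prognostic system
======================================================
Factors: {T, N, M}    cohorts: 30 (min size 50, 0 excluded)
Patients: 15000    ensemble runs: 200    seed: 7
Groups: 3    C-index: 0.7093
------------------------------------------------------
group  patients  cohorts  60-mo rate
    1      5000       10      54.0%
    2      5000       10      16.7%
    3      5000       10       0.4%
```

The knee rule recovered the three planted tiers exactly (each group holds
its 10 planted cohorts); group 1 is the low-risk tier with 54% five-year
survival, group 3 the high-risk tier with essentially none, and the group
number predicts survival with concordance 0.709.

Comparing against AJCC staging on the same patients:

```python
out = res.compare_with_ajcc()
print(f"rho = {out['rho']:.4f}")
print(out["test"])
```

```
rho = 0.0582
C_a = 0.7093, C_b = 0.5141, delta = 0.1952 (95% CI 0.1887 to 0.2018), p = 0
```

On this synthetic cohort the planted risk tiers are unrelated to anatomic
stage by construction, so the stage/group rank correlation is near zero and
the paired C-index test finds the fitted system far more concordant than
staging (ΔC = 0.195). On real registry data, where anatomy drives risk, the
same machinery yields a high rho and a small positive ΔC.

The bundled published stage-by-group contingency table for the 77,953-patient
lung cohort is a ready-made worked example for the rank-correlation code:

```python
from eaccd import spearman_from_contingency, table2_fixture
print(round(spearman_from_contingency(table2_fixture()), 4))  # 0.9618
```

## Command line

```sh
eaccd simulate --out cases.csv --truth truth.json --seed 1
eaccd fit --input cases.csv --out results/ --runs 200 --seed 1
eaccd compare --input cases.csv --out results/ --runs 200 --seed 1
eaccd compare --from-table table2 --out results/
```

`fit` writes the dissimilarity matrices, the dendrogram (CSV merge table and
Newick), the C-index curve, per-group Kaplan–Meier curves, a system JSON and
a manifest that reproduces the run bit-for-bit.

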