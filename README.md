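# defensin-cnv

Copy-number genotyping and mucosal-immunity association analysis for the
beta-defensin locus.

The *DEFB4* gene, encoding human beta defensin 2 (HBD2), sits in a
copy-number-variable region on chromosome 8p23.1 with diploid copy numbers
from 1 to 12. This package implements, as a tested reusable pipeline, the
analysis chain that links that copy number to cervicovaginal HBD2 protein
and bactericidal activity in pregnancy cohorts:

1. **PRT genotyping** (`defensin_cnv.prt_genotyping`) — a paralogue ratio
   test (PRT) co-amplifies a test locus inside the CNV and a reference locus
   outside it, so the capillary-electrophoresis peak-area ratio *r* is
   affine in copy number. Per fluorescence channel the pipeline fits
   *r = a·c + b* by least squares on a reference panel of samples with known
   integer copy number *c*, inverts it to calibrate cohort ratios, averages
   dye channels within each assay, pools assays by an inverse-variance
   weighted mean, and calls the integer copy number by maximum likelihood
   under independent Gaussian errors:

       log L(k) = Σᵢ [ −log(σᵢ√2π) − (xᵢ − k)² / 2σᵢ² ],   k ∈ {1, …, 12}

   with confidence L(k*)/Σₖ L(k) and ties broken to the smaller integer.
2. **Assay processing** (`defensin_cnv.assay_processing`) — ELISA HBD2
   readings below the 16 pg/ml limit of detection are substituted by
   LOD/√2 and flagged; concentrations are normalised to total protein
   (pg/ml ÷ µg/ml → pg/µg); bactericidal activity is
   %kill = 100·(1 − cfu_test/cfu_control) from triplicate means, with the
   buffer control defined as 100% survival, normalised to total protein
   (%kill/µg).
3. **Association analysis** (`defensin_cnv.association_analysis`) —
   pairwise Spearman rank correlations (mid-ranks for ties; exact
   permutation p-values for small tie-free samples, *t* approximation
   otherwise), cohort exclusion rules with an audit trail, term/preterm
   stratification, and Mann–Whitney group comparisons.
4. **Synthetic cohorts** (`defensin_cnv.synthetic_cohort`) — a generator
   whose defaults emulate an antenatal cohort of 203 women: copy numbers
   1–8 with mode 4, ~4.4% typing failure, log-scale HBD2 rising with copy
   number (ρ ≈ 0.21) and falling with gestational age (ρ ≈ −0.25), activity
   strongly coupled to HBD2 (ρ ≈ 0.49), ~12% of ELISA readings censored,
   ~8% preterm deliveries, and realistic exclusion-flag rates.
5. **Pipeline** (`defensin_cnv.pipeline`, CLI `defensin-cnv`) — runs
   simulate → genotype → process-assays → associate with a checksummed run
   manifest.

## Worked example

```python
import defensin_cnv as dc

cohort = dc.simulate_cohort(seed=7)          # synthetic cohort, n=203
res = dc.analyze_cohort(cohort.peaks, cohort.panel,
                        cohort.assays, cohort.metadata)
print(res["calls"].head())
for r in res["correlations"]:
    print(f"{r.var_x} ~ {r.var_y}: rho={r.rho:+.2f} p={r.p_value:.4f} n={r.n}")
```

prints integer calls with confidences and QC flags,

```text
sample_id  weighted_mean_cn  ml_integer_cn  confidence         qc_flags
     S001          4.823641              5         1.0
     S002               NaN           <NA>         NaN TOO_FEW_CHANNELS
     S003          4.088708              4         1.0
```

(S002 is a typing failure: fewer than two usable PRT assays, so no call is
made), and the all-comers correlation matrix,

```text
    weighted_mean_cn ~ hbd2_norm_pg_per_ug    rho=+0.20  p=0.0052  n=188
    weighted_mean_cn ~ kill_per_protein       rho=+0.12  p=0.0883  n=188
    weighted_mean_cn ~ gestational_age_days   rho=-0.03  p=0.7179  n=188
 hbd2_norm_pg_per_ug ~ kill_per_protein       rho=+0.53  p=0.0000  n=197
 hbd2_norm_pg_per_ug ~ gestational_age_days   rho=-0.11  p=0.1289  n=197
    kill_per_protein ~ gestational_age_days   rho=-0.11  p=0.1254  n=197
```

— copy number correlates positively with HBD2 protein, HBD2 strongly with
bactericidal activity, and HBD2 falls with gestational age, with n reflecting
pairwise-complete samples after typing failures. For this cohort the typing
success rate was 95.6% and 10.3% of ELISA readings were censored at
16/√2 ≈ 11.31 pg/ml.

The same run from the shell:

```sh
defensin-cnv run --seed 7 --out run_out/
```

writes `calls.csv`, `calibration.json`, `assays_processed.csv`,
`correlations.csv`, `exclusions_audit.csv`, `group_comparisons.csv`,
`scatter_matrix.json` and a `manifest.json` with checksums and per-stage row
counts.

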