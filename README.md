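# tcatrace

Analysis toolkit for **¹³C stable-isotope tracing metabolomics** of central
carbon metabolism, built for the question of how TCA-cycle nutrient use
changes under drug treatment in primary (e.g. patient-derived leukaemic
stem/progenitor) cells — and in particular for reading **pyruvate
carboxylase (PC) vs pyruvate dehydrogenase (PDH)** activity from
isotopologue distributions.

Cells cultured with a uniformly labelled tracer (¹³C₆ glucose, ¹³C₅
glutamine or ¹³C₁₆ palmitate) yield, for each n-carbon metabolite, peak
areas for isotopologues m+0 … m+n.  From these the package computes:

- **Natural-abundance correction.**  The measured mass isotopomer
  distribution (MID) is the true tracer-derived MID smeared by natural ¹³C
  (~1.07 % per carbon).  The forward model is a column-stochastic binomial
  matrix, M[i,j] = C(n−j, i−j) p^(i−j) (1−p)^(n−j−(i−j)); correction solves
  M·x = measured (non-negative least squares fallback for noisy data).
- **Fractional enrichment** = Σ_{i≥2} m_i — labelling from multi-carbon
  tracer incorporation.
- **PC/PDH ratio** = m+3/m+2 in malate, citrate and aspartate: PC
  carboxylates ¹³C₃ pyruvate to m+3 oxaloacetate, PDH feeds m+2 acetyl-CoA,
  so the ratio reads anaplerotic vs oxidative pyruvate entry.  **PC
  activity** = the aspartate m+3 fraction itself.
- **Nutrient contribution**: carbon-pool fractions Σ_i (i/n)·m_i per
  tracer, merged across parallel cultures with an explicit unassigned
  remainder.
- **Differential statistics**: paired/unpaired two-sided t-tests on log₁₀
  values with the two-stage step-up (Benjamini–Krieger–Yekutieli) adaptive
  FDR at Q = 10 %; volcano tiers q < 0.05 (strong) and q < 0.1 (weak).
- **Steady-state preprocessing**: per-batch reference normalisation,
  generalised-log transform with mean-centring, batch correction to
  no-drug controls, top-25 selection for heatmaps.
- **Extracellular exchange rates** from spent vs cell-free medium:
  (Δamount)/((cells_d0 + cells_d2)/2) per 48 h, + secretion / − consumption.
- A **single-turn TCA labelling simulator** with explicit PC / PDH /
  glutaminolysis / fatty-acid-oxidation mixing fractions, natural-abundance
  convolution, log-normal noise and paired-cohort construction, so every
  stage is testable against closed-form ground truth.

## Worked example

Simulate a 4-patient paired cohort whose treated arm has PDH flux reduced
to 60 % with PC flux untouched, then run the full tracing analysis:

```sh
tracer simulate --n-pairs 4 --seed 17 --out sim
tracer compare --input sim/isotopologues.csv --metadata sim/metadata.csv --out results
```

`results/volcano.csv` (glucose tracer, fractional enrichment) begins:

```
tracer,statistic,metabolite,log10_fc,neg_log10_q,tier
glucose,fraction_enrichment,alanine,-0.119983700666,2.80973105635,strong
glucose,fraction_enrichment,alpha-ketoglutarate,-0.209475607639,3.16871719987,strong
glucose,fraction_enrichment,aspartate,-0.136056012329,2.80973105635,strong
glucose,fraction_enrichment,citrate,-0.206088233544,3.25661288404,strong
```

Every TCA metabolite's glucose enrichment drops significantly (negative
log₁₀ fold change, strong tier), while `results/anaplerosis_stats.csv`
shows the PC/PDH ratio does *not* decrease — citrate's ratio actually
trends up (log₁₀ FC +0.34, ns) — the signature of pyruvate anaplerosis
persisting through a treatment that suppresses oxidative glucose entry:

```
metabolite,log10_fc,q_value
aspartate,-0.0680541758557,0.630386235393
citrate,0.34215709302,0.182946293783
malate,0.0365050555642,0.630386235393
```

`results/nutrient_contribution.csv` stacks the per-tracer carbon-pool
shares (glucose 0.69 of alanine carbon in controls vs 0.53 treated, with
the unassigned remainder reported explicitly), and `sim/truth.json` holds
the generating ground truth for verification.

Library use mirrors the CLI: `tcatrace.generate_cohort`,
`tcatrace.correct_table`, `tcatrace.pc_pdh_ratio`,
`tcatrace.bky_two_stage`, `tcatrace.run_tracing_analysis`, etc.

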