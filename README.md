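# crcua — cost-utility analysis of Bulgaria's pilot colorectal-cancer screening programme

`crcua` re-implements, as a tested and reusable Python package, the economic
evaluation of Bulgaria's 2024 national pilot colorectal-cancer (CRC)
screening programme: 93,381 people aged 50–74 (with extended eligibility)
screened with a faecal immunochemical test (FIT) over a single campaign. The
package is written for health economists and screening-programme analysts
who want to audit, re-run, or adapt the published analysis — every input is
a published constant, every output is recomputed.

It covers five linked analyses:

1. **A four-state Markov cohort model** (undiagnosed CRC → stage I–II →
   stage III–IV → dead) comparing *with screening* against *without
   screening* over a 50-year lifetime horizon with annual cycles and a 3.5%
   discount rate applied after the first year. Screening shifts the stage
   distribution at diagnosis (67% early vs 46% early). Annual transition
   probabilities come from 5-year literature quantities via the
   constant-hazard conversion

   `annual p = 1 − (5-year survival)^(1/5)`,

   giving mortality 1.87%/yr (stage I–II, SEER 91% 5-year survival),
   14.76%/yr (stage III–IV, 45%), and progression 2.43%/yr (pooled Danish
   5-year recurrence CIF of 11.58%). Utilities are 0.74 (early) and 0.46
   (late) per year.
2. **Incremental cost-utility comparison**: Δcost, ΔQALY,
   dominance/ICUR classification, and scaling to the 747 CRC patients the
   programme is estimated to have detected (Slovenian detection rate
   862/15,310 applied to 13,263 FIT-positives).
3. **Probabilistic sensitivity analysis**: 1,000 Monte Carlo iterations with
   costs ~ normal (SD 20% of mean), utilities ~ gamma (SD 20%),
   probabilities ~ beta (SD 10%), all method-of-moments parameterized;
   acceptability at the willingness-to-pay threshold of €44,081.03/QALY
   (3× GDP per capita) and a full CEAC.
4. **Budget-impact projection 2024–2028**: population decline −1.147%/yr,
   CRC incidence 0.431/1,000, avoided stage III–IV cases (54% → 33% of new
   diagnoses) and the €6,417.85-per-case treatment spending avoided, plus
   the theoretical GDP contribution of the QALYs gained.
5. **Campaign descriptive statistics**: positivity by sex and age band,
   communication-channel shares, cost per participant, target exceedance —
   from published aggregates or from individual-level records generated by
   the synthetic-data module.

Because the original model was built in TreeAge and its cycle-level
conventions are not fully published, the package includes a **calibration
harness** that searches a 64-point grid of structural variants (diagnosis
timing, reward timing, transition-cost discounting, colonoscopy charging,
treatment-cost accrual) against the published per-patient totals and ships
the winning variant as its default. See `docs/methods.md` for what that
search reveals about the original model's cost accrual.

## Worked example

```bash
$ crcua run-model
The screening programme dominates no screening (lower costs and more QALYs).
Per patient: delta cost -67.09 EUR (BGN -131.23), delta QALY +1.58.
```

Per screened-detected patient, lifetime discounted costs are lower by €67.09
and discounted quality-adjusted survival higher by 1.58 QALYs under
screening, so screening *dominates* (no cost-per-QALY ratio is needed). The
published analysis prints −€67.07 and +1.58.

```bash
$ crcua run-psa --seed 1
PSA (1000 iterations, seed 1): mean delta cost -67.47 EUR, mean delta QALY +1.58,
acceptability at 44,081.03 EUR/QALY: 99.2%
```

Under joint parameter uncertainty, screening remains cost-effective in 99.2%
of iterations at the Bulgarian willingness-to-pay threshold (published:
99.1%).

```bash
$ crcua project
Avoided advanced-stage cases 2024-2028: 988; savings 6,341,212.89 EUR (12,402,334.40 BGN)
```

988 stage III–IV cases avoided over five years, worth ≈ €6.34 million in
avoided advanced-stage treatment (published: €6,341,213.73).

```bash
$ crcua campaign-report
Participants: 93,381; positivity 14.22%
Target exceedance: 86.76%
Cost per participant: 7.83 EUR
Leading channel: television (45.7% of respondents)
```

The same functions are available as a library (`crcua.run_cohort`,
`crcua.compare_arms`, `crcua.run_psa`, …), and
`crcua reproduce --seed 0 --out results/` writes the full report
bundle (per-patient and cohort tables, PSA scatter + CEAC, projection table,
campaign table, manifest) as deterministic CSVs.

## Layout

| Module | Contents |
| --- | --- |
| `crcua.conversions` | 5-year → annual probability conversions, CIF pooling, EUR/BGN |
| `crcua.parameters` | shipped constants, default configurations |
| `crcua.markov` | state space, transition matrices, cohort engine, structural variants |
| `crcua.cua` | incremental comparison, detected-cohort scaling, variant calibration |
| `crcua.psa` | distribution specs, Monte Carlo PSA, acceptability curve |
| `crcua.projection` | 2024–2028 budget impact, GDP contribution |
| `crcua.campaign` | stratified positivity, channel shares, budget statistics |
| `crcua.synthetic` | participant-record generator, microsimulation oracle |
| `crcua.cli` / `crcua.report` | command-line orchestration and CSV/manifest emission |
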