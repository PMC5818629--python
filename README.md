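# genetoxbmd

Benchmark-dose (BMD) modelling and sensitivity ranking for multi-endpoint
genetic toxicology dose–response studies.

In vivo genotoxicity studies increasingly quantify several kinds of genetic
damage in many tissues of the same animals — bulky DNA adducts (per 10⁸
nucleotides), mutant frequencies at a *lacZ* transgene (mutant pfu / total
pfu) and at the endogenous *Pig-a* gene (mutant cells per 10⁶ RETs/RBCs),
and micronucleated erythrocytes (% MN-RET / MN-NCE). Risk assessors and
genetic toxicologists need more from such data than "significant at dose
X": they need a point of departure per tissue and endpoint, a defensible
way to rank tissue sensitivities, and quantitative comparisons *between*
endpoints. This package implements that analysis chain:

1. **Nested exponential dose–response family** with log-normal errors
   (`ln y ~ N(ln f(x), σ²)`):

       m1: y = a                    m2: y = a·e^{bx}
       m3: y = a·e^{bx^d}           m4: y = a·[c − (c−1)e^{−bx}]
       m5: y = a·[c − (c−1)e^{−bx^d}]

   where `a` is the background response, `c` the maximum response as a
   multiple of background, and `d ∈ [1, 4]` a shape exponent.
2. **Likelihood-ratio model selection**: a more complex member is accepted
   only when 2ΔLL exceeds the χ²₁ critical value at p < 0.05, in a ladder
   m2 → {m3, m4} → m5 with a full audit trace.
3. **BMD with profile-likelihood CI**: the BMD solves `f(BMD) = a(1+CES)`
   (CES = 1.0, a two-fold increase, by default); BMDL/BMDU are the
   two-sided 90% profile-likelihood bounds, found where the profile
   log-likelihood drops by χ²₁,₀.₉₀/2 = 1.3528.
4. **Poisson trend tests**: an overall Type-3-style LR chi-square (dose as
   categorical factor, log-denominator offset) plus per-dose-vs-control LR
   contrasts with significance tiers a/b/c/d (< 0.0001 / 0.001 / 0.01 /
   0.05).
5. **Comparative analyses**: tissues ranked by the geometric midpoint
   √(BMDL·BMDU), with two BMDs *distinguishable* exactly when their CIs do
   not overlap; cross-endpoint BMD progression with the fitted
   maximum-response `c`; a unity-slope proportionality analysis of paired
   BMDs on double-log axes; and a Ki-67 proliferation-index correlation
   check.
6. **Synthetic study generator**: seeded datasets with the full study
   structure (11 doses 0–50 mg/kg BW/day, 7 animals/group, 14 controls) and
   endpoint-appropriate noise (log-normal / Poisson / binomial), with
   presets anchored to published fold-change scales, so the entire pipeline
   is testable without any animal data.

See `docs/methods.md` for model details, assumptions and numerical choices.

## Worked example

```python
import genetoxbmd as g

ds = g.generate_preset("lacz_small_intestine", seed=1)   # 84 animals, 11 doses
sel = g.select_model(ds, seed=0)
est = g.estimate_bmd(sel, ds)                            # CES=1.0, 90% CI
trend = g.overall_trend_test(ds)
```

which prints, via the ladder trace and result objects:

```
selected: m4
  m2 vs m1: 2dLL=148.21 accepted=True
  m3 vs m2: 2dLL=0.00 accepted=False
  m4 vs m2: 2dLL=73.73 accepted=True
  m5 vs m4: 2dLL=3.40 accepted=False
BMD=3.247 BMDL=2.838 BMDU=3.705 ratio=1.31
trend chi2=6412.0 df=10
tiers: {0.1: 'ns', 0.2: 'ns', 0.39: 'ns', 0.78: 'b', 1.56: 'b', 3.13: 'a', ...}
```

Reading this: the saturating model m4 wins the likelihood ladder; the dose
estimated to double the small-intestine *lacZ* mutant frequency is
3.25 mg/kg BW/day with 90% CI [2.84, 3.71] (the generating truth for this
preset is 3.0, inside the CI; the BMDU/BMDL ratio 1.31 marks a precise
estimate). The trend test finds an overwhelming dose effect, with
per-dose contrasts becoming significant from 0.78 mg/kg BW/day upward.
Note the fitted `c` is essentially unbounded here — the data stop well
short of the plateau, a correctly-reported identifiability limit that does
not harm the BMD.

The same analysis runs from the shell:

```sh
genetoxbmd simulate --all-presets --seed 1 -o study.csv
genetoxbmd report study.csv --outdir report/ --plots
# or stage by stage: genetoxbmd fit|bmd|trend|rank|compare ...
```

`report/` then contains the BMD table (tissue, endpoint, model, BMD, BMDL,
BMDU, BMDU/BMDL), the trend-test table with tiers, per-endpoint CI-overlap
rankings, cross-endpoint comparisons, the adduct-vs-*lacZ* proportionality
analysis, forest-style CI plots, and a run log with every ladder trace.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch: it
simulates every registered preset under the 84-animal study design
(seeds derived from `--seed`), performs model selection, BMD + 90% CI
estimation, trend testing, sensitivity ranking and the proportionality
analysis, prints the resulting ranking/proportionality summary, and writes
the JSON summary to `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
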