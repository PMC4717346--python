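# felidcam

Camera-trap analysis of interactions between a dominant and a subordinate
carnivore — bobcats (*Lynx rufus*) and pumas (*Puma concolor*) across an
urbanization gradient — as a tested, reusable Python pipeline.

Motion-activated cameras record time-stamped photographs at fixed sites.
From those records the package answers three questions a field ecologist
asks about a dominant/subordinate species pair:

1. **Does the dominant species exclude the subordinate from sites over a
   season?** Conditional two-species occupancy models compare the
   subordinate's occupancy given dominant presence (Ψ^BA) versus absence
   (Ψ^Ba), and its detection when the dominant is absent (p^B) versus present
   (r^BA, r^Ba), under the constraint sets Ψ^BA = Ψ^Ba and
   p^B = r^BA = r^Ba.
2. **Does the subordinate avoid sites for a few days after a dominant
   visit?** Single-species occupancy models with logit-linked detection
   covariates: day-of-visit lag indicators P1–P4 (the visit day plus 0–3
   following days), their interactions with a wildland/urbanized grid
   indicator, a puma-photograph count per site, and a human-development (HD)
   kernel-density covariate whose spatial scale is chosen by AICc.
3. **Do the two species keep different daily schedules?** Von Mises kernel
   densities of detection clock times and the coefficient of overlap
   Δ̂ = ∫ min(f, g), with smoothed-bootstrap confidence intervals and
   interval-overlap comparison metrics.

Candidate models are ranked by AICc with Akaike weights
ω_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2).

Because no raw detection data are distributed with the motivating study, the
package ships a synthetic-data generator (`felidcam.synthetic_data`) that
reproduces the assumed data-generating process — two 20-site sampling grids,
latent two-species occupancy, daily detection with a multi-day suppression of
the subordinate after dominant visits on wildland grids, bimodal circadian
activity, and sub-hour photo bursts — so every stage is testable end to end
against known truth.

## Worked example

```python
from felidcam import (SimulationConfig, simulate_survey, pool_occasions,
                      fit_mle, fit_two_species, aicc)

sv = simulate_survey(SimulationConfig(), seed=20251)   # 40 sites, 92 days

# Fine scale: does the subordinate avoid sites for 3 days after a visit?
fit = fit_mle("psi(.), p(PumaCount + HD + G + P3 + G*P3)",
              sv.daily_b, sv.covariates, seed=0)
print(f"psi = {fit.psi_hat:.2f}, wildland 3-day lag effect = "
      f"{fit.coef('p:P3'):.2f}, HD effect = {fit.coef('p:HD'):.2f}")

# Broad scale: does dominant presence change subordinate occupancy?
hA, hB = pool_occasions(sv.daily_a, 18), pool_occasions(sv.daily_b, 18)
two = fit_two_species("psiA, (psiBA=psiBa), pA, rA, (pB=rBA=rBa(G+HD))",
                      hA, hB, sv.covariates, seed=0)
print(f"psiA = {two.estimates['psiA']:.2f}, psiB = {two.estimates['psiBA']:.2f}, "
      f"AICc = {aicc(two.neg2loglik, two.K, 40):.1f}")
```

prints (seed 20251):

```
psi = 0.83, wildland 3-day lag effect = -13.91, HD effect = -0.60
psiA = 0.78, psiB = 0.83, AICc = 494.9
```

The default generator simulates complete 3-day avoidance on the wildland
grid, so the wildland lag coefficient is driven strongly negative (the
subordinate is never photographed inside a suppression window; on the logit
scale the estimate runs toward the boundary), while subordinate occupancy
stays high and close to its configured value of 0.85 — the signature of a
behavioural response rather than exclusion. The negative HD effect recovers
the configured β_HD = −0.4 in sign.

The same pipeline is scriptable from the shell:

```bash
felidcam run --seed 1 --out results/demo --n-boot 1000
```

which writes the fixture CSVs, daily and pooled detection histories, ranked
broad- and fine-scale model-selection tables, and the per-grid activity
overlap table into `results/demo/`.

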