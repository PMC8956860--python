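# streamstate

Hierarchical Bayesian state-space analysis of aquatic-insect occurrence
under experimental water-flow disturbance.

## The problem

Stream insects differ in how they cope with hydrological disturbance: some
carry traits that help them *stay* on a substrate when a flow pulse hits
(resistance — flattened bodies, hooks, shelters), others carry traits that
help them *return* quickly afterwards (resilience — short life cycles, many
reproductive bouts). A space-state colonization experiment separates the two
axes: rows of artificial substrates are placed in streams, disturbed at
controlled frequencies (none, every 6 days, every 3 days, random) and pump
intensities (two batteries), and destructively sampled column by column so
that each row yields one presence/absence time series per taxon.

`streamstate` implements the full analysis for such experiments, plus a
synthetic-data generator with known ground truth so every inference stage
can be validated without field data. It is aimed at community ecologists
running or re-analysing manipulative disturbance experiments on
presence/absence panels.

## The model

Occurrence of genus *i* follows a two-state occupancy chain over sampling
occasions *t*:

    O_{i,t} ~ Bernoulli(P_{i,t}),   P_{i,t} = θ_i + O_{i,t-1} · ψ_i · δ_k

* **θ_i** — recolonization probability (an empty unit becomes occupied); the
  resilience axis.
* **ψ_i** — permanence probability (an occupied unit stays occupied); the
  resistance axis.
* **δ_k** — permanence deviation of treatment cell *k* (intensity ×
  frequency); δ = 1 in the control.

Genus parameters are tied to one of nine life-history strategy groups
through Beta hierarchies, θ_i ~ Beta(α1_g, β1_g) and ψ_i ~ Beta(α2_g, β2_g),
with vague Gamma(0.001, 0.001) hyperpriors; the group-level baseline is the
Beta mean α/(α+β). A companion before/after binomial model measures the
immediate effect of a single disturbance: B_i ~ Bin(n, b_g),
A_i ~ Bin(n, b_g·e_g), where e_g is a multiplicative effect on occurrence.
All models are fitted by a seeded Metropolis-within-Gibbs sampler (default
protocol: 5 chains, 5000 steps, burn-in 1000, thinning 50), summarized by
equal-tailed 95% credible intervals, and checked with Gelman-Rubin
diagnostics. A group counts as *affected* in a treatment cell when the 95%
interval of its cell permanence ψ_g·δ_{k,g} is disjoint from the control
interval of ψ_g.

## Worked example

```python
import streamstate as st

# a community whose nine groups sit at their hypothesized trait levels,
# with permanence abolished to 20% in the high-intensity / 6-day cell
truth = st.TrueParams.from_hypotheses(n_genera_per_group=4,
                                      delta={"I2F1": {g: 0.2 for g in range(1, 10)}})
panel, genus_truth = st.simulate_panel(truth, st.DesignSpec(), rng_seed=7)

model = st.TreatmentOccupancy(config=st.MCMCConfig(seed=7)).fit(panel)
perm = model.permanence_summaries()

g = 8  # hook-bearing larvae: psi very high, theta low
print(f"control psi: {perm[g]['C'].mean:.2f} "
      f"[{perm[g]['C'].lower:.2f}, {perm[g]['C'].upper:.2f}]")
print(f"I2F1 psi:    {perm[g]['I2F1'].mean:.2f} "
      f"[{perm[g]['I2F1'].lower:.2f}, {perm[g]['I2F1'].upper:.2f}]")
from streamstate import classify_affected
print("affected in I2F1:", classify_affected(perm[g]["I2F1"], perm[g]["C"]))
```

prints

```
control psi: 0.96 [0.82, 1.00]
I2F1 psi:    0.08 [0.00, 0.29]
affected in I2F1: True
```

i.e. the group's fitted control permanence (posterior mean 0.96, truth
0.90) collapses to 0.08 in the treated cell (truth 0.90 × 0.2 = 0.18), and
the cell is flagged as affecting the group because the two 95% intervals
are disjoint. Groups whose baseline permanence is already low carry little
signal about a further reduction, so with only four genera per group their
deviations stay uncertain — mirroring the fact that affected-cell calls in
such experiments are mostly driven by the high-permanence strategies.

The same steps are available from the shell:

```bash
streamstate simulate --seed 7 --out occ.csv --truth-out truth.yaml
streamstate fit-treatment occ.csv --seed 7 --draws-out draws.csv --manifest-out run.json
streamstate summarize draws.csv --out summary.csv
```

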