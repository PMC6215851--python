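# neutralassembly

Dual-scale neutral-theory tests of microbial community assembly from OTU
count tables.

Microbiome studies routinely ask whether a community's composition is
shaped by deterministic host/environmental filtering (niche assembly) or by
stochastic birth, death and immigration of ecologically equivalent taxa
(neutral assembly). This package implements the two complementary tests
used for that question on 16S survey data:

- **Community scale — Hubbell's neutral theory.** The exact probability of
  a sample's species-abundance distribution `D = (n_1, …, n_S)` under the
  dispersal-limited neutral model is the Etienne sampling formula
  `P(D | θ, m, J)`, with fundamental biodiversity number `θ`, immigration
  probability `m = I/(I+J−1)` and community size `J`. The package computes
  the likelihood in log space, fits `(θ, m)` by maximum likelihood,
  simulates neutral communities by the sequential-construction scheme, and
  runs the exact neutrality test: the deviation
  `q = −2[log L0 − log L1]` between the observed sample's likelihood and
  the mean likelihood of 100 simulated communities, scored against
  χ²(df=1); `p > 0.05` means the community passes as neutral.
- **Species scale — Sloan's neutral community model.** Each taxon's
  occurrence frequency `x_i` across destination samples is compared with
  the stationary-beta prediction
  `F_i(m) = 1 − BetaCDF(d; N_T m p_i, N_T m(1−p_i))` from its source
  abundance `p_i`; `m` is fitted by least squares, fit quality by `R²`, and
  each taxon is classified neutral / above / below a 95% binomial interval
  around its predicted occurrence.

Synthetic generators (neutral by either route, and niche-structured with
tunable selection) provide ground-truthed data for calibration and power
experiments, and a pipeline ties everything into deterministic TSV reports.
The scientific details, numerical choices and known limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Generate a small ground-truthed dataset and test it at both scales:

```sh
neutral-assembly simulate --mode sloan-neutral --samples-per-group 30 \
    --depth 1000 --migration 0.15 --seed 7 --out-dir data
neutral-assembly fit-sloan --otu data/otu.tsv --groups data/groups.tsv \
    --source lean --dest obese --n-per-group 25 --repeats 10 --seed 5 --out table2.tsv
```

prints

```
lean->obese: m=0.1145 R2=0.929 neutral=66.2%
```

the fitted migration probability (true value 0.15), the goodness of fit of
the occurrence-frequency curve, and the percentage of taxa whose observed
occurrence lies inside its predicted 95% interval, averaged over 10
balanced resampling repeats.

The community-scale machinery from Python:

```python
from neutralassembly import (
    simulate_etienne_sample, exact_neutrality_test, deviation_statistic,
)
from neutralassembly.etienne import I_from_m

sad = simulate_etienne_sample(theta=30, I=I_from_m(0.9, 1000), J=1000, seed=42)
res = exact_neutrality_test(sad, n_sim=100, seed=7)
print(f"theta={res.fit.params.theta:.1f} m={res.fit.params.m:.3f} "
      f"q={res.q:.3f} p={res.p:.4f} neutral={res.passes()}")
```

prints

```
theta=302.0 m=0.045 q=-2.166 p=1.0000 neutral=True
```

a genuinely neutral community passes (`p > 0.05`); the wandering point
estimate of `θ` reflects the well-known flatness of the single-sample
likelihood along the θ–m ridge, which is why parameter-recovery claims are
made in the median over replicate communities. The deviation statistic
applied to a community with log-likelihoods `log L0 = −86.334` and
`log L1 = −85.809` gives `q = 1.050, p = 0.305` — the scale of values
typical of gut communities that pass the test.

The full pipeline runs from a YAML config and writes `table1.tsv` (one
exact-test row per sample), `table2.tsv` (one row per source→destination
Sloan design), per-taxon classifications, rank-abundance curves and a log:

```sh
neutral-assembly run --config analysis.yaml
```

Identical config and seed reproduce byte-identical reports.

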