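# wingmorph

Quantitative genetics of a density-dependent wing dimorphism: Bayesian
binary-response animal models with genotype-by-environment (G×E) random
slopes, for full-sib half-sib breeding designs.

Many mostly flightless insects produce occasional long-winged, dispersive
individuals. Whether an individual develops long wings can depend both on
its genes and on the rearing environment — in grasshoppers and other
Orthoptera, chiefly on the density of conspecifics experienced during
nymphal development. Separating these causes, and asking whether genotypes
*differ in their response* to density (G×E), requires a threshold-trait
animal model: the binary morph y is modelled through a latent liability
with a logit link,

    y_i ~ Bernoulli(p_i)
    logit(p_i) = α + (β + a_{i,2}) x_i + c_i + a_{i,1} + e_i

where x_i is the cage's nymphal density (centred at 6.5), c_i a cage
effect with variance V_C, e_i a latent residual with variance fixed to 1,
and the additive-genetic intercepts and density slopes (a_1, a_2) follow
MVN(0, G ⊗ A) with A the pedigree relatedness matrix and
G = [[V_A,I, C_A,IS], [C_A,IS, V_A,S]]. V_A,S > 0 is heritable variation
in density sensitivity — G×E. The package fits this model (and its
random-intercept reduction) with an exact Pólya-Gamma Gibbs sampler,
decomposes variance on the link and data scales — including the
marginalized additive variance V_A,M = V_A,I + V_A,S·V_x + μ²·V_A,S +
2μ·C_A,IS and the conditional heritable share V_A(x) along the density
gradient — and evaluates the significance of V_A,S against 19
permutation-null refits. A bundled simulator generates breeding-design
datasets (sires × dams × egg pods × cages, cage splitting above 8
nymphs, 25% early mortality) so the whole pipeline is testable without
any external data. Target audience: evolutionary ecologists and
quantitative geneticists working with threshold traits in structured
pedigrees.

## Worked example

```python
import numpy as np
from wingmorph import (
    SimulationConfig, simulate_dataset, pedigree_from_data,
    relatedness_matrix, fit_animal_model, ModelSpec, MCMCConfig,
    posterior_summary, covariate_moments, link_scale_proportions,
    summarize_components, conditional_decomposition,
)

cfg = SimulationConfig(seed=1001)        # study-sized design, 68 sires
data = simulate_dataset(cfg)
ped = pedigree_from_data(data)
ids = data.loc[data.y.notna(), "id"].tolist()
A = relatedness_matrix(ped, subset=ids)

fit = fit_animal_model(
    data, A, ModelSpec(random_slope=True),
    MCMCConfig(n_chains=2, warmup=800, sampling_iterations=1600, thin=2, seed=1),
)
print(posterior_summary(fit).round(3))
```

```
           median     sd  hpd_low  hpd_high
parameter
alpha       1.034  0.132    0.793     1.299
beta        0.554  0.052    0.468     0.672
V_C         0.548  0.172    0.236     0.906
V_A_I       1.248  0.514    0.462     2.306
V_A_S       0.100  0.067    0.014     0.241
C_A_IS      0.063  0.116   -0.093     0.325
```

The data were generated with α = 1.146, β = 0.589, V_C = 0.572,
V_A,I = 1.485, V_A,S = 0.191, C_A,IS = 0.183; every generative value lies
inside its 95% HPD interval. `V_A_S` bounded away from zero is the G×E
signal: families differ heritably in how strongly density induces long
wings.

```python
m = covariate_moments(data)              # mu, V_x of centred density
props = summarize_components(link_scale_proportions(fit, m))
print(props.loc[["prop_fixed", "prop_additive", "prop_cage"], "median"].round(3))
```

```
prop_fixed       0.189
prop_additive    0.217
prop_cage        0.066
```

About 19% of the liability variance in this replicate is explained by
density itself, ~22% by (marginalized) additive genetic variation and
~7% by shared cage effects. The conditional decomposition
(`conditional_decomposition(fit, data_scale=True, P=data.y.mean())`)
shows the heritable share of the *observed* morph peaking at moderate
densities (0.21 at 3 nymphs per cage, falling below 0.01 at density 12)
— where environmental induction is neither rare nor saturated, genes
matter most.

A command-line interface mirrors the library
(`wingmorph simulate | fit | decompose | nulltest | describe | pipeline`);
`wingmorph pipeline --seed 11 --out results/` runs every stage from one
seed and is bit-reproducible.

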