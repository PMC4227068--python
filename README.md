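# codivabc

Approximate-Bayesian model choice for **shared divergence times** across
co-distributed pairs of populations.

Large-scale geological or climatic events — a seaway opening, sea-level
fluctuations fragmenting an island system — can split many co-distributed
species at the same moment. Given multi-locus DNA sequence alignments from
*Y* pairs of sister populations, `codivabc` estimates how many divergence
events those pairs share, which pairs co-diverged, and when, while
integrating over gene-tree and demographic uncertainty.

## The model

Each pair *i* of populations descends from an ancestral population
(mutation-scaled size θ<sub>A</sub> = 4*N*μ) that split at time
*T<sub>i</sub>* into two descendants (θ<sub>D1</sub>, θ<sub>D2</sub>) that
may pass through a post-divergence bottleneck of severity
ζ ∈ (0, 1] ending a fraction τ<sub>B</sub> of the way back to the split,
then recover exponentially; symmetric migration at rate *m* is optional.
Gene trees follow the multi-population Kingman coalescent and sequences
evolve under HKY85 with per-locus parameters ϕ and fixed scalings ρ
(ploidy / generation time) and ν (relative rate), plus gamma-distributed
rate multipliers υ ~ Gamma(α, 1/α) across loci.

A *divergence model* **t** assigns the *Y* pairs to |**τ**| ≤ *Y*
divergence-time classes; each class time τ is drawn from a gamma (or
uniform) prior, in coalescent units of 4*N<sub>C</sub>* generations, where
θ<sub>C</sub> = E(θ<sub>D</sub>) defines the reference population. Three
priors over **t** are implemented:

* a **Dirichlet process** (Chinese restaurant process) over the
  *B<sub>Y</sub>* ordered models, with concentration χ (optionally
  χ ~ Gamma(a<sub>χ</sub>, b<sub>χ</sub>)); under it
  p(t<sub>i</sub> = t<sub>j</sub>) = 1/(1+χ) and the class-count prior is
  p(|**τ**| = k) = c(Y, k) χ<sup>k</sup> / ∏(χ + i − 1) with *c* the
  unsigned Stirling numbers of the first kind;
* a **discrete uniform** prior over the |a(Y)| unordered models (integer
  partitions of *Y*);
* the classic **"U-shaped"** prior (|**τ**| uniform on 1..*Y*, pairs
  assigned by a symmetric multinomial conditioned on no empty class),
  which concentrates mass on very few or very many events.

Inference is by rejection ABC. Each alignment is reduced to four summary
statistics — π, Watterson's θ<sub>W</sub>, Nei's π<sub>net</sub>, and
SD(π − θ<sub>W</sub>) — assembled per pair (optionally re-sorted by
descending between-population diversity π<sub>b</sub>, the unordered-model
layout). Prior draws are ranked by Euclidean distance on standardized
statistics; the retained sample yields posterior probabilities over
divergence models, the number of events |**τ**|, and the dispersion index
of divergence times D<sub>T</sub> = s²<sub>T</sub>/T̄ (D<sub>T</sub> < 0.01
is the conventional one-event criterion). Continuous parameters can be
sharpened by weighted local-linear regression adjustment; discrete model
quantities never are.

## Worked example

Four population pairs, a known two-event history (pairs 1–2 split at
τ = 0.5, pairs 3–4 at τ = 3.0, so the true D<sub>T</sub> = 0.89), analyzed
against 10,000 draws from a diffuse DPP prior:

```python
import numpy as np
import codivabc as c
from codivabc.experiments import default_pair_specs, simulate_prior_table
from codivabc.abc import reject, model_probabilities, hpd_interval

specs = default_pair_specs(4)            # 10+10 samples, 1000-bp locus
cfg = c.PriorConfig(Y=4)                 # DPP, chi ~ Gamma(2,2)
rng = np.random.default_rng(8)

model = c.DivergenceModel((1, 1, 2, 2), (0.5, 3.0))
demos = tuple(c.DemographicParams(0.025, 0.025, 0.025) for _ in range(4))
draw = c.ParameterDraw(model, demos, alpha=10.0, upsilon=(1.0,) * 4)
observed = c.summarize_dataset(
    c.simulate_dataset(draw, specs, c.theta_C(cfg), rng))

table = simulate_prior_table(cfg, specs, 10_000,
                             np.random.default_rng(1), seed=1)
post = reject(table, observed, n_retain=100)
probs = model_probabilities(post)
dt = post.retained["D_T"].to_numpy()
print("p(|tau|=k):", {k: round(v, 2) for k, v in probs["ntau"].items()})
print("MAP model:", probs["map_signature"])
print("D_T median %.3f, 95%% HPD (%.3f, %.3f)"
      % (np.median(dt), *hpd_interval(dt)))
```

prints

```
p(|tau|=k): {1: 0.03, 2: 0.19, 3: 0.41, 4: 0.37}
MAP model: 2+1+1
D_T median 0.626, 95% HPD (0.000, 1.220)
```

The posterior puts almost no mass on a single shared event
(p(|**τ**|=1) = 0.03, p(D<sub>T</sub> < 0.01) = 0.04), spreads the rest
over 2–4 events — a single 1000-bp locus per pair carries little
information about the exact partition — and brackets the true dispersion
index 0.89 inside the 95% HPD interval. That diffuse-but-honest behavior,
rather than overconfident collapse onto one event, is the point of the
DPP prior.

The same pipeline is available from the shell: `codivabc simulate-prior`,
`observe` (FASTA + sample sheet → statistics), `reject`, `adjust`,
`summarize`, and the experiment harnesses `calibrate` and `power`. See
`docs/methods.md` for the model conventions and experiment designs.

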