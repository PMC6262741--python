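# allosim

An individual-based, spatially explicit resource–consumer model of
**size-dependent movement in fragmented landscapes**, for ecologists studying
how habitat isolation and resource productivity select on consumer body-size
distributions — and what that does to occupancy, biomass stability and
metapopulation functioning.

Consumers live on a toroidal lattice whose suitable patches regrow a resource
logistically (carrying capacity K = 2,000 J, growth rate r per day, floor
E_nc = 1 J). Every consumer trait scales allometrically with body mass W
(kg): ingestion `2·W^0.80·t_f`, basal metabolism `0.14·W^0.751` W, walking
speed `v_opt = 0.3·W^0.29` m/s, locomotion cost `0.17·W^0.75 + 3.4·W` J/s,
perceptual range `301·W + 0.097` m, clutch mass `0.158·W^0.92` kg over 15
eggs. The heritable gene is the asymptotic adult mass W_max ∈ [0.01 g, 3 g]
(mutation probability 0.001, uniform within ±50 % of the parental value).
Each day an individual eats (scramble competition), pays maintenance, may
move — with probability `p = max(0, 1 − R/Σi_max)` — to the richest patch
inside the circular area it can search (radius from its daily path length
and perceptual range), grows along the West ontogenetic curve
`dW/dt = a·W^(3/4)·(1 − (W/W_max)^(1/4))`, matures at 99 % of W_max, and
reproduces once before dying. Isolation is the nearest-neighbour distance
(NND) between patches; the *coupled* model ties speed and perception to
mass, the *decoupled* null model redraws them daily from the uniform ranges
[0.0106, 0.0557] m/s and [0.1, 1] m.

Downstream analyses implement the measurement protocol: patch occupancy,
the Wang–Loreau α/β₂/γ biomass-variability decomposition from a 100-patch
panel, W_max distribution moments, egg-cohort movement tracking, and a
redundancy-analysis variation partitioning (adjusted R², vegan-style) of run
summaries over coupling × isolation × growth speed.

See `docs/methods.md` for the full model description and design decisions.

## Worked example

A desk-scale coupled run (100 patches, NND 2, r = 0.5, 100 founders,
2,000 days):

```python
from allosim import SimulationConfig, LandscapeConfig, run

cfg = SimulationConfig(
    landscape=LandscapeConfig(nnd=2, n_suitable_target=100, resource_r=0.5),
    mode="coupled", n_init=100, t_max=2000, seed=7,
)
result = run(cfg)
print(result.summary())
```

prints (abridged):

```
mode: coupled        nnd: 2        r: 0.5       extinct: False
n_final: 1468        wmax_mean: 3.1955e-05      wmax_cv: 1.439
occupancy: 0.3291
alpha_cv: 3.5916     gamma_cv: 0.0647           beta2: 3.5269
```

A surviving population of 1,468 consumers has evolved a mean adult mass of
0.032 g — above the 0.01 g lower bound, because two empty cells between
patches already reward bodies large enough to search across gaps — occupying
a third of the patches at any sampling time. Local biomass fluctuates
strongly (α = 3.59) but patches fluctuate asynchronously, so the
metacommunity as a whole is far more stable (γ = 0.065, β₂ = α − γ). Rerun
with `nnd=4` or `resource_r=0.1` and the evolved mass rises; decoupling
movement from size (`mode="decoupled"`) collapses it toward the minimum.

The same run is available from the shell:

```sh
allosim run --mode coupled --nnd 2 --growth 0.5 --patches 100 \
            --n-init 100 --days 2000 --seed 7 --out out/run7
allosim experiment --scale reduced --replicates 3 --out out/exp   # factorial
allosim varpart --runs out/exp/manifest.csv --response weights    # Table-style
allosim metrics --panel out/run7/panel.csv                        # α/β₂/γ
```

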