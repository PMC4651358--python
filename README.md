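# swarmstate

State-space analysis of movement in sympatric sheep and red deer.

Hill sheep (*Ovis aries*) and red deer (*Cervus elaphus*) share large areas
of upland grazing, and how the two species attract, repel and avoid each
other shapes habitat impact, competition and disease transmission. Given
hourly GPS fixes of both species on a shared plot, this package infers the
*deterministic* part of each animal's movement — a one-step map from the
current configuration of neighbours (and local vegetation, thermal stress
and season) to the next position — and turns it into interaction diagrams
that read off attraction and repulsion as a function of separation
distance. A synthetic two-species swarm generator reproduces the study
conditions (60 ewes and 20 hinds on a ~1 km² fenced moorland plot, hourly
fixes, GPS error with 95% of fixes within 14 m), so the entire analysis
runs and is tested without any field data.

## The model

For focal sheep *i* at time *t* with position *s<sub>i</sub>(t)*, the
**interaction vector** stacks offsets to its *m* nearest sheep and *n*
nearest deer:

> v(s<sub>i</sub>(t)) = (s<sub>i</sub>−s<sub>k(1)</sub>, …, s<sub>i</sub>−s<sub>k(m)</sub>; s<sub>i</sub>−d<sub>h(1)</sub>, …, s<sub>i</sub>−d<sub>h(n)</sub>)

plus a covariate vector *w* describing the focal animal's location
(one-hot vegetation class, standardised thermal stress, season). A
one-step predictor *F* with **F(v; w) ≈ s<sub>i</sub>(t+1)** is fitted by
least squares over all animals and hours. *F* is built from a single
scalar radial-basis-function surface *f* through the rotation composition

> F(v; w) = [f(v; w), 0] + R·[f(R⁻¹v; w), 0],

where R is the anticlockwise 90° rotation applied to every 2-D offset; *f*
is odd under 180° rotation of its vector inputs by construction, which
makes *F* exactly rotation-equivariant — the inferred interaction rules
cannot depend on the compass orientation of the coordinate frame. Basis
functions (Gaussians, Ricker wavelets, sharpened/flattened Gaussian
"tophats") are selected greedily under a **minimum-description-length**
criterion, DL = (N/2)·ln(RSS/N) + (k/2)·ln N, so extra parameters must buy
enough fit to pay for themselves.

From a fitted model, **interaction diagrams** plot the median predicted
change in separation (p − Δ, where Δ is the current mean separation to the
n′ nearest targets and p the predicted one) against Δ: negative values are
attraction, positive repulsion. Movement statistics include daily distance
travelled analysed with a linear mixed model (species × season fixed
effects, animal random intercept, Satterthwaite df, Bonferroni pairwise
comparisons), monthly root-mean-square one-step predictability, and the
neighbour-density function D(k), the mean distance to the k-th nearest
neighbour.

## Worked example

The numbered scripts under `analysis/` run the full chain on synthetic
study-condition data (each writes its tables under `results/`):

```bash
python analysis/01_simulate.py          # environment + swarm + GPS collars
python analysis/02_build_dataset.py     # interaction-vector datasets
python analysis/03_fit_models.py        # F (sheep) and G (deer)
python analysis/04_interaction_diagrams.py
python analysis/05_movement_stats.py
```

A run with the committed seeds prints, in order:

```
simulated 80 animals for 240 h; 40 collared tracks written to .../results
sheep: 5497 rows (skips: {'missing_next_fix': 23})
deer: 4063 rows (skips: {'missing_next_fix': 17})
sheep: 2 bases (+4 linear), DL=27464.8 nats, one-step RMS=12.13 m, n=5497
deer: 10 bases (+4 linear), DL=19350.6 nats, one-step RMS=10.74 m, n=4063
sheep/heterospecific: zero crossing(s) at 48 m
deer/heterospecific: zero crossing(s) at 30 m
D(k), m: {1: 14.2, 2: 25.4, 3: 31.5, 4: 37.3, 5: 42.2, 6: 47.8}
```

Reading this: each collared animal-hour with a full neighbour set and a
next-hour fix becomes one training row; the selected sheep model carries 2
basis functions on top of the linear part and predicts the next hourly
position to ~12 m RMS (GPS noise alone contributes σ√2 ≈ 8.1 m). The
inter-species interaction curves cross zero near 30–50 m — animals of
different species repel below that separation and attract above it, with
the intra-species attraction stronger at long range — and on this
snapshot a circle of diameter ≲ 14 m around an animal typically contains
no other animal (D(1) ≈ 14 m).

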