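# groupgame

Agent-based simulation and analysis of **scale-induced category
convergence**: why large populations that play pairwise label-coordination
games over a continuum of ambiguous stimuli independently arrive at similar
category systems, while isolated pairs drift apart.

The package is written for researchers in cultural evolution, language
dynamics and collective behaviour who want a reproducible, fully synthetic
test bed for critical-mass (tipping-point) accounts of convention formation —
no human-subject data is required anywhere.

## The model in brief

`N` agents play 100 rounds of a pairwise "grouping game" over a 1500-slice
stimulus continuum (scenes of 3 slices, pairwise ≥ 75 apart; no slice shown
twice to the same subject).  Agents dynamically partition the normalised
continuum into perceptual categories down to a resolution `d_min = 0.01` and
attach labels per category.  Innovation is governed by a shared pool of
`|L| = 5000` candidate labels with Zipf weights `w_r ∝ r^(−b)`, `b = 1`: each
agent privately labels a coarse personal partition of the continuum with
draws from the pool, so a few labels are in many repertoires and most are
idiosyncratic.  Successful coordination locks a pairwise convention; blind
lucky guesses and failures are mere exposure.

A label *reaches critical mass* when at least `θN` agents (θ = 0.25)
introduce it independently; the probability of that event is
`P[X ≥ ⌈θN⌉]` with `X ~ Binomial(N, p)` (or `Hypergeometric(M, K, N)` for a
finite universe of M with K carriers).  Because this tail probability grows
with N for common labels and collapses for rare ones, large populations
filter the same few labels out of individual diversity — the mechanism the
simulator exhibits and the `critical_mass` module computes in closed form.

Per trial, the emergent vocabulary is extracted by DBSCAN (MinPts = 3,
radius at the knee of the k-distance curve) over each label's
(successes, adopters) features; convergence between trials is the Jaccard
index of those vocabularies.

## Worked example

```python
import groupgame as gg

params = gg.GameParams(n_agents=50)          # 100 rounds, d_min=0.01, |L|=5000, b=1
logs = gg.run_ensemble(params, n_trials=5, base_seed=42)
report = gg.convergence_report(logs)
for vocab in report.vocabularies:
    print(sorted(vocab))
print("mean pairwise Jaccard:", round(report.mean_jaccard, 3))
print("mean diversity:", round(sum(report.diversity) / len(report.diversity), 1))
```

prints

```
['bird', 'bunny', 'crab', 'moth']
['bunny', 'crab', 'horn', 'worm']
['bunny', 'crab', 'fish', 'moth']
['bunny', 'crab', 'moth', 'worm']
['bunny', 'claw', 'crab', 'fish']
mean pairwise Jaccard: 0.467
mean diversity: 35.3
```

Five *independent* 50-person populations — sharing nothing but the
statistics of individual coinage — converge on nearly the same vocabulary
(the high-Zipf-rank labels "crab", "bunny", ...), with a mean pairwise
Jaccard similarity of 0.47.  Each subject encountered ~35 distinct labels on
the way.  Running the same ensemble with `n_agents=2` yields vocabularies
that are almost pairwise disjoint (Jaccard ≈ 0.05): small populations
entrench idiosyncratic conventions.

The same machinery exposes a CLI:

```
groupgame simulate -n 50 --n-trials 15 --seed 1 -o out/      # interaction logs (CSV)
groupgame analyze out/trial0.csv out/trial1.csv               # vocabularies + metrics
groupgame predict --n-grid 2,6,8,24,50 --n-trials 15 --seed 1 -o out/
groupgame confederate --n-trials 6 --seed 1 -o out/           # seeded-takeover trials
groupgame reproduce --seed 1 -o results/                      # headline battery
```

`confederate` plants an immutable minority (37% of N = 24) that promotes
rare labels ("sumo", ...) over the whole continuum, and tracks the cumulative
successful uses of "sumo" versus the spontaneously popular "crab" among
experimental subjects.

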