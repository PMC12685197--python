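# neodose

Hypertension in preterm neonates (gestational age < 37 weeks) is treated
without dosing guidelines: clinicians titrate antihypertensive agents by
experience, and the dosing strategies actually in use are largely
undocumented. `neodose` is a pipeline for describing those strategies
from inpatient EMR extracts. It converts medication administration
records into weight-standardized, hourly piecewise-constant **dose
trajectories**, selects a common follow-up window, groups the curves
with deterministic **functional K-means**, and characterizes the
resulting clusters with standard nonparametric tests. It is written for
pharmacoepidemiologists and biostatisticians working with neonatal
medication-administration data.

Because real extracts of this kind are access-restricted, the package
ships a first-class synthetic cohort generator with planted dosing
archetypes and ground-truth labels, so the whole pipeline is testable
end to end.

## Method

For a treatment course (one drug within one visit), each administration
at time $t$ is standardized by the weight measured closest in time
(ties in minutes averaged): $d(t) = m(t)/w(t)$ in mg/kg for oral drugs,
or rate$/w(t)$ in mg/kg/min for IV infusions. The trajectory is the
step function on a left-closed hour grid anchored at the first
administration, carrying each standardized dose forward until the next
dose change; oral courses hold the final dose for six hours (the modal
dosing interval) and then drop to 0 mg/kg.

The common clustering window $T$ maximizes the sample standard
deviation of all pairwise Euclidean distances between curves truncated
(zero-padded) to $[0, T)$:

$$T^* = \arg\max_T \; \mathrm{SD}\{\, \lVert x_i - x_j \rVert_{[0,T)} : i < j \,\}$$

with a per-drug analyst override for profiles whose global maximum sits
at an unrealistically short window. Curves are clustered at
$k = 2, 3, 4$ by K-means with deterministic maximin ("max-dist")
seeding — first two seeds the most distant pair, each further seed the
farthest point from the chosen seeds — followed by Lloyd iterations and
a single-move polish that guarantees no single reassignment can lower
the within-cluster sum of squares. Clusters are compared on
demographics and ICD-coded comorbidities with Kruskal–Wallis,
Pearson chi-square, or Fisher's exact test (when any expected cell
count is < 5).

## Worked example

```python
import neodose as nd

cfg = nd.GeneratorConfig(n_patients=100, seed=1)
visits, admins, weights, truths = nd.generate_cohort(cfg)
res = nd.DosingTrajectoryStudy(visits, admins, weights).fit()
print(res.summary())
```

```
Dosing-trajectory study
  visits: 100 total, 93 included, 7 excluded
  top agents: propranolol, captopril, esmolol
  propranolol: 67 courses, window 702 h
    k=2: sizes A=54, B=13, WCSS 2919
    k=3: sizes A=30, B=24, C=13, WCSS 1200
    k=4: sizes A=30, B=24, C=9, D=4, WCSS 1005
  captopril: 13 courses, window 402 h
    k=2: sizes A=7, B=6, WCSS 48.99
    k=3: sizes A=7, B=3, C=3, WCSS 18.57
    ...
```

Seven of the 100 synthetic visits were excluded (term gestational age,
IV propranolol, or a hemangioma diagnosis — the deliberate exclusion
spikes), 93 were retained, and the three agents' curves were clustered
at each drug's selected window. For propranolol, the three clusters of
sizes 30/24/13 recover the three planted archetypes (hold at a target
dose; start low and titrate up; high starting dose) — at the default
noise level the agreement with ground truth is exact (adjusted Rand
index 1.0). The clustering model is also usable directly,
statsmodels-style:

```python
km = nd.TrajectoryKMeans.from_trajectories(
    res.trajectories["propranolol"], window=702, k=3)
print(km.fit().summary())
```

```
Functional K-means (max-dist init), k=3, n=67, window=702 h
WCSS: 1199.77   iterations: 2   converged: True
Cluster sizes: A=30, B=24, C=13
```

The same pipeline runs from a shell:

```sh
neodose simulate --n 100 --seed 1 --out data/
neodose run --in data/ --out results/ --override esmolol 50
```

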