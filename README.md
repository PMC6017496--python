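# basinsel

Basin-based decoy selection for template-free protein structure prediction.

Template-free methods such as Rosetta generate tens of thousands of candidate
conformations (*decoys*) per target, but their energy functions are unreliable
indicators of nativeness, so picking the near-native decoys out of the
ensemble remains hard. The prevailing remedy ignores energy entirely and
clusters decoys by conformational similarity. `basinsel` instead treats the
decoy ensemble Ω as a sample of the protein's energy landscape and selects
decoys by the *basins of attraction* of that landscape:

1. Embed Ω in an ε-nearest-neighbor graph G = (V, E): an edge (u, v)
   whenever d(u, v) ≤ ε, with d the lRMSD (least RMSD after Kabsch
   superposition) or any conformational distance.
2. A vertex u is a local minimum if f(u) ≤ f(v) for all neighbors v; every
   other vertex follows a discrete negative gradient — the edge maximising
   (f(u) − f(v)) / d(u, v) — until it reaches a minimum. Vertices reaching
   the same minimum form its basin.
3. Each basin B carries a size |B|, a focal energy f(B) (its deepest
   point), a pseudo-saddle, a persistence f(saddle) − f(B), and a stability
   |f(saddle) − f(B)|/√2. Basins with persistence below a threshold
   p_thresh are merged into the basin across their saddle.
4. Basins are ranked by size (**Basin-Size**), by focal energy within the
   ten largest (**Basin-Size+Energy**), or by Pareto optimality on
   (size, −energy) under strong dominance: **Basin-PR** orders by Pareto
   rank (number of dominating basins, ascending) and **Basin-PR+PC** breaks
   PR ties by Pareto count (number of dominated basins, descending). The
   top x groups G1..Gx are offered as the prediction.

Two baselines calibrate the comparison: **Cluster-Size** (follow-the-leader
clustering, largest clusters first) and **Cluster-Random** (uniform random
groups matched in size to the top clusters, averaged over 5 runs).
Selections are scored against natives — decoys within a per-target
`dist_thresh` lRMSD of the experimental structure — by

* `n` = % of all natives captured by G1∪…∪Gx,
* `p` = purity, % of G1∪…∪Gx that is native,
* `s` = % of Ω selected.

## Worked example

A planted three-well landscape (150 samples per well, native well deepest,
energy noise at 5% of the shallowest depth), scored at `dist_thresh` = 2:

```python
from basinsel import (PlantedLandscapeSpec, generate_planted, select,
                      label_natives, score_groups)

spec = PlantedLandscapeSpec(n_basins=3, samples_per_basin=150, seed=42)
ds, truth = generate_planted(spec)
labels, n_nat = label_natives(ds, dist_thresh=2.0)
print(f"{len(ds)} decoys, {n_nat} native (dist_thresh = 2.0)")
for strat in ("Cluster-Size", "Cluster-Random", "Basin-Size", "Basin-PR+PC"):
    ranked = select(ds, strat, x=3, seed=0)
    rows = score_groups(ranked, labels, len(ds), x_max=3)
    cells = "  ".join(f"x={r.x}: n={r.n:5.1f}% p={r.p:5.1f}% s={r.s:5.1f}%"
                      for r in rows)
    print(f"{strat:16s} {cells}")
```

prints

```
450 decoys, 136 native (dist_thresh = 2.0)
Cluster-Size     x=1: n= 46.3% p=100.0% s= 14.0%  x=2: n= 46.3% p= 55.8% s= 25.1%  x=3: n= 46.3% p= 39.4% s= 35.6%
Cluster-Random   x=1: n= 13.1% p= 28.3% s= 14.0%  x=2: n= 22.2% p= 28.5% s= 23.6%  x=3: n= 30.6% p= 29.3% s= 31.6%
Basin-Size       x=1: n=100.0% p= 90.7% s= 33.3%  x=2: n=100.0% p= 45.3% s= 66.7%  x=3: n=100.0% p= 30.3% s= 99.8%
Basin-PR+PC      x=1: n=100.0% p= 90.7% s= 33.3%  x=2: n=100.0% p= 45.3% s= 66.7%  x=3: n=100.0% p= 30.3% s= 99.8%
```

The top basin captures the entire native well (n = 100% at 90.7% purity),
while the top cluster fragments it (n = 46.3%) and random draws track the
global native fraction (~30%). Real decoy sets are read from PDB files plus
a score table with `basinsel.read_decoy_set`, and the same pipeline is
available from the shell:

```sh
basinsel simulate --n-basins 3 --seed 42 --out decoys.tsv
basinsel evaluate --table decoys.tsv --dist-thresh 2.0 --out report.json
basinsel plot --table decoys.tsv --kind disks --out basins.png
```

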