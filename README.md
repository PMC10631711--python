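# fatepattern

Recognition and reconstruction of cell-fate patterns in simulated stem-cell
colonies and organoids.

During early mammalian development, inner-cell-mass (ICM) cells segregate
into epiblast and primitive-endoderm precursors in spatial arrangements that
range from fine-grained checkerboards to fully engulfing core–shell
patterns.  `fatepattern` is a toolkit for studying how such binary (or
four-class NANOG/GATA6) patterns relate to the *range* of the intercellular
signal that created them:

- **`tissue_sim`** — an agent-based model that grows 2D colonies and 3D
  organoids (division with radius rule `r_new = 2^(-1/dim) r_old`, soft
  repulsion) and then runs mutual-inhibition fate dynamics coupled by a
  distance-dispersed signal.  A single dispersion parameter `q ∈ (0, 1)`
  morphs the pattern from checkerboard (`q → 0`, lateral inhibition between
  contacts) to engulfing (`q → 1`, whole-tissue integration).
- **`cellgraph`** — thresholded Delaunay cell graphs with normalized
  distance edge weights, and disjoint-union batching.
- **`spatialstats`** — Moran's index
  `I = n/ΣA · (x−x̄)ᵀA(x−x̄) / (x−x̄)ᵀ(x−x̄)` on the cell graph, two-type
  pair correlation functions ρ_u, ρ_v, and 1000-resample randomization
  envelopes.
- **`recognition`** — a graph neural network (two graph-convolution-with-
  skip layers `Z′ = D^(−1/2)AD^(−1/2)XW₁ + XW₂ + b` with 450/150 channels,
  global attention-sum pooling, sigmoid head) that regresses `q` from a
  whole tissue.  Implemented in NumPy/SciPy with hand-written gradients.
- **`reconstruction`** — a 3×64 ReLU perceptron that imputes one cell's
  fate from the fates and distances of its k nearest neighbours, with
  neighbour sweeps, crosstraining matrices and confusion matrices.
- **`fates` / `synthdata`** — mapping between the four NANOG/GATA6 classes
  (N+G+=0, N−G+=1, N−G−=2, N+G−=3) and binary fates (random proportion-
  preserving reassignment, 2-means binarization), plus a generator of
  synthetic ICM-organoid tables with controllable rim structure.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import fatepattern as fp

# grow a 150-cell 2D colony and pattern it at two dispersion ranges
colony = fp.grow_tissue(fp.GrowthParams(dim=2, t_growth=30, n_steps=6000,
                                        target_cells=150, seed=5))
for q in (0.05, 0.95):
    patterned = fp.run_fate_dynamics(colony, fp.FateParams(q=q, seed=3))
    graph = fp.build_graph(patterned)
    I = fp.moran_index(graph, patterned.fates).I
    print(f"q={q}: Moran's I = {I:+.3f}, fate-1 fraction = {patterned.fates.mean():.2f}")
```

prints

```
q=0.05: Moran's I = -0.207, fate-1 fraction = 0.49
q=0.95: Moran's I = +0.698, fate-1 fraction = 0.51
```

— at `q = 0.05` neighbouring cells anti-correlate (checkerboard, I < 0); at
`q = 0.95` the same colony segregates into a core and a rim (I ≈ 0.7), and
the rim type's pair correlation function rises sharply at the largest pair
distances.

The same objects feed the learning models:

```python
tissues = fp.simulate_dataset("C", seed=1, n_replicates=10)   # 9 q-levels
graphs = [fp.build_graph(t) for t in tissues]
model, report = fp.train_recognizer(graphs, fp.RecogTrainConfig(seed=0))
print(report.mse)          # held-out MSE of predicted vs true q

rows = fp.neighbor_features(tissues[0], k=7)                  # label,F1,D1,...
imputer, rep = fp.train_imputer(rows, n_classes=2)
print(rep.accuracy)        # held-out fate-imputation accuracy
```

A CLI wraps the same functionality:

```
fatepattern simulate --recipe C --seed 1 --out data/
fatepattern stats --in data/dataset_C.csv --out stats.json
fatepattern train-recognizer --data data/dataset_C.csv --seed 0 --out model/
fatepattern train-imputer --data data/dataset_C.csv --k 7 --seed 0 --out imp.json
fatepattern synth-icm --seed 1 --out icm.csv
```

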