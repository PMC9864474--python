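# downselect

Pick the *n* mutually most dissimilar (or most similar) items out of a
population of *N*, given only the pairwise dissimilarity matrix.

The core method is a greedy heuristic: take the natural log of the matrix,
start from the exactly optimal pair, and repeatedly select the item whose
summed log-distance to everything already chosen is largest. The subset
quality metric is the **log-sum objective** — the sum of ln(d_ij) over all
unordered pairs inside the subset, equal to the log of the product of
pairwise distances but immune to float overflow/underflow at any subset
size. Because the greedy prefix never changes, one O(N²) pass yields the
solution for *every* set size at once, and the size-*n* solution always
nests inside the size-(*n*+1) solution.

Two baselines are included for benchmarking: best-of-*k* Monte Carlo
sampling over uniform random subsets, and exhaustive enumeration of all
C(N, n) subsets (guarded, since that count reaches 2.08 × 10¹³ already at
N = 50,000, n = 3). A conformer front-end builds RMSD dissimilarity
matrices from multi-record XYZ or SDF files, the intended application
being downselection of molecular conformer ensembles before expensive
property calculations.

## Layout

| module | contents |
|---|---|
| `downselect.matrix_core` | matrix validation, log transform, set objective, binomial search-space size, analytic random-subset mean, text/binary matrix I/O |
| `downselect.selectors` | greedy (`sds_select`, `sds_select_all`), Monte Carlo (`mc_select`), exhaustive (`exact_select`) |
| `downselect.conformer_io` | XYZ/SDF ensembles, corresponding-atom RMSD (optionally Kabsch-superposed), matrix construction |
| `downselect.synthetic` | seeded generators: Euclidean point clouds, random symmetric matrices, Gaussian-perturbed conformer ensembles |
| `downselect.bench` | benchmark harness (greedy vs MC, greedy vs exact/mean/minimum) |
| `downselect.cli` | `downselect` command-line entry point |

## Usage

```python
import downselect as ds

m = ds.random_point_population(2000, 3, seed=0)   # or ds.read_matrix(path)
result = ds.sds_select(m, n=7)                    # greedy, "dissimilar" mode
result.order            # selection order (size-k prefixes are the size-k solutions)
result.objective.value  # log-sum objective of the chosen set

mc = ds.mc_select(m, n=7, iterations=10_000, seed=0)
ex = ds.exact_select(ds.random_point_population(20, 3, seed=0), n=10)
```

Conformer pipeline:

```python
ens = ds.read_xyz("conformers.xyz")       # same atoms, same order per record
m = ds.build_matrix(ens, superpose=False) # corresponding-atom RMSD (Å)
best = ds.sds_select(m, n=5)
```

### CLI

```bash
downselect synth --kind points --n 500 --dim 3 --seed 1 --output m.tsv
downselect select --matrix m.tsv --n 5 --method sds --json
downselect build-matrix --input conf.xyz --format xyz --output rmsd.sdsm --matrix-format binary
downselect bench-mc --matrix m.tsv --n-values 3,4,5,6,7 --iterations 10000 --seed 0
downselect bench-exact --matrix m.tsv --n 10
```

Matrix formats: labelled tab/comma-delimited text, or a compact binary
form (`SDSM` magic, version byte, uint64 N, strict upper triangle as
little-endian float64).

## Notes & limitations

- Matrices are dense and in-memory: O(N²) doubles (N = 50,000 ≈ 20 GB).
  Shipped tests stay at N ≤ 2,000.
- Zero distances (exact duplicates) propagate as −inf through the log-sum,
  so a duplicate is never greedily selected while any finite-scored
  candidate remains; in "similar" mode they are the best candidates.
- All ties break deterministically (smallest index / lexicographically
  smallest subset); every stochastic routine requires an explicit seed.
- RMSD uses corresponding atoms as given by default; `superpose=True`
  applies least-squares rigid superposition first. No equivalent-atom
  symmetry correction.
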