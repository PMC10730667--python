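# mfnj

Distance-based phylogenetic tree reconstruction that handles **ties in
proximity** honestly. The package implements:

- **`run_nj`** — classic neighbor joining (Studier–Keppler selection
  criterion `S_ij = (N−2)·D_ij − R_i − R_j`), which must break ties between
  equally-close pairs arbitrarily and is therefore sensitive to the input
  order of taxa;
- **`run_mfnj`** — a multifurcating variant that detects *all* pairs
  attaining the minimal criterion, merges them into disjoint groups by
  transitive closure, and joins each whole group into a single internal
  node (a polytomy) in one iteration, using group generalizations of the
  pairwise distance-update and branch-length formulas. The result is a
  unique tree, independent of taxon input order; with no ties it is
  identical to classic NJ;
- **`enumerate_nj_trees`** — an exhaustive tie-break enumerator that
  returns every distinct unrooted topology classic NJ can produce.

A nine-bear mitochondrial-DNA distance matrix ships as a packaged example
(`mfnj.bear_fixture()`): classic NJ reaches an exact tie at its fifth
iteration and can produce two different trees, while the multifurcating
variant resolves the tie as a single polytomy joining three subtrees.

## Command line

```sh
mfnj mfnj bears.phy                  # multifurcating tree (Newick on stdout)
mfnj nj bears.phy --log joins.jsonl  # classic NJ + JSON-lines join log
mfnj enumerate bears.phy             # one Newick per distinct NJ tree,
                                     # then "distinct_trees=K truncated=..."
mfnj simulate --n-leaves 12 --seed 7 -o sim.phy --tree-out true.nwk
mfnj audit bears.phy --permutations 100   # input-order invariance check
```

Input matrices are PHYLIP-style (square or lower-triangular, relaxed
labels) or CSV/TSV with a header row; format is auto-detected from the
extension and can be forced with `--format`. Useful flags: `--root longest`
(midpoint-root the longest branch for display), `--clamp-negative`,
`--precision`, `--tie-rtol` / `--tie-atol` (tie-detection tolerances).
Exit codes: 0 success, 2 bad input, 1 internal error.

## Library example

```python
import mfnj

dm = mfnj.bear_fixture()
tree, log = mfnj.run_mfnj(dm)
print(mfnj.to_newick(tree))
print(len(mfnj.enumerate_nj_trees(dm)))   # -> 2 distinct classic-NJ trees
```

`mfnj.synthetic` generates seeded random trees (optionally multifurcating),
their additive path-length matrices, star matrices `D_ij = l_i + l_j`, and
Gaussian perturbations — all used as ground truth by the test suite.

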