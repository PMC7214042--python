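# covpower

Covariation significance and detection-power analysis for RNA multiple
sequence alignments with proposed consensus secondary structures.

Given an alignment (Stockholm 1.0 with a `#=GC SS_cons` line, or aligned
FASTA plus a structure file), covpower:

1. builds (or reads) a phylogenetic tree relating the sequences
   (neighbor-joining on Jukes–Cantor-corrected identity distances, or any
   user-supplied Newick tree);
2. infers the minimum number of substitutions per column with Fitch
   parsimony, and per proposed basepair as `s_ij = s_i + s_j`;
3. scores pairwise covariation (G-test by default, mutual information
   optional, APC optional) and assigns empirical E-values against a
   phylogeny-preserving null built from simulated negative-control
   alignments, in *one-set* (all `L(L-1)/2` pairs) or *two-set* (basepair
   set vs complement) mode;
4. evaluates each basepair's detection power from a fitted `power(s)` curve
   and reports `cov-bp-exp` (expected number of significantly covarying
   basepairs), the *alignment power* (its mean over the `B` proposed pairs),
   the observed significant count, and a low/high-power classification
   (threshold: alignment power > 10%).

A high-power alignment with no observed covariation is evidence against a
conserved structure; a low-power alignment is simply inconclusive.

The package also ships the evolutionary alignment simulator used to
validate the power model: a root sequence is evolved down a tree with
basepair-aware 16-state substitution for paired columns, 4-state
substitution for unpaired columns, and indels restricted to unpaired
regions, with branch lengths rescaled to hit a target average pairwise
identity.

## Command line

```sh
# full analysis: per-pair TSV + power summary
covpower analyze my.sto --mode two_set --seed 42 --out results/

# all-pairs screen without a structure
covpower analyze my.sto --mode one_set --out results/

# simulate a structural alignment at 60% average identity
covpower simulate template.sto --n-taxa 20 --target-id 0.6 --out sim.sto

# refit the power curve from a directory of annotated alignments
covpower fit-power alignments/ --out curve.tsv

# write synthetic test fixtures
covpower fixtures --out fixtures/
```

Useful `analyze` flags: `--stat GT|MI`, `--apc`, `--evalue` (default 0.05),
`--nulls` / `--null-stats` (null-distribution size), `--tree tree.nwk`,
`--curve curve.tsv`, `--structure ss.txt` (WUSS string file overriding
SS_cons), `--seed`, `--quiet`.

Outputs: `pairs.tsv` (1-based positions, statistic, E-value, substitution
count, power per pair), `summary.txt` (total bp | expected covary |
observed covary | alignment power | classification) and `summary.json`.
Exit codes: 0 success, 2 usage/format error, 3 statistical precondition
failure.

## Library layout

| module | contents |
|---|---|
| `covpower.msa_io` | Stockholm/FASTA I/O, WUSS ↔ basepair-list conversion |
| `covpower.phylo` | Newick I/O, identity/JC distances, NJ, rescaling, taxon subsampling |
| `covpower.parsimony` | Fitch per-column and joint 16-state pair counts |
| `covpower.covariation` | MI / G-test / APC, null alignments, E-values, one-set/two-set tests |
| `covpower.evolver` | rate models, tree-structured simulation with indels, identity targeting |
| `covpower.power` | binning, power-curve fitting (isotonic / polynomial / exponential), alignment power reports |
| `covpower.cli` | `covpower` command-line entry point |
| `covpower.fixtures` | seed-deterministic synthetic data generators |
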