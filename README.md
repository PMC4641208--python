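# mcpsc

Multicriteria protein structure comparison (MCPSC) toolkit: pluggable
pairwise structure-comparison methods, consensus scoring, load-balanced
scheduling of the pairwise job farm, and cluster-quality evaluation.

## What it does

Given a set of protein domains (PDB files, first chain, C-alpha trace), the
pipeline:

1. **Compares every pair with several methods** (`mcpsc.methods`):
   - `usm` — normalized compression distance between the domains' contact
     maps, with gzip as the complexity approximator;
   - `tm` / `rmsd` — a built-in rigid-superposition aligner (global sequence
     alignment + iterative Kabsch refinement) producing a length-normalized
     similarity in [0, 1] and an RMSD; both come from a single alignment
     pass. Scores from real external aligners can be ingested from TSV via
     `load_external_scores`, replacing the built-in stand-ins.
2. **Builds a consensus score** (`mcpsc.consensus`): the P × M score matrix
   is made dissimilarity-only (similarities s become 1 − s), each method
   column is min-max normalized to [0, 1], and the per-pair mean is the
   consensus (0 = most similar).
3. **Schedules the job farm** (`mcpsc.scheduling`): K_Q × K_D jobs per
   method; fast methods run sequentially in the coordinator, the rest on a
   worker pool. Static partitioning (random, greedy LPT on sum/product of
   pair lengths) and dynamic sorted round-robin dispatch are provided,
   along with a cost-model fitter (linear/quadratic in the length
   attributes) and a schedule simulator reporting makespan, speedup and
   efficiency.
4. **Evaluates clusterings** (`mcpsc.evaluation`): consensus scores become
   a symmetric distance matrix, clustered by unweighted average linkage
   (UPGMA), cut to C clusters, and scored against fold labels with the
   F-measure (majority-class mapping).
5. **Generates synthetic benchmarks** (`mcpsc.synthetic`): labeled fold
   families from helix/strand/mixed C-alpha templates plus noise, indels
   and random rigid transforms, PDB round-trip writing, and simulated job
   runtimes — so the whole pipeline is testable offline.

## CLI

```sh
# synthesize a labeled benchmark (PDB files + labels.tsv)
mcpsc synth --families 5 --members 7 --out-dir fixtures/ --seed 42

# all-to-all comparison with all three methods
mcpsc run --pdb-dir fixtures/ --methods usm,tm,rmsd --workers 4 \
      --strategy rr-sorted-product --out raw.tsv

# consensus scoring and clustering + F-measure
mcpsc consensus --scores raw.tsv --out consensus.tsv
mcpsc cluster --consensus consensus.tsv --labels fixtures/labels.tsv \
      --k 5 --out clusters.tsv --newick tree.nwk

# scheduling experiments with simulated costs
mcpsc jobs --pdb-dir fixtures/ --methods tm,rmsd --out jobs.tsv
mcpsc synth-costs --jobs jobs.tsv --coeffs 5e-6,0,0.05 --noise-sd 0.1 \
      --seed 1 --out costs.tsv
mcpsc schedule-sim --jobs jobs.tsv --costs costs.tsv --workers 47 \
      --strategy greedy-product --report report.tsv
```

## Layout

```
src/mcpsc/
  structio.py    PDB C-alpha parsing, contact maps, canonical serialization
  methods.py     usm / tm / rmsd methods, registry, caches, external adapter
  consensus.py   score matrix, normalization, consensus, TSV round trip
  scheduling.py  job farm, partitioners, dispatch, executor, cost models
  evaluation.py  distance matrix, UPGMA, tree cut, F-measure
  synthetic.py   synthetic families, benchmarks, runtimes, PDB writing
  cli.py         `mcpsc` command group
tests/           unit + property tests; test_acceptance.py mirrors the
                 acceptance criteria; oracles.py holds brute-force checks
scripts/acceptance.py
```
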