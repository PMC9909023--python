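# passar

Passive-sampling species–area analysis for microbial count tables.

`passar` takes a sample-by-taxon count table from equal-area passive samples
(plus sample areas and, optionally, a rooted phylogeny) and runs the full
analysis chain:

1. **Island models** — repeatedly draw 1..K−1 samples at random and
   superimpose their areas and counts into an area-nested ladder of groups.
2. **SAR fits** — ordinary least squares of `log S = C + z·log A` per model,
   with slope CI and p-value (base-10 logs, areas in cm² by default).
3. **Random-placement null** — the expectation
   `E(S_j) = Σ_i [1 − (1 − a_j/A_T)^{n_i}]` for each island area, stratified
   by abundance class (abundant > 0.1 % total relative abundance,
   rare < 0.01 %, moderate between), compared to observations with a paired
   t-test (differences = expectation − observation).
4. **Beta diversity** — Podani-style partition of pairwise dissimilarity into
   similarity / replacement / richness-difference triplets (Jaccard and
   Sørensen families) and unweighted / weighted UniFrac distances.
5. **Alpha diversity** — richness, Shannon (nats), Gini–Simpson, ACE.

A synthetic-community module generates all inputs from scratch: a regional
pool with a long-tailed species-abundance distribution (log-series or
lognormal), a "dart-throwing" placement simulator (each individual of
species *i* lands on island *j* with probability `m_i·a_j/A_T`), and random
rooted trees. With all occupancy multipliers `m_i = 1` the simulator
satisfies the random-placement expectation by construction, which is what
the test-suite oracles exploit.

## CLI

```bash
# end-to-end on simulated data
passar run --simulate --seed 1 --out results/run1

# or stage by stage
passar simulate --n-species 5000 --total-individuals 250000 --seed 1 --out work
passar islands  --table work/table.tsv --areas work/areas.tsv --seed 1 --out work
passar sar      --manifest work/islands_manifest.tsv --out work
passar coleman  --table work/table.tsv --areas work/areas.tsv \
                --manifest work/islands_manifest.tsv --out work
passar beta     --table work/table.tsv --out work
passar unifrac  --table work/table.tsv --tree work/tree.nwk --out work
```

`passar run` also accepts a YAML config (`--config cfg.yaml`, flags win) and
writes every intermediate as TSV plus `report.json` / `summary.txt`; runs are
byte-identical given the same seed.

Input formats: tab-separated count table (taxa as rows by default; the header
corner cell is used to auto-detect orientation, `--samples-as-rows`-style
overrides available in the API), BIOM-v1-style JSON, two-column
`sample_id<TAB>area` TSV, Newick trees.

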