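# tdssgrn

Inference of instantaneous and time-delayed gene regulatory networks from
multi-replicate time-series expression data.

Each target gene is modeled by a time-delayed S-system rate law

```
dX_i/dt = alpha_i * prod_j X_j(t - tau_gij)^g_ij  -  beta_i * prod_j X_j(t - tau_hij)^h_ij
```

with integer lags counted in sampling intervals. Candidate equations are
encoded as fixed-length two-gene GEP chromosomes (head/tail symbol strings
decoded level-order into expression trees) carrying three coding regions:
structure symbols, real parameters (rate constants, kinetic orders) and
binary-coded delays. A hybrid GA/GEP evolves all three regions at once
under a partitioned map/reduce-style generation loop: fitness evaluation is
embarrassingly parallel (map), chromosomes draw random partition ids, and
each partition reproduces independently via roulette selection, crossover
and mutation (reduce) before merging. Fitted equations are read off into a
directed edge list, each edge labeled instantaneous (lag 0) or time-delayed
(lag > 0), and scored by sensitivity/specificity against a truth network.

## Layout

| module | contents |
| --- | --- |
| `tdssgrn.tdss_core` | model terms/equations, chromosome encoding, level-order decoder |
| `tdssgrn.simulation` | RK4 integration: full delay network and decoupled single gene |
| `tdssgrn.evolution` | fitness (1/(1+SSE)), mutation/crossover/selection operators |
| `tdssgrn.parallel_engine` | map/reduce generation loop, per-partition RNG substreams |
| `tdssgrn.inference` | per-gene decomposition driver, edge extraction |
| `tdssgrn.metrics` | confusion counts, Sn, Sp, speedup ratio |
| `tdssgrn.synthetic_data` | ground-truth network + replicate dataset generator |
| `tdssgrn.io_cli` | TSV/SIF formats, YAML config, `tdssgrn` CLI |

## CLI

Generate a synthetic benchmark (truth edges + replicate expression files):

```bash
tdssgrn generate --genes 50 --edges 128 --delayed 10 \
    --replicates 10 --timepoints 21 --seed 7 --out benchmark/
```

Infer a network from expression matrices (first row `time<TAB>...`, one
`gene_id<TAB>values...` row per gene; one file per replicate):

```bash
tdssgrn infer benchmark/expr_rep*.tsv --population 300 --iterations 60 \
    --partitions 10 --seed 1 --out inferred/
```

Evaluate against the truth:

```bash
tdssgrn evaluate --predicted inferred/edges.tsv \
    --truth benchmark/truth_edges.tsv --genes 50
```

All defaults (population 2000, 200 iterations, p_c 0.7, p_m 0.3, rate
constants in [0,3], kinetic orders in [0,1], delays in [0,3], 200
partitions) can be overridden by flags or a YAML config (`--config`).
Runs are fully reproducible from the master seed; per-gene seeds are
`seed + gene_index` and per-partition streams are derived from
(seed, generation, partition).

## Chromosome text form

One line per chromosome, used in logs and checkpoints:

```
head|tail ; rate ; k1,k2,... ; bits1,bits2,... - head|tail ; rate ; ... ; ...
```

where `head`/`tail` are space-separated symbols (`*m` = product of m
operands, `x1..xN` gene variables, `R` constant), `k*` the per-position
kinetic orders, and `bits*` the fixed-width delay bit strings (MSB first).

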