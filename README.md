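# comodnet

Condition-annotated gene co-expression networks from mixed-condition
expression compendia.

## Why

A gene co-expression network (GCN) joins transcripts whose expression
correlates across samples. When samples pool several biological conditions
(e.g. tumor subtypes), plain Pearson/Spearman networks suffer from
**co-modality**: a gene pair with two separated expression modes — one per
condition — shows high correlation even when neither mode is internally
correlated, and genuinely condition-specific co-expression is diluted below
any global threshold. comodnet is for systems biologists building GCNs from
heterogeneous compendia (public repositories, multi-subtype cohorts) who
want edges that know *which samples produced them*.

## What it does

For every transcript pair with expression vectors x_a, x_b the complete
observations form a 2-D cloud modeled as a Gaussian mixture

    f(x | θ) = Σ_k p_k N(x | μ_k, Σ_k),

fit by EM with random data-point initialization; the number of modes K is
chosen by the Integrated Completed Likelihood, ICL = BIC + 2·ENT, whose
assignment-entropy term favors well-separated modes. Each sufficiently large
mode (n ≥ 30, from the Fisher-z power bound at α = 0.05, β = 0.2, r = 0.5)
is correlated separately (Spearman by default), and each qualifying mode
becomes its own edge annotated with a **sample string** — one digit per
sample: `1` in the edge's cluster, `0` observed but outside it, `9` missing,
`6`/`8` removed as pre-/within-cluster outliers.

The correlation threshold is chosen by random-matrix statistics: scan τ
upward until the nearest-neighbour spacing distribution of the thresholded
matrix's unfolded eigenvalues transitions from GOE (Wigner–Dyson, correlated
noise) to Poisson (modular signal), tested by chi-square against exponential
bin counts. Overlapping modules come from link communities (edge clustering
by neighborhood Jaccard similarity, cut at maximum partition density
D = (2/M) Σ_c m_c(m_c−(n_c−1))/((n_c−2)(n_c−1))). Modules are tested for
enrichment of sample-level clinical annotations through their edges' sample
strings (Fisher's exact test over the samples present in ≥95% of module
edges) and of gene-level GMT terms; network quality is scored by
neighbor-voting guilt-by-association AUROC with cross-validation.

A seeded synthetic-compendium generator plants condition-specific modules
with known latent correlation, so the whole pipeline is testable
quantitatively without any downloads.

## Worked example

Simulate a small two-condition compendium (40 + 40 samples, one 6-gene
module co-expressed only in condition CA, 20 background genes) and run
every stage:

```bash
cat > run.json <<'EOF'
{
  "out_dir": "out",
  "seed": 11,
  "tau": 0.5,
  "synth": {
    "conditions": [["CA", 40], ["CB", 40]],
    "modules": [{"gene_count": 6, "active_conditions": ["CA"]}],
    "background_genes": 20,
    "missing_rate": 0.02
  }
}
EOF
comodnet run-all --config run.json
```

which logs:

```
INFO comodnet: simulated GEM: 26 x 80
INFO comodnet: similarity: 325 pairs, 448 clusters tested
INFO comodnet: threshold: user override tau=0.5000
INFO comodnet: network: 6 nodes, 15 edges kept
INFO comodnet: modules: 1 modules, partition density 1.0000
```

All 15 edges among the 6 planted genes are recovered (and none else — the
module is a perfect clique, hence partition density 1.0). The network file
shows per-edge sample strings:

```
gene_a   gene_b   cluster_index  rho           ...  sample_string
PM1_G01  PM1_G02  0              0.8577524893  ...  111111111111111111119111011111111111111100000...
```

The first 40 digits (condition CA) are `1` — the edge exists in the
CA-specific mode, whose Spearman correlation is 0.86 — while the CB samples
read `0`; a `9` marks a missing measurement, an `8` a within-cluster
outlier. Clinical enrichment of the module's samples confirms the planted
condition:

```
module_id  attribute  category  a   b  c  d   p          significant
M0001      condition  CA        35  0  5  40  1.14e-17   True
M0001      condition  CB        0  35  40  5  1.00       False
```

35 of the samples present in ≥95% of the module's edges are CA samples and
none are CB, so the module is condition-specific exactly as planted.

Individual stages are also available as subcommands (`simulate`,
`preprocess`, `similarity --chunk A:B`, `threshold`, `extract`, `heatmap`,
`modules`, `enrich`, `evaluate`); `similarity` windows over the pair index
make the heavy stage embarrassingly parallel.

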