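# comodule

Discovery of phenotype-associated protein-family co-occurrence modules from
genome and metagenome annotations.

The pipeline treats each genome (or taxonomic metagenome bin) as a document
of protein-family identifiers, infers co-occurrence modules with a latent
Dirichlet allocation topic model fitted by collapsed Gibbs sampling, ranks
the modules by their association with a binary phenotype, stabilizes them
across repeated runs into consensus modules, evaluates the consensus modules
as phenotype classifiers, predicts module occurrences in unlabeled samples,
and maps module families to gene clusters on replicons.

## Components

| Module | Role |
| --- | --- |
| `comodule.annotation_io` | HMMER3 domtblout / annotation TSV reading, e-value and bit-score filtering, capped family-count corpus construction, phenotype tables |
| `comodule.topic_model` | Collapsed Gibbs LDA (`fit_lda`), topic-to-module thresholding (`extract_modules`) |
| `comodule.module_ranking` | Completeness weights, F_beta scoring, exhaustive threshold optimization, module ranking |
| `comodule.consensus` | Jaccard / symmetrized-KL module distances, Hungarian cross-run matching, Bron–Kerbosch stable cliques, quorum consensus modules |
| `comodule.evaluation` | Leave-one-out and repeated 10-fold cross-validation, Clopper–Pearson intervals, macro-accuracy |
| `comodule.phenotype_prediction` | Module-occurrence prediction rule, saprophyte family-count rule, co-assignment summaries |
| `comodule.gene_clusters` | Gene-cluster detection (≥4 neighboring module-annotated genes, gaps ≤2 kb), cross-module merging, cluster statistics, GFF3/BED I/O |
| `comodule.synthetic_data` | Ground-truth corpora and gene tables from the forward generative process |
| `comodule.cli` | `comodule` command-line interface |

Default parameters follow the published analysis: 400 topics, α = 50/T,
β = 0.01, 2000 burn-in sweeps, 50 collected Gibbs samples, module cutoff
C = 0.01, F_0.5 ranking on a 38-positive / 82-negative learning set,
18 runs, top-15 modules per run, consensus from cliques spanning ≥75% of
runs with a 9-module family quorum. Scaled-down settings for desk-scale
experiments are provided by `comodule.topic_model.scaled_down_config`.

## Command line

```sh
# synthetic end-to-end run with planted ground truth
comodule run-all --simulate --seed 7 --out-dir out/

# real data: filter hits, build the corpus, then run the pipeline
comodule filter-hits scan.domtblout --db dbcan --out hits.tsv
comodule build-corpus annotations.tsv --out corpus.tsv
comodule run-all --corpus corpus.tsv --phenotypes phenotypes.tsv --out-dir out/

# stage-by-stage
comodule fit corpus.tsv --topics 400 --seed 1 --out model.json
comodule rank model.json corpus.tsv phenotypes.tsv --out ranking.tsv
comodule clusters genome.gff3 out/consensus.tsv --sample-id g1 --out clusters.tsv
comodule saprophytes corpus.tsv --out saprophytes.tsv
```

Annotation TSV columns: `sample_id protein_id family_id [evalue bitscore db
model_len ga]`. Phenotype TSV: `sample_id label` with labels
positive/negative/unknown (`+`/`-`/`?` accepted). Gene tables are GFF3 with
family annotations in a `families=` attribute or a separate join table.

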