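# lesionkit

Toolkit for lesion-centric transcriptomics: screen genes and gene sets for
radial expression gradients around an annotated lesion in spatial data,
derive shared glial injury signatures from single-cell data, and map single
cells onto spatial spots for deconvolution. A built-in simulator generates
spatial and single-cell datasets with planted ground truth so the whole
pipeline is testable offline.

## Modules

| Module           | Purpose                                                                |
| ---------------- | ---------------------------------------------------------------------- |
| `io_formats`     | MatrixMarket counts + feature/barcode lists, Visium-style positions, GMT gene sets, TSV tables |
| `synthetic_data` | Negative-binomial simulators: spot lattice with a circular lesion core and radial gradient genes; scRNA-seq with cell types, reactive states, planted programs, batches |
| `preprocess`     | QC filtering, depth normalization + log1p, HVG selection, Leiden clustering, batch centering, group downsampling, control-matched gene-set scores |
| `gradient`       | Concentric-ring binning, radial profiles, template-model screening (4 descending + 4 ascending shapes), multi-lesion merging ranked by `p_value_mean` |
| `mapping`        | Probabilistic cell-to-spot mapping (per-gene cosine objective, softmax rows), per-cluster spatial probability, nuclei-constrained greedy deconvolution, radial cluster profiles |
| `differential`   | Overestimated-variance marker t-test, Wald condition contrasts, DEG threshold filters, exclusive/inclusive set intersections, hypergeometric over-representation, top-k marker Jaccard similarity |

## CLI

All subcommands that draw random numbers take `--seed`; repeated runs are
byte-identical.

```bash
# simulate a spatial dataset with planted gradient genes
lesionkit simulate spatial --config spatial.yaml --out sim/ --seed 1

# screen genes (and optionally GMT gene sets) against radial templates
lesionkit gradient screen --counts sim/ --positions sim/tissue_positions.csv \
    --lesion 1900,1900,200 --binwidth 95 --n-bins 13 \
    --genesets sets.gmt --out screen.tsv

# single-cell pipeline
lesionkit simulate scrna --config sc.yaml --out sc/ --seed 1
lesionkit qc --counts sc/ --out qc/ --min-reads 1000 --max-mito 0.25
lesionkit normalize --counts qc/ --out norm/
lesionkit hvg --counts norm/ -n 2000 --out hvg.txt
lesionkit cluster --counts norm/ --genes hvg.txt --seed 0 --out labels.tsv
lesionkit markers --counts qc/ --clusters labels.tsv --out markers.tsv
lesionkit score --counts norm/ --gmt sets.gmt --out scores.tsv

# cell-to-spot mapping and deconvolution
lesionkit map --sc sc/ --spatial sim/ --sc-clusters labels.tsv --out map/
lesionkit deconvolve --mapping map/ --sc-clusters labels.tsv \
    --nuclei nuclei.tsv --out composition.tsv

# set algebra and enrichment
lesionkit intersect --gmt deg_lists.gmt --out intersections.tsv
lesionkit enrich --query query.txt --gmt sets.gmt --universe universe.txt \
    --out enrichment.tsv
lesionkit similarity --markers markers.tsv --k-top 20 --out similarity.tsv
```

Simulator YAML configs mirror the fields of `SpatialSimConfig` /
`ScSimConfig` (see `lesionkit/synthetic_data.py`); any field can be set,
e.g. `n_genes: 2000`, `n_gradient_genes: {linear_descending: 100}`.

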