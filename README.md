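# glycotma

Quantification of two glycan antigens (CA19-9 and sTRA) in multi-round
immunofluorescence images of tissue-microarray cores, and the downstream
outcome analyses: pixel-mask boolean algebra for exclusive/colocalized
expression, per-core presence calls, nonparametric tumor-vs-adjacent and
short-vs-long time-to-progression (TTP) comparisons, and a Marker State
Space (MSS) panel search with 10-fold cross-validation and random-label
null runs.

A synthetic-data module renders core images with planted glycan regions
and draws patient cohorts with planted marker/outcome structure — with
full ground truth — so every stage is testable end to end without any
external data.

## Modules

| module | purpose |
| --- | --- |
| `glycotma.synthetic_data` | scene/cohort generators, TIFF+CSV dataset writer, Bayes-accuracy benchmark of the cohort generator |
| `glycotma.signal_finder` | tissue masking and parameter-free per-image signal detection (mode + 3·MAD threshold, small-component/hole cleanup), percent-of-tissue quantification |
| `glycotma.coloc_engine` | AND/OR/NOT expressions over signal maps, the five marker-type percentages (total, exclusive, dual), per-core averaging, >1% presence calls and core categories |
| `glycotma.cohort_stats` | Wilcoxon signed-rank elevation tests with Benjamini-Hochberg FDR, rank-sum group tests, TTP dichotomization at 24 months, median splits, Kaplan-Meier and log-rank |
| `glycotma.mss_panel` | exhaustive ≤3-marker threshold/state-table panel search gated at 80%/80% training sensitivity/specificity, k-fold cross-validation, random-label nulls |
| `glycotma.cli` | `simulate` / `quantify` / `stats` / `mss` / `all` subcommands |

## Command line

```bash
# render a synthetic dataset (images, truth masks, cohort, manifest)
glycotma simulate --seed 1 --outdir out/dataset

# per-core marker quantification from the dataset
glycotma quantify --dataset out/dataset --outdir out

# elevation / rank-sum / survival analyses on the cohort table
glycotma stats --cohort out/dataset/cohort.csv --outdir out

# panel search + cross-validation + random-label null
glycotma mss --seed 1 --cohort out/dataset/cohort.csv --outdir out

# or everything at once
glycotma all --seed 1 --outdir out
```

Options: `--config config.yaml` overrides the defaults documented in
`glycotma.cli.DEFAULT_CONFIG`; `--seed` sets the global seed from which
each stage derives its own seed (`(seed + crc32(stage)) % 2**32`); the
effective config is echoed as `config.json` into every output directory.

Outputs are plain CSV/JSON plus 16-bit TIFF images and 8-bit truth masks.
Cross-validation reports use one row per round and one column per split;
splits where no panel met the training minima are left empty (rendered as
an em-dash in the `*_human.csv` variants).

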