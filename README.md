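# dcmotif

Divide & Conquer decomposition of a transcription factor's binding-site
collection into hierarchically organized submotif families, combined into an
OR-voting multi-classifier whose submotif usage and thresholds are tuned by a
genetic algorithm, optionally fused with fuzzy IF-THEN rules over TF–RNAP
distance classes, and analyzed for per-position rates of binding-site
evolution.

## What is in the box

| module | role |
| --- | --- |
| `dcmotif.seqio` | binding-site / annotation / genome data model; FASTA, TSV site tables, GFF3/BED, MEME-minimal PWM I/O; one-hot encoding |
| `dcmotif.divide` | possibilistic fuzzy c-means with Xie–Beni model-order selection, single-linkage and subtractive baselines, hypergeometric submotif hierarchy |
| `dcmotif.encode` | PWM estimation, information content, min–max-normalized log-odds scoring, window scanning |
| `dcmotif.classify` | voting multi-classifier, CC / standardized CC, empirical FDR |
| `dcmotif.optimize` | seeded generational GA over (presence, threshold) pairs: max-min arithmetical crossover, asymmetric presence mutation, accuracy/complexity Pareto front |
| `dcmotif.fuse` | triangular distance fuzzy sets, submotif×distance rule mining (hypergeometric), product/maximum inference, GA rule optimization |
| `dcmotif.evolve` | HKY85 background estimation, Halpern–Bruno position-specific rates, expected-distance profiles, MSD |
| `dcmotif.scan` | genome-wide region scanning, tiling-array peak calling with randomization FDR, five-way gene categorization, cross-species submotif presence matrix |
| `dcmotif.synth` | seeded generators for every input the pipeline needs (planted PWM families, Markov background, decoy negatives, genome fixture with signal + expression calls) |
| `dcmotif.cli` | `dcmotif` executable wiring the phases together |

## CLI

One executable with subcommands mirroring the workflow phases; every run
writes a `manifest.json` (inputs, config hash, seed, version):

```sh
dcmotif synth    --seed 11 --out run/ds
dcmotif divide   --sites run/ds/positives.tsv --out run/div --seed 1
dcmotif encode   --sites run/ds/positives.tsv --tree run/div/submotif_tree.json --out run/enc
dcmotif optimize --positives run/ds/positives.tsv --negatives run/ds/negatives.tsv \
                 --pwms run/enc/submotifs.meme --out run/opt --seed 2
dcmotif fuse     --positives run/ds/positives.tsv --negatives run/ds/negatives.tsv \
                 --pwms run/enc/submotifs.meme --out run/fuse --seed 3
dcmotif scan     --classifier run/opt/classifier.json --genome run/ds/genome.fa \
                 --annotation run/ds/annotation.gff3 --signal run/ds/tiling_signal.tsv \
                 --expression run/ds/expression_calls.tsv --out run/scan --seed 4
dcmotif evolve   --pwms run/enc/submotifs.meme --background background.tsv --out run/ev
dcmotif report   --classifier run/opt/classifier.json --positives run/ds/positives.tsv --out run/rep
```

Exit codes: 0 success, 1 runtime failure, 2 usage error.

## Notes on conventions

- Coordinates are 0-based half-open internally; GFF3 converted at the boundary.
- PWM scores are min–max normalized log-odds: the consensus scores exactly 1,
  the worst achievable sequence exactly 0.
- Possibilistic memberships are `1 / (1 + (d²/η)^(1/(m−1)))`; `η` may be a
  fixed scalar or estimated from a seeded k-means pre-pass (`"auto"` — mean
  within-cluster squared distance, used for model-order selection;
  `"auto-max"` — maximum, used for hard cluster extraction at the 0.5 cut).
- SCC rescales the negative-class counts to the positive-class magnitude
  before applying the correlation-coefficient formula.
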