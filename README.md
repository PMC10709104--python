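# repvar

Regression of single amino acid variant effects on frozen per-position
protein-sequence representations. A twin-branch head (two independent
1280→128 affine layers with learnable-slope rectifiers and dropout, an
entry-wise product merge, and per-dataset scalar output layers — 328,067
trainable parameters at the default configuration) is trained in two phases:
multi-task pretraining with shared branches and per-dataset heads, then
per-dataset fine-tuning with differential learning rates. The package also
implements the masked-marginal log-ratio baseline score and the evaluation
split protocols (repeated ten-fold CV, leave-one-position-out, few-shot
fraction splits, leave-one-dataset-out zero-shot), all scored by Spearman
rank correlation.

Everything runs offline: representation vectors come from a pluggable
provider contract with a deterministic synthetic backend (an adapter for a
real transformer backbone is loaded only on demand and requires the optional
`torch`/`fair-esm` packages), and the planted-signal generator in
`repvar.synthetic_data` produces datasets whose scores are emitted by a
hidden head of the same family, making recovery an identifiable oracle test.
The training loops (Adam, MSE, inverted dropout, head/group isolation) are
implemented directly on NumPy; runs are bit-reproducible given a seed.

## Layout

| module | contents |
|---|---|
| `repvar.dms_data` | mutation codes, variant tables, FASTA input, packaged 38-row dataset manifest |
| `repvar.embeddings` | provider contract, synthetic provider, windowing, binary embedding cache |
| `repvar.head_model` | the twin-branch regression head, forward/backward, checkpoints |
| `repvar.training` | score standardization, multi-task pretraining, two-group fine-tuning |
| `repvar.evaluation` | Spearman scoring, split plans, the four evaluation protocols |
| `repvar.esm_baseline` | masked log-ratio variant score over pluggable probability sources |
| `repvar.synthetic_data` | planted datasets, shared-mechanism multi-task suites, manifest fixture |
| `repvar.cli` | `repvar` command line entry point |

## Command line

All subcommands share `--seed`, `--config` (YAML defaults), `--out-dir` and
`--provider {synthetic,cache,external}`; every run directory receives a
`run_config.yaml` snapshot.

```bash
# generate a planted-signal fixture suite (FASTA + variant CSV + truth CSV)
repvar simulate --seed 3 --out-dir sim --n-datasets 2 --n-variants 300 --seq-length 40

# pretrain shared branches + per-dataset heads, then fine-tune one dataset
repvar pretrain --seed 3 --dim 64 --fasta sim/sequences.fasta \
    --dms sim/sim_0.csv --dms sim/sim_1.csv --out-dir pre
repvar finetune --seed 3 --dim 64 --fasta sim/sequences.fasta \
    --dms sim/sim_0.csv --checkpoint pre/pretrained.ckpt --out-dir ft

# run an evaluation protocol end to end (CSV + JSON report)
repvar evaluate --strategy fewshot --seed 3 --dim 64 --fasta sim/sequences.fasta \
    --target sim/sim_1.csv --pool sim/sim_0.csv --fraction 0.3 --out-dir eval

# masked log-ratio baseline from a probability dump (or the seeded synthetic source)
repvar esm-score --fasta sim/sequences.fasta --dms sim/sim_0.csv --out-dir base
```

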