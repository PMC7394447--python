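# uncrowd

Recurrent grouping/segmentation models of visual (un)crowding.

A capsule network with iterative routing-by-agreement is trained to
recognize verniers (two vertical bars with a small horizontal offset) and
groups of shapes — never both in the same image — and is then tested on
crowding/uncrowding stimuli (a vernier inside one flanker, inside a row of
five identical or alternating flankers, or outside the configuration).
Matched feedforward and recurrent fully connected comparison models, an
iteration-sweep analysis (error rate vs number of routing iterations for
line vs cuboid flankers), and the human-psychophysics machinery (PEST
adaptive staircase + cumulative-Gaussian threshold fits, validated on
simulated 2AFC observers) complete the pipeline.

Everything — including convolutions, routing, losses, Adam, and cosine
warm-restart scheduling — runs on a small reverse-mode autodiff engine over
NumPy (`uncrowd.autograd`); no deep-learning framework is required.

## Layout

| module | contents |
| --- | --- |
| `uncrowd.stimuli` | procedural stimulus generation (verniers, shape groups, line groups, cuboid pairs, scrambled cuboids), augmentation, training sets, test batteries |
| `uncrowd.capsule_core` | conv feature stack, primary capsules, squash, routing-by-agreement, `CapsuleNetwork` |
| `uncrowd.heads_losses` | decoder heads and the loss terms (margin, vernier/repetition/location cross entropies, reconstruction) and their weighted totals |
| `uncrowd.alt_architectures` | ffCNN, lateral-recurrent and top-down-recurrent comparison heads with neuron-count parity |
| `uncrowd.training` | Adam, cosine warm restarts, single/ensemble training, the experiment-2 ceiling/floor exclusion rule |
| `uncrowd.evaluation` | (un)crowding test protocol, uncrowding scores, iteration sweeps, per-capsule reconstructions, line fits and t-tests |
| `uncrowd.psychophysics` | stimulus geometry in arcmin, PEST staircase, maximum-likelihood psychometric fits, simulated observers, duration-series analysis |
| `uncrowd.cli` / `uncrowd.config` | YAML config, run manifests, command-line entry points |

## CLI

```bash
uncrowd stimuli --experiment 1 --n-frames 100 --out runs/stimuli
uncrowd train --experiment 1 --arch capsnet --n-networks 3 --steps 2000 --out runs/train
uncrowd evaluate --experiment 1 --arch capsnet --n-networks 2 --out runs/eval
uncrowd psychophysics-sim --n-subjects 5 --out runs/psy
uncrowd figures --results runs/eval/results.csv --out runs/figs
uncrowd run --experiment 1 --arch capsnet,ffcnn --n-networks 2 --out runs/full
```

All stages accept `--config config.yaml` (sections: `stimulus`, `network`,
`training`, `augmentation`) and `--seed`; every stochastic stage is seeded.

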