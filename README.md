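# molcycle

Cycle-consistent adversarial translation between two molecule domains in a
56-dimensional latent space. Two LSTM+attention generators (G: X→Y,
F: Y→X) and two discriminators are trained with least-squares adversarial,
cycle-consistency, and identity-mapping losses; domains are defined by
pharmacophore feature counts (aliphatic rings, aromatic rings, hydrogen-bond
acceptors/donors); a MOSES-style metric suite scores the translations.

## Layout

| module | contents |
| --- | --- |
| `molcycle.mol_features` | SMILES parsing, feature counting, charge filter, X/Y domain splits |
| `molcycle.embedding`    | pluggable 56-d encoder/decoder; fingerprint-projection surrogate; synthetic Gaussian latent domains |
| `molcycle.networks`     | reference generator/discriminator forward passes (LSTM stack, attention pooling, head-to-tail fusion) |
| `molcycle.training`     | LSGAN / cycle / identity losses, alternating Adam training loop |
| `molcycle._engine`      | vectorised float32 forward/backward used by the training loop (validated against `networks` and finite differences) |
| `molcycle.metrics`      | Valid/Filters/Novelty/Uniqueness/Non-identity/Success rate, Tanimoto, SNN, IntDiv, Frag, Scaff, Fréchet activation distance, MW/logP/SA profiles |
| `molcycle.pipeline` / `molcycle.cli` | stage orchestration, config, fixtures, toy corpus |

### Generator architecture (widths)

Input 56 → Dense 56 (+BatchNorm, ReLU) → LSTM 56 → LSTM 28 → LSTM 56 →
Attention (56 steps, key width 64, value width 1) → concatenate the Dense-56
"head" with the width-1 attention "tail" (57) → Dense 56. A width-56 vector
is unrolled as 56 scalar time steps through the LSTM stack. The
discriminator is Dense 56/28/56 → attention over 56 scalar steps → sigmoid →
Dense 1 (the sigmoid placement follows the printed layer table; it can be
disabled via `DiscriminatorParams.final_sigmoid`).

### Conventions worth knowing

- The combined generator objective is `adv_G + adv_F + 0.4·cycle +
  0.15·identity`. The printed form of the combined loss repeats an
  adversarial term where the cycle term belongs; the cycle-consistency
  reading is implemented.
- Frag/Scaff are reported as cosine **similarities** (matching the result
  tables, which mark them "higher is better"); `as_distance=True` gives the
  printed `1 − cos` form.
- The default Fréchet-distance activation provider is a physicochemical
  descriptor surrogate, *not* pretrained ChemNet — values are labelled
  `fcd_surrogate` and are not comparable to published FCD numbers.
- The latent encoder/decoder is pluggable. The bundled surrogate projects
  2048-bit circular fingerprints through a seeded linear map and decodes by
  nearest library neighbour; it exists so the full pipeline runs
  self-contained. A graph-autoencoder (JT-VAE) adapter can be dropped in by
  implementing `encode`/`decode` with `dimension == 56`.

## CLI

```bash
molcycle config run.yaml                 # write a default config
molcycle split --spec aliphatic_rings --seed 1 --out runs/demo \
         --input corpus.smi --train-sizes 40000 40000
molcycle train    --config run.yaml --out runs/demo
molcycle generate --config run.yaml --out runs/demo
molcycle evaluate --config run.yaml --out runs/demo
molcycle all      --seed 1 --out runs/demo   # toy corpus end-to-end
molcycle fixtures --kind gaussian --n 2000 --seed 1 --out runs/fix
```

Artifacts per stage: `.smi` partitions + `split_manifest.json`; latent
matrices as tab-separated text (56 columns); checkpoints as a JSON manifest
plus `params.npz`; `history.csv`; `report.csv`, `tanimoto_pairs.csv`,
`properties.csv`; every stage writes a seed-stamped `run.json`.

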