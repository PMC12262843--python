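# tmrkit

Consensus analysis of transmembrane helix-bundle structural models and
coarse-grained trajectories: multi-predictor model comparison (pairwise
Kabsch RMSD matrices, pLDDT/PAE confidence profiling), inter-helix
contact-interface classification, membrane-ejection quality control,
joint PCA/TICA conformational-landscape embedding, and K-medoids state
clustering with per-cluster contact fingerprints.

The package targets a four-helix transmembrane region organised as two
hairpins — HP1 (TM1+TM2) and HP2 (TM3+TM4) — and ships a synthetic
generator of membrane-embedded bundles with planted contact
architectures, stochastic state-switching dynamics and irreversible
membrane-ejection events, so the full pipeline is testable without any
external downloads.

## Layout

| module | role |
| --- | --- |
| `tmrkit.structure_io` | PDB model I/O, pLDDT (B-factor) channel, PAE JSON, subdomain maps |
| `tmrkit.superposition` | Kabsch superposition, region extraction, pairwise RMSD matrices |
| `tmrkit.contact_analysis` | distance/contact maps, interface classification, dimer intra/inter decomposition |
| `tmrkit.membrane_qc` | hairpin z-series, sticky ejection detection, replica exclusion |
| `tmrkit.landscape` | trajectory alignment, PCA, static-model projection, TICA, DCC, 2-D density |
| `tmrkit.clustering` | PAM-style K-medoids, elbow k-selection, cluster representatives |
| `tmrkit.synthetic_data` | ideal-helix bundle builder, stochastic trajectory generator with planted truth |
| `tmrkit.pipeline` / `tmrkit.cli` | end-to-end runs, YAML config, manifests, CLI |

## CLI

Every subcommand takes a YAML `--config` and an optional `--seed`:

```sh
# generate a synthetic two-hairpin bundle + trajectory with planted truth
tmrkit simulate --seed 1 --architecture TM2-TM3 --n-frames 500 --out sim_out

# model comparison: RMSD matrices, interface calls, majority consensus
tmrkit compare-models --config run.yaml

# membrane-ejection QC / full landscape run / combined report
tmrkit qc --config run.yaml
tmrkit landscape --config run.yaml
tmrkit report --config run.yaml
```

A minimal `run.yaml`:

```yaml
models:
  - {path: models/AF.pdb, predictor: AF, model_id: AF}
  - {path: models/ESM.pdb, predictor: ESM, model_id: ESM}
trajectories:
  - {path: trajs/replica_0.pdb, replica_id: r0}
cutoff: 12.0          # contact cutoff, Angstrom
qc_margin: 5.0        # slab margin for ejection detection
qc_persistence: 50    # frames outside the slab before a hairpin counts as ejected
tica_lag: 100
k_range: [2, 10]
output_dir: out
```

All outputs (TSV matrices, JSON reports, medoid PDBs) are listed in
`out/manifest.json` with content hashes; identically-seeded runs
reproduce the manifest bit-for-bit.

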