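# helixstate

Two-state conformational-switch analysis of MD trajectories, built around the
inactive→active repositioning of a C-terminal helix (H12) against a
ligand-binding-domain core:

- **Geometric state criteria** — a Cβ–Cβ anchor-pair distance (reference
  cutoff 4.6 Å, from the agonist-bound crystal structure) and a core-fitted
  RMSD of the mobile helix residues 466–473 (cutoff 1.9 Å). A frame is
  *active* iff its metric is strictly below the cutoff.
- **Cutoff derivation** — least-squares skew-normal fit to a pooled RMSD
  histogram; the fitted distribution mean (ξ + ωδ√(2/π)) becomes the cutoff.
- **Replica statistics** — per-replica occupancy (% of frames active),
  reached-active flags, dwell (persistence) times.
- **Significance tests** — two-sided Mann-Whitney U on per-replica
  occupancies (exact for small tie-free groups, tie-corrected normal
  approximation otherwise) and a one-sided pooled-variance Student's *t* on
  0/1 reached-state indicators.
- **Synthetic generator** — a telegraph-process (two-state Markov) simulator
  that moves an 8-residue helix segment between anchor poses in a rigid toy
  scaffold with Gaussian positional noise, retaining the ground-truth state
  sequence for recovery tests. Stands in for μs-scale MD cohorts
  (15 replicas × 1000 frames per system by default).

Structure I/O supports single/multi-model PDB (via biotite), plain XYZ frame
streams, and optionally DCD (via MDAnalysis). Coordinates are Å throughout;
residue numbers are author numbering and are never remapped.

## CLI

```sh
# generate a synthetic 4-system cohort (active/inactive × WT/variant layout)
helixstate simulate --preset paper-like --seed 7 --out cohort/

# run the full analysis described by the generated config
helixstate analyze --config cohort/config.yaml

# print the reached-state table and test results
helixstate report --analysis-dir cohort/analysis

# fit the skew-normal RMSD cutoff for one system
helixstate fit-cutoff --config cohort/config.yaml --system active_WT

# replica-level tests between two exported summaries
helixstate compare cohort/analysis/summary.json cohort/analysis/summary.json \
    --label-a inactive_WT --label-b inactive_T296I --criterion distance
```

The analysis config is YAML; the generated `config.yaml` is a complete,
commented-by-structure example (reference/topology PDBs, per-system
trajectory lists, criterion definitions with cutoffs or `fit_from`,
comparison pairs). Outputs are deterministic TSV/JSON: pooled histograms,
replica and system summaries, pairwise tests with significance stars
(∗ p ≤ 0.05 … ∗∗∗∗ p ≤ 0.0001), and a compact reached-state table.

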