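# helixgauge

A library and command-line tool for measuring the *global* helical geometry
of superhelical proteins and their compatibility with B-form DNA:

- **Helical gauge** (`helixgauge.geometry`): given an ordered path of anchor
  points (e.g. one Cα per repeat motif), find the plane containing the best
  least-squares circle (SVD-backed Kåsa fit) over a `(φ, θ)` orientation
  grid with simplex refinement, and read off radius, signed helical sweep Φ,
  axial rise Δz and pitch κ = |Δz|·360/|Φ| (axial rise per full turn).
- **Structure I/O** (`helixgauge.structure_io`): PDB reading (Biopython
  parser) and plain-text writing, multi-model ensembles, anchor-spec
  resolution, Kabsch superposition and split fit/measure RMSD series.
- **Elastic network** (`helixgauge.enm`): Cα anisotropic network model with
  a distance cutoff (default 24 Å) and distance-weighted springs
  γ = r^−2.5, mode extraction, square fluctuations, B-factor correlation,
  cutoff sweeps and ±scaled mode projections.
- **Ensemble analysis** (`helixgauge.ensemble_analysis`): coordinate PCA
  (iterative mean alignment) and RMSIP subspace overlap.
- **B-DNA model** (`helixgauge.dna`): a minimal-atom fiber generator
  (P, C1', glycosidic N; twist 36°, rise 3.38 Å, P radius 8.91 Å),
  cross-strand phosphate-midpoint groove sites (default offset frozen by a
  geometric discrimination rule) and groove-width series.
- **Complex metrics & pose filter** (`helixgauge.complexes`): mean
  anchor-to-groove-site distance, KD-tree steric clash counts, Shrake–Rupley
  contact surface area, translocation distance, sliding-rate conversion,
  windowed averaging, and an ordered accept/reject pose funnel
  (pitch < 42 Å, radius 9–16 Å, groove distance ≤ 11 Å, zero clashes by
  default).
- **Synthetic fixtures** (`helixgauge.fixtures`): seeded generators for
  ideal/noisy helices, planted-mode ensembles and toy sliding trajectories,
  so the whole pipeline is testable offline.

The shipped MTERF1 anchor list (`helixgauge/data/mterf1_anchors.yaml`) marks
the seven S-loop proline residue numbers as *example defaults*; only the two
exceptions (A279, W383) are documented ground truth, and the list should be
verified once against the deposited entry before use on real coordinates.
The reference workflow (ANM of the deposited Cα coordinates vs PCA of an MD
ensemble) reports an RMSIP of 0.77 at n = 10; the trajectories behind that
number are not distributed, so the repository exercises the workflow
end-to-end on synthetic ensembles only.

## Command line

All operations are subcommands of a single `helixgauge` entry point; every
tabular output carries `# key=value` provenance headers and identical
invocations produce byte-identical files.

```sh
helixgauge helix-fit --pdb structure.pdb --anchors anchors.yaml --out fit.tsv
helixgauge anm --pdb structure.pdb --chain A --cutoff 24 --power 2.5 \
               --nmodes 10 --scale 50 --out-prefix anm
helixgauge pca --ensemble traj.pdb --select "name CA" --n 10 --out pca.tsv
helixgauge rmsip --a anm_modes.tsv --b pca.tsv --n 10
helixgauge bdna-generate --seq ACGTACGTACGTACGTACGTAC --out dna.pdb \
               --sites-out sites.tsv
helixgauge groove-distance --complex complex.pdb --anchors anchors.yaml \
               --dna-chains B,C
helixgauge filter-poses --poses poses/ --anchors anchors.yaml \
               --dna-chains A,B --report report.tsv
helixgauge slide --ensemble traj.pdb --anchors anchors.yaml \
               --dna-chains A,B --window 50 --rise 3.0 --out slide.tsv
helixgauge fixtures make-sliding --seed 1 --out fixtures/
```

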