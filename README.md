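# kirpharm

Analysis toolkit for structure-based discovery of Kir6 (K_ATP pore subunit)
channel inhibitors. It covers the computational stages of a repurposing
pipeline that starts from MD simulations of a thiazolidinedione ligand
(rosiglitazone-like) bound near the PIP2 site of Kir6.1 and ends at
patch-clamp dose-response analysis of candidate blockers:

- **Trajectory analysis** — multi-model PDB trajectories with a YAML
  selection config; ligand RMSD after rigid superposition, Shrake-Rupley
  buried interface areas, binding-site occupancy and residence intervals.
- **Interaction maps** — per-frame pharmacophore-style interaction
  detection (hydrophobic, aromatic, H-bond donor/acceptor, positive
  ionizable) against a protein + PIP2 receptor scope, aggregated into a
  ligand-fragment x residue percentage-of-frames matrix.
- **Dynamic pharmacophore models** — per-frame models built from the
  interactions, merged into representative models by identical feature
  kinds and ligand atoms, and used for common-hits-approach (CHA) virtual
  screening of conformer libraries.
- **Umbrella-sampling PMFs** — WHAM with overlap diagnostics and
  bootstrap error bands.
- **Dose-response analysis** — fractional block, Hill-equation IC50
  fits, and drug-induced rectification tests.
- **Synthetic data** — seeded generators for every input (feature
  ensembles, biased Boltzmann windows, Hill tables, active/decoy
  libraries) with known ground truth.

Intended users: computational pharmacologists and method developers who
need a tested, scriptable reimplementation of this pipeline's analysis
stages — the MD engine, docking, and wet-lab acquisition are out of scope.

## The core quantities

**Interaction map.** For fragment f (the ligand is decomposed into
RingA/RingB/RingC and two linkers), residue r and interaction kind k,

    cell(r, k, f) = 100 x |{frames with >= 1 such interaction}| / n_frames.

**Representative pharmacophore models.** Each frame's model is the set of
ligand features participating in at least one interaction. Frames whose
models share feature kinds *and* involved ligand atoms merge into one
representative with a frame count; feature centers are averaged.

**CHA screening score.** A conformer matches a model when an injective,
kind-consistent assignment followed by least-squares rigid superposition
puts every feature pair within the tolerance radius r_tol. Per model
s_m = 1 − d̄/r_tol (d̄ = mean pair distance); a molecule matching
n_active ≥ 2 models is a hit with CHA score S = Σ s_m, so S sits just
below n_active — the structure seen in published CHA hit lists.

**WHAM.** With biases w_i(ξ) = k_i/2 (ξ−ξ_i)² the unbiased distribution
solves P(ξ_b) = Σ_i n_i(b) / Σ_j N_j exp(−β[w_j(ξ_b) − F_j]) with
exp(−βF_j) = Σ_b P(ξ_b) exp(−βw_j(ξ_b)); W = −k_B T ln P anchored at the
bulk plateau. Errors come from 100x bootstrap resampling.

**Hill fit.** B([D]) = ([D]/IC50)^h / (1 + ([D]/IC50)^h), fit by
least squares to fractional block with B(0)=0 and B(∞)=1 fixed.

## Worked example

```sh
# synthetic dose-response table at the rosiglitazone wild-type outward
# parameters (IC50 25.98 uM, h 1.0; 4 doses, 8 patches, noise SD 0.03)
$ kirpharm simulate dose --seed 42 --out dose.csv
$ kirpharm hill dose.csv
synthetic outward: IC50 = 25.5 +/- 0.45 uM, h = 1.02 +/- 0.021 (rss 0.000109, converged True)
```

The fitted IC50 (25.5 uM) recovers the planted 25.98 uM within its
standard error; h stays near 1 as planted.

```sh
# merge per-frame pharmacophore models of a 2,000-frame synthetic ensemble
$ kirpharm models --seed 42 --frames 2000 --out models.json
5 representative models from 2000 frames; dominant frequency 95.25% (1905 frames)

# screen a planted active/decoy library against them
$ kirpharm simulate library --seed 3 --out lib.csv
$ kirpharm screen models.json lib.csv --out hits.csv
10 hits -> hits.csv
```

The ensemble merges into exactly five representative models with the
dominant one covering >95% of frames; all ten planted actives are
retrieved (each hit's CHA score is bounded by its active-model count)
and the fifty geometry-scrambled decoys are rejected.

Other stages work the same way: `kirpharm wham us/windows.csv --nboot 100
--seed 2 --out pmf.csv` for free-energy profiles, `kirpharm imap`,
`kirpharm rmsd`, `kirpharm occupancy`, `kirpharm area` for trajectory
analysis. Every command is a thin wrapper over the library API
(`kirpharm.fit_hill`, `kirpharm.WHAM`, `kirpharm.CommonHitsScreen`, ...).

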