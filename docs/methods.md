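# Methods

This note documents the models and procedures implemented in `kirpharm`,
the defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Trajectory substrate

A trajectory is a fixed topology (atom id, name, element, residue, chain,
ligand/PIP2 flags) plus an (n_frames, n_atoms, 3) coordinate array in
Angstrom and a strictly increasing clock in ns. The exchange format is
multi-model PDB; because PDB carries no time axis or chemistry, a YAML
selection config supplies the frame spacing, ligand atom ids, ligand
fragment sets, PIP2 residues and the ligand atom typing. Residue numbering
follows the Kir6.1 convention of the source structures (e.g. PHE76,
VAL172 on chains A/D); fixtures declare numbering explicitly and nothing
renumbers.

RMSD uses least-squares rigid superposition (Kabsch, proper rotations
only) of a fit selection before measuring an analyze selection, so
ligand-on-protein-fit and ligand-on-ligand-fit conventions are both
expressible; which atoms define the fit is a caller decision. RMSD is
reported in Angstrom, reaction coordinates in nm — the two-unit split is
deliberate and matches field convention.

Surface areas use Shrake-Rupley with 960 deterministic golden-spiral
points per atom, probe 1.4 A, and a bundled Bondi-style vdW radius table.
Buried interface area is ½(SASA_ligand + SASA_receptor − SASA_complex) in
nm². A test point lying exactly on a neighbour's solvent-expanded sphere
counts as buried only when the neighbour has a lower atom index; this
tie-break makes exactly coincident identical spheres expose one surface
(not zero or two), so the overlap limit of the buried-area formula is
½·SASA(single sphere), and keeps the method fully deterministic.

## Interaction perception

Feature perception is declarative: bonds, aromatic atoms/rings,
donors, acceptors and protonatable nitrogens come from the ligand config,
never from on-the-fly protonation or charge prediction — determinism and
testability over convenience. Hydrophobic features sit at centroids of
connected apolar-carbon clusters (explicitly declarable), aromatic
features at ring centroids with SVD plane normals, donor/acceptor
features on heavy atoms, positive-ionizable features on declared
nitrogens.

Interaction rules are conventional geometric cutoffs, all configurable,
and are documented as reimplementation conventions rather than values
taken from any specific screening engine (which do not publish theirs):

| rule | default |
| --- | --- |
| hydrophobic C···C | ≤ 4.5 A |
| aromatic centroid distance / normal tilt | ≤ 5.0 A / ≤ 30° |
| H-bond heavy-atom distance | ≤ 3.5 A |
| D–H···A angle (skipped without H direction) | ≥ 130° |
| charged N to anionic O | ≤ 5.6 A |
| feature tolerance radius r_tol | 1.5 A (per-kind override) |

The receptor scope is protein plus PIP2; bulk lipid (POPC) and water are
excluded before detection and can never appear as partners. PIP2
inclusion is a parameter because ligand-lipid hydrogen bonds exist in the
source trajectories but are conventionally excluded from interaction
maps; the default includes PIP2 and excludes bulk lipid.

## Interaction maps and occupancy

A map cell is the percentage of frames containing at least one
interaction of a given (residue, kind, fragment); within-frame
multiplicity never counts. Cells times n_frames/100 are therefore
integers, which the recount oracle tests exploit. Merging maps from two
trajectories is the frame-count-weighted mean.

Residence intervals use the fence-post convention: n contiguous bound
frames at spacing dt span (n−1)·dt, so a run over frames 300–1500 at
1 ns spacing reads as 300 ns – 1.5 μs (1.2 μs). A frame is bound when the
minimum heavy-atom distance between ligand and site residues is within
the cutoff; centre-of-mass and other criteria were considered and the
minimum-distance rule chosen as the least parameter-sensitive. The
default site cutoff is 4.0 A and configs must be explicit, because
display shells (3.5–6 A) and site definitions are different things.

## Dynamic pharmacophore models and CHA screening

A per-frame model keeps the ligand features participating in at least one
interaction that frame (all-features mode is available as an option);
frames with no interactions yield an empty sentinel excluded from the
frequency denominator, which is reported alongside. Models sharing the
sorted multiset of (feature kind, involved ligand atom ids) merge into
one representative whose centers are member means; representatives order
by count, then key.

Matching enumerates every injective kind-consistent assignment of model
features to conformer features (models carry 2–4 features; enumeration is
capped at 6), superposes the model's feature centers by least squares,
and requires every pair distance within r_tol. The score of a matched
model is s = 1 − d̄/r_tol and the CHA score of a molecule is the sum of
its matched models' best per-conformer scores; the hit filter keeps
molecules matching at least two models. This scoring is this package's
convention: it reproduces the *structure* of published CHA rankings
(three-model hits score just under 3, two-model hits just under 2) and is
not bit-compatible with any proprietary engine. Ties between equal-score
assignments break on the lexicographically smallest pairing. Racemic
inputs are handled by listing both enantiomers' conformers under one
molecule id; the conformer cap is 200 per molecule, matching the usual
conformer-library generation limit.

## Umbrella sampling and WHAM

Defaults: T = 310 K, k_B = 0.0083145 kJ mol⁻¹ K⁻¹ (k_BT ≈ 2.577 kJ/mol),
bin width 0.02 nm, convergence tolerance 1e-6 kJ/mol on the window free
energies, max 1e5 iterations, and a 10% equilibration trim in the window
file loader (the convention of discarding the first 1 ns of a 10 ns
window). The self-consistent iteration works in log space (logsumexp);
empty bins are excluded from the profile. The profile anchors W = 0 at
the largest-ξ populated bin — the ligand-in-bulk-solvent plateau — with
`min` and `none` anchors available, since the reaction-coordinate
direction and anchor of any given study are not generally published and
absolute well depths should not be compared across anchors.

Adjacent windows with zero histogram overlap abort with an error naming
the gap; the overlap diagnostic Σ_b min(p_i, p_j) warns below 0.05,
the criterion used to decide whether intermediate windows are needed.

Bootstrap errors (default 100 replicates, seed mandatory) resample each
window's samples with replacement — a simple bootstrap, appropriate for
the uncorrelated synthetic samples; a block variant for correlated MD
series is deliberately left out of scope. Because a PMF is defined only
up to an additive constant, each replicate profile is aligned to the
point estimate by its mean offset before per-bin standard deviations are
taken; without this the bands mostly measure the sampling noise of the
anchor bin (the worst-sampled bin in the bulk tail) rather than the
profile shape, and the expected 1/√N shrinkage is invisible.

## Dose-response analysis

Fractional block is 1 − I_drug/I_control at −80 mV (inward) and +50 mV
(outward); no rundown correction is applied, matching the acquisition
convention the data assume. The Hill fit fixes B(0) = 0 and B(∞) = 1 —
the asymptotes are not free because currents are normalised to control.
Initialisation: IC50₀ = geometric mean of the doses, h₀ = 1; bounds
IC50 ∈ (0, 10⁴] μM, h ∈ (0, 5]. The default fits per-dose means weighted
by their SEM, falling back to unweighted when SEMs are degenerate
(noiseless fixtures, n = 1); unweighted and all-replicates modes exist
because published fits rarely state which was used. Standard errors come
from the fit covariance; the convergence flag is honest (a failed
optimiser run is reported, not masked).

Rectification is mean(outward block)/mean(inward block) with a paired
two-tailed t-test; identical pairs degenerate to t = 0, p = 1,
non-rectifying, and a zero inward mean guards the index at infinity.

## Synthetic generators: what they emulate, and what they do not

The generators exist to give every stage inputs with known ground truth;
they are statistical emulations, not simulations.

- **Feature ensemble** (`gen_feature_trajectory`): per frame a regime is
  drawn from a categorical distribution; default five regimes with
  probabilities (0.9552, 0.0120, 0.0120, 0.0120, 0.0088), chosen so the
  expected dominant-model count over 5,000 frames is 4,776. All regimes
  share the two ring hydrophobic features; the dominant regime adds the
  thiazolidinedione N–H donor, the others drop it or swap in carbonyl
  acceptors — five distinct identity keys. Feature centers get isotropic
  Gaussian jitter (σ = 0.3 A, comfortably inside the 1.5 A matching
  tolerance). The trajectory clock spans 100 ns. The stub receptor is a
  static shell of the slide-helix/TM2 pocket residues plus one PIP2 head
  group and one bulk lipid (present only to exercise scope exclusion).
  Not emulated: conformational correlation between frames, receptor
  motion, frame-to-frame regime autocorrelation — so passing tests show
  correct counting and merging, not kinetic realism.
- **Umbrella windows** (`gen_us_windows`): exact inverse-CDF sampling of
  the biased Boltzmann density on a 10⁴-point grid; samples are i.i.d.,
  hence the simple bootstrap is exactly appropriate. Real pull-code
  output is autocorrelated; error bars on real data need block methods.
- **Dose-response** (`gen_dose_response`): Hill mean plus i.i.d. Gaussian
  noise (σ = 0.03 fractional-block units), truncated to [−0.05, 1.05].
  Patch-to-patch variance components and rundown are not modelled.
- **Screening library** (`gen_screen_library`): actives place conformer
  features within r_tol/2 of their chosen representatives (norm-clipped
  Gaussian jitter); decoys copy a model's feature-kind multiset and
  displace each feature by 2.5–6 tolerance radii in a random direction,
  destroying internal geometry while keeping kind composition. Real
  decoys share physicochemistry, not just kinds.

All generators require an explicit seed and are bit-reproducible under
(spec, seed).

## Problem sizes

The test suite and the acceptance script run entirely on generated data
at desk scale: 5,000-frame ensembles, 5–17 umbrella windows of 1,000–5,000
samples with 100 bootstrap replicates, 200-replicate dose-response
recovery sweeps, and 500-instance matching oracles — sizes chosen so the
statistical assertions (binomial bounds, 1/√N scaling, 10–15% recovery
tolerances) are well-powered while the whole suite stays fast on one CPU.

## Known limitations

- No MD engine, docking, homology modelling or conformer generation from
  SMILES; libraries arrive as 3-D SDF or precomputed feature tables.
- No water-mediated interactions, no exclusion volumes, no on-the-fly
  protonation; typing is declared, not predicted.
- WHAM is strictly 1-D; no MBAR, no 2-D surfaces.
- The CHA score is a documented convention, not a reproduction of any
  proprietary engine's numbers; only structural consistency (S ≤
  n_active, ranking monotonicity) is claimed.
- Absolute PMF well depths depend on the anchor and reaction-coordinate
  definition and should not be compared across studies.
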