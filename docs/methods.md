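# Methods

## The screening model

`gluefinder` operationalizes a template-transfer hypothesis for molecular
glue discovery: if a ligand is observed bound in a pocket adjacent to a
protein–protein interface (an *interface-adjacent pocket*, IAP) anywhere in
the structural record, then a structurally similar interface-adjacent
pocket on another dimer is a candidate site for the same chemotype, and a
rigid transfer of the template pose gives a first model of the bound glue.
The pipeline is four stages, each with an explicit, residue-level rule:

1. **Interface mining.** Two residues on opposite chains *interact* when
   their minimum heavy-atom distance is ≤ 4.5 Å (the standard heavy-atom
   contact criterion; the underlying sources never quantify "interacting",
   so the cutoff is a configurable default). A two-chain structure is a
   genuine dimer when each chain contributes ≥ 5 interacting residues. A
   bound ligand is an IAP ligand when it contacts ≥ 5 distinct residues on
   *each* chain; exactly one chain ⇒ `single_chain`, neither ⇒
   `non_binder`. Waters are never classified; single-atom metal HETATMs
   are classified like other ligands but tallied separately.

2. **Pocket detection.** A LIGSITE-style grid scan stands in for the
   original cavity detector, whose algorithm is not public: atoms are
   rasterized with per-element van der Waals radii onto a cubic grid
   (default spacing 1.0 Å, snapped origin so rigidly translated copies
   rasterize compatibly), and an empty cell is a cavity cell when protein
   occurs on both sides along ≥ 5 of 7 scan directions (3 axes + 4 body
   diagonals). Pockets are maximal 6-connected cavity components; volume
   is `cells × spacing³`; lining residues are those with a heavy atom
   within `probe_radius + spacing` (default 1.4 + 1.0 Å) of a cavity cell.
   Library pockets need ≥ 10 lining residues and ≥ 100 Å³. A pocket is
   *interface-adjacent* when its lining contains interface residues of
   both chains — a deliberately residue-level reading of "adjacent".

3. **Pocket alignment and significance.** Pockets are compared on the Cα
   atoms of their lining residues with an iterative seed–superpose–extend
   aligner: seeds are pairs of consecutive residue triples with matching
   internal distances (plus the index-aligned seed, which makes
   self-alignment exact); refinement alternates mutual-nearest-neighbour
   correspondence under a 2·d0 gate with Kabsch re-superposition until the
   correspondence is a fixed point; the best result under
   (score, length, −RMSD) wins, with an early exit at score ≥ 0.9. The
   similarity score is TM-score-like,
   `s = (1/L_min) Σ 1/(1+(dᵢ/d0)²)` with `d0 = 0.55·L_min^⅓ + 1.0` Å, so
   it is length-normalized and bounded by 1. The computation runs in a
   canonical role order and is inverted on output, making the score
   exactly symmetric under query/template swap.

   Significance comes from an empirical null: scores of randomly paired
   unrelated pockets, fitted per aligned-length bin (5–15, 16–30, >30).
   The fitted family is a **normal** location/scale per bin, not an
   extreme-value (Gumbel) law: the score is a bounded average of
   per-residue similarity terms, and the "best over seeds" maximum is over
   strongly correlated candidates, so the observed null is near-Gaussian
   with a mild left skew. Empirically the per-bin normal fit leaves the
   Kolmogorov–Smirnov statistic of fresh null p-values at ~0.03–0.09
   (n = 1000), while a Gumbel fit exceeds 0.1. Underflowing tail
   probabilities clamp to 1e-16 so p-values stay in (0, 1].

4. **Transfer, filtering, precision.** For each interface-adjacent target
   pocket, every library template is aligned; matches must pass the pocket
   p-value cutoff (default 0.05) and, when configured, a template sequence
   identity cutoff applied to the *maximum* identity between any template
   chain and **either** target chain (global Needleman–Wunsch, BLOSUM62,
   gap open 11 / extend 1, identities divided by alignment length
   including gaps). The template ligand is carried through the alignment
   transform; poses with more than 5 atom pairs closer than 1.5 Å to
   protein heavy atoms are sterically disqualified. Predictions are
   grouped per chemical component code into pose ensembles and ranked by
   precision, then p-value, then identity, then code — fully
   deterministic.

## Binding precision

The original pipeline scores candidates with a trained affinity model that
is not available; this package replaces it with a transparent calibration
table, documented as such. `CalibrationTable` maps (score, p-value) decile
bins to the empirical fraction of correct transfers in a labeled synthetic
set. Fitting pools the two features into a combined rank (score decile up,
p-value decile down) and applies 1D isotonic regression over that rank, so
the table is monotone non-decreasing in score and non-increasing in
p-value *by construction* while remaining an empirical-fraction estimate.
Labels are outcome-based: a candidate match is positive when transferring
a probe point through the alignment lands within 2 Å of the planted ground
truth. The default table shipped in `src/gluefinder/data/calibration.json`
is fitted on 400 perturbed-homolog and 400 unrelated pocket pairs
(`gluefinder.fixtures.make_calibration_set`, seed 42) and can be rebuilt
with `python scripts/build_calibration.py`; users can load their own table
from JSON. A clash count above the hard limit zeroes the estimate.

The calibration population covers the remote-homology regime the screen
operates in (coordinate noise 0.3–0.9 Å scaled with the pocket's d0,
mutations 10–80%, deletions ≤ 15%). Outside that regime — e.g. homologs
perturbed far beyond the score's distance scale — score ceases to order
transfer quality (a heavily eroded homolog can score below unrelated pairs
yet still transfer correctly), and no (score, p) table can be calibrated
there; such matches are excluded from the screen by the p-value filter
anyway.

## What the synthetic generators emulate

All tests and the acceptance script run on generated structures with
planted ground truth (`gluefinder.fixtures`); every generator is a pure
function of its arguments and a mandatory seed.

- **Open dimers** (`make_dimer_fixture`): two idealized Cα traces at 3.8 Å
  spacing with an exact number of inter-chain contacts at 4.0 Å and
  ligands whose atoms each contact exactly one residue, so per-chain
  contacted-residue counts are exact by construction.
- **Analytic cavities** (`make_cavity_fixture`): a closed atom shell whose
  wall planes sit exactly one carbon vdW radius outside the nominal void,
  so the sphere-free interior is the requested box and the detected volume
  is analytically exact at any grid spacing that divides the box.
- **Glue complexes** (`make_glue_complex`): an irregular ellipsoidal cage
  (seeded axes 0.85–1.5 × 4.5 Å plus a low-order lumpy radial profile)
  lined with sparse Cα pseudo-residues at protein-like spacing, enclosed
  by a dense blocker shell collapsed into one many-atom residue per chain,
  split into two chains at the z = 0 seam, with a native ligand anchored to
  ≥ 6 lining residues of each chain. The sparse, individually shaped
  lining is essential: dense regular walls make every fixture pocket
  near-identical at the score's d0 scale, and a planted homolog would be
  statistically indistinguishable from an unrelated fixture. Each chain
  carries 80 sequence-padding residues in a lattice blob far from the
  cavity, because identity filters behave very differently on 25-mers than
  on realistic chain lengths.
- **Homologs** (`make_homolog` / `perturb_pocket`): deterministic counts of
  mutations and deletions (`round(rate·n)`, positions seeded), Gaussian
  coordinate noise on polymer atoms, and a known rigid transform carried
  in the returned truth. At the benchmark's default mutation rate 0.8 the
  *aligned* sequence identity measures ≈ 0.22–0.27: global alignment with
  gaps recovers slightly more matches than the planted gapless fraction,
  which is why the rate is set above 0.75.
- **Fingerprint blobs** (`make_fingerprint_blobs`): disjoint core bits per
  blob plus per-member private bits, giving exact within-blob Tanimoto
  `core/(core+2u) ≥ w` and zero across blobs.

What these fixtures do *not* emulate: side-chain packing, conformational
heterogeneity, crystallographic artifacts, sequence–structure correlation
(mutations here never move atoms), and the redundancy structure of the
real structural record. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated geometry, not
database-scale performance on experimental structures; quantities that
depend on a specific archive snapshot (total IAP ligand counts, cluster
counts, dimer-set recall figures) are out of scope by design.

## Problem sizes and numerical choices

The benchmark in the acceptance script uses 50 generated targets, one
remote homolog each plus 5 decoys, a 400-pair null fit, and a 1000-pair
uniformity check — sizes chosen so the whole script completes in a few
minutes on one core while keeping the binomial noise on recall (n = 50)
and the KS statistic (n = 1000) well inside their acceptance margins.
Other defaults: grid spacing 1.0 Å (0.5 Å used in the convergence test),
probe 1.4 Å, enclosure 5 of 7 directions, aligner seed cap 24 with early
exit at 0.9, ≤ 50 refinement iterations with a 3-iteration stall cutoff,
null fit with ≥ 30 samples per bin (smaller bins inherit the pooled fit).
Alternate conformers resolve to the highest occupancy (ties by altloc id);
assembly handling defaults to biological assembly 1 when the file defines
one. Fingerprints hash linear paths of 0–7 bonds (single atoms count as
0-bond paths, so any non-empty molecule sets ≥ 1 bit) into 2048 bits via
SHA-1, scheme-versioned as `linear-path-sha1-v1`.

## Known limitations

- The pocket aligner is a documented stand-in, deterministic and tested
  against planted ground truth, but not bit-compatible with APoc; the
  cavity detector likewise does not reproduce Cavitator numerically.
- Pose transfer is rigid; no ligand flexibility, protonation, or
  binding-energy estimation.
- The precision estimator is only as good as its calibration set; the
  shipped default is synthetic and should be refitted on experimental
  labels for production use.
- Sequence identity uses full chains (not pocket regions) per the
  "either monomer of the target dimer" reading; pocket-region identity
  would be stricter for multi-domain chains.
- The center-of-mass deviation is the Euclidean distance between heavy-atom
  centroids of predicted and reference poses; all-atom RMSD after
  superposition is a stricter alternative not adopted here.
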