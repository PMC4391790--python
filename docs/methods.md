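# Methods

## Scope and model

`kolfold` quantifies, per alignment column, how much residue-type
diversity evolution has left at a position, and relates those scores to
per-residue structural descriptors of the protein the alignment
describes. It deliberately does not build alignments, assign secondary
structure from coordinates, compute solvent accessibility, or
reconstruct 3D coordinates from contact maps; alignments,
secondary-structure strings and accessibility/B-value tracks are
inputs.

### Alignment orientation

Some alignment servers print the transposed alignment in fixed-width
(typically 70-column) blocks, so that one printed row holds every
ortholog's residue at a single sequence position. `kolfold` follows
the universal MSA convention — rows are sequences, columns are
positions — and the `wrapped-blocks` reader reassembles block output
into that orientation by concatenating each identifier's subsequences
in block order. This mapping is stated once here; everywhere else
"column" means alignment position.

### The three column scores

Let a column have residue-type relative frequencies p₁…p_t, computed
excluding gaps and `X` (both overridable; an unknown residue carries
no type information, and a gap is an artifact of the alignment rather
than an observed residue).

* **VAR** (default definition): #{i : pᵢ ≥ f}, f = 0.01. Published
  variability conventions differ and at least one produces values
  below 1, which a type count cannot; the definition is therefore a
  pluggable callable and every downstream filter bound is
  configuration, not a constant.
* **ENT** = 100·(−Σ pᵢ ln pᵢ)/ln 20, clipped to [0, 100]. The ln 20
  normalization makes 100 the uniform-over-20-amino-acids maximum; the
  0–100 scale (rather than [0, 1]) is what makes the published ENT
  filter band of 50–60 meaningful.
* **KOL**: the column's residue string — uppercase, ortholog order,
  gaps verbatim, one ASCII byte per symbol, no separators or trailing
  newline — is compressed with bzip2 at level 9, and the
  compressed/raw byte ratio is reported (`mode="raw-bytes"` gives the
  raw compressed size). The serialization is fixed so scores are
  bit-reproducible. bzip2's ~40-byte container overhead means ratios
  exceed 1 for short or incompressible inputs and the asymptotic scale
  depends on n_seqs (at 1000 sequences a uniform column sits near
  0.6, a conserved one near 0.045); no clipping is applied and the
  box-filter bounds are per-dataset configuration.

All-gap columns are flagged `all-gap` with VAR/ENT undefined — never
silently dropped, so tracks stay aligned to the MSA — while KOL is
still computed from the gap bytes.

### Structural descriptors

* **HST**: S=1, H=2, G(3₁₀)=3, T=4, C=5. DSSP input maps E→S, H→H,
  G→G, T→T and everything else (B, I, S, blank) → C.
* **HST(D)**: first and last residues of every maximal S run → 0, H
  run → 0.5 (a length-1 run gets the terminus value once). Only S and
  H runs are differentiated by default — they are the SSEs whose
  termini carry the conservation signal — with `terminus_values`
  extending the rule to G/T if wanted.
* **AREA**: ½·‖(CA_{i+2} − CA_i) × (CG − CA_i)‖ for i = 1…L−2,
  reported at position i (so the track runs slightly "right" of the
  residue axis; correlation analyses can compensate with the `lag`
  parameter). CG is the unweighted CA centroid — the only
  well-defined choice on CA-only input; a mass-weighted all-atom CG
  would need the full structure.
* **Contact map**: (i, j) is a contact iff ‖CA_i − CA_j‖ ≤ cutoff
  (default 8.0 Å, inclusive) and j − i ≥ min_separation (default 1).
  The defaults make the pair universe all i<j pairs of size L(L−1)/2,
  which is exactly the universe the shipped published confusion rows
  sum to; both parameters are configurable, and an evaluation `mask`
  can exclude positions without defined scores.
* **Superposition**: orthogonal-Procrustes/Kabsch via scipy's
  `Rotation.align_vectors` on centroided coordinates; returns (R, t,
  RMSD). `fit_positions` restricts the fit to a subset (e.g. a static
  domain) while the transform applies to all residues.
* **DISP**: ‖CA_i^A − T(CA_i^I)‖ with T the superposition transform
  (on by default). For hinge-motion analysis the fit should be
  restricted to the static domain: a whole-structure fit distributes
  the moving domain's displacement into the static one and blurs the
  hinge signature.

### Contact prediction and evaluation

Positions passing every score filter (inclusive bounds on both ends;
"between X and Y" is ambiguous, so inclusivity is fixed and stated)
form a passing set; the predicted map is all pairs of passing
positions (rank-1 structure; `predict_contacts` is the hook to replace
with a genuine pair-scoring function). Confusion counts are taken over
the (unmasked) pair universe and summarized by
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), computed with
the four marginal sums formed before multiplication (counts of order
10⁵ would otherwise overflow the product) and defined as 0 when a
marginal is zero.

The package ships the published confusion counts for 20 chains × 2
box-filter methods (`data/contact_benchmark.tsv`) as exact arithmetic
inputs; all 40 published MCCs reproduce from their counts to < 5·10⁻⁵,
and every row total is a triangular number, confirming the all-pairs
universe. The published actual-contact counts (TP+FN) differ slightly
between the two methods for the same chain, implying some undocumented
per-method masking of unscored positions; the `mask` parameter exists
to emulate such causes but no specific cause is assumed.

### Correlation reports

Pearson product-moment by default, Spearman as an option (the
linearity of these relationships is not established, so both are
offered); pairwise deletion over positions defined in both tracks
(≥ 3 required); integer `lag` aligns offset tracks. Reports default to
|r|: a sequence score can track the tempo of a structural signal in
either sense, and displacement-derived tracks in particular
anticorrelate as often as they correlate. Signed values are always
available. Zero-variance tracks give an undefined (flagged)
coefficient.

## Synthetic fixtures

The generator module emulates the *inputs* of the analysis, not their
biology:

* `synth_msa` draws each column i.i.d. from k randomly chosen residue
  types (uniform within the set, or Dirichlet-weighted), gaps i.i.d.
  at `gap_rate`. There is no phylogeny, no substitution matrix, no
  site correlation: passing tests show the scores respond correctly
  to controlled conservation, not that real alignments behave this
  way.
* `synth_helix_trace`: canonical 100°/residue twist, 1.52 Å rise,
  radius ≈ 2.28 Å solved from the exact 3.81 Å CA–CA chord
  constraint. `synth_extended_trace`: planar zigzag, 3.81 Å steps,
  6.5 Å i→i+2 span. `synth_globule_trace`: origin-biased
  self-avoiding random walk with 3.81 Å steps (clearance 3.5 Å) — a
  compact chain with a realistic contact density, but no sterics or
  side chains.
* `synth_hinge_pair` rotates the residues after a hinge by a given
  angle about an axis through the hinge CA, optionally adding
  isotropic Gaussian noise to both copies; a residue at perpendicular
  distance r from the axis moves by exactly the chord 2r·sin(θ/2),
  giving an analytic oracle for DISP.
* `synth_correlated_tracks`: y = ρx + √(1−ρ²)ε with x, ε standard
  normal.

All generators take explicit seeds, use one local `numpy` generator
per call, and are bit-reproducible.

## Numerical and design choices

* Indexing: 0-based internally, 1-based in every file format and API
  position argument. A/I residue correspondence is positional (the
  intended use pairs conformations of identical sequence).
* Degenerate inputs: collinear AREA triples → 0; all-gap columns →
  flagged; zero MCC marginals → 0; zero-variance correlation →
  undefined flag; empty column for KOL → error.
* PDB reading (gemmi): first model, highest-occupancy altloc,
  CA-less residues skipped with a warning.
* Helix-vs-strand AREA comparison: tested with a *shared* CG placed at
  an equal perpendicular offset (12–20 Å) from both segments. An
  isolated helix's own centroid sits on its axis at mid-height, so the
  end triangles acquire large axial offsets and dominate the mean — a
  fixture artifact with no analogue for an SSE embedded in a globule.
  At a common CG distance the comparison isolates what actually
  differs between the SSE types, the i→i+2 chord (≈ 4.49 Å helix vs
  6.5 Å strand), and the compact-helix-smaller-AREA ordering holds
  robustly.
* Hinge DISP validation fits the superposition on the static domain
  (equivalently, compares raw coordinates, since the static domain is
  shared exactly); see the DISP note above for why a whole-structure
  fit cannot localize a hinge motion.
* Problem sizes in tests and the acceptance script (alignments up to
  400 columns × 1000 sequences, traces up to 524 residues, 1000-point
  correlation tracks) are chosen so every stochastic property holds
  with wide margin while the whole suite runs in seconds.

## Known limitations

* The default VAR type-count cannot reproduce alignment-server
  variability values below 1; users comparing against such output must
  supply the matching definition and bounds.
* KOL's absolute scale depends on n_seqs and on the compressor's
  container overhead; box bounds must be chosen per dataset
  (the shipped defaults correspond to a particular published
  pipeline's normalization, which is not fully specified).
* Contact maps use CA–CA distances only; no CB or all-atom option.
* The pipeline's correlation stage reports pairwise coefficients only;
  no partial or multivariate decomposition.
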