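# Methods

This note documents the models and procedures `pcdhkit` implements, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions adopted where the design was open.

## Alignment handling and reweighting

Alignments are held as `LabeledMSA`: gapped sequences over the 20 amino
acids plus `-` (`.` and lowercase are normalised on read), each carrying a
(species, isoform, subfamily) label parsed from its header by a configurable
delimiter/regex rule; unparseable labels degrade to `unknown` rather than
failing. Surviving columns always remember their original 1-based numbering,
so filtered alignments stay addressable in the source coordinate system.

Filtering is one pass each, sequences first: drop sequences with gap
fraction strictly above 0.5, then columns strictly above 0.3 (computed over
the surviving sequences). *Caveat:* one-pass filtering is not exactly
idempotent — removing gap-rich columns can in principle push a remaining
sequence back over the sequence threshold; at moderate gap rates the two
coincide, and iterated filtering is deliberately off.

Redundancy weights follow the standard clustering rule: `w_i = 1/k_i` with
`k_i` the number of sequences (including *i*) more than 90% identical to
*i*, and `Neff = Σ w_i`. Pairwise identity is gap-aware by default — matches
are equal non-gap residues, the denominator is the number of columns where
at least one sequence is non-gap — because "identical over the full length"
is ambiguous; a raw Hamming convention (gap counts as a matchable symbol,
denominator = alignment length) is available via `gap_mode="hamming"` since
published effective-sequence counts can be sensitive to this choice.

## Isoform conservation ratio

For a subfamily with isoform groups (one isoform, all species) and species
groups (one species, all isoforms), at each column:

- `pid_ortholog` = mean over isoform groups of the modal non-gap residue
  frequency within the group;
- `pid_paralog` = the same over species groups;
- `ICR = pid_ortholog / pid_paralog`.

Per-group averaging (rather than pooling counts across groups) is the
default: the ratio is a group statistic and averaging avoids size bias when
isoforms are unevenly sampled; pooled counting is available via
`pooled=True`. Gaps never enter modal counts; an all-gap group contributes
nothing, and a column where every group is all-gap is undefined (NaN). Ties
for the modal residue need no tiebreak because only the tied frequency is
used. Normalised values divide by the whole-sequence mean over defined
positions (so the normalised track averages exactly 1), and the smoothed
track is a centred moving mean (default window 5, odd required) taken over
the subsequence of defined positions — undefined positions are bridged, not
zero-filled, and the window shrinks at the ends.

## Pseudo-likelihood Potts model and coupling selection

The coupling model is a q = 21 Potts distribution (20 amino acids + gap)
with fields `h` and symmetric couplings `J`. It is fit by minimising the
weighted, L2-regularised negative pseudo-log-likelihood — the sum over sites
of the conditional multinomial logistic loss of each column given the rest —
normalised by Neff, jointly over all sites with L-BFGS. The objective is
convex, so the fit is deterministic up to the optimiser tolerance
(projected-gradient ∞-norm, default 1e-3; exceeding the iteration cap
without reaching it raises an error carrying the final gradient norm).
Regularisation defaults are `lambda_h = 0.01` and `lambda_J = 0.01·(L−1)`,
with the coupling penalty applied per matrix element as `lambda_J/(L−1)` so
the default is scale-matched to the field penalty. A single-column alignment
degenerates gracefully: couplings are empty and `softmax(h)` reproduces the
weighted column frequencies up to regularisation shrinkage.

Pair scores are Frobenius norms of the coupling block in the zero-sum gauge
restricted to the 20 non-gap states, with the product-form average-product
correction `APC_ij = m_i·m_j/m` applied by default (raw norms are emitted
alongside, since the correction convention is a choice). Note the product
form is *not* invariant to shifting all raw scores by a constant (only an
additive variant is); its honest invariances — a zero table stays zero, a
constant table is annihilated — are what the tests assert.

Selection against structures: pairs failing the locality rule (|i−j| > 5) or
the position cap (both ≤ 400, where alignment gaps dominate the signal) are
discarded. Each remaining pair is labelled against every supplied structure:
**true** if its mapped residues have minimum heavy-atom distance < 8 Å in at
least one structure, **false** if mappable somewhere but never in contact,
**unscorable** if no structure resolves both residues. Cumulative precision
over evaluable *intra-domain* pairs, in rank order, defines the threshold:
the largest retained rank whose cumulative precision is ≥ the 80% target
("largest k" rather than first-crossing; both are recoverable from the
emitted curve). Inter-domain pairs are selected when above the threshold but
excluded from the precision denominator by default (a switch includes them),
since they are the predictions the calibration exists to validate.

## Geometry, SASA and interfaces

Structures are read from PDB/mmCIF via biotite: hydrogens and waters
dropped, alternate locations resolved to highest occupancy, hetero
compounds kept on the array but excluded from contacts and SASA by default.
Declared EC-repeat ranges with missing residues are an error listing the
gaps (override with `allow_gaps`).

Superposition is the Kabsch algorithm (SVD with the determinant sign
correction, so reflections are never returned); fewer than three pairs or
collinear point sets are errors. Repeat principal axes are eigenvectors of
the Cα covariance tensor ordered by decreasing extent, with rotation-
covariant sign rules: the long axis points from the N-terminal half centroid
to the C-terminal half, the second axis follows the first residue's
perpendicular offset, and the third completes a right-handed frame. Tilt
between adjacent repeats is the angle between long axes, computed as
`atan2(|v1a × v1b|, v1a·v1b)` — the arccos form has a ~2e-6-degree noise
floor near parallel axes that breaks exact tilt-0 detection. Azimuth is
measured about the first repeat's long axis from its second axis to the
projection of the second repeat's long axis, in [0, 360); it is reported as
NaN (never fabricated) when the tilt is below 1e-6 degrees. The azimuth
reference is internal: self-consistent across structures analysed together,
but not an absolute convention comparable to other software.

SASA is Shrake–Rupley sphere sampling (biotite), probe 1.4 Å, default 960
points per atom, per-element van der Waals radii (explicit per-atom radii
can be supplied, e.g. 1.7 Å carbons for the toy structures). Per-residue BSA
in a two-protomer assembly is `SASA(protomer alone) − SASA(in assembly)`,
floored at zero (quadrature noise); the footprint is residues with
BSA > 10 Å². Each footprint residue is assigned to the repeat pair spanned
by its closest cross-protomer contact (e.g. `EC1/EC4`), and per-protomer
totals sum footprint BSA within each repeat pair. Conserved interface
positions across structures follow a per-region count rule, by default 5 of
6 structures for EC2/EC3 and 4 of 5 for EC1/EC4. Half-vs-half superposition
pairs the Cα atoms of the two halves of a repeat tandem by global sequence
alignment (BLOSUM62, gap open −11 / extend −1) and emits the pairing table
so the pair count is auditable.

## Classification

Interface residues (footprint members with a supplied ΔΔG_calc, in
kcal/mol, from an external alanine-scanning calculation — never computed
here) are classified on the (normalised ICR, ΔΔG) plane:

- *affinity*: ΔΔG ≥ `ddg_hi` (default 1.0) and ICR ≤ `icr_lo` (default 1.0);
- *specificity*: ΔΔG ≤ `ddg_lo` (default 0.5) and ICR ≥ `icr_hi`
  (default 1.5);
- *main*: everything else.

The defaults are documented conventions on the normalised scales, required
config rather than published constants; the classification is monotone in
both coordinates by construction. Hydropathy summaries are
frequency-weighted Kyte–Doolittle means over non-gap states (renormalised),
so they are linear in the frequency vector; alternative scales are
pluggable but must cover all 20 residues.

## Synthetic generators

All generators draw from `numpy.random.default_rng(seed)` (PCG64) and are
bit-reproducible.

**Ortholog/paralog alignments** use a star phylogeny: per-isoform consensus
sequences derive from one ancestral sequence, isoform-specific positions
receive a distinct consensus residue per isoform, and each sequence mutates
its consensus i.i.d. (substitutions drawn uniformly over the 20 residues, so
an effective rate slightly below nominal). Defaults — 10 species × 6
isoforms, L = 60 with 8 isoform-specific and 8 globally conserved positions,
substitution rates 0.6 background / 0.05 conserved / 0.05 isoform-specific,
gap rate 0 — give desk-scale alignments in the size range of a clustered-Pcdh
subfamily panel with unambiguous planted signal. Not emulated: realistic
phylogenetic correlation, indel structure, or compositional bias; passing
tests demonstrate the statistics, not robustness to tree-shaped noise.

**Potts samples** come from one independent Gibbs chain per output sequence
(uniform random start, 200 burn-in sweeps + 10 decorrelation sweeps), so
samples are mutually independent — sparse planted couplings mix fast enough
that this is cheap. Planted pairs use diagonal blocks
`J(a,b) = s·δ(a,b)` with default strength 1.5 and fields N(0, 0.3): strong
enough that each pair's mutual information sits far above the n = 1000
finite-sample floor, weak enough that columns stay far from fixation.

**Toy structures** are two-repeat rods (20 residues per repeat, 4 Å spacing
along the long axis, 0.5/0.3 Å transverse helical offsets so the three
principal moments are distinct), with the second repeat rotated to the
requested tilt/azimuth about the first repeat's numerically computed axes —
making the round-trip exact by construction. The dimer partner is a 180°
rotation about an axis perpendicular to the chain at 12 Å separation; the
central 6 patch residues carry a 4.5 Å protrusion toward the partner. With
1.7 Å carbons and a 1.4 Å probe, atoms occlude within 6.2 Å: patch
protrusions sit 2–4 Å apart (well buried, > 10 Å² each) while every
non-patch atom stays beyond 6.4 Å (zero burial), so footprint recovery is
exact by geometry, not by tolerance. These rods are deliberately not folded
domains; they validate the axis, contact and surface machinery only.

## Numerical conventions and limitations

- Frequency profiles are gap-inclusive 21-state by default (rows sum to 1);
  gap-exclusive renormalisation is a flag recorded in the output.
- Contact and footprint thresholds are strict inequalities (< 8 Å,
  > 10 Å²), matching the filter conventions (> 50%/30%/90% to remove).
- Pipeline TSV output uses fixed `%.6g` formatting; reruns with identical
  config and inputs are byte-identical (the manifest embeds the config hash
  and seed, never timestamps).
- The test suite and `scripts/acceptance.py` run everything at desk scale
  (alignments ≤ 60 × 60 for ICR, Potts at L = 50 / n = 1000 over 20 and 5
  seeds respectively, toy dimers of 92 atoms); reproducing published
  interface areas or coupling counts for real protocadherins additionally
  requires the deposited alignments and PDB structures as config inputs.
- SASA accuracy is quadrature-limited: at 960 points per atom, per-residue
  areas move by < 1% when the point count doubles from 2000; the analytic
  two-sphere check holds to 2% at 10000 points. Published interface areas
  computed with other radii sets can differ by a few percent.
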