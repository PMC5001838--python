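# pcdhkit

Sequence–structure analysis of affinity and specificity in antiparallel
protocadherin EC1–4 dimers.

Clustered protocadherins (Pcdhs) give vertebrate neurons their surface
identity through strictly homophilic *trans* dimers of their extracellular
cadherin (EC) repeats: EC1–4 of one protomer zips antiparallel against EC4–1
of the partner. The puzzle this package addresses is how one interface
architecture encodes both a generic attractive force and dozens of mutually
exclusive recognition specificities. It provides the computational toolkit
for dissecting that question: which interface residues drive binding
*affinity*, and which encode isoform *specificity*?

`pcdhkit` is aimed at structural bioinformaticians working on cadherin-family
(or other tandem-repeat) adhesion proteins. It implements:

- **Isoform conservation ratio (ICR).** For one subfamily, at each alignment
  column *c*,

      ICR(c) = pid_ortholog(c) / pid_paralog(c)

  where `pid_ortholog` is the modal-residue identity of each isoform across
  species (averaged over isoforms) and `pid_paralog` the modal-residue
  identity of each species across isoforms (averaged over species). Values
  are normalised by the whole-sequence subfamily mean and optionally smoothed
  with a centred 5-residue window. High ICR flags positions conserved within
  an isoform but diversified between isoforms — candidate specificity
  determinants.
- **Evolutionary couplings.** A 21-state Potts model (fields *h_i(a)*,
  symmetric couplings *J_ij(a,b)*) fit by L2-regularised pseudo-likelihood on
  a redundancy-reweighted alignment (sequences > 90% identical share weight;
  Neff = Σ w_i). Pairs are scored by the Frobenius norm of the zero-sum-gauge
  coupling block over the 20 amino-acid states with the average-product
  correction, then calibrated against structural contacts: the cumulative
  precision of non-local (|i−j| > 5) intra-domain pairs, in rank order,
  fixes the deepest rank still meeting an 80% precision target, and all
  pairs above it — including the inter-domain candidates — are selected.
- **Structure geometry.** Kabsch superposition, inter-repeat tilt/azimuth
  from principal axes of the Cα cloud, residue contact maps (minimum
  heavy-atom distance < 8 Å), Shrake–Rupley SASA, per-residue buried surface
  area (BSA = SASA alone − SASA in the dimer), interface footprints
  (BSA > 10 Å²) and their aggregation into EC1/EC4 vs EC2/EC3 regions.
- **Affinity/specificity classification.** Interface residues are placed on
  the (normalised ICR, ΔΔG_calc) plane — ΔΔG_calc being a supplied
  computational alanine-scan table — and partitioned into *affinity*
  (high ΔΔG, low ICR), *specificity* (low ΔΔG, high ICR) and *main* classes,
  with per-region summaries and Kyte–Doolittle hydropathy profiles.
- **Synthetic data.** Seeded generators for labelled ortholog/paralog
  alignments with planted conservation classes, Gibbs-sampled Potts
  alignments with planted couplings, and toy two-repeat dimer structures
  with planted tilt/azimuth and contact patches — so every stage is
  exercisable, with known ground truth, without downloading anything.

## Worked example

```python
import numpy as np
from pcdhkit import (
    OrthologParalogSpec, simulate_ortholog_paralog_msa,
    compute_icr, normalize_icr, compute_weights,
    PlantedPottsSpec, sample_potts, fit_plm, score_couplings,
    ToyStructureSpec, build_toy_assembly, interface_bsa,
)

msa, classes = simulate_ortholog_paralog_msa(OrthologParalogSpec(seed=0))
_, neff = compute_weights(msa)
prof = normalize_icr(compute_icr(msa, "synth"))
by_pos = dict(zip(prof.positions.tolist(), prof.icr_norm))
iso = np.nanmean([by_pos[p] for p, c in classes.items() if c == "isoform_specific"])
bg = np.nanmean([by_pos[p] for p, c in classes.items() if c == "background"])

pairs = PlantedPottsSpec.random_pairs(L=50, n_pairs=10, seed=0)
potts = sample_potts(PlantedPottsSpec(pairs=pairs, seed=1))
weighted, _ = compute_weights(potts)
table = score_couplings(fit_plm(weighted))
top = table.pairs.sort_values("rank").head(10)
found = {(int(i), int(j)) for i, j in zip(top["i"], top["j"])}

ds, truth = build_toy_assembly(ToyStructureSpec())
iface = interface_bsa(ds, radii=truth["atom_radius"])
```

This prints (via the obvious `print` calls):

```
alignment: 60 sequences x 60 columns
Neff at 90% identity: 60.0
mean normalised ICR: isoform-specific 3.44, background 0.62
planted couplings recovered in top 10: 10/10
planted patch [18, 19, 20, 21, 22, 23] -> footprint [18, 19, 20, 21, 22, 23]
buried area per protomer: 177 A^2
```

Reading the numbers: the 60 synthetic sequences are all mutually below the
90% redundancy threshold, so every sequence counts fully (Neff = 60).
Positions planted as isoform-specific score a mean normalised ICR of 3.44
against 0.62 for background positions — the separation the classifier relies
on. All ten planted Potts couplings rank in the top ten APC scores, and the
six-residue contact patch planted in the toy dimer is recovered exactly as
the BSA > 10 Å² footprint, burying 177 Å² per protomer.

## Command line

The same stages run from a shell, reading/writing TSV, FASTA and PDB
artifacts under an output directory:

```bash
pcdhkit run-all --seed 1 --out out/
pcdhkit run --stages simulate,filter,weights,icr --seed 1 --out out/
```

Subcommands (`simulate`, `msa-filter`, `weights`, `icr`, `plm`, `precision`,
`geometry`, `interface`, `classify`, `report`) mirror the stages; every
threshold lives in a YAML config (`--config`) with the standard defaults
(50%/30% gap filters, 90% identity reweighting, |i−j| > 5, positions ≤ 400,
8 Å contacts, 80% precision, BSA > 10 Å², 5-residue ICR window). To analyse
real data instead of the synthetic defaults, point the config at your own
alignment (`alignment:`), structures (`structures:`, `repeat_ranges:`) and
alanine-scan table (`ddg_table:`).

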