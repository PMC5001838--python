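"""Seeded generators for synthetic inputs with known ground truth.

Three generators cover the three data types the analysis consumes:

* :func:`simulate_ortholog_paralog_msa` — labelled star-phylogeny alignments
  with planted position classes (background / globally conserved /
  isoform-specific), emulating the conservation structure that makes the
  isoform conservation ratio informative;
* :func:`sample_potts` — Gibbs samples from a Potts model with planted
  pairwise couplings, the validation oracle for pseudo-likelihood inference;
* :func:`build_toy_assembly` — two-repeat rod "structures" with prescribed
  inter-repeat tilt/azimuth and a two-fold dimer carrying a planted contact
  patch, exercising the geometry and interface machinery.

All generators draw from ``numpy.random.default_rng(seed)`` (PCG64) and are
bit-reproducible given their spec.  The rods are deliberately not folded
domains and the phylogeny is a star: sufficient for the statistics tested,
not a simulation of real cadherin evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .msa import AMINO_ACIDS, GAP, LabeledMSA, Q, SeqLabel
from .geometry import DomainStructure, principal_axes


# ---------------------------------------------------------------------------
# ortholog/paralog alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologParalogSpec:
    """Star-phylogeny alignment with planted position classes.

    Position classes: ``isoform_specific`` positions carry a distinct
    consensus residue per isoform, ``global_conserved`` one consensus for
    all, and ``background`` positions substitute freely.  Substitution rates
    are per-sequence probabilities of replacing the consensus with a uniform
    random amino acid.
    """

    n_species: int = 10
    n_isoforms: int = 6
    L: int = 60
    n_isoform_specific: int = 8
    n_global_conserved: int = 8
    rate_background: float = 0.6
    rate_conserved: float = 0.05
    rate_isoform_specific: float = 0.05
    gap_rate: float = 0.0
    seed: int = 0


def simulate_ortholog_paralog_msa(
    spec: OrthologParalogSpec,
) -> tuple[LabeledMSA, dict[int, str]]:
    """Generate the alignment and the truth map position -> class (1-based)."""
    if spec.n_isoforms > len(AMINO_ACIDS):
        raise ValueError(
            "more isoforms than amino acids: cannot plant distinct "
            "isoform-specific consensus residues"
        )
    if spec.n_isoform_specific + spec.n_global_conserved > spec.L:
        raise ValueError("planted position counts exceed alignment length")
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(AMINO_ACIDS))
    positions = rng.permutation(spec.L)
    iso_pos = np.sort(positions[: spec.n_isoform_specific])
    cons_pos = np.sort(
        positions[spec.n_isoform_specific : spec.n_isoform_specific + spec.n_global_conserved]
    )
    classes = {}
    for p in range(spec.L):
        if p in iso_pos:
            classes[p + 1] = "isoform_specific"
        elif p in cons_pos:
            classes[p + 1] = "global_conserved"
        else:
            classes[p + 1] = "background"

    ancestral = rng.integers(0, len(aa), size=spec.L)
    consensus = np.tile(ancestral, (spec.n_isoforms, 1))
    for p in iso_pos:
        # distinct residue per isoform at specificity positions
        consensus[:, p] = rng.choice(len(aa), size=spec.n_isoforms, replace=False)

    rate = np.full(spec.L, spec.rate_background)
    rate[cons_pos] = spec.rate_conserved
    rate[iso_pos] = spec.rate_isoform_specific

    seqs, labels = [], []
    for iso in range(spec.n_isoforms):
        for sp in range(spec.n_species):
            codes = consensus[iso].copy()
            mut = rng.random(spec.L) < rate
            codes[mut] = rng.integers(0, len(aa), size=int(mut.sum()))
            chars = aa[codes]
            if spec.gap_rate > 0:
                gaps = rng.random(spec.L) < spec.gap_rate
                chars = np.where(gaps, GAP, chars)
            header = f"sp{sp}|iso{iso}|synth"
            seqs.append("".join(chars))
            labels.append(
                SeqLabel(species=f"sp{sp}", isoform=f"iso{iso}", subfamily="synth",
                         header=header)
            )
    return LabeledMSA(sequences=seqs, labels=labels), classes


# ---------------------------------------------------------------------------
# Potts sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPottsSpec:
    """Potts distribution with sparse planted couplings.

    Each planted pair (i, j, strength) contributes a diagonal coupling block
    ``J[a, b] = strength * delta(a, b)`` favouring matched states — strong
    enough at the default 1.5 that the pair's mutual information stands far
    above the finite-sample floor at n = 1000.  Fields are i.i.d. normal
    with scale ``field_magnitude``.  One independent Gibbs chain per output
    sequence is burned in for ``burn_in`` sweeps (plus ``thin`` extra), so
    samples are mutually independent.
    """

    L: int = 50
    q: int = Q
    pairs: tuple[tuple[int, int, float], ...] = ()
    field_magnitude: float = 0.3
    n_sequences: int = 1000
    burn_in: int = 200
    thin: int = 10
    seed: int = 0

    @staticmethod
    def random_pairs(
        L: int, n_pairs: int, strength: float = 1.5, seed: int = 0,
        min_separation: int = 5,
    ) -> tuple[tuple[int, int, float], ...]:
        """Draw distinct non-local planted pairs (1-based positions)."""
        rng = np.random.default_rng(seed)
        pairs: list[tuple[int, int, float]] = []
        used: set[tuple[int, int]] = set()
        while len(pairs) < n_pairs:
            i, j = sorted(rng.choice(L, size=2, replace=False) + 1)
            if j - i <= min_separation or (i, j) in used:
                continue
            used.add((int(i), int(j)))
            pairs.append((int(i), int(j), strength))
        return tuple(pairs)


def sample_potts(spec: PlantedPottsSpec) -> LabeledMSA:
    """Gibbs-sample an alignment from the planted Potts distribution."""
    if spec.burn_in <= 0:
        raise ValueError("burn_in sweeps must be positive")
    for i, j, _ in spec.pairs:
        if not (1 <= i < j <= spec.L):
            raise ValueError(f"planted pair ({i}, {j}) outside [1, L]")
    if len({(i, j) for i, j, _ in spec.pairs}) != len(spec.pairs):
        raise ValueError("planted pairs must be distinct")
    rng = np.random.default_rng(spec.seed)
    L, q, n = spec.L, spec.q, spec.n_sequences
    h = rng.normal(0.0, spec.field_magnitude, size=(L, q))
    partners: dict[int, list[tuple[int, float]]] = {i: [] for i in range(L)}
    for i, j, s in spec.pairs:
        partners[i - 1].append((j - 1, s))
        partners[j - 1].append((i - 1, s))

    states = rng.integers(0, q, size=(n, L))
    sweeps = spec.burn_in + spec.thin
    for _ in range(sweeps):
        for i in range(L):
            logits = np.broadcast_to(h[i], (n, q)).copy()
            for j, s in partners[i]:
                # diagonal block: bonus s when state matches the partner
                logits[np.arange(n), states[:, j]] += s
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n)
            states[:, i] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)

    alphabet = np.array(list(AMINO_ACIDS + GAP))[:q]
    seqs = ["".join(alphabet[row]) for row in states]
    labels = [
        SeqLabel(species=f"chain{k}", isoform="iso0", subfamily="potts",
                 header=f"chain{k}|iso0|potts")
        for k in range(n)
    ]
    return LabeledMSA(sequences=seqs, labels=labels)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyStructureSpec:
    """Two-repeat rod chains forming a two-fold dimer with a planted patch.

    Each repeat is a gentle helix of Cα pseudo-atoms (all carbon) along its
    long axis; the second repeat is rotated to realise the requested
    tilt/azimuth.  The dimer partner is generated by a 180° rotation about
    an axis perpendicular to the chain, offset by ``patch_separation``; the
    ``patch_size`` central residues of each chain carry a protruding atom
    toward the partner so exactly those residues bury surface on dimer
    formation.
    """

    residues_per_repeat: int = 20
    spacing: float = 4.0
    tilt: float = 0.0
    azimuth: float = 0.0
    patch_size: int = 6
    patch_separation: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tilt <= 180:
            raise ValueError("tilt must lie in [0, 180] degrees")
        if not 0 <= self.azimuth < 360:
            raise ValueError("azimuth must lie in [0, 360) degrees")
        if self.patch_size > 2 * self.residues_per_repeat:
            raise ValueError("patch larger than the chain")


def _repeat_template(m: int, spacing: float) -> np.ndarray:
    k = np.arange(m)
    return np.column_stack(
        [0.5 * np.cos(0.7 * k), 0.3 * np.sin(0.7 * k), spacing * k]
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b (Rodrigues)."""
    c = float(np.dot(a, b))
    if c > 1 - 1e-15:
        return np.eye(3)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def build_toy_assembly(
    spec: ToyStructureSpec,
) -> tuple[DomainStructure, dict]:
    """Construct the dimer; returns (structure, truth).

    Truth carries the planted ``tilt``/``azimuth`` (azimuth None when tilt is
    zero), the planted ``patch`` residue ids, and the protrusion length.
    Steric clashes closer than 1 Å between protomers are an error.
    """
    m = spec.residues_per_repeat
    template = _repeat_template(m, spec.spacing)
    cen, axes = principal_axes(template)
    v1, v2, v3 = axes
    theta = np.radians(spec.tilt)
    phi = np.radians(spec.azimuth)
    v1b = (
        np.cos(theta) * v1
        + np.sin(theta) * (np.cos(phi) * v2 + np.sin(phi) * v3)
    )
    R = _rotation_between(v1, v1b)
    start2 = template[-1] + spec.spacing * v1b
    repeat2 = (template - template[0]) @ R.T + start2
    chain = np.vstack([template, repeat2])  # 2m residues

    n_res = 2 * m
    patch_start = m - spec.patch_size // 2
    patch = list(range(patch_start + 1, patch_start + spec.patch_size + 1))  # res ids

    prot_len = 4.5
    coords_a, res_ids_a, names_a = [], [], []
    for idx in range(n_res):
        coords_a.append(chain[idx])
        res_ids_a.append(idx + 1)
        names_a.append("CA")
        if (idx + 1) in patch:
            coords_a.append(chain[idx] + np.array([prot_len, 0.0, 0.0]))
            res_ids_a.append(idx + 1)
            names_a.append("CB")
    coords_a = np.asarray(coords_a)

    # two-fold: 180 deg about the y axis through (sep/2, 0, z_mid)
    cx = spec.patch_separation / 2.0
    cz = float(chain[patch_start : patch_start + spec.patch_size, 2].mean()) if spec.patch_size else float(chain[:, 2].mean())
    coords_b = coords_a.copy()
    coords_b[:, 0] = 2 * cx - coords_b[:, 0]
    coords_b[:, 2] = 2 * cz - coords_b[:, 2]

    from scipy.spatial import cKDTree

    dmin = cKDTree(coords_a).query(coords_b, k=1)[0].min()
    if dmin < 1.0:
        raise ValueError(
            f"protomers sterically clash (minimum atom distance {dmin:.2f} Å)"
        )

    n_atoms = 2 * len(res_ids_a)
    arr = struc.AtomArray(n_atoms)
    arr.coord = np.vstack([coords_a, coords_b]).astype(np.float32)
    arr.chain_id = np.array(["A"] * len(res_ids_a) + ["B"] * len(res_ids_a))
    arr.res_id = np.array(res_ids_a + res_ids_a)
    arr.res_name = np.full(n_atoms, "ALA")
    arr.atom_name = np.array(names_a + names_a)
    arr.element = np.full(n_atoms, "C")
    arr.hetero = np.zeros(n_atoms, dtype=bool)

    ds = DomainStructure(
        atoms=arr,
        repeats={
            "A": [("EC1", 1, m), ("EC2", m + 1, 2 * m)],
            "B": [("EC1", 1, m), ("EC2", m + 1, 2 * m)],
        },
        assembly=["A", "B"],
        structure_id="toy_dimer",
    )
    truth = {
        "tilt": spec.tilt,
        "azimuth": spec.azimuth if spec.tilt > 0 else None,
        "patch": patch,
        "protrusion_length": prot_len,
        "atom_radius": 1.7,
        # full-precision Cα coordinates of the two repeats (the AtomArray
        # container stores float32; angle round-trips at 1e-6 degrees need
        # the construction-precision coordinates)
        "repeat_ca": (template.copy(), repeat2.copy()),
    }
    return ds, truth
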