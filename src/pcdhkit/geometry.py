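"""Structure geometry: I/O, superposition, repeat axes, contacts, SASA/BSA.

Cadherin ectodomains are beads-on-a-string tandems of ~100-residue EC
repeats.  This module partitions an atomic structure into its EC repeats and
measures the quantities the dimer analysis needs: rigid superposition RMSD
(Kabsch), inter-repeat tilt/azimuth from principal axes of the Cα cloud,
residue contact maps at a minimum heavy-atom distance cutoff, solvent
accessible surface area (Shrake–Rupley via biotite), per-residue buried
surface area of a two-protomer assembly, and interface footprints
(BSA above a threshold) aggregated by repeat pair (EC1/EC4 vs EC2/EC3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.info as strucinfo
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile
from biotite.structure.io.pdbx import get_structure as _pdbx_get_structure
from scipy.spatial import cKDTree

from .coupling import ContactTruth

logger = logging.getLogger(__name__)

RepeatRanges = Mapping[str, Sequence[tuple[str, int, int]]]


@dataclass
class DomainStructure:
    """Heavy-atom coordinates plus EC-repeat ranges and assembly chains."""

    atoms: struc.AtomArray
    repeats: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    assembly: list[str] = field(default_factory=list)
    structure_id: str = ""

    def __post_init__(self) -> None:
        for chain, ranges in self.repeats.items():
            prev_last = None
            for label, first, last in ranges:
                if first > last:
                    raise ValueError(f"repeat {label} range inverted: {first}-{last}")
                if prev_last is not None and first <= prev_last:
                    raise ValueError(f"repeat ranges overlap or descend at {label}")
                prev_last = last
        if not self.assembly:
            self.assembly = sorted(set(self.atoms.chain_id))

    # -- selections -------------------------------------------------------

    def chain_atoms(self, chains: str | Sequence[str]) -> struc.AtomArray:
        if isinstance(chains, str):
            chains = [chains]
        return self.atoms[np.isin(self.atoms.chain_id, list(chains))]

    def residue_ids(self, chain: str) -> list[int]:
        mask = self.atoms.chain_id == chain
        return sorted(set(int(r) for r in self.atoms.res_id[mask]))

    def repeat_of(self, chain: str, res_id: int) -> str | None:
        for label, first, last in self.repeats.get(chain, []):
            if first <= res_id <= last:
                return label
        return None

    def ca_coords(self, chain: str, repeat: str | None = None) -> np.ndarray:
        """Cα coordinates of a chain (or one repeat), ordered N- to C-terminal."""
        mask = (self.atoms.chain_id == chain) & (self.atoms.atom_name == "CA")
        sub = self.atoms[mask]
        if repeat is not None:
            ranges = {lab: (a, b) for lab, a, b in self.repeats.get(chain, [])}
            if repeat not in ranges:
                raise KeyError(f"repeat '{repeat}' not declared for chain {chain}")
            first, last = ranges[repeat]
            sub = sub[(sub.res_id >= first) & (sub.res_id <= last)]
        order = np.argsort(sub.res_id, kind="stable")
        return np.asarray(sub.coord[order], dtype=float)

    def sequence(self, chain: str, res_ids: Sequence[int] | None = None) -> str:
        from biotite.sequence import ProteinSequence

        mask = (self.atoms.chain_id == chain) & (self.atoms.atom_name == "CA")
        sub = self.atoms[mask]
        order = np.argsort(sub.res_id, kind="stable")
        sub = sub[order]
        if res_ids is not None:
            keep = np.isin(sub.res_id, list(res_ids))
            sub = sub[keep]
        out = []
        for name in sub.res_name:
            try:
                out.append(ProteinSequence.convert_letter_3to1(name.capitalize()))
            except Exception:
                out.append("X")
        return "".join(out)


def read_structure(
    path: str | Path,
    format: str | None = None,
    repeat_ranges: RepeatRanges | None = None,
    assembly: Sequence[str] | None = None,
    allow_gaps: bool = False,
) -> DomainStructure:
    """Read a PDB/mmCIF file into a :class:`DomainStructure`.

    Hydrogens and waters are dropped; alternate locations resolve to the
    highest-occupancy conformer.  Hetero compounds are kept on the atom array
    (they are excluded later by the SASA/contact defaults).  Declared repeat
    ranges with missing residues are a hard error listing the gaps unless
    ``allow_gaps`` is set.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format == "pdb":
        arr = PDBFile.read(str(path)).get_structure(model=1, altloc="occupancy")
    elif format == "mmcif":
        arr = _pdbx_get_structure(CIFFile.read(str(path)), model=1, altloc="occupancy")
    else:
        raise ValueError(f"unsupported structure format '{format}'")
    keep = ~np.isin(arr.element, ["H", "D"]) & ~struc.filter_solvent(arr)
    arr = arr[keep]
    if arr.array_length() == 0:
        raise ValueError(f"no heavy atoms in {path}")
    repeats = {c: list(r) for c, r in (repeat_ranges or {}).items()}
    for chain, ranges in repeats.items():
        present = set(int(r) for r in arr.res_id[arr.chain_id == chain])
        for label, first, last in ranges:
            missing = [r for r in range(first, last + 1) if r not in present]
            if missing and not allow_gaps:
                raise ValueError(
                    f"chain {chain} repeat {label}: missing residues {missing}"
                )
    return DomainStructure(
        atoms=arr,
        repeats=repeats,
        assembly=list(assembly) if assembly else [],
        structure_id=path.stem,
    )


def write_structure(ds: DomainStructure, path: str | Path) -> None:
    """Write the structure as PDB-format text."""
    pdb = PDBFile()
    pdb.set_structure(ds.atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns ``(R, t, rmsd)`` with the proper rotation ``R`` (det +1) and
    translation ``t`` such that ``moving @ R.T + t`` best fits ``fixed``.
    Fewer than 3 pairs or collinear point sets are errors.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    n = moving.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    A, B = moving - mc, fixed - fc
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise ValueError("moving coordinates are collinear; rotation underdetermined")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = fc - R @ mc
    diff = (moving @ R.T + t) - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# principal axes and inter-repeat angles
# ---------------------------------------------------------------------------

def principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and principal axes of a Cα cloud, ordered by spatial extent.

    ``coords`` must be ordered N- to C-terminal: the long axis sign points
    from the N-terminal half centroid toward the C-terminal half, and the
    second axis sign follows the first residue's perpendicular offset, so
    both are covariant under rigid motions.  A spherically degenerate cloud
    is an error.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
        raise ValueError("need at least 4 ordered (x, y, z) points")
    c = coords.mean(axis=0)
    X = coords - c
    cov = X.T @ X / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 1e-10 or (evals[0] - evals[2]) / evals[0] < 1e-6:
        raise ValueError("degenerate (near-spherical) coordinate cloud")
    v1, v2, v3 = evecs[:, 0], evecs[:, 1], evecs[:, 2]
    half = coords.shape[0] // 2
    nc = coords[half:].mean(axis=0) - coords[:half].mean(axis=0)
    if np.dot(v1, nc) < 0:
        v1 = -v1
    perp = X[0] - np.dot(X[0], v1) * v1
    if np.dot(v2, perp) < 0:
        v2 = -v2
    v3 = np.cross(v1, v2)
    return c, np.vstack([v1, v2, v3])


def inter_repeat_angles(
    coords_a: np.ndarray, coords_b: np.ndarray, tilt_tol: float = 1e-6
) -> tuple[float, float]:
    """Tilt and azimuth between two adjacent repeats' principal axes.

    Tilt (degrees, [0, 180]) is the angle between the long axes.  Azimuth
    (degrees, [0, 360)) is measured about repeat A's long axis from its
    second axis to the projection of repeat B's long axis; it is NaN when the
    tilt is ~0 (projection degenerate).  The azimuth reference is internal —
    self-consistent across structures but not an absolute convention.
    """
    _, axes_a = principal_axes(coords_a)
    _, axes_b = principal_axes(coords_b)
    v1a, v2a, v3a = axes_a
    v1b = axes_b[0]
    # atan2 form is exact for (near-)parallel axes where arccos loses precision
    tilt = float(
        np.degrees(np.arctan2(np.linalg.norm(np.cross(v1a, v1b)), np.dot(v1a, v1b)))
    )
    proj = v1b - np.dot(v1b, v1a) * v1a
    norm = np.linalg.norm(proj)
    if tilt < tilt_tol or tilt > 180 - tilt_tol or norm < 1e-12:
        return tilt, float("nan")
    az = float(np.degrees(np.arctan2(np.dot(proj, v3a), np.dot(proj, v2a)))) % 360.0
    return tilt, az


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

Residue = tuple[str, int]


@dataclass
class ContactMap:
    """Residue pairs whose minimum heavy-atom distance is below a cutoff."""

    structure_id: str
    pairs: set[tuple[Residue, Residue]]
    cutoff: float
    scope: str
    resolved: dict[str, set[int]] = field(default_factory=dict)

    def has_contact(self, a: Residue, b: Residue) -> bool:
        return tuple(sorted((a, b))) in self.pairs

    def to_truth(
        self, chain: str, domain_of: Mapping[int, str] | None = None
    ) -> ContactTruth:
        """Single-chain truth object (residue-number keyed) for calibration."""
        pairs = {
            (min(a[1], b[1]), max(a[1], b[1]))
            for a, b in self.pairs
            if a[0] == chain and b[0] == chain
        }
        return ContactTruth(
            structure_id=self.structure_id,
            pairs=pairs,
            resolved=set(self.resolved.get(chain, set())),
            domain_of=domain_of,
        )


def contact_map(
    ds: DomainStructure,
    cutoff: float = 8.0,
    scope: str = "both",
    include_hetero: bool = False,
) -> ContactMap:
    """All residue pairs with minimum heavy-atom distance strictly < cutoff."""
    if scope not in ("intrachain", "interchain", "both"):
        raise ValueError(f"unknown scope '{scope}'")
    arr = ds.atoms
    if not include_hetero:
        arr = arr[~arr.hetero]
    coords = np.asarray(arr.coord, dtype=float)
    tree = cKDTree(coords)
    idx_pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if idx_pairs.size:
        d = np.linalg.norm(coords[idx_pairs[:, 0]] - coords[idx_pairs[:, 1]], axis=1)
        idx_pairs = idx_pairs[d < cutoff]
    pairs: set[tuple[Residue, Residue]] = set()
    chain_id, res_id = arr.chain_id, arr.res_id
    for ai, aj in idx_pairs:
        ra: Residue = (str(chain_id[ai]), int(res_id[ai]))
        rb: Residue = (str(chain_id[aj]), int(res_id[aj]))
        if ra == rb:
            continue
        same_chain = ra[0] == rb[0]
        if scope == "intrachain" and not same_chain:
            continue
        if scope == "interchain" and same_chain:
            continue
        pairs.add(tuple(sorted((ra, rb))))
    resolved: dict[str, set[int]] = {}
    for c, r in zip(chain_id, res_id):
        resolved.setdefault(str(c), set()).add(int(r))
    return ContactMap(
        structure_id=ds.structure_id, pairs=pairs, cutoff=cutoff, scope=scope,
        resolved=resolved,
    )


# ---------------------------------------------------------------------------
# SASA / BSA
# ---------------------------------------------------------------------------

def _vdw_radii(arr: struc.AtomArray, radii) -> np.ndarray:
    if isinstance(radii, np.ndarray):
        return radii
    if isinstance(radii, (int, float)):
        return np.full(arr.array_length(), float(radii))
    out = np.empty(arr.array_length())
    for i, el in enumerate(arr.element):
        r = strucinfo.vdw_radius_single(el)
        if r is None:
            raise ValueError(f"no van der Waals radius configured for element '{el}'")
        out[i] = r
    return out


def sasa(
    ds: DomainStructure | struc.AtomArray,
    probe: float = 1.4,
    n_points: int = 960,
    radii="single",
    include_hetero: bool = False,
) -> pd.Series:
    """Per-residue solvent-accessible surface area (Å²), Shrake–Rupley.

    ``radii`` is ``"single"`` (per-element van der Waals set), a scalar, or a
    per-atom array.  Hetero compounds are excluded (as surface and as
    occluders) unless requested.
    """
    arr = ds.atoms if isinstance(ds, DomainStructure) else ds
    if not include_hetero:
        arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise ValueError("no atoms selected for SASA")
    atom_sasa = struc.sasa(
        arr, probe_radius=probe, point_number=n_points, vdw_radii=_vdw_radii(arr, radii)
    )
    df = pd.DataFrame(
        {
            "chain": arr.chain_id,
            "res_id": arr.res_id,
            "sasa": np.nan_to_num(np.asarray(atom_sasa, dtype=float)),
        }
    )
    return df.groupby(["chain", "res_id"])["sasa"].sum()


@dataclass
class InterfaceTable:
    """Per-residue buried surface area of a two-protomer assembly."""

    structure_id: str
    residues: pd.DataFrame  # protomer, chain, res_id, repeat, bsa, pair_label
    bsa_min: float

    def footprint(self, protomer: int | None = None) -> pd.DataFrame:
        df = self.residues[self.residues["bsa"] > self.bsa_min]
        if protomer is not None:
            df = df[df["protomer"] == protomer]
        return df.reset_index(drop=True)

    def totals(self) -> pd.DataFrame:
        """Summed footprint BSA per protomer and repeat pair."""
        fp = self.footprint()
        return (
            fp.groupby(["protomer", "pair_label"])["bsa"].sum().reset_index()
        )

    def write_tsv(self, path: str | Path) -> None:
        self.residues.to_csv(path, sep="\t", index=False, float_format="%.6g")


def interface_bsa(
    ds: DomainStructure,
    protomers: tuple[Sequence[str], Sequence[str]] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    radii="single",
    bsa_min: float = 10.0,
    assign_cutoff: float = 8.0,
) -> InterfaceTable:
    """Per-residue BSA = SASA(protomer alone) − SASA(in assembly).

    ``protomers`` gives the chain sets of the two subunits (default: the two
    assembly chains).  Interface residues (BSA > ``bsa_min``) are assigned to
    the repeat pair their closest cross-protomer contact spans, e.g. an EC1
    residue packing against the partner's EC4 is labelled ``EC1/EC4``.
    """
    if protomers is None:
        if len(ds.assembly) != 2:
            raise ValueError("assembly must have exactly 2 protomers (chains)")
        protomers = ([ds.assembly[0]], [ds.assembly[1]])
    chains_a, chains_b = (list(p) for p in protomers)
    all_chains = set(chains_a) | set(chains_b)
    arr = ds.atoms[~ds.atoms.hetero]
    present = set(arr.chain_id)
    if present - all_chains:
        raise ValueError(
            f"protomer split leaves chains unassigned: {sorted(present - all_chains)}"
        )
    complex_arr = arr[np.isin(arr.chain_id, sorted(all_chains))]
    sasa_complex = sasa(complex_arr, probe, n_points, radii, include_hetero=True)

    rows = []
    for pi, chains in enumerate((chains_a, chains_b)):
        alone = arr[np.isin(arr.chain_id, chains)]
        sasa_alone = sasa(alone, probe, n_points, radii, include_hetero=True)
        other = arr[np.isin(arr.chain_id, chains_b if pi == 0 else chains_a)]
        other_coords = np.asarray(other.coord, dtype=float)
        tree = cKDTree(other_coords)
        for (chain, res_id), s_alone in sasa_alone.items():
            s_cplx = float(sasa_complex.get((chain, res_id), 0.0))
            bsa = max(float(s_alone) - s_cplx, 0.0)
            pair_label = ""
            if bsa > bsa_min:
                mask = (alone.chain_id == chain) & (alone.res_id == res_id)
                res_coords = np.asarray(alone.coord[mask], dtype=float)
                dists, idx = tree.query(res_coords, k=1)
                best = int(np.argmin(dists))
                partner_chain = str(other.chain_id[idx[best]])
                partner_res = int(other.res_id[idx[best]])
                own_rep = ds.repeat_of(chain, int(res_id)) or "?"
                partner_rep = ds.repeat_of(partner_chain, partner_res) or "?"
                pair_label = "/".join(sorted((own_rep, partner_rep)))
            rows.append(
                {
                    "protomer": pi,
                    "chain": chain,
                    "res_id": int(res_id),
                    "repeat": ds.repeat_of(chain, int(res_id)) or "?",
                    "bsa": bsa,
                    "pair_label": pair_label,
                }
            )
    return InterfaceTable(
        structure_id=ds.structure_id,
        residues=pd.DataFrame(rows),
        bsa_min=bsa_min,
    )


def conserved_interface_positions(
    tables: Sequence[InterfaceTable],
    alignment_maps: Sequence[Mapping[Residue, int]],
    bsa_min: float = 10.0,
    min_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Alignment positions buried in enough structures, per interface region.

    ``alignment_maps[k]`` maps ``(chain, res_id)`` of table *k* to a common
    alignment column.  A position counts for a table when any mapped residue
    there has BSA above ``bsa_min``; it is selected when its count meets the
    per-region rule (default: 5 of the EC2/EC3 tables, 4 of the EC1/EC4
    tables, following the conserved-interface convention).  Unmapped residues
    are excluded with a logged warning.
    """
    if min_counts is None:
        min_counts = {"EC2/EC3": 5, "EC1/EC4": 4}
    counts: dict[tuple[int, str], set[int]] = {}
    for k, (table, amap) in enumerate(zip(tables, alignment_maps)):
        fp = table.residues[table.residues["bsa"] > bsa_min]
        for _, row in fp.iterrows():
            key: Residue = (row["chain"], int(row["res_id"]))
            pos = amap.get(key)
            if pos is None:
                logger.warning(
                    "structure %s residue %s/%d has no alignment mapping; excluded",
                    table.structure_id, key[0], key[1],
                )
                continue
            region = row["pair_label"] or row["repeat"]
            counts.setdefault((pos, region), set()).add(k)
    rows = []
    for (pos, region), table_set in sorted(counts.items()):
        need = min_counts.get(region)
        rows.append(
            {
                "position": pos,
                "region": region,
                "count": len(table_set),
                "selected": need is not None and len(table_set) >= need,
            }
        )
    return pd.DataFrame(rows, columns=["position", "region", "count", "selected"])


# ---------------------------------------------------------------------------
# half-vs-half superposition
# ---------------------------------------------------------------------------

def half_vs_half_rmsd(
    ds: DomainStructure,
    chain: str,
    halves: tuple[Sequence[str], Sequence[str]] | None = None,
) -> tuple[float, int, pd.DataFrame]:
    """Superpose the first half of a repeat tandem onto the second half.

    The halves (default: first two repeats vs last two) are paired by a
    global sequence alignment of their Cα sequences; returns the Kabsch RMSD,
    the number of paired Cα atoms, and the pairing table so the count is
    auditable.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    reps = [lab for lab, _, _ in ds.repeats.get(chain, [])]
    if halves is None:
        if len(reps) < 2 or len(reps) % 2:
            raise ValueError("need an even number of repeats to split in half")
        halves = (reps[: len(reps) // 2], reps[len(reps) // 2 :])
    ranges = {lab: (a, b) for lab, a, b in ds.repeats[chain]}

    def collect(labels):
        res_ids = []
        for lab in labels:
            first, last = ranges[lab]
            res_ids.extend(
                r for r in ds.residue_ids(chain) if first <= r <= last
            )
        seq = ds.sequence(chain, res_ids)
        mask = (ds.atoms.chain_id == chain) & (ds.atoms.atom_name == "CA")
        sub = ds.atoms[mask]
        order = np.argsort(sub.res_id, kind="stable")
        sub = sub[order]
        keep = np.isin(sub.res_id, res_ids)
        return seq, np.asarray(sub.coord[keep], dtype=float), list(sub.res_id[keep])

    seq1, xyz1, ids1 = collect(halves[0])
    seq2, xyz2, ids2 = collect(halves[1])
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(seq1.replace("X", "A"), seq2.replace("X", "A"))[0]
    pairs = []
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        for o in range(e1 - s1):
            pairs.append((s1 + o, s2 + o))
    if len(pairs) < 3:
        raise ValueError("fewer than 3 aligned residue pairs")
    i1 = [p[0] for p in pairs]
    i2 = [p[1] for p in pairs]
    _, _, rmsd = kabsch_superpose(xyz1[i1], xyz2[i2])
    pairing = pd.DataFrame(
        {
            "res_id_first_half": [ids1[i] for i in i1],
            "res_id_second_half": [ids2[i] for i in i2],
        }
    )
    return rmsd, len(pairs), pairing
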