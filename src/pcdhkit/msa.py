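"""Labeled multiple-sequence-alignment container, I/O, filtering and reweighting.

The alignments analysed here are ortholog/paralog collections of protocadherin
ectodomain repeats (EC1-4).  Every sequence carries a (species, isoform,
subfamily) label parsed from its header; downstream conservation-ratio and
coupling analyses group sequences by these labels.

Conventions
-----------
* Alphabet: the 20 standard amino acids plus the gap symbol ``-`` (21 states).
  ``.`` and lowercase characters are normalised to ``-``/uppercase on read.
* Filtering removes sequences with a gap fraction *strictly* greater than the
  sequence threshold first, then columns strictly above the column threshold.
* Redundancy weights: sequence *i* receives weight 1/k where k is the number
  of sequences (including itself) more than ``identity_threshold`` identical
  to it; the effective sequence number Neff is the sum of the weights.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # 21 states, gap last
Q = len(ALPHABET)
_CODE = {c: i for i, c in enumerate(ALPHABET)}

UNKNOWN = "unknown"


class RaggedAlignmentError(ValueError):
    """Raised when records in an alignment have unequal lengths."""


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a symbol outside the 21-state alphabet."""


@dataclass(frozen=True)
class SeqLabel:
    """Per-sequence annotation: species / isoform / subfamily plus raw header."""

    species: str = UNKNOWN
    isoform: str = UNKNOWN
    subfamily: str = UNKNOWN
    header: str = ""


@dataclass
class LabeledMSA:
    """An alignment with per-sequence labels and an original-column map.

    ``columns`` keeps the 1-based position of every surviving column in the
    original (unfiltered) alignment so that filtered alignments remain
    addressable in the original coordinate system.  ``ref_numbering`` is an
    optional map from alignment column to reference-protein residue number.
    """

    sequences: list[str]
    labels: list[SeqLabel]
    columns: np.ndarray = None  # type: ignore[assignment]
    weights: np.ndarray | None = None
    ref_numbering: dict[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment contains no sequences")
        L = len(self.sequences[0])
        for i, s in enumerate(self.sequences):
            if len(s) != L:
                name = self.labels[i].header if i < len(self.labels) else f"record {i}"
                raise RaggedAlignmentError(
                    f"record '{name}' has length {len(s)}, expected {L}"
                )
        if len(self.labels) != len(self.sequences):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.sequences)} sequences"
            )
        if self.columns is None:
            self.columns = np.arange(1, L + 1)
        else:
            self.columns = np.asarray(self.columns)
            if self.columns.size != L:
                raise ValueError("column map length differs from alignment length")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.size != len(self.sequences):
                raise ValueError("weights count differs from sequence count")
            if np.any(self.weights <= 0) or np.any(self.weights > 1):
                raise ValueError("weights must lie in (0, 1]")

    # -- basic properties -------------------------------------------------

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def encoded(self) -> np.ndarray:
        """Integer matrix (n, L); 0..19 amino acids, 20 gap.

        Raises :class:`UnknownResidueError` naming the symbol and record.
        """
        mat = np.empty((self.n_sequences, self.length), dtype=np.int8)
        for i, s in enumerate(self.sequences):
            for j, c in enumerate(s):
                code = _CODE.get(c)
                if code is None:
                    raise UnknownResidueError(
                        f"unknown residue symbol '{c}' in record "
                        f"'{self.labels[i].header}' at column {j + 1}"
                    )
                mat[i, j] = code
        return mat

    def subset_sequences(self, idx: Sequence[int]) -> "LabeledMSA":
        idx = list(idx)
        return LabeledMSA(
            sequences=[self.sequences[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            columns=self.columns.copy(),
            weights=None if self.weights is None else self.weights[idx],
            ref_numbering=self.ref_numbering,
        )

    def subset_columns(self, keep: np.ndarray) -> "LabeledMSA":
        keep = np.asarray(keep)
        seqs = ["".join(s[j] for j in np.flatnonzero(keep)) for s in self.sequences]
        return LabeledMSA(
            sequences=seqs,
            labels=list(self.labels),
            columns=self.columns[keep],
            weights=self.weights,
            ref_numbering=self.ref_numbering,
        )


# ---------------------------------------------------------------------------
# header parsing and I/O
# ---------------------------------------------------------------------------

def delimited_label_parser(
    delimiter: str = "|", order: Sequence[str] = ("species", "isoform", "subfamily")
) -> Callable[[str], SeqLabel]:
    """Build a parser splitting headers like ``mouse|gB3|gamma`` by a delimiter."""

    def parse(header: str) -> SeqLabel:
        parts = header.split(delimiter)
        fields = {"species": UNKNOWN, "isoform": UNKNOWN, "subfamily": UNKNOWN}
        for name, value in zip(order, parts):
            if value:
                fields[name] = value
        return SeqLabel(header=header, **fields)

    return parse


def regex_label_parser(pattern: str) -> Callable[[str], SeqLabel]:
    """Build a parser from a regex with named groups species/isoform/subfamily."""
    rx = re.compile(pattern)

    def parse(header: str) -> SeqLabel:
        m = rx.search(header)
        if not m:
            return SeqLabel(header=header)
        g = m.groupdict()
        return SeqLabel(
            species=g.get("species") or UNKNOWN,
            isoform=g.get("isoform") or UNKNOWN,
            subfamily=g.get("subfamily") or UNKNOWN,
            header=header,
        )

    return parse


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_msa(
    path: str | Path,
    format: str = "fasta",
    label_parser: Callable[[str], SeqLabel] | None = None,
) -> LabeledMSA:
    """Read a FASTA or Stockholm alignment into a :class:`LabeledMSA`.

    Unparseable labels become ``unknown`` rather than errors; ragged or empty
    files are hard errors.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format '{format}'")
    path = Path(path)
    if label_parser is None:
        label_parser = delimited_label_parser()
    # AlignIO enforces equal lengths but reports unhelpfully; pre-check fasta.
    if format == "fasta":
        records = list(_iter_fasta(path))
        if not records:
            raise ValueError(f"empty alignment file: {path}")
        L = len(records[0][1])
        for name, seq in records:
            if len(seq) != L:
                raise RaggedAlignmentError(
                    f"record '{name}' has length {len(seq)}, expected {L}"
                )
        seqs = [_normalise(seq) for _, seq in records]
        headers = [name for name, _ in records]
    else:
        try:
            aln = AlignIO.read(str(path), "stockholm")
        except ValueError as exc:
            raise ValueError(f"cannot read stockholm alignment {path}: {exc}") from exc
        if len(aln) == 0:
            raise ValueError(f"empty alignment file: {path}")
        seqs = [_normalise(str(rec.seq)) for rec in aln]
        headers = [rec.id for rec in aln]
    return LabeledMSA(sequences=seqs, labels=[label_parser(h) for h in headers])


def _iter_fasta(path: Path):
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name, chunks = line[1:].strip(), []
            elif line:
                if name is None:
                    raise ValueError(f"sequence data before first header in {path}")
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def write_msa(msa: LabeledMSA, path: str | Path, format: str = "fasta") -> None:
    """Write the alignment; headers are emitted verbatim (round-trip safe)."""
    records = [
        SeqRecord(Seq(s), id=lab.header or f"seq{i}", description="")
        for i, (s, lab) in enumerate(zip(msa.sequences, msa.labels))
    ]
    AlignIO.write(MultipleSeqAlignment(records), str(path), format)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_msa(
    msa: LabeledMSA,
    max_seq_gap_frac: float = 0.5,
    max_col_gap_frac: float = 0.3,
) -> LabeledMSA:
    """Drop gappy sequences, then gappy columns (both strict inequalities).

    One pass each, sequences first: a sequence is removed when its gap
    fraction exceeds ``max_seq_gap_frac``; afterwards a column is removed when
    its gap fraction (over the surviving sequences) exceeds
    ``max_col_gap_frac``.  The original column numbering is retained in
    ``columns``.
    """
    for frac in (max_seq_gap_frac, max_col_gap_frac):
        if not 0 <= frac <= 1:
            raise ValueError("gap-fraction thresholds must lie in [0, 1]")
    mat = msa.encoded()
    gap = mat == _CODE[GAP]
    seq_keep = gap.mean(axis=1) <= max_seq_gap_frac
    if not seq_keep.any():
        raise ValueError("sequence gap filter removed every sequence")
    out = msa.subset_sequences(np.flatnonzero(seq_keep))
    col_keep = gap[seq_keep].mean(axis=0) <= max_col_gap_frac
    if not col_keep.any():
        raise ValueError("column gap filter removed every column")
    return out.subset_columns(col_keep)


# ---------------------------------------------------------------------------
# redundancy reweighting
# ---------------------------------------------------------------------------

def pairwise_identity_matrix(msa: LabeledMSA, gap_mode: str = "gap_aware") -> np.ndarray:
    """Fractional pairwise identity for all sequence pairs.

    gap_aware (default): matches are equal non-gap residues; the denominator
    is the number of columns where at least one of the two sequences is
    non-gap (gap-gap columns drop out entirely).
    hamming: matches are equal symbols including gap; denominator is the full
    alignment length.
    """
    mat = msa.encoded()
    n, L = mat.shape
    gap_code = _CODE[GAP]
    if gap_mode == "hamming":
        onehot = np.stack([(mat == a) for a in range(Q)]).astype(np.float64)
        matches = np.einsum("anl,aml->nm", onehot, onehot)
        with np.errstate(invalid="ignore"):
            return matches / L
    if gap_mode != "gap_aware":
        raise ValueError(f"unknown gap_mode '{gap_mode}'")
    onehot = np.stack([(mat == a) for a in range(Q - 1)]).astype(np.float64)
    matches = np.einsum("anl,aml->nm", onehot, onehot)
    gapvec = (mat == gap_code).astype(np.float64)
    gap_gap = gapvec @ gapvec.T
    denom = L - gap_gap
    ident = np.ones((n, n))
    nz = denom > 0
    ident[nz] = matches[nz] / denom[nz]
    return ident


def compute_weights(
    msa: LabeledMSA,
    identity_threshold: float = 0.9,
    gap_mode: str = "gap_aware",
) -> tuple[LabeledMSA, float]:
    """Redundancy downweighting at an identity threshold; returns (msa, Neff).

    ``w_i = 1 / |{j : identity(i, j) > threshold}|`` with the cluster
    including *i* itself; ``Neff = sum_i w_i``.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must lie in (0, 1]")
    if msa.n_sequences == 0:
        raise ValueError("empty alignment")
    ident = pairwise_identity_matrix(msa, gap_mode=gap_mode)
    counts = (ident > identity_threshold).sum(axis=1)  # diagonal == 1 > thr
    weights = 1.0 / counts
    neff = float(weights.sum())
    return replace(msa, weights=weights), neff


def write_weights(msa: LabeledMSA, neff: float, path: str | Path) -> None:
    """TSV of (sequence id, weight) with a trailing Neff summary line."""
    if msa.weights is None:
        raise ValueError("weights not computed")
    with open(path, "w") as fh:
        fh.write("sequence_id\tweight\n")
        for lab, w in zip(msa.labels, msa.weights):
            fh.write(f"{lab.header}\t{w:.6g}\n")
        fh.write(f"#Neff\t{neff:.6g}\n")


# ---------------------------------------------------------------------------
# column frequency profiles
# ---------------------------------------------------------------------------

@dataclass
class FrequencyProfile:
    """Per-position relative amino-acid frequencies (optionally gap-inclusive)."""

    positions: np.ndarray  # original alignment columns
    freqs: np.ndarray  # (n_positions, 21), gap last
    weighted: bool
    include_gap: bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (self.positions.size, Q):
            raise ValueError("frequency matrix shape mismatch")

    def freq(self, position: int, residue: str) -> float:
        (idx,) = np.flatnonzero(self.positions == position)
        return float(self.freqs[idx, _CODE[residue]])


def frequency_profile(
    msa: LabeledMSA,
    positions: Sequence[int] | None = None,
    weighted: bool = False,
    include_gap: bool = True,
) -> FrequencyProfile:
    """Column frequency vectors over the 21-state alphabet.

    ``positions`` are original alignment columns (default: all).  With
    ``include_gap=False`` the 20 amino-acid frequencies are renormalised to
    sum to 1 over non-gap states (all-gap columns keep zero vectors).
    """
    mat = msa.encoded()
    if weighted:
        if msa.weights is None:
            raise ValueError("weighted profile requested but weights not computed")
        w = msa.weights / msa.weights.sum()
    else:
        w = np.full(msa.n_sequences, 1.0 / msa.n_sequences)
    if positions is None:
        col_idx = np.arange(msa.length)
    else:
        col_idx = []
        for p in positions:
            hits = np.flatnonzero(msa.columns == p)
            if hits.size == 0:
                raise ValueError(f"position {p} is not a column of this alignment")
            col_idx.append(hits[0])
        col_idx = np.asarray(col_idx)
    freqs = np.zeros((col_idx.size, Q))
    for out_i, j in enumerate(col_idx):
        np.add.at(freqs[out_i], mat[:, j], w)
    if not include_gap:
        nongap = freqs[:, :-1]
        tot = nongap.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            nongap = np.where(tot > 0, nongap / tot, 0.0)
        freqs = np.concatenate([nongap, np.zeros((col_idx.size, 1))], axis=1)
    return FrequencyProfile(
        positions=msa.columns[col_idx],
        freqs=freqs,
        weighted=weighted,
        include_gap=include_gap,
    )
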