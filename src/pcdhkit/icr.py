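"""Isoform conservation ratio (ICR) profiles.

The ICR quantifies, per alignment position, how conserved a residue is among
orthologs (the same isoform across species) relative to paralogs (different
isoforms within one species).  Positions that are fixed within each isoform
but diversified between isoforms — candidate specificity determinants — score
high; uniformly conserved or uniformly variable positions score near 1.

For one subfamily:

    pid_ortholog(c) = mean over isoforms of the modal-residue frequency of
                      that isoform's cross-species sequence set at column c
    pid_paralog(c)  = mean over species of the modal-residue frequency of
                      that species' cross-isoform sequence set at column c
    icr_raw(c)      = pid_ortholog(c) / pid_paralog(c)

Raw values are normalised by the whole-sequence subfamily mean, and a
centred sliding window (default 5 positions) produces the smoothed track
used to compare subfamilies.  Gaps never count toward modal frequencies; a
group that is entirely gapped at a position contributes nothing, and a
position where every group is all-gap is undefined (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .msa import GAP, LabeledMSA


@dataclass
class ICRProfile:
    """Per-position ICR track for one subfamily (NaN marks undefined)."""

    subfamily: str
    positions: np.ndarray
    pid_ortholog: np.ndarray
    pid_paralog: np.ndarray
    icr_raw: np.ndarray
    icr_norm: np.ndarray | None = None
    icr_smooth: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.positions).size
        for name in ("pid_ortholog", "pid_paralog", "icr_raw"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n:
                raise ValueError(f"{name} length differs from positions")
            setattr(self, name, arr)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": self.positions,
                "pid_ortholog": self.pid_ortholog,
                "pid_paralog": self.pid_paralog,
                "icr_raw": self.icr_raw,
            }
        )
        if self.icr_norm is not None:
            df["icr_norm"] = self.icr_norm
        if self.icr_smooth is not None:
            df["icr_smooth"] = self.icr_smooth
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _group_modal_freqs(columns: list[str], groups: dict[str, list[int]], pooled: bool) -> float:
    """Mean (or pooled) modal non-gap residue frequency over groups at a column.

    ``columns`` is the list of residues at one column; groups map label -> row
    indices.  Returns NaN when every group is all-gap.
    """
    if pooled:
        modal_sum = 0.0
        total = 0
        for rows in groups.values():
            counts: dict[str, int] = {}
            for r in rows:
                c = columns[r]
                if c != GAP:
                    counts[c] = counts.get(c, 0) + 1
            if counts:
                modal_sum += max(counts.values())
                total += sum(counts.values())
        return modal_sum / total if total else float("nan")
    vals = []
    for rows in groups.values():
        counts = {}
        for r in rows:
            c = columns[r]
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        if counts:
            vals.append(max(counts.values()) / sum(counts.values()))
    return float(np.mean(vals)) if vals else float("nan")


def compute_icr(msa: LabeledMSA, subfamily: str, pooled: bool = False) -> ICRProfile:
    """Per-position ortholog/paralog conservation ratio for one subfamily.

    ``pooled=True`` pools modal counts across groups (size-weighted) instead
    of averaging per-group modal frequencies (the default).
    """
    idx = [i for i, lab in enumerate(msa.labels) if lab.subfamily == subfamily]
    if not idx:
        raise ValueError(f"subfamily '{subfamily}' absent from alignment labels")
    sub = msa.subset_sequences(idx)
    isoforms: dict[str, list[int]] = {}
    species: dict[str, list[int]] = {}
    for i, lab in enumerate(sub.labels):
        isoforms.setdefault(lab.isoform, []).append(i)
        species.setdefault(lab.species, []).append(i)
    if len(isoforms) < 2:
        raise ValueError(
            f"subfamily '{subfamily}' has {len(isoforms)} isoform(s); "
            "need at least 2 for a paralog comparison"
        )
    if len(species) < 2:
        raise ValueError(
            f"subfamily '{subfamily}' has {len(species)} species; "
            "need at least 2 for an ortholog comparison"
        )
    L = sub.length
    pid_o = np.empty(L)
    pid_p = np.empty(L)
    for j in range(L):
        col = [s[j] for s in sub.sequences]
        pid_o[j] = _group_modal_freqs(col, isoforms, pooled)
        pid_p[j] = _group_modal_freqs(col, species, pooled)
    with np.errstate(invalid="ignore", divide="ignore"):
        icr = np.where((pid_p > 0) & np.isfinite(pid_o), pid_o / pid_p, np.nan)
    return ICRProfile(
        subfamily=subfamily,
        positions=sub.columns.copy(),
        pid_ortholog=pid_o,
        pid_paralog=pid_p,
        icr_raw=icr,
    )


def normalize_icr(profile: ICRProfile) -> ICRProfile:
    """Divide raw ICR by its whole-sequence mean over defined positions."""
    defined = np.isfinite(profile.icr_raw)
    if not defined.any():
        raise ValueError("every position is undefined; cannot normalise")
    mean = profile.icr_raw[defined].mean()
    return replace(profile, icr_norm=profile.icr_raw / mean)


def smooth_icr(profile: ICRProfile, window: int = 5) -> ICRProfile:
    """Centred sliding average of the normalised track.

    The window shrinks at the sequence ends; undefined (NaN) positions are
    bridged — excluded from every window mean, and left NaN themselves.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if profile.icr_norm is None:
        profile = normalize_icr(profile)
    x = profile.icr_norm
    half = window // 2
    smooth = np.full(x.size, np.nan)
    defined = np.flatnonzero(np.isfinite(x))
    vals = x[defined]
    for k in range(defined.size):
        lo, hi = max(0, k - half), min(defined.size, k + half + 1)
        smooth[defined[k]] = vals[lo:hi].mean()
    return replace(profile, icr_smooth=smooth)
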