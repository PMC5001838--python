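"""Affinity/specificity classification of interface residues.

Interface residues are partitioned by two per-residue measures: the
normalised isoform conservation ratio (ICR) and the computed alanine-scan
binding penalty ΔΔG_calc (kcal/mol, supplied by an external calculation).
Hotspot residues with high ΔΔG and low ICR drive binding **affinity**;
residues with low ΔΔG but high isoform-specific conservation encode
**specificity**; everything else is the **main** cluster.  In protocadherin
EC1-4 dimers, affinity residues concentrate in the EC1/EC4 region and
specificity residues in EC2/EC3.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .icr import ICRProfile
from .msa import AMINO_ACIDS
from .geometry import InterfaceTable

#: Kyte-Doolittle hydropathy, the default scale for interface composition.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class ClassThresholds:
    """Class boundaries on the (icr_norm, ΔΔG) plane.

    Defaults are documented conventions, not published constants: affinity
    needs ΔΔG >= ``ddg_hi`` and icr_norm <= ``icr_lo``; specificity needs
    ΔΔG <= ``ddg_lo`` and icr_norm >= ``icr_hi``.
    """

    icr_lo: float = 1.0
    icr_hi: float = 1.5
    ddg_lo: float = 0.5
    ddg_hi: float = 1.0


@dataclass
class ResidueClassTable:
    """Per-interface-residue ICR, ΔΔG and affinity/specificity/main class."""

    residues: pd.DataFrame  # chain, res_id, position, icr_norm, ddg, bsa, region, cls
    thresholds: ClassThresholds

    def write_tsv(self, path: str | Path) -> None:
        self.residues.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _classify_one(icr_norm: float, ddg: float, t: ClassThresholds) -> str:
    if ddg >= t.ddg_hi and icr_norm <= t.icr_lo:
        return "affinity"
    if ddg <= t.ddg_lo and icr_norm >= t.icr_hi:
        return "specificity"
    return "main"


def classify_residues(
    icr: ICRProfile,
    ddg_table: pd.DataFrame,
    footprint: InterfaceTable,
    thresholds: ClassThresholds = ClassThresholds(),
    alignment_map: Mapping[tuple[str, int], int] | None = None,
) -> ResidueClassTable:
    """Partition interface residues into affinity / specificity / main.

    ``ddg_table`` needs columns ``chain``, ``res_id``, ``ddg``;
    ``alignment_map`` translates (chain, res_id) to alignment columns
    (identity on res_id by default).  Only footprint residues (BSA above the
    table's threshold) are classified; residues with a ΔΔG but no alignment
    mapping are excluded with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    icr_by_pos = dict(zip(icr.positions.tolist(), np.asarray(icr.icr_norm, dtype=float)))
    ddg_by_res = {
        (str(r["chain"]), int(r["res_id"])): float(r["ddg"])
        for _, r in ddg_table.iterrows()
    }
    rows = []
    for _, r in footprint.footprint().iterrows():
        key = (str(r["chain"]), int(r["res_id"]))
        pos = alignment_map.get(key) if alignment_map is not None else key[1]
        if pos is None or pos not in icr_by_pos or not np.isfinite(icr_by_pos[pos]):
            if key in ddg_by_res:
                logger.warning(
                    "residue %s/%d has ΔΔG but no alignment mapping; excluded",
                    key[0], key[1],
                )
            continue
        if key not in ddg_by_res:
            continue
        icr_val = float(icr_by_pos[pos])
        ddg_val = ddg_by_res[key]
        rows.append(
            {
                "chain": key[0],
                "res_id": key[1],
                "position": pos,
                "icr_norm": icr_val,
                "ddg": ddg_val,
                "bsa": float(r["bsa"]),
                "region": r["pair_label"] or r["repeat"],
                "cls": _classify_one(icr_val, ddg_val, thresholds),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["chain", "res_id", "position", "icr_norm", "ddg", "bsa", "region", "cls"],
    )
    return ResidueClassTable(residues=df, thresholds=thresholds)


def region_summary(table: ResidueClassTable) -> pd.DataFrame:
    """Class-by-region contingency counts plus headline fractions.

    Emits one row per (region, class) and, as attributes on the frame,
    the fraction of affinity residues falling in EC1/EC4 and of specificity
    residues falling in EC2/EC3.
    """
    df = table.residues
    counts = (
        df.groupby(["region", "cls"]).size().rename("count").reset_index()
        if len(df)
        else pd.DataFrame(columns=["region", "cls", "count"])
    )
    out = counts.copy()
    n_aff = int((df["cls"] == "affinity").sum()) if len(df) else 0
    n_spec = int((df["cls"] == "specificity").sum()) if len(df) else 0
    aff_ec14 = (
        int(((df["cls"] == "affinity") & (df["region"] == "EC1/EC4")).sum())
        if len(df)
        else 0
    )
    spec_ec23 = (
        int(((df["cls"] == "specificity") & (df["region"] == "EC2/EC3")).sum())
        if len(df)
        else 0
    )
    out.attrs["frac_affinity_in_ec14"] = aff_ec14 / n_aff if n_aff else float("nan")
    out.attrs["frac_specificity_in_ec23"] = spec_ec23 / n_spec if n_spec else float("nan")
    return out


def hydropathy_summary(
    profile,
    scale: Mapping[str, float] | None = None,
    regions: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Frequency-weighted mean hydropathy per position (and per region).

    The mean at a position is sum over amino acids of freq(aa) * scale(aa)
    with frequencies renormalised over non-gap states; a scale missing any of
    the 20 amino acids is an error.  ``regions`` optionally labels positions
    so per-region means can be compared (e.g. EC1/EC4 vs EC2/EC3).
    """
    if scale is None:
        scale = KYTE_DOOLITTLE
    missing = [aa for aa in AMINO_ACIDS if aa not in scale]
    if missing:
        raise ValueError(f"hydropathy scale missing residues: {missing}")
    weights = np.array([scale[aa] for aa in AMINO_ACIDS])
    nongap = profile.freqs[:, : len(AMINO_ACIDS)]
    tot = nongap.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_h = np.where(tot > 0, (nongap @ weights) / np.where(tot > 0, tot, 1.0), np.nan)
    df = pd.DataFrame({"position": profile.positions, "hydropathy": mean_h})
    if regions is not None:
        df["region"] = [regions.get(int(p)) for p in profile.positions]
    return df
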