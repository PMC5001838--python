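"""End-to-end orchestration of the dimer sequence-structure analysis.

Stages (dependency order)::

    simulate -> filter -> weights -> icr
                                  -> plm -> precision
             -> geometry
             -> interface -> classify -> report

Every stage reads its inputs either from the run configuration or from the
artifacts a previous stage wrote under ``outdir/<stage>/``, and writes TSV /
FASTA / PDB / JSON artifacts with fixed floating-point formatting, so a
rerun with identical config and inputs is byte-identical.  A manifest
records the config hash, seed, package version and thresholds used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .msa import (
    LabeledMSA,
    compute_weights,
    filter_msa,
    frequency_profile,
    read_msa,
    write_msa,
    write_weights,
)
from .icr import compute_icr, normalize_icr, smooth_icr
from .coupling import (
    ContactTruth,
    calibrate_precision,
    fit_plm,
    score_couplings,
)
from .geometry import (
    contact_map,
    inter_repeat_angles,
    interface_bsa,
    read_structure,
    write_structure,
)
from .classify import ClassThresholds, classify_residues, region_summary
from .synthetic import (
    OrthologParalogSpec,
    PlantedPottsSpec,
    ToyStructureSpec,
    build_toy_assembly,
    sample_potts,
    simulate_ortholog_paralog_msa,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate",
    "filter",
    "weights",
    "icr",
    "plm",
    "geometry",
    "interface",
    "precision",
    "classify",
    "report",
]


@dataclass
class RunConfig:
    """All inputs and thresholds of the pipeline, with the standard defaults.

    Numeric defaults are the analysis constants: 0.5/0.3 gap filters, 0.9
    identity reweighting, |i-j| > 5 locality, positions <= 400, 8 Å contacts,
    80% precision target, 10 Å² footprint threshold, 5-of-6 / 4-of-5
    conserved-interface counts, 5-residue ICR window.
    """

    # inputs (None -> use the simulate stage's synthetic artifacts)
    alignment: str | None = None
    alignment_format: str = "fasta"
    coupling_alignment: str | None = None
    structures: list[str] = field(default_factory=list)
    repeat_ranges: dict = field(default_factory=dict)  # chain -> [[label, first, last], ...]
    ddg_table: str | None = None
    subfamilies: list[str] = field(default_factory=list)
    # msa thresholds
    max_seq_gap_frac: float = 0.5
    max_col_gap_frac: float = 0.3
    identity_threshold: float = 0.9
    gap_mode: str = "gap_aware"
    # icr
    window: int = 5
    # coupling
    lambda_h: float = 0.01
    lambda_J: float | None = None
    min_separation: int = 5
    max_position: int = 400
    precision_target: float = 0.8
    # geometry / interface
    contact_cutoff: float = 8.0
    sasa_probe: float = 1.4
    sasa_points: int = 960
    bsa_min: float = 10.0
    min_count_ec23: int = 5
    min_count_ec14: int = 4
    # classification
    icr_lo: float = 1.0
    icr_hi: float = 1.5
    ddg_lo: float = 0.5
    ddg_hi: float = 1.0
    # run
    outdir: str = "out"
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    d = Path(cfg.outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path}; run the '{producer}' stage first "
            f"or point the config at an existing input"
        )
    return path


def _validate(cfg: RunConfig, stages: list[str]) -> None:
    """Fail before any computation when a selected stage lacks its inputs."""
    if "classify" in stages and cfg.ddg_table is None:
        synth = Path(cfg.outdir) / "simulate" / "ddg_synthetic.tsv"
        if "simulate" not in stages and not synth.exists():
            raise PipelineError(
                "classify stage requires a ΔΔG table (config 'ddg_table') "
                "or a prior simulate stage"
            )
    if cfg.ddg_table is not None and "classify" in stages:
        if not Path(cfg.ddg_table).exists():
            raise PipelineError(f"ΔΔG table not found: {cfg.ddg_table}")
    for p in cfg.structures:
        if not Path(p).exists():
            raise PipelineError(f"structure file not found: {p}")
    if cfg.alignment is not None and not Path(cfg.alignment).exists():
        raise PipelineError(f"alignment file not found: {cfg.alignment}")


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig) -> None:
    out = _stage_dir(cfg, "simulate")
    msa_spec = OrthologParalogSpec(seed=cfg.seed)
    msa, classes = simulate_ortholog_paralog_msa(msa_spec)
    write_msa(msa, out / "ortholog_msa.fasta")
    pd.DataFrame(
        {"position": list(classes), "cls": [classes[p] for p in classes]}
    ).to_csv(out / "truth_classes.tsv", sep="\t", index=False)

    pairs = PlantedPottsSpec.random_pairs(L=50, n_pairs=10, seed=cfg.seed)
    potts_spec = PlantedPottsSpec(pairs=pairs, seed=cfg.seed + 1)
    potts = sample_potts(potts_spec)
    write_msa(potts, out / "potts_msa.fasta")
    pd.DataFrame(
        [(i, j, s) for i, j, s in pairs], columns=["i", "j", "strength"]
    ).to_csv(out / "planted_pairs.tsv", sep="\t", index=False, float_format="%.6g")

    toy_spec = ToyStructureSpec(seed=cfg.seed)
    ds, truth = build_toy_assembly(toy_spec)
    write_structure(ds, out / "toy_dimer.pdb")
    m = toy_spec.residues_per_repeat
    rows = []
    for res in truth["patch"]:
        rows.append({"chain": "A", "res_id": res, "ddg": 2.0 if res <= m else 0.2})
    pd.DataFrame(rows).to_csv(
        out / "ddg_synthetic.tsv", sep="\t", index=False, float_format="%.6g"
    )
    (out / "toy_truth.json").write_text(
        json.dumps(
            {k: truth[k] for k in ("tilt", "azimuth", "patch")}, sort_keys=True
        )
    )


def _load_alignment(cfg: RunConfig) -> LabeledMSA:
    if cfg.alignment is not None:
        return read_msa(cfg.alignment, format=cfg.alignment_format)
    path = _require(Path(cfg.outdir) / "simulate" / "ortholog_msa.fasta", "simulate")
    return read_msa(path)


def _stage_filter(cfg: RunConfig) -> None:
    out = _stage_dir(cfg, "filter")
    msa = _load_alignment(cfg)
    filtered = filter_msa(msa, cfg.max_seq_gap_frac, cfg.max_col_gap_frac)
    write_msa(filtered, out / "filtered.fasta")
    np.savetxt(
        out / "columns.tsv", filtered.columns, fmt="%d", header="column", comments=""
    )


def _read_filtered(cfg: RunConfig) -> LabeledMSA:
    path = _require(Path(cfg.outdir) / "filter" / "filtered.fasta", "filter")
    msa = read_msa(path)
    cols = np.loadtxt(Path(cfg.outdir) / "filter" / "columns.tsv", skiprows=1, dtype=int)
    msa.columns = np.atleast_1d(cols)
    return msa


def _stage_weights(cfg: RunConfig) -> dict:
    out = _stage_dir(cfg, "weights")
    msa = _read_filtered(cfg)
    weighted, neff = compute_weights(msa, cfg.identity_threshold, cfg.gap_mode)
    write_weights(weighted, neff, out / "weights.tsv")
    return {"neff": neff, "n_sequences": weighted.n_sequences}


def _stage_icr(cfg: RunConfig) -> dict:
    out = _stage_dir(cfg, "icr")
    msa = _read_filtered(cfg)
    subfamilies = cfg.subfamilies or sorted(
        {lab.subfamily for lab in msa.labels if lab.subfamily != "unknown"}
    )
    summary = {}
    for fam in subfamilies:
        profile = smooth_icr(normalize_icr(compute_icr(msa, fam)), cfg.window)
        profile.write_tsv(out / f"icr_{fam}.tsv")
        summary[fam] = float(np.nanmean(profile.icr_raw))
    return {"subfamily_mean_icr_raw": summary}


def _load_coupling_alignment(cfg: RunConfig) -> LabeledMSA:
    if cfg.coupling_alignment is not None:
        return read_msa(cfg.coupling_alignment, format=cfg.alignment_format)
    path = _require(Path(cfg.outdir) / "simulate" / "potts_msa.fasta", "simulate")
    return read_msa(path)


def _stage_plm(cfg: RunConfig) -> dict:
    out = _stage_dir(cfg, "plm")
    msa = _load_coupling_alignment(cfg)
    msa = filter_msa(msa, cfg.max_seq_gap_frac, cfg.max_col_gap_frac)
    weighted, neff = compute_weights(msa, cfg.identity_threshold, cfg.gap_mode)
    model = fit_plm(weighted, lambda_h=cfg.lambda_h, lambda_J=cfg.lambda_J)
    table = score_couplings(
        model, apc=True, min_separation=cfg.min_separation,
        max_position=cfg.max_position,
    )
    table.write_tsv(out / "couplings.tsv")
    return {"coupling_neff": neff, "n_pairs": len(table.pairs)}


def _structures(cfg: RunConfig):
    if cfg.structures:
        ranges = {
            chain: [tuple(r) for r in rr]
            for chain, rr in cfg.repeat_ranges.items()
        }
        return [
            read_structure(p, repeat_ranges=ranges or None) for p in cfg.structures
        ]
    path = _require(Path(cfg.outdir) / "simulate" / "toy_dimer.pdb", "simulate")
    m = ToyStructureSpec().residues_per_repeat
    ds = read_structure(
        path,
        repeat_ranges={
            "A": [("EC1", 1, m), ("EC2", m + 1, 2 * m)],
            "B": [("EC1", 1, m), ("EC2", m + 1, 2 * m)],
        },
        assembly=["A", "B"],
    )
    return [ds]


def _stage_geometry(cfg: RunConfig) -> dict:
    out = _stage_dir(cfg, "geometry")
    rows = []
    for ds in _structures(cfg):
        for chain, reps in ds.repeats.items():
            for (lab_a, *_), (lab_b, *_) in zip(reps, reps[1:]):
                tilt, az = inter_repeat_angles(
                    ds.ca_coords(chain, lab_a), ds.ca_coords(chain, lab_b)
                )
                rows.append(
                    {
                        "structure": ds.structure_id,
                        "chain": chain,
                        "repeat_a": lab_a,
                        "repeat_b": lab_b,
                        "tilt": tilt,
                        "azimuth": az,
                    }
                )
        cmap = contact_map(ds, cutoff=cfg.contact_cutoff)
        pd.DataFrame(
            sorted(
                (a[0], a[1], b[0], b[1]) for a, b in cmap.pairs
            ),
            columns=["chain_i", "res_i", "chain_j", "res_j"],
        ).to_csv(out / f"contacts_{ds.structure_id}.tsv", sep="\t", index=False)
    pd.DataFrame(rows).to_csv(
        out / "angles.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return {"n_repeat_pairs": len(rows)}


def _stage_interface(cfg: RunConfig) -> dict:
    out = _stage_dir(cfg, "interface")
    summary = {}
    for ds in _structures(cfg):
        table = interface_bsa(
            ds, probe=cfg.sasa_probe, n_points=cfg.sasa_points, bsa_min=cfg.bsa_min,
            radii=1.7 if ds.structure_id == "toy_dimer" else "single",
        )
        table.write_tsv(out / f"bsa_{ds.structure_id}.tsv")
        totals = table.totals()
        totals.to_csv(
            out / f"totals_{ds.structure_id}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        summary[ds.structure_id] = {
            f"{int(r['protomer'])}:{r['pair_label']}": float(r["bsa"])
            for _, r in totals.iterrows()
        }
    return {"interface_totals": summary}


def _stage_precision(cfg: RunConfig) -> dict:
    out = _stage_dir(cfg, "precision")
    coup_path = _require(Path(cfg.outdir) / "plm" / "couplings.tsv", "plm")
    from .coupling import CouplingTable

    table = CouplingTable(pairs=pd.read_csv(coup_path, sep="\t"))
    planted_path = Path(cfg.outdir) / "simulate" / "planted_pairs.tsv"
    if cfg.structures:
        truths = []
        for ds in _structures(cfg):
            cmap = contact_map(ds, cutoff=cfg.contact_cutoff, scope="intrachain")
            chain = ds.assembly[0]
            domain_of = {
                r: ds.repeat_of(chain, r) for r in ds.residue_ids(chain)
            }
            truths.append(cmap.to_truth(chain, domain_of))
    elif planted_path.exists():
        planted = pd.read_csv(planted_path, sep="\t")
        L = int(max(table.pairs["j"].max(), planted["j"].max()))
        truths = [
            ContactTruth(
                structure_id="planted",
                pairs={(int(r["i"]), int(r["j"])) for _, r in planted.iterrows()},
                resolved=set(range(1, L + 1)),
                domain_of=None,
            )
        ]
    else:
        raise PipelineError(
            "precision stage needs structures in the config or a prior "
            "simulate stage's planted pairs"
        )
    result = calibrate_precision(
        table,
        truths,
        min_separation=cfg.min_separation,
        max_position=cfg.max_position,
        precision_target=cfg.precision_target,
    )
    result.curve.to_csv(
        out / "precision_curve.tsv", sep="\t", index=False, float_format="%.6g"
    )
    result.selected.to_csv(
        out / "selected_pairs.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return {
        "threshold_rank": result.threshold_rank,
        "n_selected": len(result.selected),
    }


def _stage_classify(cfg: RunConfig) -> dict:
    out = _stage_dir(cfg, "classify")
    if cfg.ddg_table is not None:
        ddg = pd.read_csv(cfg.ddg_table, sep="\t")
    else:
        path = _require(
            Path(cfg.outdir) / "simulate" / "ddg_synthetic.tsv", "simulate"
        )
        ddg = pd.read_csv(path, sep="\t")
    icr_dir = Path(cfg.outdir) / "icr"
    icr_files = sorted(icr_dir.glob("icr_*.tsv")) if icr_dir.exists() else []
    if not icr_files:
        raise PipelineError("missing ICR profiles; run the 'icr' stage first")
    prof_df = pd.read_csv(icr_files[0], sep="\t")
    from .icr import ICRProfile

    profile = ICRProfile(
        subfamily=icr_files[0].stem.replace("icr_", ""),
        positions=prof_df["position"].values,
        pid_ortholog=prof_df["pid_ortholog"].values,
        pid_paralog=prof_df["pid_paralog"].values,
        icr_raw=prof_df["icr_raw"].values,
        icr_norm=prof_df["icr_norm"].values,
    )
    iface_dir = Path(cfg.outdir) / "interface"
    bsa_files = sorted(iface_dir.glob("bsa_*.tsv")) if iface_dir.exists() else []
    if not bsa_files:
        raise PipelineError("missing interface tables; run the 'interface' stage first")
    from .geometry import InterfaceTable

    table = InterfaceTable(
        structure_id=bsa_files[0].stem.replace("bsa_", ""),
        residues=pd.read_csv(bsa_files[0], sep="\t"),
        bsa_min=cfg.bsa_min,
    )
    thresholds = ClassThresholds(
        icr_lo=cfg.icr_lo, icr_hi=cfg.icr_hi, ddg_lo=cfg.ddg_lo, ddg_hi=cfg.ddg_hi
    )
    classes = classify_residues(profile, ddg, table, thresholds)
    classes.write_tsv(out / "classes.tsv")
    summary = region_summary(classes)
    summary.to_csv(out / "region_summary.tsv", sep="\t", index=False)
    return {
        "n_classified": len(classes.residues),
        "class_counts": classes.residues["cls"].value_counts().to_dict()
        if len(classes.residues)
        else {},
    }


def _stage_report(cfg: RunConfig, results: dict) -> dict:
    out = _stage_dir(cfg, "report")
    payload = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "results": results,
    }
    (out / "report.json").write_text(json.dumps(payload, sort_keys=True, indent=2, default=str))
    return {"report": str(out / "report.json")}


_STAGE_FUNCS = {
    "simulate": lambda cfg, res: _stage_simulate(cfg),
    "filter": lambda cfg, res: _stage_filter(cfg),
    "weights": lambda cfg, res: _stage_weights(cfg),
    "icr": lambda cfg, res: _stage_icr(cfg),
    "plm": lambda cfg, res: _stage_plm(cfg),
    "geometry": lambda cfg, res: _stage_geometry(cfg),
    "interface": lambda cfg, res: _stage_interface(cfg),
    "precision": lambda cfg, res: _stage_precision(cfg),
    "classify": lambda cfg, res: _stage_classify(cfg),
    "report": lambda cfg, res: _stage_report(cfg, res),
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Run the selected stages in dependency order; returns stage results.

    An empty stage list is a successful no-op.  Input validation happens
    before any stage executes; a stage whose upstream artifact is missing
    raises :class:`PipelineError` naming the stage to run first.
    """
    if stages is None:
        stages = list(STAGE_ORDER)
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGE_ORDER if s in set(stages)]
    if not ordered:
        return {}
    _validate(cfg, ordered)
    results: dict = {}
    for stage in ordered:
        logger.info("running stage %s", stage)
        out = _STAGE_FUNCS[stage](cfg, results)
        results[stage] = out if out is not None else {}
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": ordered,
        "config": yaml.safe_load(cfg.to_yaml()),
    }
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str)
    )
    return results
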