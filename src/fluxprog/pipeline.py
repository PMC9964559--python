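"""End-to-end pipeline orchestration and the on-disk table contracts.

Stages (each also exposed as a CLI subcommand): cohort filtering -> flux
estimation -> prognostic reactions -> correlation modules -> pair scan +
subtype summary -> differential flux -> WDA pathway scores.  Every stage
writes a deterministic TSV/JSON artifact; a manifest records config hash,
seeds and per-stage row counts so identical configs reproduce identical
outputs byte for byte.

Input table contracts (all tab-separated with headers)
------------------------------------------------------
expression.tsv   gene_id, then one column per sample (FPKM)
kinetics.tsv     reaction_id, kcat_f, kcat_b[, source]
clinical.tsv     sample_id, time_months, event, idh1_mutant
uptake.tsv       reaction_id, lb, ub  (exchange bounds, negative lb = uptake)

To run on a public cohort instead of a synthetic one, export the FPKM
matrix from the GDC and the clinical/mutation table from cBioPortal into
exactly these layouts; no downloader is bundled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ValidationError
from .gpmm_flux import GpmmConfig, gpmm_flux_matrix, read_kinetics_tsv, validate_expression
from .network_io import apply_medium, read_model, read_uptake_tsv
from .prognostic_modules import (
    differential_flux,
    extract_modules,
    find_prognostic_reactions,
    wda_scores,
)
from .subtyping import GOOD, assign_subtype, scan_pairs, summarize_subtype, _oriented_fluxes
from .survival_stats import SurvivalRecord

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

__all__ = ["PipelineConfig", "run_pipeline", "load_clinical_tsv", "load_expression_tsv"]


@dataclass
class PipelineConfig:
    model_path: str = ""
    model_format: str = "json"
    expression_path: str = ""
    kinetics_path: str = ""
    clinical_path: str = ""
    uptake_path: str = ""
    outdir: str = "results"
    gpmm: GpmmConfig = field(default_factory=GpmmConfig)
    alpha_prognosis: float = 0.01
    alpha_diff: float = 0.01
    r_threshold: float = 0.8
    min_neighbors: int = 1
    min_group_size: int = 5
    exclude_idh1_mutant: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_prognosis", "alpha_diff", "r_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValidationError(f"{name} must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        gpmm = GpmmConfig(**doc.pop("gpmm", {}))
        return cls(gpmm=gpmm, **doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return validate_expression(df)


def load_clinical_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_months", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"clinical table must have columns {sorted(required)}")
    if "idh1_mutant" not in df.columns:
        df["idh1_mutant"] = 0
    return df


def _survival_records(clinical: pd.DataFrame) -> list[SurvivalRecord]:
    recs = []
    n_dropped = 0
    for row in clinical.itertuples():
        try:
            time = float(row.time_months)
            event = int(row.event)
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if pd.isna(time) or time <= 0 or event not in (0, 1):
            n_dropped += 1
            continue
        recs.append(SurvivalRecord(str(row.sample_id), time, event))
    if n_dropped:
        logger.info("dropped %d samples with missing/invalid survival", n_dropped)
    return recs


# ---------------------------------------------------------------------------
# Stage runners (each reads upstream artifacts, writes one artifact)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> int:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
    return len(df)


def stage_filter_cohort(config: PipelineConfig, outdir: Path) -> dict:
    expr = load_expression_tsv(config.expression_path)
    clinical = load_clinical_tsv(config.clinical_path)
    n_before = len(clinical)
    if config.exclude_idh1_mutant:
        mutant = clinical["idh1_mutant"].fillna(0).astype(int) == 1
        clinical = clinical[~mutant]
        logger.info("excluded %d IDH1-mutant samples", int(mutant.sum()))
    keep = [s for s in expr.columns if s in set(clinical["sample_id"].astype(str))]
    expr = expr[keep]
    clinical = clinical[clinical["sample_id"].astype(str).isin(keep)]
    _write_tsv(clinical, outdir / "cohort.tsv", index=False)
    expr.to_csv(outdir / "expression_filtered.tsv", sep="\t", float_format=FLOAT_FMT)
    return {"n_input": n_before, "n_kept": len(clinical)}


def stage_fluxes(config: PipelineConfig, outdir: Path) -> dict:
    network = read_model(config.model_path, format=config.model_format)
    if config.uptake_path:
        network = apply_medium(network, read_uptake_tsv(config.uptake_path))
    expr = load_expression_tsv(outdir / "expression_filtered.tsv")
    kinetics = read_kinetics_tsv(config.kinetics_path)
    flux = gpmm_flux_matrix(network, expr, kinetics, config.gpmm)
    n = _write_tsv(flux, outdir / "flux_matrix.tsv")
    subsystems = pd.DataFrame(
        {"reaction_id": [r.id for r in network.reactions],
         "subsystem": [r.subsystem for r in network.reactions]}
    )
    _write_tsv(subsystems, outdir / "subsystems.tsv", index=False)
    return {"n_reactions": n, "n_samples": flux.shape[1]}


def _read_flux(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "flux_matrix.tsv", sep="\t", index_col=0)


def _read_survival(outdir: Path) -> list[SurvivalRecord]:
    return _survival_records(load_clinical_tsv(outdir / "cohort.tsv"))


def stage_prognosis(config: PipelineConfig, outdir: Path) -> dict:
    flux = _read_flux(outdir)
    surv = _read_survival(outdir)
    prog = find_prognostic_reactions(flux, surv, alpha=config.alpha_prognosis)
    df = pd.DataFrame(
        [
            {"reaction_id": p.reaction_id, "logrank_p": p.logrank_p,
             "direction": p.direction, "log_hr": p.log_hr}
            for p in prog
        ],
        columns=["reaction_id", "logrank_p", "direction", "log_hr"],
    ).sort_values("reaction_id")
    n = _write_tsv(df, outdir / "prognostic_reactions.tsv", index=False)
    return {"n_prognostic": n}


def _read_prognosis(outdir: Path):
    from .prognostic_modules import ReactionPrognosis

    df = pd.read_csv(outdir / "prognostic_reactions.tsv", sep="\t")
    return [
        ReactionPrognosis(str(r.reaction_id), float(r.logrank_p),
                          int(r.direction), float(r.log_hr))
        for r in df.itertuples()
    ]


def stage_modules(config: PipelineConfig, outdir: Path) -> dict:
    flux = _read_flux(outdir)
    prog = _read_prognosis(outdir)
    modules = extract_modules(
        flux, prog, r_threshold=config.r_threshold, min_neighbors=config.min_neighbors
    )
    rows = [
        {"module_id": m.module_id, "member": member, "direction": m.direction,
         "representative": m.representative, "mixed_direction": int(m.mixed_direction)}
        for m in modules
        for member in m.members
    ]
    df = pd.DataFrame(rows, columns=["module_id", "member", "direction",
                                     "representative", "mixed_direction"])
    _write_tsv(df, outdir / "modules.tsv", index=False)
    return {"n_modules": len(modules)}


def _read_modules(outdir: Path):
    from .prognostic_modules import FluxModule

    df = pd.read_csv(outdir / "modules.tsv", sep="\t")
    modules = []
    for mid, grp in df.groupby("module_id", sort=True):
        modules.append(
            FluxModule(
                module_id=str(mid),
                members=sorted(grp["member"].astype(str)),
                direction=int(grp["direction"].iloc[0]),
                representative=str(grp["representative"].iloc[0]),
                mixed_direction=bool(grp["mixed_direction"].iloc[0]),
            )
        )
    return modules


def stage_subtype(config: PipelineConfig, outdir: Path) -> dict:
    flux = _read_flux(outdir)
    surv = _read_survival(outdir)
    modules = _read_modules(outdir)
    if len(modules) < 2:
        logger.warning("fewer than 2 modules; subtype stage writes empty outputs")
        _write_tsv(pd.DataFrame(columns=["pair", "module_a", "module_b", "n_good",
                                         "n_bad", "hazard_ratio", "logrank_p"]),
                   outdir / "pair_scan.tsv", index=False)
        _write_tsv(pd.DataFrame(columns=["sample_id", "label", "flux_pos", "flux_neg"]),
                   outdir / "subtype_assignments.tsv", index=False)
        (outdir / "subtype_summary.json").write_text("{}\n")
        return {"n_pairs": 0}
    scan = scan_pairs(modules, flux, surv, min_group_size=config.min_group_size)
    _write_tsv(scan, outdir / "pair_scan.tsv", index=False)
    if len(scan) == 0:
        _write_tsv(pd.DataFrame(columns=["sample_id", "label", "flux_pos", "flux_neg"]),
                   outdir / "subtype_assignments.tsv", index=False)
        (outdir / "subtype_summary.json").write_text("{}\n")
        return {"n_pairs": 0}

    best = scan.iloc[0]
    by_id = {m.module_id: m for m in modules}
    mod_a, mod_b = by_id[best.module_a], by_id[best.module_b]
    fpos, fneg = _oriented_fluxes(mod_a, mod_b, flux)
    labels = assign_subtype(fpos.to_dict(), fneg.to_dict())
    assign_df = pd.DataFrame(
        {
            "sample_id": list(labels),
            "label": [labels[s] for s in labels],
            "flux_pos": [fpos[s] for s in labels],
            "flux_neg": [fneg[s] for s in labels],
        }
    ).sort_values("sample_id")
    _write_tsv(assign_df, outdir / "subtype_assignments.tsv", index=False)
    summary = summarize_subtype(labels, surv)
    summary["pair"] = str(best.pair)
    with open(outdir / "subtype_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"n_pairs": len(scan), "best_pair": str(best.pair)}


def stage_diff(config: PipelineConfig, outdir: Path) -> dict:
    flux = _read_flux(outdir)
    assign = pd.read_csv(outdir / "subtype_assignments.tsv", sep="\t")
    groups = {
        str(r.sample_id): ("high" if r.label == GOOD else "low")
        for r in assign.itertuples()
        if r.label != "other"
    }
    if len(set(groups.values())) < 2 or len(groups) < 4:
        logger.warning("no usable subtype contrast; diff stage writes empty output")
        _write_tsv(pd.DataFrame(columns=["reaction_id", "log2fc", "t_moderated",
                                         "p_value", "p_adj_bh", "significant",
                                         "scale", "prior_df"]),
                   outdir / "differential_flux.tsv", index=False)
        return {"n_tested": 0}
    diff = differential_flux(flux, groups, alpha=config.alpha_diff)
    n = _write_tsv(diff, outdir / "differential_flux.tsv")
    return {"n_tested": n, "n_significant": int(diff["significant"].sum())}


def stage_wda(config: PipelineConfig, outdir: Path) -> dict:
    diff = pd.read_csv(outdir / "differential_flux.tsv", sep="\t", index_col=0)
    subsystems = pd.read_csv(outdir / "subsystems.tsv", sep="\t")
    submap = {
        str(r.reaction_id): str(r.subsystem)
        for r in subsystems.itertuples()
        if isinstance(r.subsystem, str) and r.subsystem
    }
    if len(diff) == 0:
        wda = pd.DataFrame(
            {"subsystem": sorted(set(submap.values())), "n_fluxes": 0,
             "n_increased": 0, "n_decreased": 0, "weight": 0.0, "wda": 0.0}
        ).set_index("subsystem")
    else:
        diff["significant"] = diff["significant"].astype(bool)
        wda = wda_scores(diff, submap)
    n = _write_tsv(wda, outdir / "wda.tsv")
    return {"n_pathways": n}


STAGES = [
    ("filter_cohort", stage_filter_cohort),
    ("fluxes", stage_fluxes),
    ("prognosis", stage_prognosis),
    ("modules", stage_modules),
    ("subtype", stage_subtype),
    ("diff", stage_diff),
    ("wda", stage_wda),
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; returns (and writes) the run manifest.

    A stage failure is recorded in the manifest and re-raised; artifacts of
    completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    try:
        for name, fn in STAGES:
            logger.info("stage %s ...", name)
            manifest["stages"][name] = fn(config, outdir)
    except Exception as exc:
        manifest["failed_stage"] = name
        manifest["error"] = str(exc)
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
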