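"""End-to-end orchestration: filter → profile → fit → loads → statistics →
subgroups → pathway projection, from a single YAML config, with a
machine-readable run manifest (versions, seeds, input checksums, per-stage
row counts). Layers whose inputs are absent are skipped and noted in the
manifest, so SNP-only runs are valid.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .loads import SeverityMap, patient_loads
from .maf import DEFAULT_DIALECT, read_maf, run_filters, write_maf
from .profiles import build_patient_profiles, profile_matrix
from .signatures import SignatureRefit, default_catalog, load_signature_catalog
from .stats import (
    assign_age_groups,
    gene_wise_age_correlation,
    local_median_curve,
    stratified_age_correlation,
)
from .subgroups import (
    characterize_subgroups,
    classify_signature_subgroups,
    gene_level_matrices,
    pathway_age_correlation,
    pathway_subgroup_tests,
    project_pathways,
    read_gmt,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs, options and output location for a full pipeline run.

    Statistical constants default to the analysis' standard settings
    (B=1000 bootstrap replicates, FDR threshold 0.2, ±10-year local-median
    window, cohort-mean subgroup thresholds on SI6/SI26) and are all
    overridable from the YAML file.
    """

    maf: str
    clinical: str
    out_dir: str
    cnv: str | None = None
    methylation: str | None = None
    catalog: str | None = None
    gmt: str | None = None
    severity_map: str | None = None
    excluded_patients: list[str] = field(default_factory=list)
    subgroup_signatures: tuple[str, str] = ("SI6", "SI26")
    bootstrap_replicates: int = 1000
    fdr_threshold: float = 0.2
    local_median_halfwidth: float = 10.0
    ssgsea_alpha: float = 0.25
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        for name in ("maf", "clinical", "cnv", "methylation", "catalog", "gmt", "severity_map"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                problems.append(f"{name} path does not exist: {value}")
        if not 0.0 < self.fdr_threshold < 1.0:
            problems.append(f"fdr_threshold must be in (0,1), got {self.fdr_threshold}")
        if problems:
            raise ValueError("invalid RunConfig: " + "; ".join(problems))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage whose inputs are present; return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "luscage_version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "skipped": [],
        "tables": {},
    }
    for name in ("maf", "clinical", "cnv", "methylation", "catalog", "gmt", "severity_map"):
        value = getattr(config, name)
        if value is not None:
            manifest["inputs"][name] = {"path": str(value), "sha256": _sha256(value)}

    def emit(name: str, frame: pd.DataFrame, **to_csv_kwargs) -> None:
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", **to_csv_kwargs)
        manifest["tables"][name] = {"path": str(path), "rows": int(len(frame))}

    severity = SeverityMap.from_yaml(config.severity_map) if config.severity_map else SeverityMap()

    # --- filtering -------------------------------------------------------
    records, n_dropped = read_maf(config.maf, DEFAULT_DIALECT)
    records, report = run_filters(records, tuple(config.excluded_patients))
    write_maf(records, out / "filtered.maf")
    report_dict = report.to_dict()
    report_dict["n_unparseable_rows"] = n_dropped
    with open(out / "filter_report.json", "w") as fh:
        json.dump(report_dict, fh, indent=2)
    manifest["stages"]["filtering"] = report_dict

    clinical = pd.read_csv(config.clinical, sep="\t", index_col="patient_id")
    ages = clinical["age_years"]

    # --- profiles and exposures -----------------------------------------
    profiles = profile_matrix(build_patient_profiles(records))
    emit("profiles_96", profiles)
    catalog = load_signature_catalog(config.catalog) if config.catalog else default_catalog()
    refit = SignatureRefit(profiles, catalog).fit()
    emit("exposures", refit.exposures, float_format="%.6g")
    emit("exposure_diagnostics", refit.diagnostics, float_format="%.6g")
    manifest["stages"]["refitting"] = {
        "patients": int(len(refit.exposures)),
        "median_reconstruction_cosine": float(
            refit.diagnostics["reconstruction_cosine"].median()
        ),
    }

    # --- loads -----------------------------------------------------------
    cnv = _read_matrix(config.cnv) if config.cnv else None
    methylation = _read_matrix(config.methylation) if config.methylation else None
    if cnv is None:
        manifest["skipped"].append("cnv")
    if methylation is None:
        manifest["skipped"].append("methylation")
    loads = patient_loads(records, clinical, cnv, methylation, severity)
    emit("patient_loads", loads, float_format="%.6g")

    # --- age associations ------------------------------------------------
    B, seed = config.bootstrap_replicates, config.seed
    assoc_frames = []
    load_cols = [c for c in ("snp_load", "disrupted_gene_count", "cnv_load",
                             "methylation_change_rate") if c in loads.columns]
    for i, col in enumerate(load_cols):
        table = stratified_age_correlation(
            loads[col], ages.reindex(loads.index),
            loads["tobacco_smoking_history_indicator"].reindex(loads.index)
            if "tobacco_smoking_history_indicator" in loads.columns else ["all"] * len(loads),
            B=B, seed=seed + 100 * i,
        )
        table.insert(0, "load", col)
        assoc_frames.append(table)
    emit("age_associations", pd.concat(assoc_frames), float_format="%.6g")

    curves = {}
    for col in load_cols:
        ok = loads[col].notna()
        curve = local_median_curve(
            ages.reindex(loads.index)[ok], loads.loc[ok, col],
            halfwidth=config.local_median_halfwidth, B=B, seed=seed,
        )
        curves[col] = curve.to_frame().assign(load=col)
    emit("local_median_curves", pd.concat(curves.values()), index=False, float_format="%.6g")

    sig_ages = ages.reindex(refit.exposures.index)
    sig_assoc = gene_wise_age_correlation(refit.exposures.T, sig_ages, ci=True, B=B, seed=seed)
    sig_assoc.index.name = "signature"
    emit("signature_age_associations", sig_assoc, float_format="%.6g")
    manifest["stages"]["associations"] = {"families": len(load_cols) + 1}

    # --- subgroups --------------------------------------------------------
    sig_a, sig_b = config.subgroup_signatures
    labels = classify_signature_subgroups(refit.exposures, sig_a, sig_b)
    emit("subgroup_labels", labels)
    discordant = (f"low-{sig_a}/high-{sig_b}", f"high-{sig_a}/low-{sig_b}")
    comparison = characterize_subgroups(
        labels["label"], *discordant,
        continuous=loads[["snp_load", *[c for c in ("cnv_load", "methylation_change_rate")
                                        if c in loads.columns]]].join(ages),
        categorical=clinical[[c for c in ("tobacco_smoking_history_indicator",
                                          "transversion_status")
                              if c in clinical.columns]],
    )
    emit("subgroup_comparison", comparison, float_format="%.6g")
    manifest["stages"]["subgroups"] = {
        "sizes": labels["label"].value_counts().to_dict()
    }

    # --- pathway projection ----------------------------------------------
    if config.gmt:
        gene_sets = read_gmt(config.gmt)
        matrices = gene_level_matrices(records, cnv, methylation, severity)
        scores = project_pathways(matrices, gene_sets, alpha=config.ssgsea_alpha)
        pathway_stage = {}
        for layer, score in scores.items():
            emit(f"ssgsea_{layer}", score, float_format="%.6g")
            tests = pathway_subgroup_tests(score, labels["label"], *discordant)
            emit(f"ssgsea_{layer}_subgroup_tests", tests, float_format="%.6g")
            corr = pathway_age_correlation(score, ages, B=B, seed=seed)
            emit(f"ssgsea_{layer}_age_correlation", corr, float_format="%.6g")
            pathway_stage[layer] = int(len(score))
        manifest["stages"]["pathways"] = pathway_stage
    else:
        manifest["skipped"].append("pathways")

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
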