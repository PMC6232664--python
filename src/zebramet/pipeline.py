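"""End-to-end pipeline: simulate/load -> QC filter -> normalize -> block
correction -> exogenous exclusion -> PCA -> paired PLS-DA -> Venn partition.

The stage order is fixed.  Every intermediate table and report is written
to the output directory as CSV, together with a machine-readable run
manifest (package version, config hash, seed, per-stage summaries).  QC
pools flow through filtering and normalization, are passed through block
correction unchanged, and are excluded from exclusion correlations and
PLS-DA; they appear in the all-sample PCA only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from . import __version__
from .block_correction import apply_block_correction, compute_block_factors
from .data_model import (
    FeatureTable,
    read_compound_list,
    read_feature_table,
    write_feature_table,
)
from .exogenous_exclusion import exclude_exogenous, load_default_compounds
from .marker_selection import run_paired_models, venn_partition
from .multivariate import pca
from .preprocess import (
    autoscale,
    filter_by_qc_rsd,
    pqn_normalize,
    total_area_normalize,
)
from .synthetic_data import SimulationConfig, simulate_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, stage parameters, and output location for one run.

    Provide either the two input CSV paths or ``simulation``; thresholds
    default to the analysis conventions (RSD 0.3, 5 ppm, r 0.9, VIP 1.0).
    """

    out_dir: str = "zebramet_run"
    intensity_csv: Optional[str] = None
    sample_meta_csv: Optional[str] = None
    compounds_csv: Optional[str] = None  # default: shipped screening list
    simulation: Optional[SimulationConfig] = None
    rsd_threshold: float = 0.3
    ppm_tol: float = 5.0
    r_threshold: float = 0.9
    vip_threshold: float = 1.0
    pqn_reference: str = "median_all"
    pca_components: int = 2
    pls_components: int = 5
    drugs: tuple[str, ...] = ("paracetamol", "tdf", "tfv")
    seed: int = 1

    def validate(self) -> None:
        have_files = self.intensity_csv is not None and self.sample_meta_csv is not None
        if not have_files and self.simulation is None:
            raise ValueError(
                "config must provide input CSVs or a simulation block"
            )
        for name in ("rsd_threshold", "ppm_tol", "r_threshold", "vip_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _config_dict(config: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    return d


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_config_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _block_silhouette(table: FeatureTable) -> float:
    """Mean silhouette of extraction-block labels in PC1-2 score space of
    the biological samples: the 'is the block effect visible?' diagnostic."""
    from sklearn.metrics import silhouette_score

    bio = table.subset(sample_filter=lambda s: s.is_biological)
    blocks = [s.block for s in bio.samples]
    if len(set(blocks)) < 2:
        return float("nan")
    X = autoscale(bio.intensities.T).scaled
    model = pca(X, n_components=2)
    return float(silhouette_score(model.scores, blocks))


@dataclass
class PipelineResult:
    table: FeatureTable  # final table (filtered, normalized, corrected, excluded)
    manifest: dict[str, Any]
    out_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see the module docstring for the order."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "zebramet",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": _config_dict(config),
        "stages": {},
    }
    stages = manifest["stages"]

    # -- input -----------------------------------------------------------
    truth = None
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        table, truth = simulate_table(sim)
        write_feature_table(
            table, out / "simulated_intensities.csv", out / "sample_metadata.csv"
        )
        pd.DataFrame(
            {"feature_id": truth.feature_ids,
             "truth_label": [truth.labels[f] for f in truth.feature_ids]}
        ).to_csv(out / "truth_labels.csv", index=False)
        stages["input"] = {"source": "simulation",
                           "n_features": table.n_features,
                           "n_samples": table.n_samples}
    else:
        table = read_feature_table(config.intensity_csv, config.sample_meta_csv)
        stages["input"] = {"source": "files",
                           "n_features": table.n_features,
                           "n_samples": table.n_samples}

    # -- QC RSD filter ---------------------------------------------------
    table, rsd_report = filter_by_qc_rsd(table, threshold=config.rsd_threshold)
    rsd_report.to_csv(out / "rsd_report.csv", index=False)
    stages["qc_filter"] = {
        "threshold": config.rsd_threshold,
        "n_removed": int((~rsd_report["keep"]).sum()),
        "n_kept": table.n_features,
    }

    # -- normalization ---------------------------------------------------
    table = total_area_normalize(table)
    table, pqn_report = pqn_normalize(table, reference=config.pqn_reference)
    pqn_report.dilution.rename_axis("sample_id").reset_index().to_csv(
        out / "pqn_dilution.csv", index=False
    )
    stages["normalize"] = {
        "pqn_reference": config.pqn_reference,
        "n_usable_features": pqn_report.n_usable_features,
    }

    # -- block correction ------------------------------------------------
    sil_before = _block_silhouette(table)
    factors = compute_block_factors(table)
    table = apply_block_correction(table, factors)
    factors.to_frame().rename_axis("feature_id").reset_index().to_csv(
        out / "block_factors.csv", index=False
    )
    sil_after = _block_silhouette(table)
    stages["block_correction"] = {
        "n_blocks": len(factors.block_ids),
        "block_silhouette_before": sil_before,
        "block_silhouette_after": sil_after,
    }

    # -- exogenous exclusion ----------------------------------------------
    if config.compounds_csv is not None:
        compounds = read_compound_list(config.compounds_csv)
    elif truth is not None:
        compounds = truth.compounds
    else:
        compounds = load_default_compounds()
    table, excl = exclude_exogenous(
        table, compounds, ppm_tol=config.ppm_tol, r_threshold=config.r_threshold
    )
    pd.DataFrame(
        [
            {"feature_id": fid, "step": 1, "detail": m.compound,
             "adduct": m.adduct, "isotope": m.isotope, "ppm": m.ppm}
            for fid, m in excl.step1.items()
        ]
        + [
            {"feature_id": fid, "step": 2, "detail": anchor,
             "adduct": "", "isotope": "", "ppm": r}
            for fid, (anchor, r) in excl.step2.items()
        ]
    ).to_csv(out / "exclusion_report.csv", index=False)
    stages["exogenous_exclusion"] = {
        "n_step1": len(excl.step1),
        "n_step2": len(excl.step2),
        "n_excluded": len(excl.excluded_ids),
        "n_surviving": excl.n_surviving,
    }
    write_feature_table(
        table, out / "final_intensities.csv", out / "final_sample_metadata.csv"
    )

    # -- PCA ---------------------------------------------------------------
    pca_block: dict[str, Any] = {}
    for scope, pred in (
        ("all_samples", None),
        ("biological", lambda s: s.is_biological),
    ):
        sub = table.subset(sample_filter=pred) if pred else table
        X = autoscale(sub.intensities.T).scaled
        k = min(config.pca_components, *X.shape)
        model = pca(X, n_components=k)
        pd.DataFrame(
            model.scores,
            index=sub.sample_ids,
            columns=[f"PC{a + 1}" for a in range(k)],
        ).rename_axis("sample_id").reset_index().to_csv(
            out / f"pca_scores_{scope}.csv", index=False
        )
        pca_block[scope] = {
            "explained_pct": [
                round(float(f) * 100, 3)
                for f in model.explained_variance_fraction
            ]
        }
    stages["pca"] = pca_block

    # -- paired PLS-DA + Venn ---------------------------------------------
    specs = run_paired_models(
        table,
        drugs=list(config.drugs),
        vip_threshold=config.vip_threshold,
        n_components=config.pls_components,
    )
    # control-vs-tier diagnostics, logged but not used for the Venn
    diag = run_paired_models(
        table,
        drugs=list(config.drugs),
        pairs=(("control", "lc10"), ("control", "half_lc10")),
        vip_threshold=config.vip_threshold,
        n_components=config.pls_components,
    )
    stages["plsda"] = {
        f"{s.drug}:{s.group_a}-vs-{s.group_b}": {
            "n_samples": s.n_samples,
            "r2y_comp1": round(s.r2y1, 4),
            "n_selected": len(s.selected),
        }
        for s in specs + diag
    }
    rows = []
    for s in specs:
        vip1 = s.model.vip if s.model.n_components == 1 else None
        for fid in sorted(s.selected):
            rows.append({"drug": s.drug, "feature_id": fid})
    pd.DataFrame(rows).to_csv(out / "selected_features.csv", index=False)

    selections = {s.drug: s.selected for s in specs}
    if len(selections) >= 2:
        venn = venn_partition(selections)
        venn_rows = [
            {"region": "common", "feature_id": fid} for fid in sorted(venn.common)
        ]
        for d, ids in venn.specific.items():
            venn_rows += [
                {"region": f"specific:{d}", "feature_id": fid}
                for fid in sorted(ids)
            ]
        for pair, ids in venn.shared_pairs.items():
            venn_rows += [
                {"region": "shared:" + "+".join(pair), "feature_id": fid}
                for fid in sorted(ids)
            ]
        pd.DataFrame(venn_rows).to_csv(out / "venn_partition.csv", index=False)
        stages["venn"] = {
            "common": len(venn.common),
            **{f"specific:{d}": len(ids) for d, ids in venn.specific.items()},
            **{
                "shared:" + "+".join(p): len(ids)
                for p, ids in venn.shared_pairs.items()
            },
        }
        if truth is not None:
            stages["recovery"] = _recovery_metrics(venn, selections, truth, excl)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline finished; manifest at %s", manifest_path)
    return PipelineResult(table=table, manifest=manifest, out_dir=out)


def _recovery_metrics(venn, selections, truth, excl) -> dict[str, float]:
    """Ground-truth recovery rates for a simulated run."""
    common = set(truth.common_ids)
    out: dict[str, float] = {}
    if common:
        out["common_sensitivity"] = len(venn.common & common) / len(common)
    spec_hits = spec_total = 0
    for drug, ids in truth.specific_ids.items():
        if drug in venn.specific:
            spec_hits += len(venn.specific[drug] & set(ids))
            spec_total += len(ids)
    if spec_total:
        out["specific_sensitivity"] = spec_hits / spec_total
    background = set(truth.background_ids)
    if background:
        out["background_common_rate"] = len(venn.common & background) / len(
            background
        )
    parents, sats = set(truth.parent_ids), set(truth.satellite_ids)
    if parents:
        out["parent_removal_rate"] = len(excl.excluded_ids & parents) / len(parents)
    if sats:
        out["satellite_removal_rate"] = len(excl.excluded_ids & sats) / len(sats)
    if background:
        out["background_exclusion_rate"] = len(excl.excluded_ids & background) / len(
            background
        )
    endo = background | common | set().union(
        *truth.specific_ids.values()
    ) if truth.specific_ids else background | common
    if endo:
        out["endogenous_exclusion_rate"] = len(excl.excluded_ids & endo) / len(endo)
    return out
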