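"""Shared fixtures: small hand-built tables and a 20-seed simulation study.

The multi-seed study runs the full analysis chain (simulate -> QC filter ->
total-area -> PQN -> block correction -> exogenous exclusion -> paired
PLS-DA -> Venn) once per seed and records every ground-truth recovery
metric; the session-scoped fixture is shared by the property and
acceptance tests so the chain runs only once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from zebramet import (
    FeatureMeta,
    FeatureTable,
    SampleMeta,
    SimulationConfig,
    apply_block_correction,
    compute_block_factors,
    exclude_exogenous,
    filter_by_qc_rsd,
    pqn_normalize,
    run_paired_models,
    simulate_table,
    total_area_normalize,
    venn_partition,
)

N_STUDY_SEEDS = 20
EFFECT_DRUGS = ("paracetamol", "tdf", "tfv")


def make_table(matrix, sample_meta=None, mz=None) -> FeatureTable:
    """A small table with minimal metadata for unit tests."""
    matrix = np.asarray(matrix, dtype=float)
    nf, ns = matrix.shape
    if sample_meta is None:
        sample_meta = [
            SampleMeta(f"S{i + 1}", "biological", block=1) for i in range(ns)
        ]
    features = [
        FeatureMeta(f"F{j + 1}", mz=(mz[j] if mz is not None else 100.0 + j), rt=60.0)
        for j in range(nf)
    ]
    return FeatureTable(matrix, features, sample_meta)


@dataclass
class StudyMetrics:
    """Everything one simulated end-to-end analysis reveals about recovery."""

    seed: int
    n_bio: int
    n_qc: int
    unstable_rsd: np.ndarray  # empirical QC RSD of injected unstable features
    stable_rsd: np.ndarray  # empirical QC RSD of all other features
    satellite_corr: np.ndarray  # raw satellite-parent r over exposed samples
    pqn_dilution_r: float  # corr(estimated quotient, true dilution), biological
    block_factor_r: float  # corr(estimated, true) block factors across features
    parent_removal: float
    satellite_removal: float
    background_exclusion: float
    common_sensitivity: float
    specific_sensitivity: float
    background_common_rate: float
    r2y1: dict  # drug -> component-1 r2y of the lc10-vs-half model
    separation_ok: dict  # drug -> component-1 scores separate with no overlap
    n_selected: dict  # drug -> VIP>1 selection size
    venn_sizes: dict


def run_study(seed: int) -> StudyMetrics:
    table, truth = simulate_table(SimulationConfig(seed=seed))
    bio_mask = table.sample_mask(lambda s: s.is_biological)
    qc_mask = ~bio_mask

    # empirical QC RSD per feature, before any filtering
    qc = table.intensities[:, qc_mask]
    rsd = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    unstable = np.array([f.truth_label == "unstable" for f in table.features])

    # raw satellite-parent correlations over the samples where the parent
    # is present (exposed samples for drug compounds, all biological for
    # buffer-type compounds)
    sat_r = []
    for sat, par in truth.satellite_parent.items():
        ps = table.intensities[table.feature_index(par), bio_mask]
        ss = table.intensities[table.feature_index(sat), bio_mask]
        scope = ps > 0
        sat_r.append(np.corrcoef(ps[scope], ss[scope])[0, 1])

    filtered, _ = filter_by_qc_rsd(table)

    # PQN dilution recovery, measured on data that still carries dilution
    _, pqn_direct = pqn_normalize(filtered)
    est = pqn_direct.dilution
    tru = np.array([truth.dilution[s.sample_id] for s in filtered.samples])
    fb = filtered.sample_mask(lambda s: s.is_biological)
    pqn_r = float(np.corrcoef(est.to_numpy()[fb], tru[fb])[0, 1])

    normalized = total_area_normalize(filtered)
    normalized, _ = pqn_normalize(normalized)
    factors = compute_block_factors(normalized)
    tr_idx = {f: j for j, f in enumerate(truth.feature_ids)}
    tru_bf = np.vstack(
        [truth.block_factors[tr_idx[f]] for f in normalized.feature_ids]
    )
    block_r = float(
        np.corrcoef(factors.factors.ravel(), tru_bf.ravel())[0, 1]
    )
    corrected = apply_block_correction(normalized, factors)

    final, excl = exclude_exogenous(corrected, truth.compounds)
    parents = set(truth.parent_ids)
    sats = set(truth.satellite_ids)
    background = set(truth.background_ids) & set(corrected.feature_ids)
    removed = excl.excluded_ids

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        specs = run_paired_models(final, ["gentamicin", *EFFECT_DRUGS])
    r2y1 = {s.drug: s.r2y1 for s in specs}
    separation = {}
    for s in specs:
        t1 = s.model.scores[:, 0]
        grp = np.array(
            [lab == s.group_a for lab in _pair_labels(final, s)]
        )
        separation[s.drug] = (t1[grp].min() > t1[~grp].max()) or (
            t1[~grp].min() > t1[grp].max()
        )
    venn = venn_partition({s.drug: s.selected for s in specs if s.drug != "gentamicin"})

    common = set(truth.common_ids)
    spec_hits = sum(
        len(venn.specific[d] & set(truth.specific_ids[d])) for d in EFFECT_DRUGS
    )
    spec_total = sum(len(truth.specific_ids[d]) for d in EFFECT_DRUGS)
    bg_final = set(truth.background_ids) & set(final.feature_ids)

    return StudyMetrics(
        seed=seed,
        n_bio=int(bio_mask.sum()),
        n_qc=int(qc_mask.sum()),
        unstable_rsd=rsd[unstable],
        stable_rsd=rsd[~unstable],
        satellite_corr=np.array(sat_r),
        pqn_dilution_r=pqn_r,
        block_factor_r=block_r,
        parent_removal=len(removed & parents) / len(parents),
        satellite_removal=len(removed & sats) / len(sats),
        background_exclusion=len(removed & background) / len(background),
        common_sensitivity=len(venn.common & common) / len(common),
        specific_sensitivity=spec_hits / spec_total,
        background_common_rate=len(venn.common & bg_final) / len(bg_final),
        r2y1=r2y1,
        separation_ok=separation,
        n_selected={s.drug: len(s.selected) for s in specs},
        venn_sizes={
            "common": len(venn.common),
            **{d: len(venn.specific[d]) for d in EFFECT_DRUGS},
        },
    )


def _pair_labels(table, spec):
    mask = table.sample_mask(
        lambda s: s.is_biological
        and s.drug == spec.drug
        and s.tier in (spec.group_a, spec.group_b)
    )
    return [s.tier for s, m in zip(table.samples, mask) if m]


@pytest.fixture(scope="session")
def study_metrics() -> list[StudyMetrics]:
    return [run_study(seed) for seed in range(1, N_STUDY_SEEDS + 1)]


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated table + truth (seed 1)."""
    return simulate_table(SimulationConfig(seed=1))
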