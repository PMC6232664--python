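"""Synthetic LC-MS feature tables with full ground truth.

Emulates the statistical structure the downstream analysis assumes for a
zebrafish-larva drug-toxicity study: 83 biological samples in 10
dose groups plus 12 QC-pool injections, four extraction blocks with
per-(feature, block) multiplicative effects, per-sample dilution, shared and
drug-specific toxicity signatures between the LC10 and half-LC10 tiers,
"unstable" features whose QC replicate scatter exceeds the retention filter,
and exogenous contaminants (buffer + administered drugs) with highly
correlated adduct/isotope/fragment satellites at mass-consistent m/z.

Everything is multiplicative (log-normal): LC-MS intensities are positive
and their noise scales with intensity.  QC pools are built as the arithmetic
mean of the biological samples' pre-noise intensities, mirroring the
physical pooling of reconstituted extracts before injection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_model import (
    ExogenousCompound,
    FeatureMeta,
    FeatureTable,
    SampleMeta,
    TableValidationError,
)
from .exogenous_exclusion import ADDUCT_SHIFTS, NEUTRON_MASS, theoretical_ions

__all__ = [
    "ContaminantSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_CONTAMINANTS",
    "generate_design",
    "simulate_table",
]

# Printed study design: 10 exposure groups totalling 83 larvae pools.  The
# two negative-control arms (6 + 7) are kept as separate entries so counts
# match the design exactly; both are unexposed (drug none, tier control).
DEFAULT_GROUP_SIZES: tuple[tuple[str, str, int], ...] = (
    ("gentamicin", "lc10", 10),
    ("gentamicin", "half_lc10", 10),
    ("paracetamol", "lc10", 10),
    ("paracetamol", "half_lc10", 10),
    ("tdf", "lc10", 10),
    ("tdf", "half_lc10", 10),
    ("tfv", "lc10", 5),
    ("tfv", "half_lc10", 5),
    ("none", "control", 6),
    ("none", "control", 7),
)

# loss of water: a plausible in-source fragment for the satellite set
_WATER = 18.010565
# satellite m/z offsets relative to the parent [M+H]+ ion, in generation order
_SATELLITE_OFFSETS: tuple[tuple[str, float], ...] = (
    ("M+Na", ADDUCT_SHIFTS["M+Na"] - ADDUCT_SHIFTS["M+H"]),
    ("M+K", ADDUCT_SHIFTS["M+K"] - ADDUCT_SHIFTS["M+H"]),
    ("M+1", NEUTRON_MASS),
    ("M+2", 2 * NEUTRON_MASS),
    ("fragment", -_WATER),
)


@dataclass(frozen=True)
class ContaminantSpec:
    """One exogenous compound family to inject.

    ``drug`` names the exposure that carries the compound ("none" means the
    compound is present in every biological sample, e.g. an extraction
    buffer).  Each parent gets ``n_satellites`` satellite features drawn
    from the adduct/isotope/fragment offset table, each a fixed ratio of the
    parent so its Pearson correlation with the parent reaches
    ``satellite_corr``.
    """

    name: str
    formula: str
    drug: str = "none"
    n_parents: int = 1
    n_satellites: int = 3
    satellite_corr: float = 0.95


DEFAULT_CONTAMINANTS: tuple[ContaminantSpec, ...] = (
    ContaminantSpec("HEPES", "C8H18N2O4S", drug="none", n_satellites=5),
    ContaminantSpec("gentamicin", "C21H43N5O7", drug="gentamicin"),
    ContaminantSpec("paracetamol", "C8H9NO2", drug="paracetamol"),
    ContaminantSpec("tenofovir_disoproxil", "C19H30N5O10P", drug="tdf"),
    ContaminantSpec("tenofovir", "C9H14N5O4P", drug="tfv"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_features: int = 445
    group_sizes: tuple[tuple[str, str, int], ...] = DEFAULT_GROUP_SIZES
    n_qc: int = 12
    n_blocks: int = 4
    block_effect_sd: float = 0.25
    base_log_mean: float = 11.5
    base_log_sd: float = 1.0
    dilution_sd: float = 0.2
    biological_cv: float = 0.25
    analytical_cv: float = 0.05
    qc_extra_cv: float = 0.05
    n_unstable: int = 30
    unstable_cv_range: tuple[float, float] = (0.35, 0.8)
    n_common: int = 119
    n_specific_per_drug: tuple[tuple[str, int], ...] = (
        ("paracetamol", 23),
        ("tdf", 25),
        ("tfv", 30),
    )
    effect_fold_lc10: float = 2.0
    effect_fold_half: float = 1.2
    effect_drugs: tuple[str, ...] = ("paracetamol", "tdf", "tfv")
    contaminants: tuple[ContaminantSpec, ...] = DEFAULT_CONTAMINANTS
    seed: int = 1

    def n_contaminant_features(self) -> int:
        return sum(c.n_parents * (1 + c.n_satellites) for c in self.contaminants)

    def validate(self) -> None:
        counts = dict(
            n_features=self.n_features,
            n_qc=self.n_qc,
            n_unstable=self.n_unstable,
            n_common=self.n_common,
        )
        for name, v in counts.items():
            if v < 0:
                raise TableValidationError(f"{name} must be >= 0, got {v}")
        if self.n_blocks < 1:
            raise TableValidationError("n_blocks must be >= 1")
        if any(n < 0 for _, n in self.n_specific_per_drug):
            raise TableValidationError("specific feature counts must be >= 0")
        if self.effect_fold_lc10 <= 0 or self.effect_fold_half <= 0:
            raise TableValidationError("effect folds must be > 0")
        reserved = (
            self.n_unstable
            + self.n_common
            + sum(n for _, n in self.n_specific_per_drug)
            + self.n_contaminant_features()
        )
        if reserved > self.n_features:
            raise TableValidationError(
                f"label partition infeasible: {reserved} reserved features "
                f"exceed n_features={self.n_features}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a simulated table."""

    labels: dict[str, str]  # feature_id -> truth label
    block_factors: np.ndarray  # features x blocks, simulated multiplicative factor
    feature_ids: list[str]
    dilution: dict[str, float]  # sample_id -> true dilution factor
    common_ids: list[str]
    specific_ids: dict[str, list[str]]
    parent_ids: list[str]
    satellite_ids: list[str]
    satellite_parent: dict[str, str]  # satellite feature -> its parent feature
    unstable_ids: list[str]
    compounds: list[ExogenousCompound]

    @property
    def background_ids(self) -> list[str]:
        return [f for f, lab in self.labels.items() if lab == "background"]


def generate_design(config: SimulationConfig) -> list[SampleMeta]:
    """Sample metadata for the configured design.

    Biological samples are assigned to extraction blocks round-robin within
    each (drug, tier) condition after a seeded shuffle of the block cycle,
    so every condition appears in every block whenever its group is at least
    as large as the number of blocks — the balance the block correction
    relies on.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples: list[SampleMeta] = []
    counter = 0
    group_totals: dict[tuple[str, str], int] = {}
    for drug, tier, n in config.group_sizes:
        group_totals[(drug, tier)] = group_totals.get((drug, tier), 0) + n
        for _ in range(n):
            counter += 1
            samples.append(
                SampleMeta(
                    sample_id=f"S{counter:03d}",
                    sample_type="biological",
                    drug=drug,
                    tier=tier,
                    block=0 if config.n_blocks == 0 else 1,  # placeholder
                )
            )
    # block assignment: per condition, cycle blocks from a random start
    if config.n_blocks > 0 and samples:
        assigned: list[SampleMeta] = []
        by_group: dict[tuple[str, str], list[SampleMeta]] = {}
        for s in samples:
            by_group.setdefault((s.drug, s.tier), []).append(s)
        blocks_by_id: dict[str, int] = {}
        for key in sorted(by_group):
            members = by_group[key]
            if len(members) < config.n_blocks:
                warnings.warn(
                    f"condition {key} has {len(members)} samples, fewer than "
                    f"{config.n_blocks} blocks: it cannot appear in every block",
                    stacklevel=2,
                )
            start = int(rng.integers(config.n_blocks))
            order = rng.permutation(len(members))
            for k, idx in enumerate(order):
                blocks_by_id[members[idx].sample_id] = (
                    (start + k) % config.n_blocks
                ) + 1
        assigned = [
            SampleMeta(
                sample_id=s.sample_id,
                sample_type="biological",
                drug=s.drug,
                tier=s.tier,
                block=blocks_by_id[s.sample_id],
            )
            for s in samples
        ]
        samples = assigned
    for k in range(config.n_qc):
        samples.append(SampleMeta(sample_id=f"QC{k + 1:02d}", sample_type="qc_pool"))
    return samples


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit median and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _qc_factors_with_exact_rsd(
    rng: np.random.Generator, cv: float, n: int
) -> np.ndarray:
    """Positive factors of length n whose sample RSD is exactly ``cv``.

    A raw log-normal draw at CV 0.35 lands below an RSD of 0.3 in a
    sizeable fraction of 12-replicate samples; rescaling the draw pins the
    realized replicate scatter to the drawn target so the "unstable" label
    is deterministic ground truth rather than a coin flip.
    """
    for _ in range(1000):
        f = _lognormal_factor(rng, cv, n)
        m, s = f.mean(), f.std(ddof=1)
        if s == 0:
            continue
        v = 1.0 + (f - m) * (cv / s)
        if np.all(v > 0):
            return v
    raise RuntimeError("could not draw positive QC factors")  # pragma: no cover


def simulate_table(
    config: SimulationConfig,
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate a feature table and its ground truth.

    Biological intensity of feature j in sample i is
    ``base_j * block_factor[j, b(i)] * dilution_i * effect_{j,i} * noise``;
    contaminant parents replace the base/effect part with a dose-driven
    level (zero in unexposed samples, half the LC10 level at the half-LC10
    tier) and satellites are a fixed ratio of their parent.  Each QC
    injection is the arithmetic mean of all biological pre-noise columns
    times analytical and extra QC noise, except "unstable" features whose
    QC replicate scatter is drawn from ``unstable_cv_range``.
    """
    config.validate()
    design = generate_design(config)
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))

    bio = [s for s in design if s.is_biological]
    qc = [s for s in design if s.is_qc]
    n_bio, n_qc = len(bio), len(qc)
    J = config.n_features
    B = config.n_blocks

    # ---- feature roles -------------------------------------------------
    labels = np.array(["background"] * J, dtype=object)
    cursor = 0

    parent_rows: list[int] = []
    sat_rows: list[int] = []
    sat_parent_row: dict[int, int] = {}
    parent_spec: dict[int, ContaminantSpec] = {}
    sat_offset: dict[int, tuple[str, float]] = {}
    compounds: list[ExogenousCompound] = []
    for spec in config.contaminants:
        compounds.append(
            ExogenousCompound(name=spec.name, formula=spec.formula)
        )
        for _ in range(spec.n_parents):
            p = cursor
            cursor += 1
            labels[p] = "exogenous_parent"
            parent_rows.append(p)
            parent_spec[p] = spec
            for k in range(spec.n_satellites):
                srow = cursor
                cursor += 1
                labels[srow] = "exogenous_satellite"
                sat_rows.append(srow)
                sat_parent_row[srow] = p
                sat_offset[srow] = _SATELLITE_OFFSETS[k % len(_SATELLITE_OFFSETS)]

    unstable_rows = list(range(cursor, cursor + config.n_unstable))
    labels[unstable_rows] = "unstable"
    cursor += config.n_unstable

    common_rows = list(range(cursor, cursor + config.n_common))
    labels[common_rows] = "toxicity_common"
    cursor += config.n_common

    specific_rows: dict[str, list[int]] = {}
    for drug, n in config.n_specific_per_drug:
        rows = list(range(cursor, cursor + n))
        labels[rows] = f"specific:{drug}"
        specific_rows[drug] = rows
        cursor += n

    # ---- m/z and retention time ---------------------------------------
    ions = theoretical_ions(compounds) if compounds else []
    ion_mz = np.array([ion.mz for ion in ions]) if ions else np.empty(0)

    mz = np.empty(J)
    rt = np.empty(J)
    # endogenous features: uniform m/z, kept > 20 ppm away from any
    # theoretical contaminant ion so mass matching has clean ground truth
    for j in range(J):
        if labels[j] in ("exogenous_parent", "exogenous_satellite"):
            continue
        while True:
            cand = rng.uniform(80.0, 1000.0)
            if ion_mz.size == 0 or np.min(np.abs(cand - ion_mz) / ion_mz) > 20e-6:
                break
        mz[j] = cand
        rt[j] = rng.uniform(30.0, 420.0)
    mono = {c.name: next(i.mz for i in ions if i.compound == c.name and i.adduct == "M+H" and i.isotope == 0) for c in compounds}
    for p in parent_rows:
        spec = parent_spec[p]
        base_mz = mono[spec.name]
        mz[p] = base_mz * (1.0 + rng.uniform(-2e-6, 2e-6))
        rt[p] = rng.uniform(30.0, 420.0)
        for srow, prow in sat_parent_row.items():
            if prow != p:
                continue
            _, off = sat_offset[srow]
            mz[srow] = (base_mz + off) * (1.0 + rng.uniform(-2e-6, 2e-6))
            rt[srow] = rt[p]  # satellites co-elute with their parent

    # ---- latent factors ------------------------------------------------
    base = rng.lognormal(config.base_log_mean, config.base_log_sd, size=J)
    block_factors = (
        np.exp(rng.normal(0.0, config.block_effect_sd, size=(J, max(B, 1))))
        if config.block_effect_sd > 0
        else np.ones((J, max(B, 1)))
    )
    dilution = (
        np.exp(rng.normal(0.0, config.dilution_sd, size=n_bio))
        if config.dilution_sd > 0
        else np.ones(n_bio)
    )

    # effect direction per toxicity feature: up- or down-regulated,
    # consistent across tiers (most real markers rise with dose; a mix
    # keeps the classifiers honest about sign)
    direction = rng.choice([1.0, -1.0], size=J)

    tier_fold = {
        "lc10": config.effect_fold_lc10,
        "half_lc10": config.effect_fold_half,
    }

    # contaminant parent levels: intense relative to the endogenous baseline
    parent_level = {
        p: rng.lognormal(config.base_log_mean + 1.0, config.base_log_sd)
        for p in parent_rows
    }
    sat_ratio = {s: rng.uniform(0.1, 0.6) for s in sat_rows}

    # ---- pre-noise biological matrix ----------------------------------
    # Per-(feature, sample) biological replicate variation: each column is
    # an independent pool of larvae, so metabolite levels (and contaminant
    # uptake) scatter between samples beyond dilution and block effects.
    bio_noise = _lognormal_factor(rng, config.biological_cv, (J, n_bio))
    pre = np.empty((J, n_bio))
    block_idx = np.array([max(s.block, 1) - 1 for s in bio])
    for j in range(J):
        lab = labels[j]
        if lab == "exogenous_satellite":
            continue  # filled from the parent below
        if lab == "exogenous_parent":
            spec = parent_spec[j]
            dose = np.empty(n_bio)
            for i, s in enumerate(bio):
                if spec.drug == "none":
                    dose[i] = 1.0
                elif s.drug == spec.drug:
                    dose[i] = 1.0 if s.tier == "lc10" else 0.5
                else:
                    dose[i] = 0.0
            row = parent_level[j] * dose * bio_noise[j]
        else:
            fold = np.ones(n_bio)
            if lab == "toxicity_common":
                for i, s in enumerate(bio):
                    if s.drug in config.effect_drugs and s.tier in tier_fold:
                        fold[i] = tier_fold[s.tier] ** direction[j]
            elif lab.startswith("specific:"):
                drug = lab.split(":", 1)[1]
                for i, s in enumerate(bio):
                    if s.drug == drug and s.tier in tier_fold:
                        fold[i] = tier_fold[s.tier] ** direction[j]
            row = base[j] * fold * bio_noise[j]
        pre[j] = row * block_factors[j, block_idx] * dilution
    # satellites are adduct/isotope/fragment ions of the parent molecule:
    # identical extraction behaviour, a fixed response ratio, so they share
    # the parent's pre-noise column (block factor included) exactly
    for srow, prow in sat_parent_row.items():
        pre[srow] = pre[prow] * sat_ratio[srow]
        block_factors[srow] = block_factors[prow]

    # ---- observed matrices --------------------------------------------
    x_bio = pre * _lognormal_factor(rng, config.analytical_cv, (J, n_bio))

    qc_base = pre.mean(axis=1) if n_bio else np.zeros(J)
    x_qc = np.empty((J, n_qc))
    stable_cv = math.sqrt(config.analytical_cv**2 + config.qc_extra_cv**2)
    for j in range(J):
        if labels[j] == "unstable" and n_qc >= 2:
            cv = rng.uniform(*config.unstable_cv_range)
            x_qc[j] = qc_base[j] * _qc_factors_with_exact_rsd(rng, cv, n_qc)
        else:
            x_qc[j] = qc_base[j] * _lognormal_factor(rng, stable_cv, n_qc)

    matrix = np.concatenate([x_bio, x_qc], axis=1)
    feature_ids = [f"F{j + 1:04d}" for j in range(J)]
    features = [
        FeatureMeta(
            feature_id=feature_ids[j],
            mz=float(mz[j]),
            rt=float(rt[j]),
            truth_label=str(labels[j]),
        )
        for j in range(J)
    ]
    table = FeatureTable(matrix, features, bio + qc)

    truth = SyntheticTruth(
        labels={feature_ids[j]: str(labels[j]) for j in range(J)},
        block_factors=block_factors,
        feature_ids=list(feature_ids),
        dilution={s.sample_id: float(d) for s, d in zip(bio, dilution)}
        | {s.sample_id: 1.0 for s in qc},
        common_ids=[feature_ids[j] for j in common_rows],
        specific_ids={
            drug: [feature_ids[j] for j in rows]
            for drug, rows in specific_rows.items()
        },
        parent_ids=[feature_ids[j] for j in parent_rows],
        satellite_ids=[feature_ids[j] for j in sat_rows],
        satellite_parent={
            feature_ids[s]: feature_ids[p] for s, p in sat_parent_row.items()
        },
        unstable_ids=[feature_ids[j] for j in unstable_rows],
        compounds=compounds,
    )
    return table, truth
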