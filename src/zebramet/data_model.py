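"""Core data containers and CSV readers/writers.

The central object is :class:`FeatureTable`: an aligned LC-MS feature
intensity matrix (features x samples) together with per-feature identity
(m/z, retention time) and per-sample study metadata (drug, concentration
tier, extraction block, biological vs QC-pool).  Every pipeline stage
consumes and returns a ``FeatureTable``; sample and feature order carry no
meaning — all joins are by id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_TYPES",
    "DRUGS",
    "TIERS",
    "TRUTH_LABEL_PREFIXES",
    "TableValidationError",
    "EmptySelectionError",
    "FeatureMeta",
    "SampleMeta",
    "ExogenousCompound",
    "FeatureTable",
    "read_feature_table",
    "write_feature_table",
    "subset",
    "read_compound_list",
    "write_compound_list",
]

SAMPLE_TYPES = ("biological", "qc_pool")
DRUGS = ("none", "gentamicin", "paracetamol", "tdf", "tfv")
TIERS = ("control", "half_lc10", "lc10", "not_applicable")
#: legal truth labels emitted by the simulator: either one of these exactly,
#: or "specific:<drug>".
TRUTH_LABEL_PREFIXES = (
    "background",
    "toxicity_common",
    "specific",
    "exogenous_parent",
    "exogenous_satellite",
    "unstable",
)


class TableValidationError(ValueError):
    """Raised when a table or its metadata violates an invariant."""


class EmptySelectionError(ValueError):
    """Raised when a subset predicate selects no rows or no columns."""


@dataclass(frozen=True)
class FeatureMeta:
    """Identity of one aligned LC-MS feature.

    Parameters
    ----------
    feature_id : unique id string.
    mz : mass-to-charge ratio in Th (> 0).
    rt : retention time in seconds (>= 0).
    truth_label : ground-truth role, populated only by the simulator.
    """

    feature_id: str
    mz: float
    rt: float
    truth_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.feature_id:
            raise TableValidationError("feature_id must be non-empty")
        if not (self.mz > 0):
            raise TableValidationError(
                f"feature {self.feature_id!r}: mz must be > 0, got {self.mz}"
            )
        if self.rt < 0:
            raise TableValidationError(
                f"feature {self.feature_id!r}: rt must be >= 0, got {self.rt}"
            )
        if self.truth_label is not None:
            head = self.truth_label.split(":", 1)[0]
            if head not in TRUTH_LABEL_PREFIXES:
                raise TableValidationError(
                    f"feature {self.feature_id!r}: unknown truth label "
                    f"{self.truth_label!r}"
                )


@dataclass(frozen=True)
class SampleMeta:
    """Study metadata of one injection.

    QC-pool injections carry ``drug='none'``, ``tier='not_applicable'`` and
    ``block=0`` (pools are made across extraction blocks); biological
    samples carry a block index in 1..B.
    """

    sample_id: str
    sample_type: str
    drug: str = "none"
    tier: str = "not_applicable"
    block: int = 0

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise TableValidationError("sample_id must be non-empty")
        if self.sample_type not in SAMPLE_TYPES:
            raise TableValidationError(
                f"sample {self.sample_id!r}: unknown sample_type "
                f"{self.sample_type!r}"
            )
        if self.drug not in DRUGS:
            raise TableValidationError(
                f"sample {self.sample_id!r}: unknown drug {self.drug!r}"
            )
        if self.tier not in TIERS:
            raise TableValidationError(
                f"sample {self.sample_id!r}: unknown tier {self.tier!r}"
            )
        if self.sample_type == "qc_pool":
            if self.drug != "none" or self.tier != "not_applicable":
                raise TableValidationError(
                    f"QC pool {self.sample_id!r} must have drug='none' and "
                    f"tier='not_applicable'"
                )
        else:
            if self.block < 1:
                raise TableValidationError(
                    f"biological sample {self.sample_id!r} needs an "
                    f"extraction block >= 1, got {self.block}"
                )

    @property
    def is_biological(self) -> bool:
        return self.sample_type == "biological"

    @property
    def is_qc(self) -> bool:
        return self.sample_type == "qc_pool"


@dataclass(frozen=True)
class ExogenousCompound:
    """A contaminant to screen out: buffer, administered drug, or metabolite.

    The monoisotopic mass may be given directly or derived from the elemental
    formula; ``adducts`` lists the singly charged positive-mode adducts to
    enumerate and ``max_isotope`` how many heavy-isotope peaks (M+1, ...) to
    add per adduct.
    """

    name: str
    formula: Optional[str] = None
    monoisotopic_mass: Optional[float] = None
    adducts: tuple[str, ...] = ("M+H", "M+Na", "M+K")
    max_isotope: int = 2

    def __post_init__(self) -> None:
        if self.formula is None and self.monoisotopic_mass is None:
            raise TableValidationError(
                f"compound {self.name!r}: need a formula or a monoisotopic mass"
            )
        if self.monoisotopic_mass is not None and not (self.monoisotopic_mass > 0):
            raise TableValidationError(
                f"compound {self.name!r}: monoisotopic mass must be > 0"
            )
        if not self.adducts:
            raise TableValidationError(f"compound {self.name!r}: adducts empty")
        if self.max_isotope < 0:
            raise TableValidationError(
                f"compound {self.name!r}: max_isotope must be >= 0"
            )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TableValidationError(f"duplicate {what} id {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix plus metadata on both axes."""

    intensities: np.ndarray
    features: list[FeatureMeta]
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise TableValidationError("intensities must be a 2-D matrix")
        nf, ns = self.intensities.shape
        if nf != len(self.features):
            raise TableValidationError(
                f"matrix has {nf} rows but {len(self.features)} feature entries"
            )
        if ns != len(self.samples):
            raise TableValidationError(
                f"matrix has {ns} columns but {len(self.samples)} sample entries"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise TableValidationError("intensities must all be finite")
        if np.any(self.intensities < 0):
            j, i = np.argwhere(self.intensities < 0)[0]
            raise TableValidationError(
                f"negative intensity at feature {self.features[j].feature_id!r}, "
                f"sample {self.samples[i].sample_id!r}"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")

    # -- convenience views ------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"no feature {feature_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"no sample {sample_id!r}") from None

    def sample_mask(self, pred: Callable[[SampleMeta], bool]) -> np.ndarray:
        return np.array([bool(pred(s)) for s in self.samples])

    def feature_mask(self, pred: Callable[[FeatureMeta], bool]) -> np.ndarray:
        return np.array([bool(pred(f)) for f in self.features])

    def with_intensities(self, intensities: np.ndarray) -> "FeatureTable":
        """Same metadata, new matrix (validated)."""
        return FeatureTable(intensities, list(self.features), list(self.samples))

    def to_frame(self) -> pd.DataFrame:
        """Intensity matrix as a DataFrame (feature ids x sample ids)."""
        return pd.DataFrame(
            self.intensities, index=self.feature_ids, columns=self.sample_ids
        )

    def subset(
        self,
        sample_filter: Optional[Callable[[SampleMeta], bool]] = None,
        feature_filter: Optional[Callable[[FeatureMeta], bool]] = None,
    ) -> "FeatureTable":
        return subset(self, sample_filter, feature_filter)


def subset(
    table: FeatureTable,
    sample_filter: Optional[Callable[[SampleMeta], bool]] = None,
    feature_filter: Optional[Callable[[FeatureMeta], bool]] = None,
) -> FeatureTable:
    """Restrict a table to the samples/features passing the predicates.

    Order is preserved on both axes.  Raises
    :class:`EmptySelectionError` when either axis would come out empty —
    downstream stages cannot operate on an empty table and callers are
    expected to handle that case explicitly.
    """
    smask = (
        table.sample_mask(sample_filter)
        if sample_filter is not None
        else np.ones(table.n_samples, dtype=bool)
    )
    fmask = (
        table.feature_mask(feature_filter)
        if feature_filter is not None
        else np.ones(table.n_features, dtype=bool)
    )
    if not smask.any():
        raise EmptySelectionError("sample filter selected no samples")
    if not fmask.any():
        raise EmptySelectionError("feature filter selected no features")
    return FeatureTable(
        table.intensities[np.ix_(fmask, smask)],
        [f for f, k in zip(table.features, fmask) if k],
        [s for s, k in zip(table.samples, smask) if k],
    )


# -- CSV I/O ---------------------------------------------------------------

_RESERVED = ("feature_id", "mz", "rt", "truth_label")


def read_feature_table(intensity_path, sample_meta_path) -> FeatureTable:
    """Read an intensity CSV and its sample-metadata CSV into a table.

    The intensity file has reserved leading columns ``feature_id``, ``mz``,
    ``rt`` (optionally ``truth_label``) followed by one column per sample;
    the metadata file has one row per sample with columns ``sample_id``,
    ``sample_type``, ``drug``, ``tier``, ``block``.  Columns are matched to
    metadata rows by sample id, and the metadata row order wins.
    """
    meta = pd.read_csv(sample_meta_path, dtype={"sample_id": str})
    required = {"sample_id", "sample_type", "drug", "tier", "block"}
    missing = required - set(meta.columns)
    if missing:
        raise TableValidationError(
            f"sample metadata is missing columns {sorted(missing)}"
        )
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            sample_type=row.sample_type,
            drug=row.drug,
            tier=row.tier,
            block=int(row.block),
        )
        for row in meta.itertuples()
    ]
    _check_unique([s.sample_id for s in samples], "sample")

    inten = pd.read_csv(
        intensity_path, dtype={"feature_id": str}, float_precision="round_trip"
    )
    for col in ("feature_id", "mz", "rt"):
        if col not in inten.columns:
            raise TableValidationError(f"intensity file is missing column {col!r}")
    has_truth = "truth_label" in inten.columns
    sample_cols = [c for c in inten.columns if c not in _RESERVED]

    meta_ids = {s.sample_id for s in samples}
    unknown = [c for c in sample_cols if c not in meta_ids]
    if unknown:
        raise TableValidationError(
            f"intensity columns with no metadata row: {unknown}"
        )
    absent = [s.sample_id for s in samples if s.sample_id not in sample_cols]
    if absent:
        raise TableValidationError(
            f"metadata samples missing from the intensity file: {absent}"
        )

    features = []
    for row in inten.itertuples():
        label = None
        if has_truth:
            raw = getattr(row, "truth_label")
            if isinstance(raw, str) and raw:
                label = raw
        features.append(
            FeatureMeta(
                feature_id=row.feature_id,
                mz=float(row.mz),
                rt=float(row.rt),
                truth_label=label,
            )
        )

    order = [s.sample_id for s in samples]
    if len(features) == 0:
        matrix = np.empty((0, len(samples)))
    else:
        block = inten[order]
        bad = block.columns[block.apply(lambda c: not np.issubdtype(c.dtype, np.number))]
        if len(bad):
            raise TableValidationError(
                f"non-numeric intensities in column(s) {list(bad)}"
            )
        matrix = block.to_numpy(dtype=float)
    return FeatureTable(matrix, features, samples)


def write_feature_table(table: FeatureTable, intensity_path, sample_meta_path) -> None:
    """Write a table as the intensity/metadata CSV pair read by
    :func:`read_feature_table`.  Floats use shortest round-trip formatting,
    so read(write(t)) reproduces t exactly."""
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in table.samples],
            "sample_type": [s.sample_type for s in table.samples],
            "drug": [s.drug for s in table.samples],
            "tier": [s.tier for s in table.samples],
            "block": [s.block for s in table.samples],
        }
    )
    meta.to_csv(sample_meta_path, index=False)

    lead = {
        "feature_id": [f.feature_id for f in table.features],
        "mz": [f.mz for f in table.features],
        "rt": [f.rt for f in table.features],
    }
    if any(f.truth_label is not None for f in table.features):
        lead["truth_label"] = [f.truth_label or "" for f in table.features]
    out = pd.DataFrame(lead)
    for i, s in enumerate(table.samples):
        out[s.sample_id] = table.intensities[:, i]
    out.to_csv(intensity_path, index=False)


# -- exogenous-compound list I/O ------------------------------------------


def read_compound_list(path) -> list[ExogenousCompound]:
    """Read a contaminant list from CSV (columns name, formula,
    monoisotopic_mass, adducts ';'-separated, max_isotope) or from an
    equivalent JSON array of objects."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path)
        records = df.to_dict(orient="records")
    compounds = []
    for rec in records:
        formula = rec.get("formula")
        if isinstance(formula, float) and np.isnan(formula):
            formula = None
        mono = rec.get("monoisotopic_mass")
        if mono is not None and (isinstance(mono, float) and np.isnan(mono)):
            mono = None
        adducts = rec.get("adducts", "M+H;M+Na;M+K")
        if isinstance(adducts, str):
            adducts = tuple(a.strip() for a in adducts.split(";") if a.strip())
        else:
            adducts = tuple(adducts)
        compounds.append(
            ExogenousCompound(
                name=str(rec["name"]),
                formula=formula or None,
                monoisotopic_mass=float(mono) if mono is not None else None,
                adducts=adducts,
                max_isotope=int(rec.get("max_isotope", 2)),
            )
        )
    return compounds


def write_compound_list(compounds: Iterable[ExogenousCompound], path) -> None:
    rows = [
        {
            "name": c.name,
            "formula": c.formula or "",
            "monoisotopic_mass": c.monoisotopic_mass
            if c.monoisotopic_mass is not None
            else "",
            "adducts": ";".join(c.adducts),
            "max_isotope": c.max_isotope,
        }
        for c in compounds
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
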