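"""Two-step removal of exogenous signals from a feature table.

Administered drugs, their metabolites, and extraction buffer (HEPES) leave
intense non-biological features in untargeted LC-MS data.  They are removed
in two passes:

1. *mass matching* — features whose m/z falls within a ppm tolerance of a
   theoretical singly charged adduct/isotope ion of a listed compound;
2. *correlation propagation* — features whose intensity profile across
   biological samples is highly correlated (Pearson r at or above a
   threshold) with any feature removed in step 1.  This catches the
   satellites mass matching cannot enumerate: in-source fragments, unusual
   adducts, and isotopologues beyond the enumerated range.

Step 2 is a single pass anchored on the step-1 features only (no transitive
closure), and the threshold applies to the signed correlation —
anti-correlated features are never excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .data_model import (
    EmptySelectionError,
    ExogenousCompound,
    FeatureMeta,
    FeatureTable,
    SampleMeta,
    read_compound_list,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PROTON_MASS",
    "ADDUCT_SHIFTS",
    "NEUTRON_MASS",
    "TheoreticalIon",
    "MassMatch",
    "ExclusionReport",
    "theoretical_ions",
    "match_exogenous",
    "correlation_propagation",
    "exclude_exogenous",
    "load_default_compounds",
]

# monoisotopic mass shifts for singly charged positive adducts (Da)
PROTON_MASS = 1.007276
ADDUCT_SHIFTS: Mapping[str, float] = {
    "M+H": 1.007276,
    "M+Na": 22.989218,
    "M+K": 38.963158,
}
NEUTRON_MASS = 1.003355  # C13 - C12 spacing, the usual isotopologue step


@dataclass(frozen=True)
class TheoreticalIon:
    """One expected contaminant ion: (compound, adduct, isotope) -> m/z."""

    compound: str
    adduct: str
    isotope: int
    mz: float


@dataclass(frozen=True)
class MassMatch:
    feature_id: str
    compound: str
    adduct: str
    isotope: int
    ppm: float


@dataclass
class ExclusionReport:
    """What was removed and why."""

    step1: dict[str, MassMatch]  # feature_id -> best mass match
    step2: dict[str, tuple[str, float]]  # feature_id -> (anchor, r)
    n_surviving: int

    @property
    def excluded_ids(self) -> set[str]:
        return set(self.step1) | set(self.step2)


def _compound_mass(compound: ExogenousCompound) -> float:
    if compound.monoisotopic_mass is not None:
        return compound.monoisotopic_mass
    from pyteomics import mass as _pmass

    try:
        return float(_pmass.calculate_mass(formula=compound.formula))
    except Exception as exc:
        raise ValueError(
            f"cannot parse formula {compound.formula!r} of compound "
            f"{compound.name!r}: {exc}"
        ) from exc


def theoretical_ions(
    compounds: Iterable[ExogenousCompound],
) -> list[TheoreticalIon]:
    """Enumerate theoretical singly charged ions for each compound.

    One ion per (compound, adduct, isotope 0..max_isotope):
    ``mz = M + adduct_shift + isotope * neutron``.
    """
    ions: list[TheoreticalIon] = []
    for c in compounds:
        m = _compound_mass(c)
        for adduct in c.adducts:
            if adduct not in ADDUCT_SHIFTS:
                raise ValueError(
                    f"compound {c.name!r}: unsupported adduct {adduct!r}"
                )
            for k in range(c.max_isotope + 1):
                ions.append(
                    TheoreticalIon(
                        compound=c.name,
                        adduct=adduct,
                        isotope=k,
                        mz=m + ADDUCT_SHIFTS[adduct] + k * NEUTRON_MASS,
                    )
                )
    return ions


def match_exogenous(
    features: Sequence[FeatureMeta],
    ions: Sequence[TheoreticalIon],
    ppm_tol: float = 5.0,
) -> dict[str, MassMatch]:
    """Step 1: features within ``ppm_tol`` of any theoretical ion.

    A feature matches iff min over ions of |mz_f - mz_ion| / mz_ion * 1e6
    is at or below the tolerance; the lowest-ppm ion is reported.
    """
    if ppm_tol <= 0:
        raise ValueError(f"ppm_tol must be > 0, got {ppm_tol}")
    if not ions:
        return {}
    ion_mz = np.array([i.mz for i in ions])
    out: dict[str, MassMatch] = {}
    for f in features:
        ppm = np.abs(f.mz - ion_mz) / ion_mz * 1e6
        best = int(np.argmin(ppm))
        if ppm[best] <= ppm_tol:
            ion = ions[best]
            out[f.feature_id] = MassMatch(
                feature_id=f.feature_id,
                compound=ion.compound,
                adduct=ion.adduct,
                isotope=ion.isotope,
                ppm=float(ppm[best]),
            )
    return out


def correlation_propagation(
    table: FeatureTable,
    anchors: Iterable[str],
    r_threshold: float = 0.9,
    sample_scope: Optional[Callable[[SampleMeta], bool]] = None,
) -> dict[str, tuple[str, float]]:
    """Step 2: non-anchor features correlated with any anchor.

    Pearson correlation is computed over the in-scope samples (biological
    only by default: QC pools are cross-sample averages and would inflate
    correlations).  Constant features have correlation 0 with everything.
    Returns a map feature_id -> (best anchor, r) for features whose signed
    r with some anchor is >= the threshold.
    """
    if sample_scope is None:
        sample_scope = lambda s: s.is_biological  # noqa: E731
    anchors = set(anchors)
    missing = anchors - set(table.feature_ids)
    if missing:
        raise KeyError(f"anchors not in table: {sorted(missing)}")
    if not anchors:
        return {}
    smask = table.sample_mask(sample_scope)
    if smask.sum() < 3:
        raise ValueError(
            f"need >= 3 in-scope samples for correlations, have {int(smask.sum())}"
        )
    X = table.intensities[:, smask]
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info(
            "%d constant feature(s) in correlation scope; their correlation "
            "is taken as 0",
            int(constant.sum()),
        )
    ids = table.feature_ids
    anchor_idx = [j for j, f in enumerate(ids) if f in anchors]
    other_idx = [j for j, f in enumerate(ids) if f not in anchors]
    if not other_idx:
        return {}

    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(sd == 0, 1.0, sd * X.shape[1])
    Z = Xc / denom[:, None]  # so Z_a @ Z_b.T * n = r
    R = (Z[other_idx] @ Z[anchor_idx].T) * X.shape[1]
    R[constant[other_idx], :] = 0.0
    R[:, constant[anchor_idx]] = 0.0

    out: dict[str, tuple[str, float]] = {}
    for row, j in enumerate(other_idx):
        best = int(np.argmax(R[row]))
        r = float(R[row, best])
        if r >= r_threshold:
            out[ids[j]] = (ids[anchor_idx[best]], r)
    return out


def exclude_exogenous(
    table: FeatureTable,
    compounds: Sequence[ExogenousCompound],
    ppm_tol: float = 5.0,
    r_threshold: float = 0.9,
    sample_scope: Optional[Callable[[SampleMeta], bool]] = None,
) -> tuple[FeatureTable, ExclusionReport]:
    """Run both exclusion steps and drop the union of their hits."""
    ions = theoretical_ions(compounds)
    step1 = match_exogenous(table.features, ions, ppm_tol=ppm_tol)
    if step1:
        step2 = correlation_propagation(
            table, step1.keys(), r_threshold=r_threshold, sample_scope=sample_scope
        )
    else:
        step2 = {}
    excluded = set(step1) | set(step2)
    report = ExclusionReport(
        step1=step1, step2=step2, n_surviving=table.n_features - len(excluded)
    )
    if not excluded:
        return table, report
    if report.n_surviving == 0:
        raise EmptySelectionError("exclusion would remove every feature")
    kept = table.subset(feature_filter=lambda f: f.feature_id not in excluded)
    logger.info(
        "exogenous exclusion removed %d feature(s): %d mass-matched, %d by "
        "correlation; %d survive",
        len(excluded),
        len(step1),
        len(step2),
        report.n_surviving,
    )
    return kept, report


def load_default_compounds() -> list[ExogenousCompound]:
    """The shipped screening list: HEPES buffer plus the four study drugs."""
    ref = resources.files("zebramet.data").joinpath("exogenous_default.csv")
    with resources.as_file(ref) as path:
        return read_compound_list(path)
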