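"""Paired PLS-DA models per drug and Venn partition of selected features.

For each drug the marker-defining contrast is LC10 vs half-LC10: both
groups were exposed, so the separation isolates toxicity-associated change
from mere exposure.  Each paired model is fitted on its own sample subset,
autoscaled fresh, and features with VIP strictly greater than 1.0 on the
first component are selected.  The per-drug selections are then partitioned
Venn-style into the common intersection (candidate general toxicity
markers), drug-specific remainders, and the in-between shared regions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import FeatureTable
from .multivariate import PLSDAModel, plsda_fit, vip_scores
from .preprocess import autoscale

logger = logging.getLogger(__name__)

__all__ = [
    "VIP_THRESHOLD_DEFAULT",
    "PairedModelSpec",
    "VennPartition",
    "run_paired_models",
    "venn_partition",
]

VIP_THRESHOLD_DEFAULT = 1.0
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (("lc10", "half_lc10"),)


@dataclass
class PairedModelSpec:
    """One drug's two-group PLS-DA and its VIP selection."""

    drug: str
    group_a: str
    group_b: str
    model: PLSDAModel
    selected: set[str]
    n_samples: int

    @property
    def r2y1(self) -> float:
        """Fraction of class variance captured by component 1 — the
        separation diagnostic."""
        return float(self.model.r2y[0])


def run_paired_models(
    table: FeatureTable,
    drugs: Sequence[str],
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    vip_threshold: float = VIP_THRESHOLD_DEFAULT,
    n_components: int = 5,
) -> list[PairedModelSpec]:
    """Fit a PLS-DA per (drug, tier pair) and select VIP > threshold
    features on component 1.

    ``group_a``/``group_b`` may be exposure tiers of the drug or
    ``"control"`` (which selects the unexposed controls regardless of the
    drug).  The subset is autoscaled on its own samples before fitting; up
    to ``n_components`` components are fitted (capped by the subset size)
    but selection uses component 1 only, with a strict inequality.  A drug
    with an empty group is skipped with a warning.
    """
    specs: list[PairedModelSpec] = []
    for drug in drugs:
        for group_a, group_b in pairs:
            def in_group(s, tier):
                if tier == "control":
                    return s.is_biological and s.tier == "control"
                return s.is_biological and s.drug == drug and s.tier == tier

            mask_a = table.sample_mask(lambda s: in_group(s, group_a))
            mask_b = table.sample_mask(lambda s: in_group(s, group_b))
            if not mask_a.any() or not mask_b.any():
                warnings.warn(
                    f"drug {drug!r}: empty group in pair ({group_a}, {group_b}); "
                    f"model skipped",
                    stacklevel=2,
                )
                continue
            mask = mask_a | mask_b
            X = table.intensities[:, mask].T  # samples x features
            labels = [
                group_a if a else group_b
                for a, b in zip(mask_a[mask], mask_b[mask])
            ]
            scaled = autoscale(X).scaled
            k = min(n_components, X.shape[0] - 1, X.shape[1])
            model = plsda_fit(scaled, labels, n_components=k)
            vip1 = vip_scores(model, 1)
            selected = {
                fid for fid, v in zip(table.feature_ids, vip1) if v > vip_threshold
            }
            logger.info(
                "PLS-DA %s %s-vs-%s: n=%d, r2y(comp1)=%.3f, %d features "
                "selected at VIP > %g",
                drug,
                group_a,
                group_b,
                int(mask.sum()),
                model.r2y[0],
                len(selected),
                vip_threshold,
            )
            specs.append(
                PairedModelSpec(
                    drug=drug,
                    group_a=group_a,
                    group_b=group_b,
                    model=model,
                    selected=selected,
                    n_samples=int(mask.sum()),
                )
            )
    return specs


@dataclass
class VennPartition:
    """Disjoint regions of >= 2 drugs' selected-feature sets.

    ``common`` holds features selected by every drug, ``specific[d]``
    features selected by drug d only, ``shared_pairs[(d1, d2)]`` features
    selected by exactly those two, and ``other`` any remaining exact
    combination (only possible with four or more drugs).  The regions are
    mutually disjoint and their union is the union of the inputs.
    """

    common: set[str]
    specific: dict[str, set[str]]
    shared_pairs: dict[tuple[str, str], set[str]]
    other: dict[tuple[str, ...], set[str]] = field(default_factory=dict)

    def regions(self) -> dict[tuple[str, ...], set[str]]:
        out: dict[tuple[str, ...], set[str]] = dict(self.other)
        for d, s in self.specific.items():
            out[(d,)] = s
        for pair, s in self.shared_pairs.items():
            out[pair] = s
        if self.common:
            out[tuple(sorted(self.specific))] = self.common
        return out


def venn_partition(selections: Mapping[str, set[str]]) -> VennPartition:
    """Partition per-drug feature selections into exact-membership regions."""
    if len(selections) < 2:
        raise ValueError("Venn partition needs selections from >= 2 drugs")
    drugs = sorted(selections)
    membership: dict[str, tuple[str, ...]] = {}
    for fid in set().union(*selections.values()):
        membership[fid] = tuple(d for d in drugs if fid in selections[d])
    common: set[str] = set()
    specific: dict[str, set[str]] = {d: set() for d in drugs}
    shared_pairs: dict[tuple[str, str], set[str]] = {}
    other: dict[tuple[str, ...], set[str]] = {}
    for fid, combo in membership.items():
        if len(combo) == len(drugs):
            common.add(fid)
        elif len(combo) == 1:
            specific[combo[0]].add(fid)
        elif len(combo) == 2:
            shared_pairs.setdefault(combo, set()).add(fid)
        else:
            other.setdefault(combo, set()).add(fid)
    return VennPartition(
        common=common, specific=specific, shared_pairs=shared_pairs, other=other
    )
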