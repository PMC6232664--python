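"""Per-feature extraction-block correction.

Samples extracted in different batches ("blocks") share multiplicative
intensity shifts that differ feature by feature.  The correction scales
each feature within each block by the quotient of its block mean to its
overall mean, computed over the biological samples: after division, every
block's mean equals the pre-correction overall mean exactly.  QC pools are
pooled across blocks and are therefore passed through unchanged.

Because every (drug, tier) condition is present in every block, block means
average over all conditions and the correction cannot absorb the drug
effect itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .data_model import FeatureTable, SampleMeta

logger = logging.getLogger(__name__)

__all__ = ["BlockFactors", "compute_block_factors", "apply_block_correction"]


@dataclass
class BlockFactors:
    """Correction factors: features x blocks, factor = block mean / overall
    mean per feature, computed over the recorded sample set."""

    factors: np.ndarray
    feature_ids: list[str]
    block_ids: list[int]
    sample_ids: list[str]  # the samples the means were computed over

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.factors,
            index=self.feature_ids,
            columns=[f"block_{b}" for b in self.block_ids],
        )


def compute_block_factors(
    table: FeatureTable,
    include: Optional[Callable[[SampleMeta], bool]] = None,
) -> BlockFactors:
    """Compute per-(feature, block) correction factors over the included
    samples (biological only by default)."""
    if include is None:
        include = lambda s: s.is_biological  # noqa: E731
    mask = table.sample_mask(include)
    if not mask.any():
        raise ValueError("no samples included in block-factor computation")
    included = [s for s, m in zip(table.samples, mask) if m]
    blocks = sorted({s.block for s in included})
    X = table.intensities[:, mask]
    overall = X.mean(axis=1)
    if np.any(overall <= 0):
        j = int(np.argmax(overall <= 0))
        raise ValueError(
            f"feature {table.feature_ids[j]!r} has non-positive overall mean; "
            f"block factors undefined"
        )
    factors = np.empty((table.n_features, len(blocks)))
    for k, b in enumerate(blocks):
        bmask = np.array([s.block == b for s in included])
        if not bmask.any():  # pragma: no cover - blocks built from included
            raise ValueError(f"block {b} has no included samples")
        factors[:, k] = X[:, bmask].mean(axis=1) / overall
    return BlockFactors(
        factors=factors,
        feature_ids=table.feature_ids,
        block_ids=list(blocks),
        sample_ids=[s.sample_id for s in included],
    )


def apply_block_correction(
    table: FeatureTable, factors: BlockFactors
) -> FeatureTable:
    """Divide each included sample's column by its block's per-feature
    factor; samples whose block has no factor column (e.g. QC pools, block
    0) pass through unchanged and are logged."""
    if factors.feature_ids != table.feature_ids:
        raise ValueError("block factors were computed on a different feature set")
    if np.any(factors.factors <= 0):
        raise ValueError("block factors must all be > 0")
    col = {b: k for k, b in enumerate(factors.block_ids)}
    included_ids = set(factors.sample_ids)
    out = table.intensities.copy()
    passed: list[str] = []
    for i, s in enumerate(table.samples):
        if s.sample_id in included_ids and s.block in col:
            out[:, i] = out[:, i] / factors.factors[:, col[s.block]]
        else:
            passed.append(s.sample_id)
    if passed:
        logger.info(
            "block correction passed through %d sample(s) outside the "
            "inclusion set: %s",
            len(passed),
            ", ".join(passed[:10]) + ("..." if len(passed) > 10 else ""),
        )
    return table.with_intensities(out)
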