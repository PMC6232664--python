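"""QC-based feature filtering, normalization, and autoscaling.

The preprocessing chain for an aligned feature table is:

1. :func:`filter_by_qc_rsd` — keep features whose relative standard
   deviation across the repeated QC-pool injections is at most 0.3
   (analytically reproducible features);
2. :func:`total_area_normalize` — divide every sample by its total signal;
3. :func:`pqn_normalize` — probabilistic quotient normalization: divide
   every sample by the median of its feature-wise quotients against a
   reference spectrum, removing residual per-sample dilution;
4. :func:`autoscale` — center and unit-variance scale each feature, applied
   fresh inside each statistical model on its own sample subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_model import FeatureTable

__all__ = [
    "RSD_THRESHOLD_DEFAULT",
    "PqnReport",
    "AutoscaleResult",
    "filter_by_qc_rsd",
    "total_area_normalize",
    "pqn_normalize",
    "autoscale",
]

RSD_THRESHOLD_DEFAULT = 0.3


def filter_by_qc_rsd(
    table: FeatureTable, threshold: float = RSD_THRESHOLD_DEFAULT
) -> tuple[FeatureTable, pd.DataFrame]:
    """Keep features with QC-pool RSD at or below ``threshold``.

    RSD is the sample standard deviation (ddof=1) over QC-pool columns
    divided by their mean; the boundary is inclusive.  A feature whose QC
    mean is zero gets RSD +inf and is removed.  Returns the filtered table
    and a per-feature report (qc_mean, qc_sd, rsd, keep) covering all input
    features.
    """
    qc_mask = table.sample_mask(lambda s: s.is_qc)
    n_qc = int(qc_mask.sum())
    if n_qc < 2:
        raise ValueError(
            f"QC RSD filter needs >= 2 QC-pool samples, found {n_qc}"
        )
    qc = table.intensities[:, qc_mask]
    qc_mean = qc.mean(axis=1)
    qc_sd = qc.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(qc_mean > 0, qc_sd / qc_mean, np.inf)
    keep = rsd <= threshold
    report = pd.DataFrame(
        {
            "feature_id": table.feature_ids,
            "qc_mean": qc_mean,
            "qc_sd": qc_sd,
            "rsd": rsd,
            "keep": keep,
        }
    )
    kept_ids = set(np.asarray(table.feature_ids, dtype=object)[keep])
    filtered = table.subset(feature_filter=lambda f: f.feature_id in kept_ids)
    return filtered, report


def total_area_normalize(table: FeatureTable) -> FeatureTable:
    """Divide each sample column by its own sum, so every column sums to 1."""
    sums = table.intensities.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"sample {table.samples[zero[0]].sample_id!r} has zero total area"
        )
    return table.with_intensities(table.intensities / sums)


@dataclass
class PqnReport:
    """Reference spectrum and the per-sample dilution quotients removed."""

    reference: np.ndarray  # per feature, aligned to the table's feature order
    dilution: pd.Series  # per sample_id, > 0
    n_usable_features: int


def pqn_normalize(
    table: FeatureTable, reference: str = "median_all"
) -> tuple[FeatureTable, PqnReport]:
    """Probabilistic quotient normalization.

    The reference spectrum is the per-feature median over all samples
    (``median_all``, the usual convention) or over the QC pools only
    (``median_qc``).  Each sample's dilution quotient is the median over
    features of (sample value / reference value); features with zero
    reference are omitted from the quotient but still rescaled.  The output
    column is the input column divided by its quotient.
    """
    if reference == "median_all":
        ref_cols = np.ones(table.n_samples, dtype=bool)
    elif reference == "median_qc":
        ref_cols = table.sample_mask(lambda s: s.is_qc)
        if not ref_cols.any():
            raise ValueError("reference='median_qc' but the table has no QC pools")
    else:
        raise ValueError(f"unknown PQN reference {reference!r}")
    ref = np.median(table.intensities[:, ref_cols], axis=1)
    usable = ref > 0
    if not usable.any():
        raise ValueError("PQN reference spectrum is zero everywhere")
    quotients = table.intensities[usable] / ref[usable, None]
    dilution = np.median(quotients, axis=0)
    if np.any(dilution <= 0):
        i = int(np.argmax(dilution <= 0))
        raise ValueError(
            f"sample {table.samples[i].sample_id!r} has a non-positive "
            f"dilution quotient"
        )
    out = table.with_intensities(table.intensities / dilution)
    report = PqnReport(
        reference=ref,
        dilution=pd.Series(dilution, index=table.sample_ids, name="dilution"),
        n_usable_features=int(usable.sum()),
    )
    return out, report


class AutoscaleResult(NamedTuple):
    scaled: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # boolean mask of zero-variance features


def autoscale(matrix: np.ndarray) -> AutoscaleResult:
    """Center and unit-variance scale each column of a samples x features
    matrix (sample SD, ddof=1).  Constant features are centered, left at 0,
    and flagged in the returned mask rather than raising.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("autoscale needs a 2-D matrix with >= 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    denom = np.where(constant, 1.0, sd)
    return AutoscaleResult((X - mean) / denom, mean, sd, constant)
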