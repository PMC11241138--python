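"""Expression filters and transforms.

TPM computation for the gene path, the "expressed" filters (strict
TPM > 1 for genes, normalized count > 1 for mature miRNAs, in at least one
sample), and mature-miRNA aggregation: each mature arm's expression is the
arithmetic mean over the precursor miRNAs it derives from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import ValidationError

VALID_UNITS = {"raw_counts", "tpm", "normalized_counts"}
VALID_CONDITIONS = {"control", "silenced"}


@dataclass
class ExpressionMatrix:
    """A features x samples matrix with a declared unit and sample conditions."""

    data: pd.DataFrame
    unit: str
    condition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unit must be one of {VALID_UNITS}")
        values = self.data.values
        if (values < 0).any():
            raise ValidationError("expression values must be >= 0")
        for sample, cond in self.condition.items():
            if cond not in VALID_CONDITIONS:
                raise ValidationError(f"{sample}: condition must be in {VALID_CONDITIONS}")
        if self.unit == "tpm":
            colsums = values.sum(axis=0)
            nonzero = colsums > 0
            if nonzero.any() and not np.allclose(colsums[nonzero], 1e6, atol=1e-3):
                raise ValidationError("TPM columns must sum to 1e6")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples_in(self, cond: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition.get(s) == cond]


def compute_tpm(
    counts: ExpressionMatrix, lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Transcripts per million: length-normalised rates rescaled to 1e6 per column.

    An all-zero column stays all-zero.
    """
    if counts.unit != "raw_counts":
        raise ValidationError("compute_tpm expects raw counts")
    missing = [f for f in counts.feature_ids if f not in lengths]
    if missing:
        raise ValidationError(f"missing length for feature(s): {missing[:5]}")
    lens = np.array([float(lengths[f]) for f in counts.feature_ids])
    if (lens <= 0).any():
        raise ValidationError("feature lengths must be > 0")
    rates = counts.data.values / lens[:, None]
    denom = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(denom > 0, 1e6 * rates / denom, 0.0)
    return ExpressionMatrix(
        data=pd.DataFrame(tpm, index=counts.data.index, columns=counts.data.columns),
        unit="tpm",
        condition=dict(counts.condition),
    )


def _filter_expressed(matrix: ExpressionMatrix, min_value: float) -> set[str]:
    mask = (matrix.data.values > min_value).any(axis=1)
    return set(np.asarray(matrix.data.index)[mask])


def filter_expressed_genes(tpm: ExpressionMatrix, min_tpm: float = 1.0) -> set[str]:
    """Genes with TPM strictly above min_tpm in at least one sample."""
    if tpm.unit != "tpm":
        raise ValidationError("filter_expressed_genes expects a TPM matrix")
    return _filter_expressed(tpm, min_tpm)


def filter_expressed_mirnas(
    norm: ExpressionMatrix, min_count: float = 1.0
) -> set[str]:
    """Matures with a normalized count strictly above min_count in >= 1 sample."""
    if norm.unit != "normalized_counts":
        raise ValidationError("filter_expressed_mirnas expects normalized counts")
    return _filter_expressed(norm, min_count)


def aggregate_mature_mirna(
    arm_counts: pd.DataFrame,
    unit: str = "raw_counts",
    condition: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Aggregate precursor-arm expression to mature miRNAs.

    ``arm_counts`` has columns ``precursor_id``, ``mature_id`` and one column
    per sample.  Each mature's value is the arithmetic mean over its
    precursor rows, per sample.
    """
    for col in ("precursor_id", "mature_id"):
        if col not in arm_counts.columns:
            raise ValidationError(f"arm table missing column {col}")
    if arm_counts.duplicated(subset=["precursor_id", "mature_id"]).any():
        raise ValidationError("duplicate (precursor_id, mature_id) rows")
    if len(arm_counts) == 0:
        raise ValidationError("arm table has no rows")
    sample_cols = [
        c for c in arm_counts.columns if c not in ("precursor_id", "mature_id")
    ]
    agg = arm_counts.groupby("mature_id", sort=True)[sample_cols].mean()
    return ExpressionMatrix(
        data=agg,
        unit=unit,
        condition=dict(condition) if condition is not None else {},
    )
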