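"""Stand-in differential-expression test, BH adjustment and DE classification.

This module deliberately does NOT reimplement DESeq2.  It offers a simple,
documented log-normal test for the synthetic path: counts are normalised by
median-of-ratios size factors, log2-transformed with a pseudo-count, and
compared between conditions with a variance-moderated two-sample t test
(per-feature pooled variances are shrunk toward a mean-expression lowess
trend with a fixed prior df, in the limma-trend spirit).  Moderation is what
makes two-replicate designs testable at all.  Externally produced DE tables
(e.g. real DESeq2 output) are accepted interchangeably downstream; only the
status classification is recomputed from the thresholds.

Fold-change sign convention: silenced relative to control, so a feature that
goes up when the TF is silenced has positive log2fc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .core_io import ValidationError

DE_METHODS = ("lognormal_t",)

#: Prior degrees of freedom for variance moderation.  Large enough that a
#: two-replicate design borrows most of its variance estimate from the trend.
MODERATION_PRIOR_DF = 50.0

#: Pseudo-count added before log2 transforms.
DEFAULT_C0 = 0.5


@dataclass(frozen=True)
class DEResult:
    """Per-feature differential-expression record."""

    feature_id: str
    log2fc: float
    pvalue: float  # may be NaN when untestable
    fdr: float = float("nan")
    status: str = "ns"  # up / down / ns

    def __post_init__(self) -> None:
        if not math.isnan(self.fdr) and not (0.0 <= self.fdr <= 1.0):
            raise ValidationError("fdr must lie in [0, 1]")
        if self.status not in {"up", "down", "ns"}:
            raise ValidationError("status must be up/down/ns")


@dataclass(frozen=True)
class Thresholds:
    """Every cut-off of the integration pipeline, collected in one object."""

    halfwidth: int = 2500
    min_neglog10p: float = 3.0
    min_overlap: int = 100
    gene_lfc: float = 1.0
    gene_fdr: float = 0.05
    mirna_lfc: float = 0.5
    mirna_fdr: float = 0.1
    min_tpm: float = 1.0
    min_mirna_count: float = 1.0
    pwm_rel_threshold: float = 0.80

    def __post_init__(self) -> None:
        for name in (
            "halfwidth",
            "min_neglog10p",
            "min_overlap",
            "gene_lfc",
            "mirna_lfc",
            "min_tpm",
            "min_mirna_count",
            "pwm_rel_threshold",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("gene_fdr", "mirna_fdr"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean pseudo-reference.

    Features with any zero count are excluded from the median (their
    geometric mean would be zero).
    """
    values = counts.values.astype(float)
    if values.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    all_nonzero = (values > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValidationError(
            "no feature has nonzero counts in every sample; consider a "
            "pseudo-reference fallback (e.g. add a pseudo-count upstream)"
        )
    sub = values[all_nonzero]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    return counts / size_factors(counts)


# ---------------------------------------------------------------------------
# Stand-in DE test
# ---------------------------------------------------------------------------


def de_test(
    counts: pd.DataFrame,
    condition: Mapping[str, str],
    method: str = "lognormal_t",
    c0: float = DEFAULT_C0,
    prior_df: float = MODERATION_PRIOR_DF,
) -> list[DEResult]:
    """Two-condition test on a raw count matrix (features x samples).

    Returns log2fc (silenced vs control on normalised group means, with
    pseudo-count ``c0``) and a p-value from a moderated t on
    log2(normalized + c0).  With fewer than two replicates in either group
    only the fold change is emitted (p = NaN).  Deterministic given inputs.
    """
    if method not in DE_METHODS:
        raise ValidationError(f"unknown method {method!r}; available: {DE_METHODS}")
    ctrl = [s for s in counts.columns if condition.get(s) == "control"]
    sil = [s for s in counts.columns if condition.get(s) == "silenced"]
    if not ctrl or not sil:
        raise ValidationError("need at least one sample per condition")

    norm = normalize_counts(counts)
    mean_c = norm[ctrl].mean(axis=1).values
    mean_s = norm[sil].mean(axis=1).values
    log2fc = np.log2((mean_s + c0) / (mean_c + c0))

    n1, n2 = len(sil), len(ctrl)
    if min(n1, n2) < 2:
        pvals = np.full(len(counts), np.nan)
    else:
        x = np.log2(norm.values + c0)
        xs = x[:, [counts.columns.get_loc(s) for s in sil]]
        xc = x[:, [counts.columns.get_loc(s) for s in ctrl]]
        delta = xs.mean(axis=1) - xc.mean(axis=1)
        df_resid = n1 + n2 - 2
        s2 = (xs.var(axis=1, ddof=1) * (n1 - 1) + xc.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
        s2_prior = _variance_trend(x.mean(axis=1), s2)
        s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
        se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = delta / se
        pvals = np.where(
            np.isfinite(t),
            2.0 * stats.t.sf(np.abs(t), df=prior_df + df_resid),
            np.nan,
        )
        # zero observed difference with zero variance: no evidence against null
        pvals = np.where((se == 0) & (delta == 0), 1.0, pvals)

    return [
        DEResult(feature_id=str(fid), log2fc=float(lfc), pvalue=float(p))
        for fid, lfc, p in zip(counts.index, log2fc, pvals)
    ]


def _variance_trend(mean_expr: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Lowess fit of pooled variances against mean log2 expression.

    Falls back to the global mean variance when there are too few features
    for a stable fit.
    """
    ok = np.isfinite(s2)
    if ok.sum() < 30:
        return np.full_like(s2, float(np.nanmean(s2)) if ok.any() else 0.0)
    fitted = lowess(
        s2[ok], mean_expr[ok], frac=0.5, it=1, xvals=mean_expr, return_sorted=False
    )
    fitted = np.asarray(fitted, dtype=float)
    floor = max(float(np.nanmean(s2[ok])) * 1e-3, 1e-12)
    return np.clip(np.nan_to_num(fitted, nan=float(np.nanmean(s2[ok]))), floor, None)


# ---------------------------------------------------------------------------
# Multiple testing and classification
# ---------------------------------------------------------------------------


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        pm = p[mask]
        if (pm < 0).any() or (pm > 1).any():
            raise ValidationError("p-values must lie in [0, 1]")
        out[mask] = multipletests(pm, method="fdr_bh")[1]
    return out


def classify_de(
    results: Sequence[DEResult], lfc_thresh: float, fdr_thresh: float
) -> list[DEResult]:
    """Attach up/down/ns status; all inequalities strict.

    up:   log2fc >  lfc_thresh and fdr < fdr_thresh
    down: log2fc < -lfc_thresh and fdr < fdr_thresh
    """
    if lfc_thresh <= 0 or fdr_thresh <= 0:
        raise ValidationError("thresholds must be positive")
    out: list[DEResult] = []
    for r in results:
        status = "ns"
        if not math.isnan(r.fdr) and r.fdr < fdr_thresh:
            if r.log2fc > lfc_thresh:
                status = "up"
            elif r.log2fc < -lfc_thresh:
                status = "down"
        out.append(replace(r, status=status))
    return out


def adjust_and_classify(
    results: Sequence[DEResult], lfc_thresh: float, fdr_thresh: float
) -> list[DEResult]:
    """BH-adjust the raw p-values, then classify."""
    fdr = bh_adjust([r.pvalue for r in results])
    withfdr = [replace(r, fdr=float(f)) for r, f in zip(results, fdr)]
    return classify_de(withfdr, lfc_thresh, fdr_thresh)


# ---------------------------------------------------------------------------
# DE table I/O
# ---------------------------------------------------------------------------

DE_COLUMNS = ["feature_id", "log2fc", "pvalue", "fdr", "status"]


def de_results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "log2fc": r.log2fc,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "status": r.status,
            }
            for r in results
        ],
        columns=DE_COLUMNS,
    )


def de_results_from_frame(df: pd.DataFrame) -> list[DEResult]:
    return [
        DEResult(
            feature_id=str(row.feature_id),
            log2fc=float(row.log2fc),
            pvalue=float(row.pvalue) if not pd.isna(row.pvalue) else float("nan"),
            fdr=float(row.fdr) if "fdr" in df.columns and not pd.isna(row.fdr) else float("nan"),
            status=str(row.status) if "status" in df.columns else "ns",
        )
        for row in df.itertuples(index=False)
    ]


def write_de_table(results: Sequence[DEResult], path: str | Path) -> None:
    de_results_to_frame(results).to_csv(path, sep="\t", index=False)
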