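"""Univariate differential expression for the miRNA and protein layers.

The workflow is deliberately simple and transparent: per-sample
normalization (quantile for arrays, median-centering for iTRAQ ratio
tables), log2 fold change as a difference of group means, a two-sided
Welch t-test, optional Benjamini-Hochberg adjustment, and an
up/down/not-significant call against configurable thresholds.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .io import Contrast, OmicsMatrix, SampleMetadata, TriomixError

log = logging.getLogger(__name__)


def quantile_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Force every sample column onto the same (rank-mean) distribution.

    The reference distribution is the row-wise mean of the sorted columns;
    within-column ranks are preserved, ties receive the average of the tied
    reference values.
    """
    X = matrix.values
    if np.isnan(X).any():
        raise TriomixError("quantile normalization requires complete data; impute first")
    n = X.shape[0]
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return dataclasses.replace(matrix, values=out)


def median_center(matrix: OmicsMatrix) -> OmicsMatrix:
    """Subtract each sample's median (per-column location normalization)."""
    med = np.nanmedian(matrix.values, axis=0)
    return dataclasses.replace(matrix, values=matrix.values - med[None, :])


def _group_columns(matrix: OmicsMatrix, meta: SampleMetadata, contrast: Contrast):
    meta.check_matrix(matrix)
    cols_a = [i for i, s in enumerate(matrix.sample_ids) if meta.group_of[s] == contrast.group_a]
    cols_b = [i for i, s in enumerate(matrix.sample_ids) if meta.group_of[s] == contrast.group_b]
    if not cols_a or not cols_b:
        raise TriomixError(f"contrast {contrast} has an empty group in this matrix")
    return cols_a, cols_b


def log2_fold_change(matrix: OmicsMatrix, meta: SampleMetadata, contrast: Contrast) -> np.ndarray:
    """Per-feature mean(group_b) - mean(group_a), on the log2 scale."""
    cols_a, cols_b = _group_columns(matrix, meta, contrast)
    return np.nanmean(matrix.values[:, cols_b], axis=1) - np.nanmean(
        matrix.values[:, cols_a], axis=1
    )


def welch_t(matrix: OmicsMatrix, meta: SampleMetadata, contrast: Contrast):
    """Vectorized two-sided Welch t-test per feature.

    Returns ``(t, df, p)``. The sign of t follows the fold-change
    orientation (positive = higher in ``group_b``). Degenerate features
    with zero variance in both groups get t=0, p=1 when the means agree,
    and p=0 (with a logged warning) when they differ.
    """
    cols_a, cols_b = _group_columns(matrix, meta, contrast)
    A = matrix.values[:, cols_a]
    B = matrix.values[:, cols_b]
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise TriomixError("each group needs >= 2 samples")
    na = np.sum(~np.isnan(A), axis=1).astype(float)
    nb = np.sum(~np.isnan(B), axis=1).astype(float)
    too_sparse = (na < 2) | (nb < 2)
    if too_sparse.any():
        log.warning(
            "%d features have < 2 observed values in a group; their p is set to 1",
            int(too_sparse.sum()),
        )
        # give them harmless placeholder counts; results are overwritten below
        na = np.maximum(na, 2)
        nb = np.maximum(nb, 2)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
        va, vb = np.nanvar(A, axis=1, ddof=1), np.nanvar(B, axis=1, ddof=1)
    va = np.where(np.isnan(va), 0.0, va)
    vb = np.where(np.isnan(vb), 0.0, vb)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    degenerate = se2 == 0
    equal = degenerate & np.isclose(mb, ma)
    unequal = degenerate & ~equal
    t[equal] = 0.0
    df[degenerate] = na[degenerate] + nb[degenerate] - 2
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[equal] = 1.0
    if unequal.any():
        log.warning(
            "%d features have zero variance in both groups but unequal means; p set to 0",
            int(unequal.sum()),
        )
        t[unequal] = np.sign(mb[unequal] - ma[unequal]) * np.inf
        p[unequal] = 0.0
    if too_sparse.any():
        t[too_sparse] = np.nan
        df[too_sparse] = np.nan
        p[too_sparse] = 1.0
    return t, df, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i}(m * p_(j) / j), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise TriomixError("bh_adjust expects a 1-d vector")
    if np.any((p < 0) | (p > 1)):
        raise TriomixError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_de(
    feature_ids: list[str],
    lfc: np.ndarray,
    pvals: np.ndarray,
    cfg: RunConfig | None = None,
    lfc_min: float | None = None,
    t: np.ndarray | None = None,
    df: np.ndarray | None = None,
    q: np.ndarray | None = None,
) -> pd.DataFrame:
    """Call each feature up / down / ns and return a sorted result table.

    ``pvals`` is whatever the caller wants thresholded (raw p or BH q).
    Rows are sorted by p ascending, ties by |lfc| descending then feature
    id. A feature is up iff lfc >= lfc_min and p <= p_de; down iff
    lfc <= -lfc_min and p <= p_de; otherwise ns.
    """
    cfg = cfg or RunConfig()
    thr = cfg.lfc_min if lfc_min is None else lfc_min
    lfc = np.asarray(lfc, float)
    pvals = np.asarray(pvals, float)
    sig = pvals <= cfg.p_de
    direction = np.where(
        sig & (lfc >= thr), "up", np.where(sig & (lfc <= -thr), "down", "ns")
    )
    df_out = pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "log2fc": lfc,
            "t": t if t is not None else np.nan,
            "df": df if df is not None else np.nan,
            "p": pvals,
            "q": q if q is not None else pvals,
            "direction": direction,
        }
    )
    df_out["_abs"] = np.abs(df_out["log2fc"])
    df_out = df_out.sort_values(
        ["p", "_abs", "feature_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_abs").reset_index(drop=True)
    return df_out


NORMALIZATION_BY_LAYER = {"mirna": "quantile", "protein": "median", "metabolite": "none"}


def run_de(
    matrix: OmicsMatrix,
    meta: SampleMetadata,
    contrast: Contrast,
    cfg: RunConfig | None = None,
    normalization: str | None = None,
) -> pd.DataFrame:
    """Full DE stage for one layer: normalize, test, adjust, classify.

    Normalization defaults per layer (quantile for miRNA arrays,
    per-sample median-centering for protein ratio tables, none for
    metabolites). In ``bh`` multiple-testing mode the q-value is
    thresholded; in ``raw`` mode the per-feature p is.
    """
    cfg = cfg or RunConfig()
    contrast.validate(meta, min_per_group=2)
    norm = normalization if normalization is not None else NORMALIZATION_BY_LAYER[matrix.layer]
    if norm == "quantile":
        matrix = quantile_normalize(matrix)
    elif norm == "median":
        matrix = median_center(matrix)
    elif norm != "none":
        raise TriomixError(f"unknown normalization {norm!r}")
    lfc = log2_fold_change(matrix, meta, contrast)
    t, df, p = welch_t(matrix, meta, contrast)
    q = bh_adjust(p)
    thresholded = q if cfg.multiple_testing == "bh" else p
    lfc_min = cfg.protein_lfc_min if matrix.layer == "protein" else cfg.lfc_min
    out = classify_de(matrix.feature_ids, lfc, thresholded, cfg, lfc_min=lfc_min, t=t, df=df, q=q)
    # report the raw p alongside whatever was thresholded
    raw = pd.Series(p, index=matrix.feature_ids)
    out["p_raw"] = raw.loc[out["feature_id"]].to_numpy()
    return out


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table: log2fc, -log10 p, direction."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(de["p_raw"] if "p_raw" in de else de["p"])
    return pd.DataFrame(
        {"feature_id": de["feature_id"], "log2fc": de["log2fc"], "neg_log10_p": neglog, "direction": de["direction"]}
    )
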