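"""From precursor reports to normalized site-level log2 matrices.

The processing chain mirrors a DIA phosphoproteomics workflow:

1. two-report localization filtering -- precursor identities come from a
   strict report (localization probability above the class-I cutoff in at
   least one sample) while quantities come from a loose report exported
   without a probability cutoff;
2. representative-precursor selection -- one precursor per unique
   modified peptide (phos_id), preferring the most complete, then the
   most intense;
3. intensity floor + log2 -- raw intensities below the floor become
   missing (never imputed), the rest are log2 transformed;
4. cyclic-LOESS normalization against a median pseudo-reference;
5. optionally, regression of total-protein abundance out of the
   phosphopeptide signal, leaving "net phosphorylation" residuals.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import META_COLUMNS

logger = logging.getLogger(__name__)


def _run_columns(report: pd.DataFrame) -> list[str]:
    return [c for c in report.columns if c not in META_COLUMNS]


def two_report_localization_filter(strict: pd.DataFrame,
                                   loose: pd.DataFrame,
                                   cutoff: float = 0.75) -> pd.DataFrame:
    """Keep loose-report records whose precursor is confidently localized.

    A precursor passes when its localization probability is strictly
    greater than ``cutoff`` in the strict report (class-I criterion);
    intensities are taken from the loose report, which typically carries
    more quantitative values for the same precursor.
    """
    if len(strict) == 0:
        logger.warning("strict report is empty; localization filter "
                       "returns no records")
        return loose.iloc[0:0].copy()
    confident = strict.loc[strict["localization_prob"] > cutoff,
                           "precursor_id"]
    keep = loose["precursor_id"].isin(set(confident))
    return loose.loc[keep].reset_index(drop=True)


def select_representative_precursor(report: pd.DataFrame) -> pd.DataFrame:
    """One representative precursor per unique modified peptide.

    Per phos_id group: (i) the precursor with the most valid (non-missing)
    intensities wins; (ii) ties are broken by the larger summed raw
    intensity; (iii) remaining ties by the lexicographically smallest
    precursor_id, for determinism.
    """
    run_cols = _run_columns(report)
    vals = report[run_cols].to_numpy(dtype=float)
    n_valid = np.isfinite(vals).sum(axis=1)
    total = np.nansum(np.where(np.isfinite(vals), vals, 0.0), axis=1)
    ranked = report.assign(_n_valid=n_valid, _total=total)
    ranked = ranked.sort_values(
        ["phos_id", "_n_valid", "_total", "precursor_id"],
        ascending=[True, False, False, True], kind="mergesort")
    best = ranked.drop_duplicates("phos_id", keep="first")
    return (best.drop(columns=["_n_valid", "_total"])
            .reset_index(drop=True))


def report_to_matrix(report: pd.DataFrame,
                     feature_col: str = "phos_id") -> pd.DataFrame:
    """Raw intensity matrix (feature x run) from a one-row-per-feature
    report."""
    if report[feature_col].duplicated().any():
        raise ValueError(f"duplicate {feature_col}; select a representative "
                         "precursor first")
    mat = report.set_index(feature_col)[_run_columns(report)].astype(float)
    return mat


def floor_log_transform(matrix: pd.DataFrame,
                        floor: float = 500.0) -> pd.DataFrame:
    """Replace raw intensities strictly below ``floor`` by NaN, then log2.

    Values equal to the floor survive (the rule is a strict ``<``).
    """
    vals = matrix.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative raw intensity")
    out = np.where(vals < floor, np.nan, vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # log2 of NaN
        out = np.log2(out)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def loess_normalize(matrix: pd.DataFrame, span: float = 0.7,
                    iterations: int = 2,
                    min_valid: int = 30) -> pd.DataFrame:
    """Cyclic-LOESS normalization against a median pseudo-reference.

    Per iteration and per sample, the difference M = sample - reference is
    smoothed against the average A = (sample + reference)/2 on complete
    pairs (reference = per-feature median across samples) and the fitted
    trend is subtracted, removing intensity-dependent distortions the way
    MA-plot normalization does.  Missing cells stay missing.  Samples with
    fewer than ``min_valid`` values fall back to median centering.
    """
    if matrix.shape[1] < 2:
        logger.warning("single sample; normalization is a no-op")
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float).copy()
    for _ in range(iterations):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            ref = np.nanmedian(vals, axis=1)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            ok = np.isfinite(col) & np.isfinite(ref)
            if ok.sum() < min_valid:
                logger.warning("sample %s has <%d values; median centering",
                               matrix.columns[j], min_valid)
                if ok.any():
                    col[np.isfinite(col)] -= np.nanmedian(col - ref)
                continue
            m = col[ok] - ref[ok]
            a = (col[ok] + ref[ok]) / 2.0
            fit = lowess(m, a, frac=span, return_sorted=True)
            trend = np.interp(a, fit[:, 0], fit[:, 1])
            col[ok] = col[ok] - trend
    out = pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)
    return out


def regress_out_protein(phospho: pd.DataFrame, proteome: pd.DataFrame,
                        feature_map: pd.Series | dict,
                        min_pairs: int = 3
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Remove protein-abundance signal from phosphopeptide signal.

    Per phosphopeptide, ordinary least squares of its log2 intensities
    (y) on the matched protein's log2 intensities (x) across shared
    samples; returned values are the residuals, i.e. phosphorylation not
    driven by protein abundance.  Features with fewer than ``min_pairs``
    complete (y, x) pairs, or without a mapped/measured protein, are
    passed through mean-centered and flagged.

    Returns the residual matrix and a boolean Series marking features
    that were actually regressed (True) versus centered (False).
    """
    feature_map = pd.Series(feature_map)
    shared = [s for s in phospho.columns if s in proteome.columns]
    if not shared:
        raise ValueError("no overlapping samples between phospho and "
                         "proteome matrices")
    out = phospho.copy()
    regressed = pd.Series(False, index=phospho.index)
    for feat in phospho.index:
        y = phospho.loc[feat].to_numpy(dtype=float)
        prot = feature_map.get(feat)
        x_full = np.full(y.shape, np.nan)
        if prot is not None and prot in proteome.index:
            prow = proteome.loc[prot]
            for k, s in enumerate(phospho.columns):
                if s in prow.index:
                    x_full[k] = prow[s]
        ok = np.isfinite(y) & np.isfinite(x_full)
        if ok.sum() >= min_pairs and np.nanstd(x_full[ok]) > 0:
            slope, intercept = np.polyfit(x_full[ok], y[ok], 1)
            resid = y - (intercept + slope * x_full)
            # samples lacking x keep y minus the feature's mean level
            resid[~np.isfinite(x_full) & np.isfinite(y)] = \
                (y - np.nanmean(y[ok]))[~np.isfinite(x_full) & np.isfinite(y)]
            out.loc[feat] = resid
            regressed[feat] = True
        else:
            out.loc[feat] = y - np.nanmean(y) if np.isfinite(y).any() else y
    return out, regressed


def preprocess_report(strict: pd.DataFrame, loose: pd.DataFrame,
                      localization_cutoff: float = 0.75,
                      floor: float = 500.0, span: float = 0.7,
                      iterations: int = 2) -> pd.DataFrame:
    """Full chain: localization filter, representative selection, floor +
    log2, LOESS normalization.  Returns a phos_id x run log2 matrix."""
    filtered = two_report_localization_filter(strict, loose,
                                              localization_cutoff)
    run_cols = _run_columns(filtered)
    floored = filtered.copy()
    floored[run_cols] = np.where(
        filtered[run_cols].to_numpy(dtype=float) < floor, np.nan,
        filtered[run_cols].to_numpy(dtype=float))
    best = select_representative_precursor(floored)
    raw = report_to_matrix(best)
    logmat = floor_log_transform(raw, floor)
    return loess_normalize(logmat, span=span, iterations=iterations)
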