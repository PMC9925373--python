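"""Per-cell-line differential statistics: treated vs time-matched control.

Two routes are provided, mirroring the split common in proteomics
practice:

* :func:`ttest_differential` -- plain two-sided Student's t-test with
  pooled variance and hard thresholds (p < .01 and linear fold change
  > 1.5); its +1/0/-1 calls feed the consensus MetScore.
* :func:`moderated_ttest` -- empirical-Bayes moderated t in the limma
  style (per-feature variances shrunk toward a common prior estimated by
  method of moments on log sample variances); its t-values feed kinase
  activity inference.

Comparisons use the time-matched control: the 30-min treatment is
compared against the 0-h control and the 24-h treatment against the 24-h
control, so that nutrient exhaustion of the medium is not mistaken for a
drug effect.  Features with fewer than two valid values in either group
get a ``missing`` call instead of being imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io import COMPARISONS, design_runs

MISSING_CALL = np.nan


def make_call(p: float, log2fc: float,
              config: PipelineConfig | None = None) -> float:
    """Significance call: +1 up, -1 down, 0 non-regulated, NaN missing.

    +1 requires p < p_threshold and log2fc > log2(fc_threshold); -1 the
    symmetric condition.  The fold-change cutoff is applied on |log2fc|.
    """
    config = config or PipelineConfig()
    if not np.isfinite(p) or not np.isfinite(log2fc):
        return MISSING_CALL
    lfc_cut = np.log2(config.fc_threshold)
    if p < config.p_threshold and log2fc > lfc_cut:
        return 1.0
    if p < config.p_threshold and log2fc < -lfc_cut:
        return -1.0
    return 0.0


def _group_values(matrix: pd.DataFrame, design: pd.DataFrame,
                  cell_line: str, comparison: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    if comparison not in COMPARISONS:
        raise ValueError(f"unknown comparison {comparison!r}")
    if cell_line not in set(design["cell_line"]):
        raise ValueError(f"unknown cell line {cell_line!r}")
    treated_cond, control_cond = COMPARISONS[comparison]
    t_runs = [r for r in design_runs(design, cell_line, treated_cond)
              if r in matrix.columns]
    c_runs = [r for r in design_runs(design, cell_line, control_cond)
              if r in matrix.columns]
    return (matrix[t_runs].to_numpy(dtype=float),
            matrix[c_runs].to_numpy(dtype=float))


def _pooled_t(treated: np.ndarray, control: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                         np.ndarray, np.ndarray]:
    """Row-wise pooled-variance Student t on possibly-missing data.

    Returns (log2fc, t, p, df, s2, valid) where s2 is the pooled variance
    and valid marks rows with >=2 values per group.  Degenerate rows with
    zero pooled variance get t=0, p=1 when the means agree and t=+/-inf,
    p~0 otherwise.
    """
    n1 = np.isfinite(treated).sum(axis=1)
    n2 = np.isfinite(control).sum(axis=1)
    valid = (n1 >= 2) & (n2 >= 2)
    with warnings.catch_warnings(), \
            np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        m1 = np.nanmean(treated, axis=1)
        m2 = np.nanmean(control, axis=1)
        v1 = np.nanvar(treated, axis=1, ddof=1)
        v2 = np.nanvar(control, axis=1, ddof=1)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
    log2fc = m1 - m2
    zero_var = valid & (s2 == 0)
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & (log2fc == 0), 0.0, t)
        t = np.where(zero_var & (log2fc != 0), np.sign(log2fc) * np.inf, t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), np.finfo(float).tiny, p)
    p = np.where(zero_var & (log2fc == 0), 1.0, p)
    return log2fc, t, p, df.astype(float), s2, valid


def _assemble(matrix: pd.DataFrame, cell_line: str, comparison: str,
              log2fc, t, p, valid, config: PipelineConfig) -> pd.DataFrame:
    q = np.full(p.shape, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    calls = np.array([
        make_call(pi, fi, config) if ok else MISSING_CALL
        for pi, fi, ok in zip(p, log2fc, valid)])
    return pd.DataFrame({
        "feature": matrix.index,
        "cell_line": cell_line,
        "comparison": comparison,
        "log2fc": np.where(valid, log2fc, np.nan),
        "t_stat": np.where(valid, t, np.nan),
        "p_value": np.where(valid, p, np.nan),
        "q_value": q,
        "call": calls,
    })


def ttest_differential(matrix: pd.DataFrame, design: pd.DataFrame,
                       cell_line: str, comparison: str,
                       config: PipelineConfig | None = None) -> pd.DataFrame:
    """Plain pooled-variance Student t-test per feature.

    log2fc = mean(treated) - mean(control) in log2 space.  Features with
    fewer than ``config.min_valid_per_group`` valid values in either
    group are reported with NaN statistics and a missing call.
    """
    config = config or PipelineConfig()
    treated, control = _group_values(matrix, design, cell_line, comparison)
    log2fc, t, p, df, s2, valid = _pooled_t(treated, control)
    n1 = np.isfinite(treated).sum(axis=1)
    n2 = np.isfinite(control).sum(axis=1)
    valid &= ((n1 >= config.min_valid_per_group)
              & (n2 >= config.min_valid_per_group))
    return _assemble(matrix, cell_line, comparison, log2fc, t, p, valid,
                     config)


# ---------------------------------------------------------------------------
# moderated t (empirical Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) / x < 1e-10):
            break
    return x


def estimate_moderation_params(s2: np.ndarray, df: np.ndarray
                               ) -> tuple[float, float]:
    """Prior df d0 and prior variance s0^2 by moments on log variances.

    Fits a scaled F distribution to the sample variances: with
    z = log(s2), e = z - digamma(df/2) + log(df/2), the prior df solves
    trigamma(d0/2) = var(e) - mean(trigamma(df/2)) and the prior
    variance is exp(mean(e) + digamma(d0/2) - log(d0/2)).  Returns
    (inf, exp(mean(e))) when the observed spread is no larger than
    expected under a single common variance.
    """
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >=2 features with estimable variance")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    excess = evar - np.mean(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * float(_trigamma_inverse(np.array([excess]))[0])
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0)
                        - np.log(d0 / 2.0)))
    return d0, s0sq


def moderated_ttest(matrix: pd.DataFrame, design: pd.DataFrame,
                    cell_line: str, comparison: str,
                    config: PipelineConfig | None = None,
                    prior: tuple[float, float] | None = None
                    ) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per feature.

    The per-feature pooled variance s^2 with d residual df is shrunk
    toward the prior: s~^2 = (d0*s0^2 + d*s^2) / (d0 + d); the moderated
    t = log2fc / (s~ * sqrt(1/n1 + 1/n2)) is referred to a t distribution
    with d + d0 degrees of freedom.  ``prior`` overrides the estimated
    (d0, s0^2), which is mainly useful for the d0=0 / d0=inf limit cases.
    """
    config = config or PipelineConfig()
    treated, control = _group_values(matrix, design, cell_line, comparison)
    log2fc, _, _, df, s2, valid = _pooled_t(treated, control)
    n1 = np.isfinite(treated).sum(axis=1)
    n2 = np.isfinite(control).sum(axis=1)
    valid &= ((n1 >= config.min_valid_per_group)
              & (n2 >= config.min_valid_per_group))
    if prior is None:
        d0, s0sq = estimate_moderation_params(s2[valid], df[valid])
    else:
        d0, s0sq = prior
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_mod = np.full(s2.shape, s0sq)
            df_mod = np.full(df.shape, np.inf)
        else:
            s2_mod = (d0 * s0sq + df * s2) / (d0 + df)
            df_mod = df + d0
        se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
        t_mod = log2fc / se
    with np.errstate(invalid="ignore"):
        p = np.where(np.isinf(df_mod),
                     2.0 * stats.norm.sf(np.abs(t_mod)),
                     2.0 * stats.t.sf(np.abs(t_mod), df_mod))
    p = np.where(np.isinf(t_mod), np.finfo(float).tiny, p)
    p = np.where(valid & (s2_mod == 0) & (log2fc == 0), 1.0, p)
    return _assemble(matrix, cell_line, comparison, log2fc, t_mod, p,
                     valid, config)


def loose_fold_changes(matrix: pd.DataFrame, design: pd.DataFrame,
                       comparison: str = "met24_vs_ctrl24") -> pd.DataFrame:
    """Replicate-mean log2 fold changes requiring >=1 value per condition.

    A deliberately permissive companion to the t-test: replicate values
    are averaged per condition (at least one value suffices) and the
    difference of means is the log2 fold change, yielding a more complete
    matrix for enrichment-style analyses.  Returns feature x cell_line.
    """
    treated_cond, control_cond = COMPARISONS[comparison]
    out = {}
    for line in pd.unique(design["cell_line"]):
        t_runs = [r for r in design_runs(design, line, treated_cond)
                  if r in matrix.columns]
        c_runs = [r for r in design_runs(design, line, control_cond)
                  if r in matrix.columns]
        with np.errstate(invalid="ignore"):
            m1 = matrix[t_runs].mean(axis=1, skipna=True)
            m2 = matrix[c_runs].mean(axis=1, skipna=True)
        out[line] = m1 - m2
    return pd.DataFrame(out, index=matrix.index)


def panel_calls(matrix: pd.DataFrame, design: pd.DataFrame,
                comparison: str = "met24_vs_ctrl24",
                config: PipelineConfig | None = None,
                moderated: bool = False) -> pd.DataFrame:
    """Call matrix (feature x cell_line) across the whole panel."""
    config = config or PipelineConfig()
    test = moderated_ttest if moderated else ttest_differential
    cols = {}
    for line in pd.unique(design["cell_line"]):
        res = test(matrix, design, line, comparison, config)
        cols[line] = res.set_index("feature")["call"]
    return pd.DataFrame(cols, index=matrix.index)
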