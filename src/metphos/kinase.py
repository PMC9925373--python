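"""Kinase (and phosphatase) activity inference from substrate statistics.

Given per-site moderated t-values for one cell line and a signed
kinase->site prior (sign +1 for phosphorylation, -1 for
dephosphorylation), each enzyme's activity is summarized as a normalized
enrichment score (NES):

    S  = sum_i sign_i * t_i / sqrt(n)        over measured targets
    NES = (S - mean(S*)) / sd(S*)

where the null scores S* come from permuting the t-value vector across
all measured sites.  Permutations are shared across kinases within a
cell line so NES values are on a common scale; the two-sided permutation
p-value uses a +1 pseudocount.  A positive NES for a kinase means its
substrates are collectively up-shifted (inferred activation); for a
phosphatase (negative-sign edges) activity rises when its targets fall.

Only enzymes with at least ``min_targets`` measured substrates (default
5) are reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def kinase_nes(t_values: pd.Series, prior: pd.DataFrame,
               min_targets: int = 5, n_perm: int = 1000,
               seed: int = 0, cell_line: str | None = None
               ) -> pd.DataFrame:
    """NES per kinase from per-site t-values and a signed prior.

    ``t_values`` is indexed by site key; ``prior`` has columns kinase,
    target_site_key, sign.  Kinases with fewer than ``min_targets``
    measured targets are omitted (logged).
    """
    t_values = t_values.dropna()
    if len(t_values) == 0:
        raise ValueError("no measured t-values")
    site_index = {s: i for i, s in enumerate(t_values.index)}
    t = t_values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    # shared permutations: one set of shuffled t-vectors for all kinases
    perms = np.empty((n_perm, len(t)))
    for b in range(n_perm):
        perms[b] = rng.permutation(t)
    rows = []
    for kin, grp in prior.groupby("kinase", sort=True):
        idx, signs = [], []
        for s, sign in zip(grp["target_site_key"], grp["sign"]):
            if s in site_index:
                idx.append(site_index[s])
                signs.append(sign)
        n = len(idx)
        if n < min_targets:
            logger.info("kinase %s has %d measured targets (<%d); omitted",
                        kin, n, min_targets)
            continue
        idx = np.asarray(idx)
        signs = np.asarray(signs, dtype=float)
        s_obs = float(signs @ t[idx] / np.sqrt(n))
        s_null = perms[:, idx] @ signs / np.sqrt(n)
        mu, sd = s_null.mean(), s_null.std(ddof=1)
        nes = 0.0 if sd == 0 else (s_obs - mu) / sd
        p = (1.0 + np.sum(np.abs(s_null - mu) >= abs(s_obs - mu))) \
            / (n_perm + 1.0)
        rows.append({"kinase": kin, "cell_line": cell_line, "nes": nes,
                     "p_value": p, "n_targets": n})
    return pd.DataFrame(rows)


def activity_matrix(activities: pd.DataFrame,
                    p_threshold: float = 0.05) -> pd.DataFrame:
    """Kinase x cell-line NES matrix restricted to informative kinases.

    Keeps kinases with a significant activity (p < ``p_threshold``) in at
    least one cell line AND an estimated activity in every cell line, so
    the heatmap has no holes.  Rows/columns are sorted for determinism.
    """
    lines = sorted(pd.unique(activities["cell_line"].dropna()))
    if len(lines) < 2:
        raise ValueError("need activities from >= 2 cell lines")
    wide = activities.pivot_table(index="kinase", columns="cell_line",
                                  values="nes", aggfunc="first")
    pmat = activities.pivot_table(index="kinase", columns="cell_line",
                                  values="p_value", aggfunc="first")
    estimated_everywhere = wide[lines].notna().all(axis=1)
    significant_somewhere = (pmat[lines] < p_threshold).any(axis=1)
    keep = estimated_everywhere & significant_somewhere
    return wide.loc[sorted(wide.index[keep]), lines]
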