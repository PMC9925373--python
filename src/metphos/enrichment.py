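"""Set-based and sequence-based enrichment analyses.

Covers four families used to interpret the consensus-score segments:

* Fisher's exact test on 2x2 membership tables, counting either
  phosphorylation events (by site) or unique proteins (by protein);
* 1D rank enrichment: per annotation term, a two-sided Mann-Whitney U of
  member values (e.g. log2 fold changes) against non-members, with a
  rank-score effect in [-1, 1];
* a rank-shift (Wilcoxon rank-sum) test for a single feature set, e.g.
  testing whether sites on a curated protein list shift upward;
* sequence analyses on 15-residue windows centred on the phosphoacceptor:
  positional residue enrichment (iceLogo-style frequency differences with
  per-cell p-values) and greedy motif extraction (motif-x style: fix the
  most significant position/residue pair, filter, recurse).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
WINDOW_LEN = 15
CENTER = WINDOW_LEN // 2


# ---------------------------------------------------------------------------
# set-based enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(foreground: set, background: set,
                      annotations: dict[str, set],
                      counting: str = "by_site",
                      feature_to_protein: dict | None = None
                      ) -> pd.DataFrame:
    """Two-sided Fisher's exact test per annotation term.

    ``counting='by_site'`` counts phosphorylation events directly;
    ``'by_protein'`` first collapses features to unique proteins via
    ``feature_to_protein`` so proteins with many phosphosites do not
    dominate.  Terms without foreground overlap are reported with p=1.
    """
    if not foreground:
        raise ValueError("empty foreground")
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    if counting == "by_protein":
        if feature_to_protein is None:
            raise ValueError("by_protein counting needs feature_to_protein")
        fg = {feature_to_protein.get(f, f) for f in foreground}
        bg = {feature_to_protein.get(f, f) for f in background}
        annotations = {t: {feature_to_protein.get(m, m) for m in members}
                       for t, members in annotations.items()}
    elif counting == "by_site":
        fg, bg = set(foreground), set(background)
    else:
        raise ValueError(f"unknown counting mode {counting!r}")
    rows = []
    for term, members in annotations.items():
        members = members & bg
        a = len(fg & members)
        b = len(fg - members)
        c = len(members - fg)
        d = len(bg) - a - b - c
        if a == 0:
            odds, p = 0.0, 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]],
                                         alternative="two-sided")
        rows.append({"term": term, "n_fg": a, "n_term": a + c,
                     "odds_ratio": odds, "p_value": p})
    res = pd.DataFrame(rows)
    if len(res):
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res = res.sort_values("p_value", kind="mergesort").reset_index(
            drop=True)
    return res


def one_d_enrichment(values: pd.Series, annotations: dict[str, set],
                     min_members: int = 5) -> pd.DataFrame:
    """Per-term rank enrichment of a numeric feature score.

    For each term, a two-sided Mann-Whitney U compares member values
    against non-member values; the effect is the rank score
    ``2 * (mean member rank - mean non-member rank) / n`` in [-1, 1]
    (positive = members sit high in the ranking).  Terms with fewer than
    ``min_members`` members carrying values are excluded.
    """
    values = values.dropna()
    ranks = values.rank()
    n = len(values)
    rows = []
    for term, members in annotations.items():
        in_term = values.index.isin(members)
        k = int(in_term.sum())
        if k < min_members:
            logger.info("term %r below min_members (%d < %d); skipped",
                        term, k, min_members)
            continue
        if k == n:
            continue
        _, p = stats.mannwhitneyu(values[in_term], values[~in_term],
                                  alternative="two-sided")
        score = 2.0 * (ranks[in_term].mean() - ranks[~in_term].mean()) / n
        rows.append({"term": term, "n_members": k, "score": score,
                     "p_value": p})
    res = pd.DataFrame(rows)
    if len(res):
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res = res.sort_values("p_value", kind="mergesort").reset_index(
            drop=True)
    return res


def set_shift_test(values: pd.Series, member_set: set
                   ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of a set shift.

    Returns (p_value, median(member values) - median(non-member values)).
    Both groups need at least 3 values.
    """
    values = values.dropna()
    in_set = values.index.isin(member_set)
    members = values[in_set]
    rest = values[~in_set]
    if len(members) < 3 or len(rest) < 3:
        raise ValueError("both groups need >= 3 values")
    _, p = stats.mannwhitneyu(members, rest, alternative="two-sided")
    return float(p), float(members.median() - rest.median())


def pairwise_set_shift(values: pd.Series,
                       groups: dict[str, set]) -> pd.DataFrame:
    """All pairwise rank-shift tests between named feature groups, with
    Benjamini-Hochberg correction across the pairs."""
    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va = values[values.index.isin(groups[a])].dropna()
            vb = values[values.index.isin(groups[b])].dropna()
            if len(va) < 3 or len(vb) < 3:
                continue
            _, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append({"group_a": a, "group_b": b, "p_value": p,
                         "median_diff": va.median() - vb.median()})
    res = pd.DataFrame(rows)
    if len(res):
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
    return res


# ---------------------------------------------------------------------------
# sequence windows
# ---------------------------------------------------------------------------

def _check_windows(windows: list[str]) -> None:
    for w in windows:
        if len(w) != WINDOW_LEN:
            raise ValueError(f"window {w!r} is not {WINDOW_LEN} residues")


def icelogo_positional(foreground: list[str], background: list[str],
                       p_cutoff: float = 0.05,
                       exact_threshold: int = 30) -> pd.DataFrame:
    """Positional residue enrichment between two window sets.

    For each of the 15 positions x 20 residues, the foreground frequency
    is compared with the background frequency; the effect is the
    frequency difference (fg - bg) and the p-value is a two-sided test of
    the foreground count against the background proportion (normal
    approximation to the sampling distribution; exact binomial when the
    background holds fewer than ``exact_threshold`` windows).  Padding
    characters are excluded from the per-position denominators.  Cells
    with p < ``p_cutoff`` are flagged enriched (+1) or depleted (-1).
    """
    _check_windows(foreground)
    _check_windows(background)
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    rows = []
    for pos in range(WINDOW_LEN):
        fg_col = [w[pos] for w in foreground if w[pos] != PAD]
        bg_col = [w[pos] for w in background if w[pos] != PAD]
        n_fg, n_bg = len(fg_col), len(bg_col)
        if n_fg == 0 or n_bg == 0:
            continue
        for aa in AMINO_ACIDS:
            k = fg_col.count(aa)
            p_bg = bg_col.count(aa) / n_bg
            freq_fg = k / n_fg
            if n_bg < exact_threshold:
                p = stats.binomtest(k, n_fg, p_bg).pvalue if 0 < p_bg < 1 \
                    else (1.0 if freq_fg == p_bg else 0.0)
            else:
                se = np.sqrt(p_bg * (1 - p_bg) / n_fg)
                if se == 0:
                    p = 1.0 if freq_fg == p_bg else 0.0
                else:
                    z = (freq_fg - p_bg) / se
                    p = 2.0 * stats.norm.sf(abs(z))
            flag = 0
            if p < p_cutoff:
                flag = 1 if freq_fg > p_bg else -1
            rows.append({"position": pos - CENTER, "residue": aa,
                         "freq_fg": freq_fg, "freq_bg": p_bg,
                         "freq_diff": freq_fg - p_bg, "p_value": p,
                         "flag": flag})
    return pd.DataFrame(rows)


@dataclass
class Motif:
    """An extracted sequence motif.

    ``pattern`` is a 15-character string with '.' at unconstrained
    positions (e.g. ``.......S P......`` without the space); ``fixed``
    lists the (relative position, residue) pairs in extraction order with
    their stepwise binomial p-values; ``n_fg`` counts supporting
    foreground windows; ``score`` is the cumulative -log10 p.
    """

    pattern: str
    fixed: list
    n_fg: int
    score: float

    def matches(self, window: str) -> bool:
        return re.fullmatch(self.pattern.replace(".", "[A-Z_]"),
                            window) is not None


def _binom_upper(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p)."""
    if p <= 0:
        return 0.0 if k > 0 else 1.0
    if p >= 1:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def motif_extract(foreground: list[str], background: list[str],
                  min_occurrence: int = 20, p_threshold: float = 1e-6,
                  max_depth: int = 5) -> list[Motif]:
    """Greedy motif-x-style extraction of over-represented motifs.

    Windows whose central residue is S/T are processed separately from
    those centred on Y.  Within a class, the algorithm repeatedly finds
    the (position, residue) pair with the smallest upper-tail binomial
    p-value given the current foreground/background; if p <
    ``p_threshold`` and the pair occurs in at least ``min_occurrence``
    foreground windows it is fixed into the motif and both sets are
    filtered to matching windows, recursing until no pair qualifies.
    The completed motif's supporting foreground windows are removed and
    extraction restarts, so motifs have disjoint support.
    """
    if not foreground:
        return []
    _check_windows(foreground)
    _check_windows(background)
    motifs: list[Motif] = []
    for central in ("ST", "Y"):
        fg_pool = [w for w in foreground if w[CENTER] in central]
        bg_pool = [w for w in background if w[CENTER] in central]
        while True:
            motif = _extract_one(fg_pool, bg_pool, min_occurrence,
                                 p_threshold, max_depth)
            if motif is None:
                break
            motifs.append(motif)
            fg_pool = [w for w in fg_pool if not motif.matches(w)]
    return motifs


def _extract_one(fg: list[str], bg: list[str], min_occurrence: int,
                 p_threshold: float, max_depth: int) -> Motif | None:
    pattern = ["."] * WINDOW_LEN
    fixed: list[tuple[int, str, float]] = []
    cur_fg, cur_bg = list(fg), list(bg)
    for _ in range(max_depth):
        best = None
        for pos in range(WINDOW_LEN):
            if pattern[pos] != ".":
                continue
            bg_col = [w[pos] for w in cur_bg if w[pos] != PAD]
            n_bg = len(bg_col)
            if n_bg == 0:
                continue
            for aa in AMINO_ACIDS:
                k = sum(1 for w in cur_fg if w[pos] == aa)
                if k < min_occurrence:
                    continue
                p_bg = bg_col.count(aa) / n_bg
                p = _binom_upper(k, len(cur_fg), p_bg)
                if p < p_threshold and (best is None or p < best[0]):
                    best = (p, pos, aa, k)
        if best is None:
            break
        p, pos, aa, _ = best
        pattern[pos] = aa
        fixed.append((pos - CENTER, aa, p))
        cur_fg = [w for w in cur_fg if w[pos] == aa]
        cur_bg = [w for w in cur_bg if w[pos] == aa]
    if not fixed:
        return None
    # the central acceptor is part of the reported pattern
    if cur_fg:
        centrals = {w[CENTER] for w in cur_fg}
        if len(centrals) == 1:
            pattern[CENTER] = centrals.pop()
    score = float(sum(-np.log10(max(p, 1e-300)) for _, _, p in fixed))
    return Motif("".join(pattern), fixed, len(cur_fg), score)


def read_gmt(path) -> dict[str, set]:
    """Annotation sets from a GMT-style TSV: term, level, then members."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out[parts[0]] = set(p for p in parts[2:] if p)
    return out
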