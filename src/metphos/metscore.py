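"""MetScore: an integer consensus score of drug response across a panel.

For every phosphosite with a valid differential call in every cell line
of the panel (the "complete matrix"), the MetScore is the signed count of
cell lines where the site responded: +1 per significantly up-regulated
line, -1 per significantly down-regulated line, 0 otherwise.  With L cell
lines the score ranges over the integers [-L, L]; |score| close to L
marks a site that responds consistently across the whole panel.

Scores are stratified into five segments for downstream enrichment:
G1 (consistently up) through G3 (unperturbed) to G5 (consistently down).
Sites with |score| at or above a high cutoff (10 of 12 lines by default)
form the consensus response signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: published stratification of the panel's 14,032-site complete matrix
PANEL_SEGMENT_COUNTS = {"G1": 1207, "G2": 1660, "G3": 8344,
                        "G4": 1607, "G5": 1214}


@dataclass
class SegmentScheme:
    """Inclusive integer score intervals per segment.

    The default bins for a 12-line panel: G1=[4,12], G2=[2,3], G3=[-1,1],
    G4=[-3,-2], G5=[-12,-4].  Bins must tile [-L, L] with no overlap.
    """

    n_lines: int = 12
    bins: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bins:
            L = self.n_lines
            self.bins = {"G1": (4, L), "G2": (2, 3), "G3": (-1, 1),
                         "G4": (-3, -2), "G5": (-L, -4)}
        covered = sorted(s for lo, hi in self.bins.values()
                         for s in range(lo, hi + 1))
        expected = list(range(-self.n_lines, self.n_lines + 1))
        if covered != expected:
            raise ValueError("segment bins must partition "
                             f"[-{self.n_lines}, {self.n_lines}] exactly")

    def segment_of(self, score: int) -> str:
        for name, (lo, hi) in self.bins.items():
            if lo <= score <= hi:
                return name
        raise ValueError(f"score {score} outside the scheme range")


def compute_metscore(calls: pd.DataFrame) -> pd.DataFrame:
    """Sum +1/0/-1 calls across cell lines for complete-case features.

    ``calls`` is a feature x cell_line matrix with entries +1, 0, -1 or
    NaN (missing).  Features with any missing call are excluded: the
    score is only meaningful when the site was testable in every line.
    Returns a DataFrame indexed by feature with columns ``score`` (int)
    and ``n_lines_tested``.
    """
    if calls.shape[1] < 2:
        raise ValueError("need calls from at least 2 cell lines")
    vals = calls.to_numpy(dtype=float)
    bad = set(np.unique(vals[np.isfinite(vals)])) - {-1.0, 0.0, 1.0}
    if bad:
        raise ValueError(f"calls must be +1/0/-1/NaN, found {sorted(bad)}")
    complete = np.isfinite(vals).all(axis=1)
    scores = vals[complete].sum(axis=1).astype(int)
    return pd.DataFrame(
        {"score": scores, "n_lines_tested": calls.shape[1]},
        index=calls.index[complete])


def stratify(table: pd.DataFrame, scheme: SegmentScheme | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each feature its segment and summarize segment occupancy.

    Returns (table with added ``segment`` column, summary with per-
    segment count and fraction; fractions sum to 1).
    """
    scheme = scheme or SegmentScheme()
    out = table.copy()
    out["segment"] = [scheme.segment_of(int(s)) for s in out["score"]]
    counts = out["segment"].value_counts()
    summary = pd.DataFrame({
        "segment": list(scheme.bins),
        "count": [int(counts.get(seg, 0)) for seg in scheme.bins],
    })
    summary["fraction"] = summary["count"] / max(len(out), 1)
    return out, summary


def extract_signature(table: pd.DataFrame, min_abs_score: int = 10
                      ) -> pd.DataFrame:
    """Features with |score| >= min_abs_score, i.e. the consensus
    signature; sorted by |score| descending, then feature key.

    Adds a ``direction`` column (+1 up, -1 down).
    """
    sel = table[table["score"].abs() >= min_abs_score].copy()
    sel["direction"] = np.sign(sel["score"]).astype(int)
    sel["_abs"] = sel["score"].abs()
    sel["_key"] = sel.index.astype(str)
    sel = sel.sort_values(["_abs", "_key"], ascending=[False, True],
                          kind="mergesort")
    return sel.drop(columns=["_abs", "_key"])
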