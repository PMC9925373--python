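"""Signature-site <-> drug bipartite networks and connectivity scoring.

Sites of the consensus response signature are linked to drugs through a
precomputed site~drug-sensitivity association table; per site only the
``top_n`` smallest-p associations are kept.  Drugs are ranked by degree
(number of distinct signature sites they connect to), nominating
compounds whose sensitivity profile tracks many signature sites.

Separately, a query phosphorylation signature can be compared with
reference perturbation profiles by a connectivity score in [-1, 1]
(Spearman rank correlation over shared sites): +1 the most similar
profile, -1 the most opposite.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


def build_drug_network(signature_sites: list[str],
                       associations: pd.DataFrame,
                       top_n: int = 50) -> tuple[nx.Graph, pd.DataFrame]:
    """Bipartite site-drug network from per-site top associations.

    Per signature site the ``top_n`` associations with the smallest
    p-values are kept (ties broken by drug name for determinism);
    associations for non-signature sites are ignored.  Returns the graph
    (nodes carry ``bipartite`` attributes 'site'/'drug'; edges carry the
    association ``direction``) and a drug table ranked by degree.
    """
    if not list(signature_sites):
        raise ValueError("empty signature")
    sig = set(signature_sites)
    assoc = associations[associations["site_key"].isin(sig)]
    kept = (assoc.sort_values(["p_value", "drug"], kind="mergesort")
            .groupby("site_key", sort=False)
            .head(top_n))
    g = nx.Graph()
    for site in sorted(sig & set(kept["site_key"])):
        g.add_node(site, bipartite="site")
    for row in kept.itertuples(index=False):
        g.add_node(row.drug, bipartite="drug")
        g.add_edge(row.site_key, row.drug, direction=row.direction,
                   p_value=row.p_value)
    drugs = sorted(n for n, d in g.nodes(data=True)
                   if d["bipartite"] == "drug")
    ranking = pd.DataFrame({
        "drug": drugs,
        "degree": [g.degree(d) for d in drugs],
    }).sort_values(["degree", "drug"], ascending=[False, True],
                   kind="mergesort").reset_index(drop=True)
    return g, ranking


def connectivity_score(query: pd.Series, reference: pd.Series,
                       min_shared: int = 5) -> dict:
    """Spearman connectivity between a query signature and a reference
    profile over their shared sites.

    Returns a dict with ``score`` in [-1, 1] (NaN with a ``reason`` when
    fewer than ``min_shared`` sites overlap) and ``n_shared``.
    """
    shared = query.dropna().index.intersection(reference.dropna().index)
    n = len(shared)
    if n < min_shared:
        return {"score": np.nan, "n_shared": n,
                "reason": f"only {n} shared features (<{min_shared})"}
    rho, _ = stats.spearmanr(query[shared], reference[shared])
    return {"score": float(rho), "n_shared": n, "reason": None}


def connectivity_table(query: pd.Series,
                       references: dict[str, pd.Series],
                       min_shared: int = 5) -> pd.DataFrame:
    """Connectivity of one query against a library of reference
    profiles, sorted by descending score."""
    rows = []
    for name, ref in references.items():
        res = connectivity_score(query, ref, min_shared)
        rows.append({"reference": name, **res})
    return (pd.DataFrame(rows)
            .sort_values("score", ascending=False, kind="mergesort")
            .reset_index(drop=True))
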