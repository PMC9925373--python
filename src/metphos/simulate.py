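"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a 12-cell-line phosphoproteomic
drug-response experiment: {control 0 h, treated 30 min, control 24 h,
treated 24 h} x 3 replicates per line, log-normal precursor intensities
with intensity-dependent missingness, per-precursor localization
probabilities, 1-3 precursors per modified peptide, and planted per-line
log2 effects at 24 h.  Acute (30-min) effects default to zero except for
explicitly configured sites, reflecting the sparsity of acute
phospho-responses relative to the late response.

All randomness flows from one integer seed through
``numpy.random.default_rng`` (PCG64), so identical configs produce
identical data on any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CONDITIONS, DEFAULT_CELL_LINES, make_site_key
from .synergy import DoseResponseCurve, loewe_expected

RESIDUES = "STY"
RESIDUE_WEIGHTS = (0.75, 0.20, 0.05)  # approximate S/T/Y phospho shares


@dataclass
class SimConfig:
    """Conditions of the simulated panel experiment.

    The defaults mirror the real study design (12 lines x 4 conditions x
    3 replicates) and plausible DIA phospho data: log2 intensities
    centred near 16 with sd 2 across sites, replicate noise 0.25 log2
    units, ~15% missingness preferentially hitting low intensities, and
    ~10% of peptides with poorly localized phosphosites.
    """

    n_cell_lines: int = 12
    n_replicates: int = 3
    n_sites: int = 5000
    baseline_log2_mean: float = 16.0
    baseline_log2_sd: float = 2.0
    line_effect_sd: float = 0.5
    noise_sd: float = 0.25
    missing_rate: float = 0.15
    frac_low_localization: float = 0.10
    loc_beta_high: tuple = (40.0, 2.0)
    loc_beta_low: tuple = (2.0, 6.0)
    max_precursors: int = 3
    effect_table: pd.DataFrame | None = None
    acute_effect_table: pd.DataFrame | None = None
    frac_heterogeneous: float = 0.20
    n_consistent_up: int = 8
    n_consistent_down: int = 4
    planted_shift: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_rate", "frac_low_localization",
                     "frac_heterogeneous"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_sites < 1 or self.n_cell_lines < 1:
            raise ValueError("need at least one site and one cell line")

    @property
    def cell_lines(self) -> list[str]:
        if self.n_cell_lines <= len(DEFAULT_CELL_LINES):
            return list(DEFAULT_CELL_LINES[:self.n_cell_lines])
        return [f"LINE{i + 1:02d}" for i in range(self.n_cell_lines)]


@dataclass
class GroundTruth:
    """Planted truth implied deterministically by a SimConfig + seed."""

    effect_table: pd.DataFrame       # site x line log2 shift at 24 h
    calls: pd.DataFrame              # site x line planted +1/0/-1
    metscore: pd.Series              # implied score per site
    low_localization: set = field(default_factory=set)


def default_effect_table(config: SimConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Planted per-line 24-h log2 shifts.

    Structure: a small block of consistently up/down sites responding in
    every line (the recoverable "signature"), plus a heterogeneous
    background where each line regulates its own random ~20% of sites
    with shifts of random sign and magnitude 1-2.5.
    """
    lines = config.cell_lines
    sites = [f"site{i:05d}" for i in range(config.n_sites)]
    eff = pd.DataFrame(0.0, index=sites, columns=lines)
    n_up, n_dn = config.n_consistent_up, config.n_consistent_down
    eff.iloc[:n_up] = config.planted_shift
    eff.iloc[n_up:n_up + n_dn] = -config.planted_shift
    background = np.arange(n_up + n_dn, config.n_sites)
    for line in lines:
        n_reg = int(round(config.frac_heterogeneous * len(background)))
        chosen = rng.choice(background, size=n_reg, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_reg)
        mags = rng.uniform(1.0, 2.5, size=n_reg)
        eff.loc[np.array(sites)[chosen], line] = signs * mags
    return eff


def _missing_mask(log2_values: np.ndarray, rate: float,
                  rng: np.random.Generator, tau: float = 0.7) -> np.ndarray:
    """Logistic intensity-dependent dropout with overall rate ``rate``.

    p_miss = sigmoid(-(z - z0) / tau) on standardized log2 intensity;
    z0 is solved by bisection so the mean dropout equals ``rate``.
    """
    if rate <= 0:
        return np.zeros(log2_values.shape, dtype=bool)
    z = (log2_values - np.nanmean(log2_values)) / \
        max(np.nanstd(log2_values), 1e-9)

    def mean_p(z0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp((z - z0) / tau))))

    lo, hi = -50.0, 50.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < rate:
            lo = mid
        else:
            hi = mid
    p = 1.0 / (1.0 + np.exp((z - 0.5 * (lo + hi)) / tau))
    return rng.random(log2_values.shape) < p


def make_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for line in config.cell_lines:
        for cond in CONDITIONS:
            for rep in range(1, config.n_replicates + 1):
                rows.append({"run_id": f"{line}.{cond}.r{rep}",
                             "cell_line": line, "condition": cond,
                             "replicate": rep})
    return pd.DataFrame(rows)


def simulate_phospho(config: SimConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a precursor report, its run design and the ground truth.

    Returns (report, design, truth).  The report carries 1-3 precursors
    per modified peptide with raw (linear-scale) intensities; a
    configured fraction of peptides has poorly localized sites (their
    localization probabilities fall below the class-I cutoff).
    """
    rng = np.random.default_rng(config.seed)
    design = make_design(config)
    lines = config.cell_lines
    sites = [f"site{i:05d}" for i in range(config.n_sites)]

    effect = config.effect_table
    if effect is None:
        effect = default_effect_table(config, rng)
    effect = effect.reindex(index=sites, columns=lines).fillna(0.0)
    acute = config.acute_effect_table
    if acute is None:
        acute = pd.DataFrame(0.0, index=sites, columns=lines)
    acute = acute.reindex(index=sites, columns=lines).fillna(0.0)

    baseline = rng.normal(config.baseline_log2_mean,
                          config.baseline_log2_sd, size=config.n_sites)
    line_fx = rng.normal(0.0, config.line_effect_sd,
                         size=(config.n_sites, len(lines)))

    # protein/site annotation: ~3 sites per protein
    proteins = [f"PROT{i // 3 + 1:05d}" for i in range(config.n_sites)]
    residues = rng.choice(list(RESIDUES), size=config.n_sites,
                          p=RESIDUE_WEIGHTS)
    positions = rng.integers(5, 1200, size=config.n_sites)
    site_keys = [make_site_key(pr, [r], [int(p)])
                 for pr, r, p in zip(proteins, residues, positions)]

    is_low = rng.random(config.n_sites) < config.frac_low_localization
    low_loc = set(np.array(sites)[is_low])

    line_index = {l: j for j, l in enumerate(lines)}
    line_idx = np.array([line_index[l] for l in design["cell_line"]])
    is24 = (design["condition"] == "met_24h").to_numpy()
    is30 = (design["condition"] == "met_30min").to_numpy()

    # site x run expected log2 level
    cond_fx = (effect.to_numpy()[:, line_idx] * is24
               + acute.to_numpy()[:, line_idx] * is30)
    base = (baseline[:, None]
            + line_fx[np.arange(config.n_sites)[:, None], line_idx[None, :]]
            + cond_fx)

    n_prec = rng.integers(1, config.max_precursors + 1,
                          size=config.n_sites)
    site_rep = np.repeat(np.arange(config.n_sites), n_prec)
    prec_rank = np.concatenate([np.arange(n) for n in n_prec])
    all_log2 = (base[site_rep]
                - 0.6 * prec_rank[:, None]  # later precursors less intense
                + rng.normal(0.0, config.noise_sd,
                             size=(len(site_rep), len(design))))
    missing = _missing_mask(all_log2, config.missing_rate, rng)
    raw = np.power(2.0, all_log2)
    raw[missing] = np.nan

    a_hi, b_hi = config.loc_beta_high
    a_lo, b_lo = config.loc_beta_low
    loc_hi = rng.beta(a_hi, b_hi, size=len(site_rep))
    loc_lo = rng.beta(a_lo, b_lo, size=len(site_rep))
    loc_prob = np.clip(np.where(is_low[site_rep], loc_lo, loc_hi), 0, 1)

    site_arr = np.array(sites)
    report = pd.DataFrame({
        "precursor_id": [f"{site_arr[i]}.{2 + r}"
                         for i, r in zip(site_rep, prec_rank)],
        "phos_id": site_arr[site_rep],
        "protein": np.array(proteins)[site_rep],
        "site_key": np.array(site_keys)[site_rep],
        "localization_prob": loc_prob,
    })
    intensities = pd.DataFrame(raw, columns=list(design["run_id"]))
    report = pd.concat([report, intensities], axis=1)

    calls = pd.DataFrame(np.sign(effect.to_numpy()), index=sites,
                         columns=lines)
    truth = GroundTruth(effect_table=effect, calls=calls,
                        metscore=calls.sum(axis=1).astype(int),
                        low_localization=low_loc)
    return report, design, truth


# ---------------------------------------------------------------------------
# kinase layer
# ---------------------------------------------------------------------------

def simulate_kinase_layer(n_sites: int = 2000, n_kinases: int = 30,
                          targets_per_kinase: int = 10,
                          frac_active: float = 0.3, shift: float = 2.0,
                          include_small_kinase: bool = True,
                          seed: int = 0
                          ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Signed kinase->site prior plus per-site t-values with planted
    kinase activities.

    Background t-values are N(0, 1); each active kinase (a random
    ``frac_active`` of the panel, signs alternating) adds
    ``sign_edge * activity_sign * shift`` to its targets' t-values.
    When ``include_small_kinase`` is set, one extra kinase with fewer
    than five targets exercises the minimum-target filter downstream.

    Returns (prior, t_values, planted_activity) where planted_activity
    maps kinase -> {-1, 0, +1}.
    """
    rng = np.random.default_rng(seed)
    sites = [f"PROT{i:05d}_S{10 + i % 900}" for i in range(n_sites)]
    t = pd.Series(rng.standard_normal(n_sites), index=sites)
    edges = []
    planted = {}
    n_active = int(round(frac_active * n_kinases))
    for k in range(n_kinases):
        kin = f"KIN{k + 1:03d}"
        targets = rng.choice(n_sites, size=targets_per_kinase,
                             replace=False)
        # mostly phosphorylation edges, some dephosphorylation
        signs = rng.choice([1, -1], size=targets_per_kinase,
                           p=[0.85, 0.15])
        activity = 0
        if k < n_active:
            activity = 1 if k % 2 == 0 else -1
        planted[kin] = activity
        for ti, sg in zip(targets, signs):
            if activity != 0:
                t.iloc[ti] += activity * sg * shift
            edges.append({"kinase": kin, "target_site_key": sites[ti],
                          "sign": int(sg)})
    if include_small_kinase:
        kin = "KIN_SMALL"
        planted[kin] = 0
        for ti in rng.choice(n_sites, size=4, replace=False):
            edges.append({"kinase": kin, "target_site_key": sites[ti],
                          "sign": 1})
    prior = pd.DataFrame(edges).drop_duplicates(
        ["kinase", "target_site_key"])
    return prior, t, pd.Series(planted)


# ---------------------------------------------------------------------------
# dose-response surfaces
# ---------------------------------------------------------------------------

def simulate_dose_response(curve_a: DoseResponseCurve | None = None,
                           curve_b: DoseResponseCurve | None = None,
                           doses_a: np.ndarray | None = None,
                           doses_b: np.ndarray | None = None,
                           offset: float = 0.0, noise_sd: float = 1.0,
                           n_replicates: int = 3, seed: int = 0,
                           drug_a: str = "metformin",
                           drug_b: str = "drugB") -> pd.DataFrame:
    """A 6x6 combination matrix (including 0-dose margins) built from two
    4PL curves combined by exact Loewe additivity plus a planted synergy
    offset at every non-margin dose pair, plus replicate noise.

    Viability is returned as percent of the untreated control.
    """
    rng = np.random.default_rng(seed)
    if curve_a is None:
        curve_a = DoseResponseCurve(0.0, 90.0, 1.0, 1.2)
    if curve_b is None:
        curve_b = DoseResponseCurve(0.0, 80.0, 0.5, 1.0)
    if doses_a is None:
        doses_a = np.array([0.0, 0.125, 0.25, 0.5, 1.0, 2.0])
    if doses_b is None:
        doses_b = np.array([0.0, 0.0625, 0.125, 0.25, 0.5, 1.0])
    rows = []
    for da in doses_a:
        for db in doses_b:
            inh = loewe_expected(curve_a, curve_b, da, db)
            if da > 0 and db > 0:
                inh += offset
            for rep in range(1, n_replicates + 1):
                viability = 100.0 - inh + rng.normal(0.0, noise_sd)
                rows.append({"drug_a": drug_a, "dose_a": da,
                             "drug_b": drug_b, "dose_b": db,
                             "replicate": rep,
                             "viability_percent": max(viability, 0.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# drug associations
# ---------------------------------------------------------------------------

def simulate_drug_associations(signature_sites: list[str],
                               n_drugs: int = 100,
                               planted_degrees: dict[str, int] | None = None,
                               assoc_per_site: int = 60,
                               seed: int = 0) -> pd.DataFrame:
    """Site~drug association table with planted high-degree drugs.

    Each signature site receives ``assoc_per_site`` associations with
    uniform p-values to random null drugs; every planted drug is
    additionally linked with very small p-values to its configured
    number of signature sites, so its degree in the top-n network is
    known in advance.
    """
    rng = np.random.default_rng(seed)
    planted_degrees = planted_degrees or {}
    drugs = [f"drug{j:03d}" for j in range(n_drugs)]
    rows = []
    for site in signature_sites:
        chosen = rng.choice(drugs, size=min(assoc_per_site, n_drugs),
                            replace=False)
        for d in chosen:
            rows.append({"site_key": site, "drug": d,
                         "p_value": float(rng.uniform(1e-4, 1.0)),
                         "direction": "+" if rng.random() < 0.5 else "-"})
    for drug, degree in planted_degrees.items():
        for site in signature_sites[:degree]:
            rows.append({"site_key": site, "drug": drug,
                         "p_value": float(rng.uniform(1e-12, 1e-8)),
                         "direction": "+"})
    assoc = pd.DataFrame(rows).drop_duplicates(["site_key", "drug"],
                                               keep="last")
    return assoc.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sequence windows (for motif/logo analyses)
# ---------------------------------------------------------------------------

def simulate_windows(n: int, central: str = "S",
                     planted: dict[int, str] | None = None,
                     planted_frac: float = 1.0,
                     seed: int = 0) -> list[str]:
    """15-residue windows with the acceptor at the centre.

    ``planted`` maps relative position (-7..7, non-zero) to a residue
    enforced in ``planted_frac`` of the windows; the rest of each window
    is drawn uniformly from the 20 amino acids.
    """
    from .enrichment import AMINO_ACIDS, CENTER, WINDOW_LEN
    rng = np.random.default_rng(seed)
    planted = planted or {}
    out = []
    for i in range(n):
        w = list(rng.choice(list(AMINO_ACIDS), size=WINDOW_LEN))
        w[CENTER] = central
        if rng.random() < planted_frac:
            for rel, aa in planted.items():
                w[CENTER + rel] = aa
        out.append("".join(w))
    return out


def write_fixture_set(out_dir: str | Path, config: SimConfig | None = None
                      ) -> dict[str, str]:
    """Write a complete synthetic fixture set for the CLI pipeline.

    Produces report TSV, design CSV, kinase prior TSV, drug association
    TSV, dose-response CSV and a ground-truth JSON; returns the paths.
    """
    from .io import (write_design, write_precursor_report, write_table)
    config = config or SimConfig(n_sites=500)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report, design, truth = simulate_phospho(config)
    prior, t_values, planted = simulate_kinase_layer(seed=config.seed)
    assoc = simulate_drug_associations(
        [f"site{i:05d}" for i in range(12)],
        planted_degrees={"drug_hub": 8}, seed=config.seed)
    dr = simulate_dose_response(offset=10.0, seed=config.seed)
    paths = {
        "report": str(out_dir / "precursor_report.tsv"),
        "design": str(out_dir / "design.csv"),
        "prior": str(out_dir / "kinase_prior.tsv"),
        "associations": str(out_dir / "drug_associations.tsv"),
        "dose_response": str(out_dir / "dose_response.csv"),
        "truth": str(out_dir / "ground_truth.json"),
    }
    write_precursor_report(report, paths["report"])
    write_design(design, paths["design"])
    write_table(prior, paths["prior"])
    write_table(assoc, paths["associations"])
    dr.to_csv(paths["dose_response"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({
            "metscore": {k: int(v) for k, v in truth.metscore.items()},
            "planted_kinase_activity": {k: int(v)
                                        for k, v in planted.items()},
            "synergy_offset": 10.0,
        }, fh, indent=1)
    return paths
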