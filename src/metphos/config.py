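"""Pipeline configuration.

All tunable thresholds of the analysis live in :class:`PipelineConfig` so
that every stage (filtering, differential calls, signature extraction,
enrichment, kinase inference, drug networking) reads its constants from one
place.  Defaults are the values used for the 12-line colorectal-cancer
panel analysis this package implements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class PipelineConfig:
    """Constants governing the phosphoproteomic pipeline.

    Parameters
    ----------
    intensity_floor : float
        Raw precursor intensities strictly below this value are treated as
        missing before log2 transformation (default 500).
    p_threshold : float
        Two-sided p-value cutoff for a significant differential call
        (default 0.01).
    fc_threshold : float
        Fold-change cutoff on the linear scale; a call additionally
        requires ``|log2fc| > log2(fc_threshold)`` (default 1.5).
    localization_cutoff : float
        Phosphosite localization-probability cutoff; a precursor is a
        confidently localized ("class I") site when its probability is
        strictly greater than this in at least one sample (default 0.75).
    min_valid_per_group : int
        Minimum non-missing values per compared group for a t-test
        (default 2); comparisons below this are reported as missing
        rather than imputed.
    min_kinase_targets : int
        Minimum measured substrate sites for a kinase to receive an
        activity estimate (default 5).
    mad_fraction : float
        Fraction of most-variable features (median absolute deviation)
        retained before consensus clustering (default 0.30).
    n_clusters : int
        Cluster number used for the response classification (default 4).
    top_drug_assoc : int
        Number of smallest-p drug associations kept per signature site
        (default 50).
    motif_min_occurrence : int
        Minimum foreground occurrences for an extracted sequence motif
        (default 20).
    motif_p : float
        Binomial enrichment p-value threshold for fixing a motif position
        (default 1e-6).
    icelogo_p : float
        Per-cell significance cutoff of the positional residue enrichment
        (default 0.05).
    seed : int
        Seed for every stochastic step (permutations, bootstrap,
        consensus resampling, simulation).
    """

    intensity_floor: float = 500.0
    p_threshold: float = 0.01
    fc_threshold: float = 1.5
    localization_cutoff: float = 0.75
    min_valid_per_group: int = 2
    min_kinase_targets: int = 5
    mad_fraction: float = 0.30
    n_clusters: int = 4
    top_drug_assoc: int = 50
    motif_min_occurrence: int = 20
    motif_p: float = 1e-6
    icelogo_p: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "intensity_floor", "p_threshold", "fc_threshold",
            "localization_cutoff", "min_valid_per_group",
            "min_kinase_targets", "n_clusters", "top_drug_assoc",
            "motif_min_occurrence", "motif_p", "icelogo_p",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("mad_fraction",):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
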