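"""Readers and writers for the pipeline's file formats.

Formats (all plain text, decimal point ``.``):

* precursor report -- TSV with columns ``precursor_id``, ``phos_id``,
  ``protein``, ``site_key``, ``localization_prob`` followed by one raw
  intensity column per MS run; empty field = missing.
* run design -- CSV with columns ``run_id,cell_line,condition,replicate``.
* intensity matrix -- TSV, first column ``feature``, one column per run.
* kinase prior -- TSV ``kinase,target_site_key,sign`` with sign +1/-1.
* drug associations -- TSV ``site_key,drug,p_value,direction`` (+/-).
* dose-response -- long CSV
  ``drug_a,dose_a,drug_b,dose_b,replicate,viability_percent``.

Missing values are encoded as empty fields on disk and as NaN in memory;
zero is never used as a missing marker because floored-but-valid raw
intensities can legitimately be small.  Numeric round-trips are lossless
to 12 significant digits (the canonical float format below).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: the four experimental conditions of the panel design
CONDITIONS = ("control_0h", "met_30min", "control_24h", "met_24h")

#: condition pairs of the two supported comparisons (treated, control)
COMPARISONS = {
    "met30_vs_ctrl0": ("met_30min", "control_0h"),
    "met24_vs_ctrl24": ("met_24h", "control_24h"),
}

#: the 12 colorectal-cancer cell lines of the default panel
DEFAULT_CELL_LINES = (
    "C2BBe1", "COLO205", "HT115", "LoVo", "MDST8", "NCI-H747",
    "RKO", "SNU-61", "SW48", "SW837", "SW948", "T84",
)

META_COLUMNS = ("precursor_id", "phos_id", "protein", "site_key",
                "localization_prob")

#: canonical float format; lossless round-trip to 12 significant digits
FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """A file does not follow its documented schema."""


class DesignMismatchError(ValueError):
    """A file's runs do not match the run design."""


# ---------------------------------------------------------------------------
# run design
# ---------------------------------------------------------------------------

def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a run-design table and return it unchanged.

    Requires columns run_id, cell_line, condition, replicate; unique
    run_ids; conditions restricted to :data:`CONDITIONS`; positive
    integer replicates.
    """
    required = ["run_id", "cell_line", "condition", "replicate"]
    missing = [c for c in required if c not in design.columns]
    if missing:
        raise FormatError(f"design is missing column(s): {missing}")
    if design["run_id"].duplicated().any():
        dup = design.loc[design["run_id"].duplicated(), "run_id"].iloc[0]
        raise FormatError(f"duplicate run_id in design: {dup!r}")
    bad = set(design["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"unknown condition label(s): {sorted(bad)}")
    reps = design["replicate"]
    if not (reps.astype(int) == reps).all() or (reps < 1).any():
        raise FormatError("replicates must be positive integers")
    return design


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, dtype={"run_id": str, "cell_line": str,
                                      "condition": str})
    return validate_design(design)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    validate_design(design).to_csv(path, index=False)


def design_runs(design: pd.DataFrame, cell_line: str | None = None,
                condition: str | None = None) -> list[str]:
    """Run ids matching the given cell line and/or condition."""
    sel = design
    if cell_line is not None:
        sel = sel[sel["cell_line"] == cell_line]
    if condition is not None:
        sel = sel[sel["condition"] == condition]
    return list(sel["run_id"])


# ---------------------------------------------------------------------------
# precursor report
# ---------------------------------------------------------------------------

def validate_precursor_report(report: pd.DataFrame,
                              design: pd.DataFrame | None = None
                              ) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in report.columns]
    if missing:
        raise FormatError(f"precursor report missing column(s): {missing}")
    loc = report["localization_prob"]
    if ((loc < 0) | (loc > 1)).any():
        raise FormatError("localization_prob outside [0, 1]")
    run_cols = [c for c in report.columns if c not in META_COLUMNS]
    vals = report[run_cols].to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise FormatError("negative intensity value")
    if design is not None:
        design_ids = list(design["run_id"])
        absent = [r for r in design_ids if r not in run_cols]
        if absent:
            raise DesignMismatchError(
                f"design run(s) absent from report: {absent}")
        unknown = [c for c in run_cols if c not in design_ids]
        if unknown:
            raise FormatError(
                f"intensity column(s) not in design: {unknown}")
    return report


def read_precursor_report(path: str | Path,
                          design: pd.DataFrame | None = None
                          ) -> pd.DataFrame:
    """Read a precursor-level pivot report.

    Every record carries an intensity slot (possibly NaN) for every run
    of the design; columns not named in the design are rejected.
    """
    report = pd.read_csv(path, sep="\t")
    return validate_precursor_report(report, design)


def write_precursor_report(report: pd.DataFrame, path: str | Path) -> None:
    validate_precursor_report(report)
    report.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# intensity matrices and generic tables
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample matrix (TSV, first column ``feature``)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        raise FormatError("duplicate feature keys in matrix")
    return mat


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "feature"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_table(obj: pd.DataFrame, path: str | Path,
                index: bool = False) -> None:
    """Write a generic result table; TSV for .tsv paths, CSV otherwise."""
    sep = "\t" if str(path).endswith(".tsv") else ","
    obj.to_csv(path, sep=sep, index=index, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# priors, associations, dose-response
# ---------------------------------------------------------------------------

def read_kinase_prior(path: str | Path) -> pd.DataFrame:
    """Signed kinase->site edges: columns kinase, target_site_key, sign."""
    prior = pd.read_csv(path, sep="\t")
    required = ["kinase", "target_site_key", "sign"]
    missing = [c for c in required if c not in prior.columns]
    if missing:
        raise FormatError(f"kinase prior missing column(s): {missing}")
    if not prior["sign"].isin([1, -1]).all():
        raise FormatError("kinase prior signs must be +1 or -1")
    if prior.duplicated(["kinase", "target_site_key"]).any():
        raise FormatError("duplicate (kinase, site) pair in prior")
    return prior


def read_drug_associations(path: str | Path) -> pd.DataFrame:
    assoc = pd.read_csv(path, sep="\t")
    required = ["site_key", "drug", "p_value", "direction"]
    missing = [c for c in required if c not in assoc.columns]
    if missing:
        raise FormatError(f"association table missing column(s): {missing}")
    p = assoc["p_value"]
    if ((p <= 0) | (p > 1)).any():
        raise FormatError("association p-values must lie in (0, 1]")
    if not assoc["direction"].isin(["+", "-"]).all():
        raise FormatError("association direction must be '+' or '-'")
    return assoc


def read_dose_response(path: str | Path) -> pd.DataFrame:
    dr = pd.read_csv(path)
    required = ["drug_a", "dose_a", "drug_b", "dose_b", "replicate",
                "viability_percent"]
    missing = [c for c in required if c not in dr.columns]
    if missing:
        raise FormatError(f"dose-response table missing column(s): {missing}")
    if (dr["viability_percent"] < 0).any():
        raise FormatError("viability must be non-negative")
    return dr


# ---------------------------------------------------------------------------
# site keys and packaged signature table
# ---------------------------------------------------------------------------

def make_site_key(protein: str, residues: Sequence[str],
                  positions: Sequence[int]) -> str:
    """Build a site key ``protein_<res><pos>[,<res><pos>...]``.

    Positions are 1-based on the protein sequence; multi-phospho keys
    list positions in ascending order joined by commas.
    """
    if len(residues) != len(positions):
        raise ValueError("residues and positions differ in length")
    pairs = sorted(zip(positions, residues))
    sites = ",".join(f"{r}{p}" for p, r in pairs)
    return f"{protein}_{sites}"


def load_signature_table() -> pd.DataFrame:
    """The published 55-site consensus metformin signature of the panel.

    Columns: metscore (integer consensus score), gene, site (residue and
    1-based position, comma-joined for multi-phospho peptides),
    fold_change (average linear fold change after 24 h of treatment) and
    regulatory ('+' when the site has a described regulatory function).
    """
    ref = importlib.resources.files("metphos.data") / \
        "crc_metformin_signature.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
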