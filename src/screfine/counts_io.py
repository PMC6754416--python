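"""Reading, validation, filtering and normalization of spectral-count matrices.

A spectral-count experiment is a proteins x runs table of non-negative
counts together with a design that assigns every run to one of exactly two
conditions.  Counts are raw integers as produced by a spectral-counting
engine, or fractional values after total-count normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "FilterSummary",
    "read_counts",
    "write_counts",
    "filter_identifications",
    "normalize_counts",
    "KERATIN_PATTERN",
    "DECOY_PREFIXES",
]

#: description regex marking keratin-family contaminants (case-insensitive)
KERATIN_PATTERN = "keratin"
#: accession prefixes marking reverse-database (decoy) hits
DECOY_PREFIXES = ("rev_", "REV_")

_META_COLUMNS = ("description", "is_contaminant", "is_decoy")


@dataclass
class FilterSummary:
    """Bookkeeping for identification filtering."""

    n_input: int
    n_contaminant: int
    n_decoy: int
    n_kept: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_contaminant": self.n_contaminant,
            "n_decoy": self.n_decoy,
            "n_kept": self.n_kept,
        }


@dataclass
class CountMatrix:
    """Protein x replicate spectral counts with a two-condition design.

    Parameters
    ----------
    counts
        DataFrame indexed by protein accession, one column per run.
        Non-negative; raw counts are integers, normalized counts may be
        fractional.
    design
        Series mapping run label -> condition label; exactly two distinct
        conditions, each with at least two runs.
    meta
        Optional per-protein table aligned with ``counts.index`` carrying
        ``description``, ``is_contaminant`` and ``is_decoy``.
    """

    counts: pd.DataFrame
    design: pd.Series
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicated protein ids: {list(dups)[:5]}")
        if (self.counts.index == "").any():
            raise ValueError("empty protein id")
        unknown = set(self.design.index) - set(self.counts.columns)
        missing = set(self.counts.columns) - set(self.design.index)
        if unknown:
            raise ValueError(f"design lists unknown runs: {sorted(unknown)}")
        if missing:
            raise ValueError(f"runs missing from design: {sorted(missing)}")
        self.design = self.design.copy()
        self.design.index.name = "run"
        conds = pd.unique(self.design)
        if len(conds) != 2:
            raise ValueError(
                f"exactly two conditions required, got {list(conds)}"
            )
        for cond in conds:
            if (self.design == cond).sum() < 2:
                raise ValueError(f"condition {cond!r} has fewer than two runs")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing count at protein {self.counts.index[r]!r}, "
                f"run {self.counts.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at protein {self.counts.index[r]!r}, "
                f"run {self.counts.columns[c]!r}"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "description": "",
                    "is_contaminant": False,
                    "is_decoy": False,
                },
                index=self.counts.index,
            )
        else:
            self.meta = self.meta.reindex(self.counts.index)
            if "description" not in self.meta:
                self.meta["description"] = ""
            self.meta["description"] = self.meta["description"].where(
                self.meta["description"].notna(), ""
            )
            for col in ("is_contaminant", "is_decoy"):
                if col not in self.meta:
                    self.meta[col] = False
                flags = self.meta[col]
                self.meta[col] = flags.where(flags.notna(), False).astype(bool)

    # -- structure ---------------------------------------------------------

    @property
    def conditions(self) -> tuple[str, str]:
        """The two condition labels, in design-file order."""
        a, b = pd.unique(self.design)
        return a, b

    @property
    def protein_ids(self) -> pd.Index:
        return self.counts.index

    def runs(self, condition: str) -> list[str]:
        """Run labels belonging to ``condition``, in design order."""
        if condition not in set(self.design):
            raise KeyError(f"unknown condition {condition!r}")
        return [r for r in self.design.index if self.design[r] == condition]

    def condition_counts(self, condition: str) -> pd.DataFrame:
        """Sub-matrix restricted to one condition's replicate runs."""
        return self.counts[self.runs(condition)]

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.counts.copy(), self.design.copy(), self.meta.copy()
        )

    def __len__(self) -> int:
        return len(self.counts)


def _read_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_counts(counts_path: Path | str, design_path: Path | str) -> CountMatrix:
    """Load a count matrix and its design table from TSV/CSV files.

    The counts file needs a protein-id first column, optional
    ``description`` / ``is_contaminant`` / ``is_decoy`` columns, and one
    numeric column per run.  The design file needs ``run`` and
    ``condition`` columns covering every run.  Decoys are additionally
    recognised by accession prefix (``rev_`` by default) and contaminants
    by a case-insensitive "keratin" in the description.
    """
    table = _read_table(counts_path)
    if table.shape[1] < 2:
        raise ValueError("counts file needs a protein-id column plus run columns")
    table = table.set_index(table.columns[0])
    table.index = table.index.astype(str)
    table.index.name = "protein_id"

    meta_cols = [c for c in _META_COLUMNS if c in table.columns]
    meta = table[meta_cols].copy() if meta_cols else None
    runs = table.drop(columns=meta_cols)
    for col in runs.columns:
        runs[col] = pd.to_numeric(runs[col], errors="raise")

    design_tab = _read_table(design_path)
    if not {"run", "condition"} <= set(design_tab.columns):
        raise ValueError("design file must have 'run' and 'condition' columns")
    design = pd.Series(
        design_tab["condition"].astype(str).to_numpy(),
        index=design_tab["run"].astype(str),
        name="condition",
    )

    if meta is None:
        meta = pd.DataFrame(index=runs.index)
    if "description" in meta:
        flagged = meta["description"].fillna("").str.contains(
            KERATIN_PATTERN, case=False, regex=True
        )
        meta["is_contaminant"] = (
            meta["is_contaminant"].fillna(False).astype(bool) | flagged
            if "is_contaminant" in meta
            else flagged
        )
    decoy_by_prefix = runs.index.str.startswith(DECOY_PREFIXES)
    if "is_decoy" in meta:
        meta["is_decoy"] = (
            meta["is_decoy"].fillna(False).astype(bool) | decoy_by_prefix
        )
    else:
        meta["is_decoy"] = decoy_by_prefix

    return CountMatrix(runs, design, meta)


def write_counts(
    matrix: CountMatrix, counts_path: Path | str, design_path: Path | str
) -> None:
    """Write a matrix + design in the format ``read_counts`` accepts."""
    out = matrix.meta.join(matrix.counts)
    out.index.name = "protein_id"
    sep = "," if Path(counts_path).suffix.lower() == ".csv" else "\t"
    out.to_csv(counts_path, sep=sep)
    design = pd.DataFrame(
        {"run": matrix.design.index, "condition": matrix.design.to_numpy()}
    )
    sep = "," if Path(design_path).suffix.lower() == ".csv" else "\t"
    design.to_csv(design_path, sep=sep, index=False)


def filter_identifications(matrix: CountMatrix) -> tuple[CountMatrix, FilterSummary]:
    """Drop contaminant (keratin) and decoy (reverse-hit) rows.

    Rows flagged both ways count once, as contaminants.
    """
    contaminant = matrix.meta["is_contaminant"].to_numpy()
    decoy = matrix.meta["is_decoy"].to_numpy() & ~contaminant
    keep = ~(contaminant | decoy)
    summary = FilterSummary(
        n_input=len(matrix),
        n_contaminant=int(contaminant.sum()),
        n_decoy=int(decoy.sum()),
        n_kept=int(keep.sum()),
    )
    if summary.n_kept == 0:
        warnings.warn("all proteins removed by identification filtering")
    filtered = CountMatrix(
        matrix.counts.loc[keep], matrix.design.copy(), matrix.meta.loc[keep]
    )
    return filtered, summary


def normalize_counts(matrix: CountMatrix) -> CountMatrix:
    """Total-count normalization: scale each run to the grand-mean run total.

    Each run's counts are multiplied by (mean of all run totals) / (run
    total), so within-run proportions are preserved and all run totals
    become equal.  Idempotent.
    """
    totals = matrix.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"run(s) with zero total count: {bad}")
    factors = totals.mean() / totals
    return CountMatrix(
        matrix.counts * factors, matrix.design.copy(), matrix.meta.copy()
    )
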