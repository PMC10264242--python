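"""Domain containers and tab-separated/BED readers and writers.

All tabular interchange is plain TSV:

* count matrix:  ``transcript_id<TAB>sample1<TAB>sample2...`` (numeric body)
* design table:  ``sample_id<TAB>covar1<TAB>covar2...`` (numeric or categorical)
* PAS counts:    ``transcript_id<TAB>site_id<TAB>sample1...``
* PAS positions: BED6 (chrom, start, end, name=site_id, score, strand),
  0-based half-open, strand-aware.

Counts are stored as pandas DataFrames (transcripts x samples); real values
are allowed everywhere because upstream quantifiers may emit fractional
(EM-apportioned) counts and CELP debiasing produces non-integer counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ReadType(str, Enum):
    """Assay that produced a count matrix."""

    RPF = "RPF"
    RNA = "RNA"
    PAS = "PAS"


class DataError(ValueError):
    """Raised when an input violates a data-model invariant."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise DataError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class CountMatrix:
    """Non-negative transcript x sample read counts for one assay.

    Parameters
    ----------
    counts : DataFrame
        Rows indexed by transcript id, columns by sample id. Real-valued,
        non-negative. Row order is preserved as given.
    read_type : ReadType
        Which assay the counts come from (RPF, RNA or PAS-aggregated).
    """

    counts: pd.DataFrame
    read_type: ReadType = ReadType.RNA

    def __post_init__(self) -> None:
        self.read_type = ReadType(self.read_type)
        _check_unique(self.counts.index, "transcript IDs")
        _check_unique(self.counts.columns, "sample IDs")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = self.counts.columns[
                [not np.issubdtype(d, np.number) for d in self.counts.dtypes]
            ]
            raise DataError(f"non-numeric count column(s): {', '.join(map(str, bad))}")
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise DataError(
                f"missing count at transcript {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise DataError(
                f"negative count at transcript {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        self.counts = self.counts.astype(float)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class DesignMatrix:
    """Per-sample covariates driving the TER and APA regressions.

    ``covariates`` holds numeric columns only; categorical covariates are
    expanded to 0/1 indicators before construction (baseline = alphabetically
    first level). An intercept column is implied by ``intercept`` and never
    stored.
    """

    covariates: pd.DataFrame
    intercept: bool = True

    def __post_init__(self) -> None:
        _check_unique(self.covariates.index, "sample IDs")
        _check_unique(self.covariates.columns, "covariate names")
        self.covariates = self.covariates.astype(float)
        X = self.matrix()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DataError(
                "design is rank-deficient; collinear columns: "
                + ", ".join(self._collinear_columns())
            )

    def _collinear_columns(self) -> list[str]:
        # greedy scan: a column is collinear if it lies in the span of the
        # intercept plus the columns accepted before it
        cols: list[str] = []
        base = (
            [np.ones(len(self.covariates))] if self.intercept else []
        )
        kept: list[np.ndarray] = list(base)
        for name in self.covariates.columns:
            v = self.covariates[name].to_numpy()
            if kept:
                A = np.column_stack(kept)
                resid = v - A @ np.linalg.lstsq(A, v, rcond=None)[0]
            else:
                resid = v
            if np.allclose(resid, 0, atol=1e-10 * max(1.0, np.abs(v).max())):
                cols.append(name)
            else:
                kept.append(v)
        return cols or list(self.covariates.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.covariates.index)

    @property
    def columns(self) -> list[str]:
        return (["intercept"] if self.intercept else []) + list(self.covariates.columns)

    def matrix(self, sample_order: Sequence[str] | None = None) -> np.ndarray:
        """Dense design matrix (intercept first if present)."""
        df = self.covariates
        if sample_order is not None:
            missing = set(sample_order) - set(df.index)
            if missing:
                raise DataError(f"samples missing from design: {sorted(missing)}")
            df = df.loc[list(sample_order)]
        X = df.to_numpy(dtype=float)
        if self.intercept:
            X = np.column_stack([np.ones(len(df)), X])
        return X


@dataclass
class SizeFactors:
    """Positive per-sample library-size factors."""

    factors: pd.Series

    def __post_init__(self) -> None:
        self.factors = self.factors.astype(float)
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            bad = self.factors.index[
                ~np.isfinite(self.factors) | (self.factors <= 0)
            ]
            raise DataError(f"non-positive size factor for sample(s): {list(bad)}")

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


@dataclass
class CodonProfileSet:
    """Codon-resolution RPF counts: one codons x samples frame per transcript.

    Codon index is 0-based from the CDS start; every sample of a transcript
    shares the transcript's codon length.
    """

    profiles: Mapping[str, pd.DataFrame]

    def __post_init__(self) -> None:
        self.profiles = dict(self.profiles)
        for tx, df in self.profiles.items():
            vals = df.to_numpy()
            if (vals < 0).any():
                raise DataError(f"negative codon count in transcript {tx!r}")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        first = next(iter(self.profiles.values()))
        return list(first.columns)

    def __getitem__(self, tx: str) -> pd.DataFrame:
        return self.profiles[tx]

    def __len__(self) -> int:
        return len(self.profiles)

    def transcript_totals(self, read_type: ReadType = ReadType.RPF) -> CountMatrix:
        """Sum codon counts into a transcript x sample matrix."""
        rows = {tx: df.sum(axis=0) for tx, df in self.profiles.items()}
        return CountMatrix(pd.DataFrame(rows).T, read_type)


@dataclass
class PasCountTable:
    """Poly(A)-site x sample counts with transcript-relative site ranks.

    Rank 1 is the most proximal site (nearest the stop codon along the
    transcript, i.e. strand-aware, not by genomic coordinate). Transcripts
    with a single site are retained but flagged untestable.
    """

    counts: pd.DataFrame          # MultiIndex (transcript_id, site_id) x samples
    ranks: pd.Series              # same MultiIndex -> int rank
    positions: pd.DataFrame | None = None  # optional: chrom, start, end, strand
    rank_source: str = "bed"      # "bed" or "lexicographic"

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise DataError("negative PAS count")
        for tx, grp in self.ranks.groupby(level=0):
            r = sorted(grp)
            if r != list(range(1, len(r) + 1)):
                raise DataError(
                    f"site ranks of transcript {tx!r} are not a permutation of 1..S"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index.get_level_values(0).unique())

    def n_sites(self, tx: str) -> int:
        return len(self.counts.loc[tx])

    def testable_transcripts(self) -> list[str]:
        """Transcripts with >= 2 sites (others are flagged untestable)."""
        sizes = self.counts.groupby(level=0, sort=False).size()
        return list(sizes.index[sizes >= 2])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_count_matrix(path, read_type: ReadType | str = ReadType.RNA) -> CountMatrix:
    """Read a transcript x sample count TSV (first column = transcript id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise DataError(
                f"non-numeric count in column {col!r}, row(s) {list(bad[:3])}"
            )
    return CountMatrix(df, ReadType(read_type))


def read_design(path) -> DesignMatrix:
    """Read a sample x covariate TSV, expanding categoricals to indicators.

    Categorical (non-numeric) columns become 0/1 indicator columns named
    ``<col>_<level>`` for every level except the alphabetically first, which
    is the baseline. Column order: input order, indicator levels alphabetical.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    out: list[pd.Series | pd.DataFrame] = []
    for col in df.columns:
        if np.issubdtype(df[col].dtype, np.number):
            out.append(df[col].astype(float))
        else:
            levels = sorted(df[col].astype(str).unique())
            for lev in levels[1:]:
                out.append(
                    (df[col].astype(str) == lev).astype(float).rename(f"{col}_{lev}")
                )
    covs = pd.concat(out, axis=1) if out else pd.DataFrame(index=df.index)
    return DesignMatrix(covs)


def read_bed6(path) -> pd.DataFrame:
    """Read a BED6 file of poly(A)-site positions keyed by site name."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    _check_unique(bed["name"], "BED site names")
    return bed.set_index("name")


def read_pas_counts(path, bed_path=None) -> PasCountTable:
    """Read a PAS count TSV, assigning transcript-relative site ranks.

    With a BED of site positions, rank 1 (proximal) is the smallest
    transcript-relative coordinate: lowest genomic start on "+" strands,
    highest genomic end on "-" strands. Without a BED, ranks follow
    lexicographic site_id order and a warning is emitted.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    tx_col, site_col = df.columns[:2]
    df = df.set_index([tx_col, site_col])
    df.index.names = ["transcript_id", "site_id"]
    cm = CountMatrix(
        df.set_axis([f"{a}::{b}" for a, b in df.index]), ReadType.PAS
    )  # reuse validation
    counts = df.astype(float)

    positions = None
    if bed_path is not None:
        bed = read_bed6(bed_path)
        site_ids = counts.index.get_level_values(1)
        missing = set(site_ids) - set(bed.index)
        if missing:
            raise DataError(f"BED is missing site(s): {sorted(missing)}")
        positions = bed.loc[list(site_ids)].set_axis(counts.index)
        # transcript-relative coordinate: start on +, -end on - (so that
        # ascending order == proximal-to-distal along the transcript)
        rel = np.where(
            positions["strand"].to_numpy() == "-",
            -positions["end"].to_numpy(dtype=float),
            positions["start"].to_numpy(dtype=float),
        )
        key = pd.Series(rel, index=counts.index)
        rank_source = "bed"
    else:
        warnings.warn(
            "no BED given: PAS ranks assigned from lexicographic site_id order",
            stacklevel=2,
        )
        key = pd.Series(
            counts.index.get_level_values(1), index=counts.index
        )
        rank_source = "lexicographic"

    ranks = (
        key.groupby(level=0, sort=False)
        .rank(method="first")
        .astype(int)
    )
    del cm
    return PasCountTable(counts, ranks, positions, rank_source)


# ---------------------------------------------------------------------------
# writer
# ---------------------------------------------------------------------------

def write_results_table(table: pd.DataFrame, path, index: bool = True) -> None:
    """Write a results table as TSV: floats at 6 significant digits, NA cells."""
    table.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", index=index)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    df = matrix.counts.copy()
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.6g")
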