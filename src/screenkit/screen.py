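"""Screen data containers, I/O and the normalization / fold-change stage.

Pooled-screen barcode counts are anchored to non-targeting controls (NTCs):
per-sample size factors equalize the NTC count statistic across samples,
per-shRNA log2 fold changes are computed final-vs-input per cell line and
replicate, and quantile normalization makes the fold-change columns
rank-exchangeable before rank-based downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

logger = logging.getLogger(__name__)

ROLES = frozenset({"target", "killing", "ntc"})

LIBRARY_COLUMNS = ["shrna_id", "barcode", "gene", "role"]
META_COLUMNS = ["sample_id", "cell_line", "timepoint", "replicate"]
TIMEPOINTS = frozenset({"input", "final"})


class ScreenFormatError(ValueError):
    """Raised when an input table violates the screen data contracts."""


@dataclass(frozen=True)
class ScreenLibrary:
    """shRNA -> (barcode, gene, role) annotation table.

    ``records`` has columns ``shrna_id, barcode, gene, role`` with unique
    ids and roles drawn from {target, killing, ntc}.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
        if missing:
            raise ScreenFormatError(f"library is missing columns: {missing}")
        dup = df["shrna_id"][df["shrna_id"].duplicated()]
        if len(dup):
            raise ScreenFormatError(
                f"duplicate shrna_id values: {sorted(set(dup))[:10]}"
            )
        bad_role = df.loc[~df["role"].isin(ROLES)]
        if len(bad_role):
            first = bad_role.iloc[0]
            raise ScreenFormatError(
                f"unknown role {first['role']!r} for shRNA {first['shrna_id']!r}"
            )
        empty_gene = df.loc[(df["role"] == "target") & (df["gene"].astype(str).str.len() == 0)]
        if len(empty_gene):
            raise ScreenFormatError(
                f"target records without gene: {list(empty_gene['shrna_id'])[:10]}"
            )
        object.__setattr__(self, "records", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreenLibrary):
            return NotImplemented
        a = self.records.sort_values("shrna_id").reset_index(drop=True)
        b = other.records.sort_values("shrna_id").reset_index(drop=True)
        return a[LIBRARY_COLUMNS].equals(b[LIBRARY_COLUMNS])

    @property
    def shrna_ids(self) -> pd.Index:
        return pd.Index(self.records["shrna_id"])

    def roles(self) -> pd.Series:
        """Role per shRNA, indexed by shrna_id."""
        return self.records.set_index("shrna_id")["role"]

    def genes(self) -> pd.Series:
        """Gene per shRNA, indexed by shrna_id."""
        return self.records.set_index("shrna_id")["gene"]

    def ids_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ScreenFormatError(f"unknown role {role!r}")
        return list(self.records.loc[self.records["role"] == role, "shrna_id"])


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: cell line, input/final timepoint, replicate."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ScreenFormatError(f"sample metadata is missing columns: {missing}")
        bad_tp = df.loc[~df["timepoint"].isin(TIMEPOINTS)]
        if len(bad_tp):
            raise ScreenFormatError(
                f"unknown timepoint {bad_tp.iloc[0]['timepoint']!r}"
            )
        key = df[["cell_line", "timepoint", "replicate"]]
        if key.duplicated().any():
            raise ScreenFormatError("duplicate (cell_line, timepoint, replicate)")
        if df["sample_id"].duplicated().any():
            raise ScreenFormatError("duplicate sample_id")
        # every final sample must be pairable to an input of its line
        for _, row in df.loc[df["timepoint"] == "final"].iterrows():
            try:
                self._input_for(df, row["cell_line"], row["replicate"])
            except ScreenFormatError:
                raise ScreenFormatError(
                    f"final sample {row['sample_id']!r} has no matching input sample"
                ) from None
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @staticmethod
    def _input_for(df: pd.DataFrame, cell_line: str, replicate) -> str:
        inputs = df.loc[(df["cell_line"] == cell_line) & (df["timepoint"] == "input")]
        matched = inputs.loc[inputs["replicate"] == replicate]
        if len(matched) == 1:
            return matched.iloc[0]["sample_id"]
        if len(inputs) == 1:
            return inputs.iloc[0]["sample_id"]
        raise ScreenFormatError(
            f"no unambiguous input sample for cell line {cell_line!r}, replicate {replicate!r}"
        )

    def input_for(self, cell_line: str, replicate) -> str:
        """Sample id of the input paired with (cell_line, replicate).

        Replicate-matched input if present, else the line's single input.
        """
        return self._input_for(self.table, cell_line, replicate)

    def finals(self) -> pd.DataFrame:
        return self.table.loc[self.table["timepoint"] == "final"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


@dataclass(frozen=True)
class CountMatrix:
    """Raw barcode counts, shRNA x sample, with attached sample metadata."""

    values: pd.DataFrame
    meta: SampleMeta

    def __post_init__(self) -> None:
        v = self.values
        if (v.to_numpy() < 0).any():
            raise ScreenFormatError("negative counts")
        missing = set(v.columns) - set(self.meta.sample_ids)
        if missing:
            raise ScreenFormatError(f"samples without metadata: {sorted(missing)}")


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Per-shRNA log2 fold changes, columns (cell_line, replicate).

    ``qn`` records whether quantile normalization has been applied.
    """

    values: pd.DataFrame  # index shrna_id, MultiIndex columns (cell_line, replicate)
    qn: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ScreenFormatError("non-finite log fold changes")

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def line(self, cell_line: str) -> pd.DataFrame:
        """Replicate columns for one cell line (shRNA x replicate)."""
        if cell_line not in self.cell_lines:
            raise KeyError(f"unknown cell line {cell_line!r}")
        return self.values[cell_line]

    def line_means(self) -> pd.DataFrame:
        """Mean log2 fold change across replicates, shRNA x cell line."""
        return self.values.T.groupby(level=0).mean().T[self.cell_lines]


# ---------------------------------------------------------------------------
# I/O


def read_library(path) -> ScreenLibrary:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ScreenLibrary(df)


def write_library(library: ScreenLibrary, path) -> None:
    library.records[LIBRARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cell_line": str, "timepoint": str})
    return SampleMeta(df)


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.table[META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path, meta_path, library: ScreenLibrary) -> CountMatrix:
    meta = read_sample_meta(meta_path) if not isinstance(meta_path, SampleMeta) else meta_path
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = df.index.difference(library.shrna_ids)
    if len(unknown):
        raise ScreenFormatError(f"counts contain unknown shrna_id: {sorted(unknown)[:10]}")
    zero_rows = df.index[(df == 0).all(axis=1)]
    if len(zero_rows):
        logger.warning("count matrix has %d all-zero shRNA rows", len(zero_rows))
    return CountMatrix(df, meta)


def write_counts(counts: CountMatrix, path, meta_path=None) -> None:
    counts.values.to_csv(path, sep="\t", index_label="shrna_id")
    if meta_path is not None:
        write_sample_meta(counts.meta, meta_path)


def _flat_column(cell_line: str, replicate) -> str:
    return f"{cell_line}__r{replicate}"


def write_fold_changes(fc: FoldChangeMatrix, path) -> None:
    flat = fc.values.copy()
    flat.columns = [_flat_column(l, r) for l, r in fc.values.columns]
    flat.to_csv(path, sep="\t", index_label="shrna_id")


def read_fold_changes(path, qn: bool = False) -> FoldChangeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    pairs = []
    for col in df.columns:
        line, _, rep = col.rpartition("__r")
        if not line:
            raise ScreenFormatError(f"column {col!r} does not follow '<line>__r<k>'")
        pairs.append((line, int(rep)))
    df.columns = pd.MultiIndex.from_tuples(pairs, names=["cell_line", "replicate"])
    return FoldChangeMatrix(df, qn=qn)


# ---------------------------------------------------------------------------
# Normalization and fold changes


def ntc_size_factors(
    counts: CountMatrix, library: ScreenLibrary, stat: str = "median"
) -> pd.Series:
    """Per-sample scale factors anchored on the NTC shRNAs.

    factor_s = stat(NTC counts in s) / geometric mean of that stat across
    samples; dividing sample s by factor_s equalizes the NTC statistic.
    ``stat`` is 'median' (default, robust) or 'total'.
    """
    ntc_ids = library.ids_with_role("ntc")
    if not ntc_ids:
        raise ScreenFormatError("library has no NTC shRNAs")
    sub = counts.values.loc[counts.values.index.intersection(ntc_ids)]
    if sub.empty:
        raise ScreenFormatError("count matrix has no NTC rows")
    all_zero = (sub == 0).all(axis=0)
    if all_zero.any():
        raise ScreenFormatError(
            f"all NTC counts are zero in samples: {list(sub.columns[all_zero])}"
        )
    if stat == "median":
        per_sample = sub.median(axis=0)
    elif stat == "total":
        per_sample = sub.sum(axis=0)
    else:
        raise ScreenFormatError(f"unknown NTC statistic {stat!r}")
    if (per_sample <= 0).any():
        bad = list(per_sample.index[per_sample <= 0])
        raise ScreenFormatError(f"non-positive NTC {stat} in samples: {bad}")
    factors = per_sample / gmean(per_sample)
    factors.name = "size_factor"
    for sid, f in factors.items():
        logger.debug("NTC size factor %s = %.4g", sid, f)
    return factors


def shrna_log_fold_change(
    counts: CountMatrix,
    factors: pd.Series,
    pseudocount: float = 0.5,
) -> FoldChangeMatrix:
    """Per-shRNA log2 fold change of each final sample against its input.

    Counts are scaled by the per-sample size factors first, then the
    pseudocount is added:
    logFC = log2((c_final/f_final + pc) / (c_input/f_input + pc)).
    """
    if pseudocount < 0:
        raise ScreenFormatError("pseudocount must be >= 0")
    meta = counts.meta
    cols: dict[tuple[str, int], pd.Series] = {}
    for _, row in meta.finals().iterrows():
        input_id = meta.input_for(row["cell_line"], row["replicate"])
        final_norm = counts.values[row["sample_id"]] / factors[row["sample_id"]]
        input_norm = counts.values[input_id] / factors[input_id]
        lfc = np.log2((final_norm + pseudocount) / (input_norm + pseudocount))
        cols[(row["cell_line"], row["replicate"])] = lfc
    if not cols:
        raise ScreenFormatError("no final samples to compute fold changes for")
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["cell_line", "replicate"])
    return FoldChangeMatrix(df.sort_index(axis=1), qn=False)


def quantile_normalize(fc: FoldChangeMatrix) -> FoldChangeMatrix:
    """Quantile-normalize the fold-change columns.

    Each column's values are replaced by the across-column means of the
    order statistics, assigned by within-column rank; ties receive the mean
    of the order-statistic means over their tied rank range. A single
    column passes through unchanged.
    """
    x = fc.values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        return FoldChangeMatrix(fc.values.copy(), qn=True)
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = mean_sorted.copy()
        sorted_col = col[order]
        # average order-statistic means over runs of tied values
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, len(col)]):
            if hi - lo > 1:
                assigned[lo:hi] = assigned[lo:hi].mean()
        out[order, j] = assigned
    return FoldChangeMatrix(
        pd.DataFrame(out, index=fc.values.index, columns=fc.values.columns), qn=True
    )
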