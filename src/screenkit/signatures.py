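"""Gene-signature scoring for single-cell expression matrices.

Covers percent-expressing per cell, mean z-score signature scores, paired
lineage scores, per-cluster box summaries and pseudotime-binned score
trajectories. Expression is a cells x genes table; raw counts are
normalized internally (counts-per-10k, log1p) before z-scoring.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

TARGET_SUM = 10_000.0

ANNOTATION_COLUMNS = ["cell_id", "cluster", "genotype", "pseudotime"]


class SignatureError(ValueError):
    pass


def load_expression(path, genes_path=None, barcodes_path=None) -> pd.DataFrame:
    """Load a cells x genes matrix from dense TSV or an MTX triplet.

    For MTX input the matrix is genes x cells (standard orientation) with
    one gene id per line in ``genes_path`` and one cell barcode per line in
    ``barcodes_path``; it is transposed to cells x genes on load.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or barcodes_path is None:
            raise SignatureError("MTX input requires genes and barcodes files")
        mat = scipy.io.mmread(path)
        genes = [l.strip().split("\t")[0] for l in Path(genes_path).read_text().splitlines() if l.strip()]
        cells = [l.strip() for l in Path(barcodes_path).read_text().splitlines() if l.strip()]
        dense = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        if dense.shape != (len(genes), len(cells)):
            raise SignatureError(
                f"matrix shape {dense.shape} does not match {len(genes)} genes x {len(cells)} cells"
            )
        return pd.DataFrame(dense.T, index=pd.Index(cells, name="cell_id"), columns=genes)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "cell_id"
    return df


def load_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns and c != "pseudotime"]
    if missing:
        raise SignatureError(f"annotation is missing columns: {missing}")
    if "pseudotime" not in df.columns:
        df["pseudotime"] = np.nan
    return df.set_index("cell_id")


def read_gene_list(path) -> list[str]:
    """Newline-delimited gene list; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def _filter_signature(expr: pd.DataFrame, signature) -> list[str]:
    signature = list(signature)
    if not signature:
        raise SignatureError("empty signature")
    present = [g for g in signature if g in expr.columns]
    dropped = len(signature) - len(present)
    if dropped:
        warnings.warn(f"{dropped} signature genes absent from matrix; dropped", stacklevel=3)
    if not present:
        raise SignatureError("no signature genes present in the expression matrix")
    return present


def percent_expressing_per_cell(expr: pd.DataFrame, signature) -> pd.Series:
    """Percent of signature genes with non-zero counts, per cell."""
    genes = _filter_signature(expr, signature)
    frac = (expr[genes] > 0).sum(axis=1) / len(genes)
    out = 100.0 * frac
    out.name = "percent_expressing"
    return out


def aggregate_by_cluster(
    values: pd.Series,
    annotation: pd.DataFrame,
    by: tuple[str, ...] = ("cluster", "genotype"),
) -> pd.DataFrame:
    """Boxplot-style summary per annotation group.

    Reports median, lower/upper quartiles (linear-interpolation convention)
    and whisker bounds: the most extreme data within 1.5 * IQR of the
    quartiles. Groups without cells are omitted (with a warning when the
    annotation declares categories that received none).
    """
    ann = annotation.loc[values.index]
    df = pd.DataFrame({"value": values})
    for col in by:
        df[col] = ann[col].array
        if isinstance(df[col].dtype, pd.CategoricalDtype):
            empty = set(df[col].cat.categories) - set(df[col].dropna())
            for cat in sorted(empty):
                warnings.warn(f"group {cat!r} has no cells; omitted", stacklevel=2)
    rows = []
    for key, sub in df.groupby(list(by), sort=True, observed=True):
        if sub.empty:  # pragma: no cover - iteration skips empty groups
            continue
        v = sub["value"].to_numpy()
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
        iqr = q3 - q1
        in_lo = v[v >= q1 - 1.5 * iqr]
        in_hi = v[v <= q3 + 1.5 * iqr]
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(
                zip(by, key),
                n=len(v),
                median=med,
                q1=q1,
                q3=q3,
                whisker_lo=in_lo.min(),
                whisker_hi=in_hi.max(),
            )
        )
    return pd.DataFrame(rows, columns=[*by, "n", "median", "q1", "q3", "whisker_lo", "whisker_hi"])


def lognormalize(expr: pd.DataFrame, target_sum: float = TARGET_SUM) -> pd.DataFrame:
    """Depth-scale each cell to ``target_sum`` total counts, then log1p.

    All-zero cells are left at zero (no division by zero).
    """
    totals = expr.sum(axis=1)
    scale = np.where(totals > 0, target_sum / np.where(totals > 0, totals, 1.0), 0.0)
    return np.log1p(expr.mul(scale, axis=0))


def signature_mean_score(
    expr: pd.DataFrame, signature, normalized: bool = False
) -> pd.Series:
    """Mean per-gene z-score over the signature, per cell.

    Raw counts (``normalized=False``) are counts-per-10k log1p normalized
    first. Genes with zero variance across cells contribute 0.
    """
    genes = _filter_signature(expr, signature)
    mat = expr if normalized else lognormalize(expr)
    sub = mat[genes].to_numpy(dtype=float)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    out = pd.Series(z.mean(axis=1), index=expr.index, name="score")
    return out


def lineage_scores(
    expr: pd.DataFrame,
    neutrophil_markers,
    monocyte_markers,
    normalized: bool = False,
) -> pd.DataFrame:
    """Joint neutrophil / monocyte lineage scores per cell."""
    neu = signature_mean_score(expr, neutrophil_markers, normalized=normalized)
    mono = signature_mean_score(expr, monocyte_markers, normalized=normalized)
    return pd.DataFrame({"neutrophil": neu, "monocyte": mono})


def pseudotime_profile(
    scores: pd.Series,
    annotation: pd.DataFrame,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Mean score per (pseudotime bin, genotype).

    Bins are equal-width over the pooled pseudotime range of scored cells.
    Returns a long frame ``bin, bin_center, genotype, mean_score, n_cells``;
    empty (bin, genotype) combinations carry NaN means.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ann = annotation.loc[scores.index]
    pt = ann["pseudotime"]
    keep = pt.notna()
    if not keep.any():
        raise SignatureError("no cells with pseudotime")
    pt = pt[keep].astype(float)
    sc = scores[keep]
    geno = ann.loc[keep, "genotype"]
    lo, hi = float(pt.min()), float(pt.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(pt, edges[1:-1], right=False), 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    df = pd.DataFrame({"bin": idx, "genotype": geno.to_numpy(), "score": sc.to_numpy()})
    rows = []
    for g in sorted(set(df["genotype"])):
        sub = df.loc[df["genotype"] == g]
        agg = sub.groupby("bin")["score"].agg(["mean", "size"])
        for b in range(n_bins):
            if b in agg.index:
                rows.append((b, centers[b], g, agg.loc[b, "mean"], int(agg.loc[b, "size"])))
            else:
                rows.append((b, centers[b], g, np.nan, 0))
    return pd.DataFrame(rows, columns=["bin", "bin_center", "genotype", "mean_score", "n_cells"])
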