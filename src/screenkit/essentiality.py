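"""Gene essentiality calling from quantile-normalized fold changes.

Per-shRNA depletion significance comes from the empirical NTC null; gene
scores are alpha-RRA (minimum Beta order-statistic tail probability over
the significant shRNAs); significance is assessed by permuting shRNA->gene
assignments, with Benjamini-Hochberg FDR over target genes. The essential
call requires depletion, gene FDR < 0.01 and >= 3 supporting shRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta
from statsmodels.stats.multitest import multipletests

from .screen import FoldChangeMatrix, ScreenFormatError, ScreenLibrary

DEFAULT_ALPHA = 0.25
MIN_NTC = 10


def shrna_null_pvalues(
    fc: FoldChangeMatrix,
    library: ScreenLibrary,
    cell_line: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    direction: str = "depletion",
) -> pd.DataFrame:
    """Per-shRNA statistics against the NTC empirical null for one cell line.

    Returns a frame with columns ``shrna_id, gene, role, mean_lfc, p,
    rank_norm, support``.  p_i = (#{NTC j: x_j <= x_i} + 1) / (N_ntc + 1)
    for depletion (>= for enrichment); normalized ranks cover target shRNAs
    only, ordered by (p, mean_lfc, shrna_id); support means p < alpha and
    mean_lfc < 0.
    """
    if not fc.qn:
        raise ScreenFormatError("fold changes must be quantile-normalized first")
    if direction not in {"depletion", "enrichment"}:
        raise ScreenFormatError(f"unknown direction {direction!r}")
    if cell_line is None:
        lines = fc.cell_lines
        if len(lines) != 1:
            raise ScreenFormatError("cell_line must be given for a multi-line matrix")
        cell_line = lines[0]
    mean_lfc = fc.line(cell_line).mean(axis=1)

    roles = library.roles().reindex(mean_lfc.index)
    if roles.isna().any():
        raise ScreenFormatError(
            f"shRNAs missing from library: {list(mean_lfc.index[roles.isna()])[:10]}"
        )
    ntc_vals = np.sort(mean_lfc[roles == "ntc"].to_numpy())
    if len(ntc_vals) < MIN_NTC:
        raise ScreenFormatError(f"need >= {MIN_NTC} NTC shRNAs, found {len(ntc_vals)}")

    x = mean_lfc.to_numpy()
    if direction == "depletion":
        n_le = np.searchsorted(ntc_vals, x, side="right")
    else:
        n_le = len(ntc_vals) - np.searchsorted(ntc_vals, x, side="left")
    p = (n_le + 1) / (len(ntc_vals) + 1)

    stats = pd.DataFrame(
        {
            "shrna_id": mean_lfc.index,
            "gene": library.genes().reindex(mean_lfc.index).to_numpy(),
            "role": roles.to_numpy(),
            "mean_lfc": x,
            "p": p,
        }
    )
    stats["rank_norm"] = np.nan
    targets = stats["role"] == "target"
    ranked = stats.loc[targets].sort_values(["p", "mean_lfc", "shrna_id"], kind="mergesort")
    n_scored = len(ranked)
    stats.loc[ranked.index, "rank_norm"] = np.arange(1, n_scored + 1) / n_scored
    if direction == "depletion":
        stats["support"] = (stats["p"] < alpha) & (stats["mean_lfc"] < 0)
    else:
        stats["support"] = (stats["p"] < alpha) & (stats["mean_lfc"] > 0)
    return stats.reset_index(drop=True)


def beta_order_statistic_cdf(r, k: int, n: int):
    """P(k-th order statistic of n iid uniforms <= r): Beta(k, n-k+1) CDF."""
    if not 1 <= k <= n:
        raise ValueError(f"require 1 <= k <= n, got k={k}, n={n}")
    return beta.cdf(r, k, n - k + 1)


def alpha_rra_score(ranks, pvalues, alpha: float = DEFAULT_ALPHA) -> float:
    """alpha-RRA score for one gene.

    ``ranks`` are the gene's shRNA normalized ranks in (0, 1], ``pvalues``
    the matching per-shRNA p-values. With j shRNAs at p < alpha, rho is the
    minimum over k = 1..j of the Beta(k, n-k+1) CDF at the k-th smallest
    rank; rho = 1 when no shRNA is selected.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    ranks = np.asarray(ranks, dtype=float)
    pvalues = np.asarray(pvalues, dtype=float)
    if ranks.shape != pvalues.shape or ranks.ndim != 1 or len(ranks) == 0:
        raise ValueError("ranks and pvalues must be equal-length 1-D arrays")
    order = np.argsort(ranks, kind="mergesort")
    r_sorted = ranks[order]
    n = len(ranks)
    j = int((pvalues < alpha).sum())
    if j == 0:
        return 1.0
    ks = np.arange(1, j + 1)
    terms = beta.cdf(r_sorted[:j], ks, n - ks + 1)
    return float(terms.min())


def _rho_matrix(sorted_ranks: np.ndarray, n_selected: np.ndarray) -> np.ndarray:
    """Vectorized alpha-RRA over rows of pre-sorted normalized ranks.

    ``sorted_ranks`` is (m, n) ascending per row; ``n_selected`` gives j per
    row (selected shRNAs are the j smallest ranks by construction).
    """
    m, n = sorted_ranks.shape
    ks = np.arange(1, n + 1)
    terms = beta.cdf(sorted_ranks, ks[None, :], (n - ks + 1)[None, :])
    masked = np.where(ks[None, :] <= n_selected[:, None], terms, np.inf)
    rho = masked.min(axis=1)
    rho[n_selected == 0] = 1.0
    return rho


@dataclass(frozen=True)
class RraResult:
    """Gene-level table plus the permutation null used to calibrate it.

    ``null_rho`` maps gene size -> sorted null rho values (pooled across
    genes of that size), kept for calibration diagnostics.
    """

    table: pd.DataFrame  # gene, rho, p_perm, fdr, n_support, mean_lfc, essential
    n_perm: int
    alpha: float
    null_rho: dict[int, np.ndarray] = None


def rra_permutation_fdr(
    stats: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 1000,
    seed: int | None = None,
    fdr_threshold: float = 0.01,
    min_support: int = 3,
) -> RraResult:
    """Gene-level alpha-RRA with a shRNA->gene permutation null.

    Null rho values are obtained by permuting the shRNA-to-gene assignment
    among target shRNAs (preserving per-gene shRNA counts) and pooling
    across genes with equal shRNA count. p_perm uses the +1 smoothing
    convention; FDR is Benjamini-Hochberg over target genes.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    targets = stats.loc[stats["role"] == "target"].reset_index(drop=True)
    if targets.empty:
        raise ScreenFormatError("no target shRNAs to aggregate")
    rng = np.random.default_rng(seed)

    ranks = targets["rank_norm"].to_numpy(dtype=float)
    selected = (targets["p"] < alpha).to_numpy()

    genes = targets.groupby("gene", sort=True)
    gene_names = []
    obs_rho = []
    n_support = []
    mean_lfc = []
    sizes = []
    for gene, sub in genes:
        gene_names.append(gene)
        obs_rho.append(alpha_rra_score(sub["rank_norm"], sub["p"], alpha=alpha))
        n_support.append(int(sub["support"].sum()))
        mean_lfc.append(float(sub["mean_lfc"].mean()))
        sizes.append(len(sub))
    sizes = np.asarray(sizes)
    obs_rho = np.asarray(obs_rho)

    # permutation null, pooled per gene size
    null_by_size: dict[int, np.ndarray] = {}
    size_counts = pd.Series(sizes).value_counts().to_dict()
    n_shrnas = len(targets)
    paired = np.column_stack([ranks, selected.astype(float)])
    for size, m_genes in size_counts.items():
        chunks = []
        usable = (n_shrnas // size) * size
        for _ in range(n_perm):
            perm = rng.permutation(n_shrnas)[:usable]
            mat = paired[perm].reshape(-1, size, 2)
            r = np.sort(mat[:, :, 0], axis=1)
            j = mat[:, :, 1].sum(axis=1).astype(int)
            chunks.append(_rho_matrix(r, j))
        null_by_size[size] = np.sort(np.concatenate(chunks))

    p_perm = np.empty(len(gene_names))
    for i, (rho, size) in enumerate(zip(obs_rho, sizes)):
        null = null_by_size[size]
        p_perm[i] = (np.searchsorted(null, rho, side="right") + 1) / (len(null) + 1)

    _, fdr, _, _ = multipletests(p_perm, method="fdr_bh")
    table = pd.DataFrame(
        {
            "gene": gene_names,
            "rho": obs_rho,
            "p_perm": p_perm,
            "fdr": fdr,
            "n_support": n_support,
            "mean_lfc": mean_lfc,
        }
    )
    table = call_essential_genes(table, fdr_threshold=fdr_threshold, min_support=min_support)
    return RraResult(table=table, n_perm=n_perm, alpha=alpha, null_rho=null_by_size)


def call_essential_genes(
    table: pd.DataFrame, fdr_threshold: float = 0.01, min_support: int = 3
) -> pd.DataFrame:
    """Apply the three-criterion essential call.

    essential <=> gene FDR < threshold AND >= min_support supporting shRNAs
    AND gene-level mean logFC < 0.
    """
    out = table.copy()
    out["essential"] = (
        (out["fdr"] < fdr_threshold)
        & (out["n_support"] >= min_support)
        & (out["mean_lfc"] < 0)
    )
    return out


def essential_gene_set(table: pd.DataFrame) -> set[str]:
    return set(table.loc[table["essential"], "gene"])


def essentiality_overlap(calls: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive intersection-class counts over per-line essential sets.

    Returns one row per non-empty membership pattern (upset-plot style);
    one boolean column per cell line plus ``count``. Classes partition the
    union of the input sets.
    """
    if len(calls) < 2:
        raise ValueError("need >= 2 cell lines for an overlap table")
    lines = list(calls)
    union = set().union(*calls.values())
    patterns: dict[tuple[bool, ...], int] = {}
    for gene in union:
        pat = tuple(gene in calls[line] for line in lines)
        patterns[pat] = patterns.get(pat, 0) + 1
    rows = [dict(zip(lines, pat), count=c) for pat, c in patterns.items()]
    df = pd.DataFrame(rows, columns=[*lines, "count"])
    return df.sort_values("count", ascending=False, kind="mergesort").reset_index(drop=True)
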