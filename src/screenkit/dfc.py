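"""Differential fold-change (DFC) analysis between cell lines.

Per-shRNA DFC = mean qn-logFC(line A) - mean qn-logFC(line B); genes
essential in line A whose shRNAs fall beyond an empirical NTC-derived
cutoff in >= 3 copies are classified as preferentially growth-inhibited
in line A.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .screen import FoldChangeMatrix, ScreenFormatError, ScreenLibrary

logger = logging.getLogger(__name__)

MIN_NTC_DFC = 10


def _single_line_means(fc: FoldChangeMatrix, cell_line: str | None) -> pd.Series:
    if cell_line is None:
        lines = fc.cell_lines
        if len(lines) != 1:
            raise ScreenFormatError("cell line must be given for a multi-line matrix")
        cell_line = lines[0]
    return fc.line(cell_line).mean(axis=1)


def per_shrna_dfc(
    fc_a: FoldChangeMatrix,
    fc_b: FoldChangeMatrix,
    library: ScreenLibrary,
    line_a: str | None = None,
    line_b: str | None = None,
) -> pd.DataFrame:
    """Per-shRNA differential fold change A - B on replicate-mean qn-logFCs.

    Returns columns ``shrna_id, gene, role, dfc``. Both inputs must be
    quantile-normalized and cover the same shRNAs.
    """
    if not (fc_a.qn and fc_b.qn):
        raise ScreenFormatError("both fold-change matrices must be quantile-normalized")
    mean_a = _single_line_means(fc_a, line_a)
    mean_b = _single_line_means(fc_b, line_b)
    only_a = mean_a.index.difference(mean_b.index)
    only_b = mean_b.index.difference(mean_a.index)
    if len(only_a) or len(only_b):
        raise ScreenFormatError(
            "mismatched shRNA sets; "
            f"missing from B: {sorted(only_a)[:10]}, missing from A: {sorted(only_b)[:10]}"
        )
    dfc = mean_a - mean_b.reindex(mean_a.index)
    out = pd.DataFrame(
        {
            "shrna_id": dfc.index,
            "gene": library.genes().reindex(dfc.index).to_numpy(),
            "role": library.roles().reindex(dfc.index).to_numpy(),
            "dfc": dfc.to_numpy(),
        }
    )
    if out["role"].isna().any():
        missing = list(out.loc[out["role"].isna(), "shrna_id"])[:10]
        raise ScreenFormatError(f"shRNAs missing from library: {missing}")
    return out.reset_index(drop=True)


def ntc_dfc_cutoff(dfc: pd.DataFrame, q: float = 0.05) -> float:
    """Empirical cutoff: the q-th linear-interpolation quantile of NTC DFCs."""
    if not 0 < q < 1:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    ntc = dfc.loc[dfc["role"] == "ntc", "dfc"].to_numpy()
    if len(ntc) < MIN_NTC_DFC:
        raise ScreenFormatError(f"need >= {MIN_NTC_DFC} NTC DFCs, found {len(ntc)}")
    cutoff = float(np.quantile(ntc, q, method="linear"))
    logger.info("NTC DFC cutoff at q=%.3g: %.4g (linear-interpolation quantile)", q, cutoff)
    return cutoff


def classify_preferential_genes(
    dfc: pd.DataFrame,
    cutoff: float,
    essential_a: set[str] | pd.DataFrame,
    min_support: int = 3,
) -> pd.DataFrame:
    """Genes with preferential growth inhibition in line A.

    A gene is classified iff it is essential in line A and at least
    ``min_support`` of its shRNAs have DFC < cutoff.
    """
    if isinstance(essential_a, pd.DataFrame):
        essential_set = set(essential_a.loc[essential_a["essential"], "gene"])
    else:
        essential_set = set(essential_a)
    targets = dfc.loc[dfc["role"] == "target"]
    grouped = targets.groupby("gene", sort=True)["dfc"]
    table = pd.DataFrame(
        {
            "gene": list(grouped.groups),
            "n_shrnas": grouped.size().to_numpy(),
            "n_below_cutoff": grouped.apply(lambda v: int((v < cutoff).sum())).to_numpy(),
            "mean_dfc": grouped.mean().to_numpy(),
        }
    )
    table["essential_in_a"] = table["gene"].isin(essential_set)
    table["classified"] = table["essential_in_a"] & (table["n_below_cutoff"] >= min_support)
    table["cutoff"] = cutoff
    return table.reset_index(drop=True)


def cross_line_intersection(calls: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes classified preferential in more than one comparison.

    ``calls`` maps comparison label -> classify_preferential_genes output.
    Returns gene plus one boolean column per comparison, restricted to
    genes classified in >= 2 comparisons.
    """
    if len(calls) < 2:
        raise ValueError("need >= 2 comparisons")
    sets = {name: set(df.loc[df["classified"], "gene"]) for name, df in calls.items()}
    union = sorted(set().union(*sets.values()))
    rows = []
    for gene in union:
        membership = {name: gene in s for name, s in sets.items()}
        if sum(membership.values()) >= 2:
            rows.append({"gene": gene, **membership})
    return pd.DataFrame(rows, columns=["gene", *sets])
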