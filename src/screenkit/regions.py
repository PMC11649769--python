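"""Genomic interval machinery and region-set enrichment.

Peaks are BED-style 0-based half-open intervals. The analysis partitions a
transcription factor's peaks by co-binding with a partner factor, assigns
peaks to genes through fixed-width windows around transcription start
sites, groups the assigned peaks into signature-specific region sets, and
tests each set for a global shift of a per-region differential-binding
statistic with a weighted running-sum enrichment score, random-set
permutation null, NES and FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 50_000


class RegionError(ValueError):
    pass


@dataclass(frozen=True)
class PeakSet:
    """Sorted genomic intervals with optional per-region statistics.

    ``intervals`` columns: chrom, start, end, region_id (unique); sorted by
    (chrom, start). ``stats`` is an optional Series indexed by region_id.
    """

    intervals: pd.DataFrame
    stats: pd.Series | None = None
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        df = self.intervals
        required = ["chrom", "start", "end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise RegionError(f"peak table is missing columns: {missing}")
        df = df.copy()
        if "region_id" not in df.columns:
            df["region_id"] = [f"region_{i}" for i in range(len(df))]
        if df["region_id"].duplicated().any():
            dups = df["region_id"][df["region_id"].duplicated()]
            raise RegionError(f"duplicate region_id: {sorted(set(dups))[:10]}")
        if (df["start"] < 0).any():
            raise RegionError("negative start coordinate")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "region_id"]
            raise RegionError(f"empty/inverted intervals: {list(bad)[:10]}")
        if self.chrom_lengths is not None:
            for chrom, sub in df.groupby("chrom"):
                if chrom not in self.chrom_lengths:
                    raise RegionError(f"unknown chromosome {chrom!r}")
                if (sub["end"] > self.chrom_lengths[chrom]).any():
                    raise RegionError(f"interval beyond the end of {chrom}")
        if not df[["chrom", "start"]].equals(
            df[["chrom", "start"]].sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        ):
            warnings.warn("peak table was not sorted; sorting by (chrom, start)", stacklevel=3)
            df = df.sort_values(["chrom", "start"], kind="mergesort")
        object.__setattr__(self, "intervals", df.reset_index(drop=True))
        if self.stats is not None:
            missing_ids = set(df["region_id"]) - set(self.stats.index)
            if missing_ids:
                raise RegionError(f"stats missing for regions: {sorted(missing_ids)[:10]}")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def region_ids(self) -> pd.Index:
        return pd.Index(self.intervals["region_id"])


def read_bed(path, chrom_lengths=None) -> PeakSet:
    """Read a BED3+ file; column 4, when present, becomes region_id."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise RegionError(f"line {i + 1}: BED needs >= 3 columns")
        row = {"chrom": fields[0], "start": int(fields[1]), "end": int(fields[2])}
        if len(fields) >= 4:
            row["region_id"] = fields[3]
        rows.append(row)
    return PeakSet(pd.DataFrame(rows), chrom_lengths=chrom_lengths)


def write_bed(peaks: PeakSet, path) -> None:
    df = peaks.intervals
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['region_id']}\n")


def read_tss_table(path) -> pd.DataFrame:
    """TSS TSV with 1-based positions; converted to 0-based on read.

    Columns: gene, chrom, tss (1-based), strand, signature.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "chrom", "tss", "strand", "signature"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RegionError(f"TSS table is missing columns: {missing}")
    df = df.copy()
    df["tss0"] = df["tss"].astype(int) - 1
    if (df["tss0"] < 0).any():
        raise RegionError("TSS position < 1 in 1-based input")
    return df


def write_tss_table(tss: pd.DataFrame, path) -> None:
    cols = ["gene", "chrom", "tss", "strand", "signature"]
    tss[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interval operations


def _overlap_flags_one_chrom(
    a_start: np.ndarray, a_end: np.ndarray, b_start: np.ndarray, b_end: np.ndarray
) -> np.ndarray:
    """True for each a-interval sharing >= 1 bp with any b-interval.

    b intervals may overlap each other; a prefix running maximum of b ends
    over b sorted by start makes the test exact in one searchsorted pass.
    """
    order = np.argsort(b_start, kind="mergesort")
    bs = b_start[order]
    be_cummax = np.maximum.accumulate(b_end[order])
    j = np.searchsorted(bs, a_end, side="left")  # count of b with bs < a_end
    flags = np.zeros(len(a_start), dtype=bool)
    nz = j > 0
    flags[nz] = be_cummax[j[nz] - 1] > a_start[nz]
    return flags


def intervals_overlap(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> pd.Series:
    """Boolean flag per region of ``a``: shares >= min_overlap bases with b.

    Requiring an overlap of at least m bases is equivalent to shrinking
    both interval sets by m - 1 bases on the right and testing plain
    overlap, which a sweep over start-sorted b with a running end maximum
    answers exactly.
    """
    if min_overlap < 1:
        raise RegionError("min_overlap must be >= 1")
    shrink = min_overlap - 1
    flags = pd.Series(False, index=a.region_ids, name="cobound")
    b_by_chrom = dict(tuple(b.intervals.groupby("chrom")))
    for chrom, sub_a in a.intervals.groupby("chrom"):
        sub_b = b_by_chrom.get(chrom)
        if sub_b is None:
            continue
        a_start = sub_a["start"].to_numpy()
        a_end = sub_a["end"].to_numpy() - shrink
        b_start = sub_b["start"].to_numpy()
        b_end = sub_b["end"].to_numpy() - shrink
        ok = (a_end > a_start) & True  # too-short a-intervals can never qualify
        res = np.zeros(len(sub_a), dtype=bool)
        keep_b = b_end > b_start
        if keep_b.any() and ok.any():
            res[ok] = _overlap_flags_one_chrom(
                a_start[ok], a_end[ok], b_start[keep_b], b_end[keep_b]
            )
        flags.loc[sub_a["region_id"].to_numpy()] = res
    return flags


def tss_window_assign(
    peaks: PeakSet,
    tss: pd.DataFrame,
    half_width: int = DEFAULT_HALF_WIDTH,
) -> pd.DataFrame:
    """Assign peaks to genes whose TSS window they overlap by >= 1 bp.

    The window for a TSS at 0-based position t is [t - half_width,
    t + half_width] inclusive, i.e. the half-open interval
    [max(0, t - half_width), t + half_width + 1). A peak may be assigned to
    several genes; every pair is returned (columns region_id, gene).
    """
    if half_width < 0:
        raise RegionError("half_width must be >= 0")
    if "tss0" not in tss.columns:
        tss = tss.assign(tss0=tss["tss"].astype(int) - 1)
    pairs: list[tuple[str, str]] = []
    tss_by_chrom = dict(tuple(tss.groupby("chrom")))
    for chrom, sub_p in peaks.intervals.groupby("chrom"):
        sub_t = tss_by_chrom.get(chrom)
        if sub_t is None:
            continue
        sub_t = sub_t.sort_values("tss0", kind="mergesort")
        w_start = np.maximum(0, sub_t["tss0"].to_numpy() - half_width)
        w_end = sub_t["tss0"].to_numpy() + half_width + 1
        genes = sub_t["gene"].to_numpy()
        # w_start and w_end are both nondecreasing (monotone TSS), so the
        # windows overlapping a peak form the contiguous index range
        # [first w_end > peak_start, last w_start < peak_end).
        for _, peak in sub_p.iterrows():
            lo = np.searchsorted(w_end, peak["start"], side="right")
            hi = np.searchsorted(w_start, peak["end"], side="left")
            for g in genes[lo:hi]:
                pairs.append((peak["region_id"], g))
    return pd.DataFrame(pairs, columns=["region_id", "gene"])


@dataclass(frozen=True)
class RegionSets:
    """Named region sets plus the construction metadata."""

    sets: dict[str, list[str]]
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}


def build_signature_region_sets(
    tf_peaks: PeakSet,
    partner_peaks: PeakSet,
    tss: pd.DataFrame,
    half_width: int = DEFAULT_HALF_WIDTH,
    exclude_cobound: bool = True,
    min_overlap: int = 1,
) -> RegionSets:
    """Signature-specific sets of TF peaks near the signature's TSSs.

    Each signature's set holds the tf peaks assigned to >= 1 of its genes'
    TSS windows; with ``exclude_cobound`` (default) peaks overlapping any
    partner peak are removed first. Empty sets are dropped with a warning.
    """
    cobound = intervals_overlap(tf_peaks, partner_peaks, min_overlap=min_overlap)
    assign = tss_window_assign(tf_peaks, tss, half_width=half_width)
    sig_of_gene = tss.set_index("gene")["signature"]
    assign = assign.assign(signature=sig_of_gene.reindex(assign["gene"]).to_numpy())
    sets: dict[str, list[str]] = {}
    for sig in sorted(set(tss["signature"])):
        ids = sorted(set(assign.loc[assign["signature"] == sig, "region_id"]))
        if exclude_cobound:
            ids = [r for r in ids if not cobound.loc[r]]
        if not ids:
            warnings.warn(f"region set {sig!r} is empty; excluded from testing", stacklevel=2)
            continue
        sets[sig] = ids
        logger.info("region set %s: %d regions", sig, len(ids))
    meta = {
        "half_width": half_width,
        "half_width_kb": half_width / 1000.0,
        "exclude_cobound": exclude_cobound,
        "min_overlap": min_overlap,
        "n_cobound": int(cobound.sum()),
    }
    return RegionSets(sets=sets, meta=meta)


# ---------------------------------------------------------------------------
# Preranked enrichment


def _enrichment_score(
    abs_stat_w: np.ndarray, hit_positions: np.ndarray, n_total: int
) -> float:
    """Signed maximum deviation of the weighted running sum.

    ``abs_stat_w`` gives |stat|^weight in ranked order for the hit
    positions only; the running sum gains w_i / sum(w) at each hit and
    loses 1/(N - N_h) at each miss. Extremes can only occur immediately
    after a hit or immediately before one, so only those 2*N_h candidate
    values are evaluated.
    """
    n_h = len(hit_positions)
    if n_h == 0:
        return 0.0
    if n_h == n_total:
        return 1.0
    total_w = abs_stat_w.sum()
    if total_w <= 0:
        # all-zero statistics inside the set: fall back to unweighted steps
        abs_stat_w = np.ones(n_h)
        total_w = float(n_h)
    miss_step = 1.0 / (n_total - n_h)
    cum_hit = np.cumsum(abs_stat_w) / total_w
    k = np.arange(n_h)
    misses_before = hit_positions - k
    at_hit = cum_hit - misses_before * miss_step
    before_hit = at_hit - abs_stat_w / total_w
    hi = at_hit.max()
    lo = min(before_hit.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def _rank_order(stats: pd.Series) -> pd.Series:
    """Stats sorted by decreasing value, ties broken by region id."""
    df = pd.DataFrame({"stat": stats})
    df = df.sort_values(["stat"], ascending=False, kind="mergesort")
    # stable sort on id within equal stats for determinism
    df["_id"] = df.index
    df = df.sort_values(["stat", "_id"], ascending=[False, True], kind="mergesort")
    return df["stat"]


def preranked_gsea(
    stats: pd.Series,
    sets: RegionSets | dict[str, list[str]],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked enrichment of region sets against a per-region statistic.

    Regions are ranked by decreasing statistic; ES is the signed maximum
    deviation of the weighted running sum; the null distribution comes from
    random same-size region sets; NES divides ES by the mean |null ES| of
    matching sign; p and FDR follow the standard signed-null conventions
    (FDR = tail fraction of pooled null NES over tail fraction of observed
    NES, clipped to [0, 1]).
    """
    if isinstance(sets, RegionSets):
        set_map = sets.sets
    else:
        set_map = dict(sets)
    if not set_map:
        raise RegionError("no region sets to test")
    if not np.isfinite(stats.to_numpy(dtype=float)).all():
        raise RegionError("non-finite statistics")
    ranked = _rank_order(stats)
    universe = ranked.index
    n_total = len(universe)
    pos_of = pd.Series(np.arange(n_total), index=universe)
    abs_w_full = np.abs(ranked.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(seed)

    results = []
    null_nes_all: list[np.ndarray] = []
    for name, members in set_map.items():
        members = list(members)
        missing = set(members) - set(universe)
        if missing:
            raise RegionError(f"set {name!r} has regions outside the universe: {sorted(missing)[:5]}")
        size = len(members)
        if size == 0:
            raise RegionError(f"set {name!r} is empty")
        if size > n_total:
            raise RegionError(f"set {name!r} larger than the region universe")
        hit_pos = np.sort(pos_of[members].to_numpy())
        es = _enrichment_score(abs_w_full[hit_pos], hit_pos, n_total)

        null_es = np.empty(n_perm)
        for i in range(n_perm):
            pos = np.sort(rng.choice(n_total, size=size, replace=False))
            null_es[i] = _enrichment_score(abs_w_full[pos], pos, n_total)
        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        mean_pos = pos_null.mean() if len(pos_null) else np.nan
        mean_neg = np.abs(neg_null).mean() if len(neg_null) else np.nan

        def _nes(e: float) -> float:
            if e >= 0:
                return e / mean_pos if np.isfinite(mean_pos) and mean_pos > 0 else np.nan
            return e / mean_neg if np.isfinite(mean_neg) and mean_neg > 0 else np.nan

        nes = _nes(es)
        if es >= 0:
            p = (np.sum(pos_null >= es) + 1) / (len(pos_null) + 1)
        else:
            p = (np.sum(neg_null <= es) + 1) / (len(neg_null) + 1)
        null_nes = np.array([_nes(e) for e in null_es])
        null_nes_all.append(null_nes[np.isfinite(null_nes)])
        results.append({"set": name, "size": size, "es": es, "nes": nes, "p": p})

    table = pd.DataFrame(results)
    pooled = np.concatenate(null_nes_all) if null_nes_all else np.array([])
    obs_nes = table["nes"].to_numpy()
    fdr = np.ones(len(table))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            fdr[i] = np.nan
            continue
        if nes >= 0:
            null_tail = np.mean(pooled[pooled >= 0] >= nes) if (pooled >= 0).any() else 0.0
            obs_tail = np.mean(obs_nes[obs_nes >= 0] >= nes)
        else:
            null_tail = np.mean(pooled[pooled < 0] <= nes) if (pooled < 0).any() else 0.0
            obs_tail = np.mean(obs_nes[obs_nes < 0] <= nes)
        fdr[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else np.nan
    table["fdr"] = fdr
    return table


def simple_region_logfc(
    counts: pd.DataFrame,
    conditions: pd.Series | dict,
    condition_a: str,
    condition_b: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Plain per-region log2 ratio of condition means as a ranking statistic.

    Samples are scaled to the median library size before averaging within
    condition; stat = log2((mean_A + pc) / (mean_B + pc)).
    """
    cond = pd.Series(conditions).reindex(counts.columns)
    if cond.isna().any():
        raise RegionError(f"samples without condition: {list(counts.columns[cond.isna()])}")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise RegionError(f"zero library size: {list(counts.columns[libsize <= 0])}")
    ref = float(np.median(libsize))
    norm = counts * (ref / libsize)
    mean_a = norm.loc[:, (cond == condition_a).to_numpy()].mean(axis=1)
    mean_b = norm.loc[:, (cond == condition_b).to_numpy()].mean(axis=1)
    if mean_a.isna().any() or mean_b.isna().any():
        raise RegionError("each condition needs >= 1 sample")
    out = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    out.name = "log2fc"
    return out
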