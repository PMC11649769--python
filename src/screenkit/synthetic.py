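"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators: (1) a pooled shRNA screen — library annotation, per-line
fitness truth and multinomially sequenced barcode counts after exponential
clone growth; (2) a single-cell expression fixture with signature-
structured effects, clusters, genotypes and a pseudotime axis; (3) genomic
peak sets with planted partner co-binding and differential-binding shifts
near signature TSSs.

All generators are fully determined by their config's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .screen import CountMatrix, FoldChangeMatrix, SampleMeta, ScreenLibrary
from .regions import PeakSet


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Screen simulation

KILLING_GENE_PREFIX = "killing_ctrl"
NTC_GENE = "luciferase"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Pooled-screen simulation parameters.

    Defaults replicate the published library design: 344 target genes with
    five shRNAs each, 30 killing-control shRNAs grouped into 3 pseudo-genes
    of 10 barcodes, 45 NTCs, three cell lines in triplicate, and 10
    population doublings between the input and final harvests.
    """

    n_target_genes: int = 344
    shrnas_per_gene: int = 5
    n_killing: int = 30
    barcodes_per_killing_gene: int = 10
    n_ntc: int = 45
    cell_lines: tuple[str, ...] = ("lineA", "lineB", "lineC")
    replicates_per_line: int = 3
    sequencing_depth: int = 1_000_000
    generations: int = 10
    essential_fraction: float = 0.1
    fitness_effect: float = -0.6
    effective_per_gene: int = 4
    killing_effect: float = -0.95
    n_preferential: int = 0
    delta: float = -1.0
    abundance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_target_genes < 0 or self.n_killing < 0 or self.n_ntc < 0:
            raise ConfigError("counts must be >= 0")
        if self.n_target_genes + self.n_killing + self.n_ntc == 0:
            raise ConfigError("library would be empty")
        if self.n_target_genes > 0 and self.shrnas_per_gene <= 0:
            raise ConfigError("shrnas_per_gene must be > 0")
        if self.n_killing > 0 and self.barcodes_per_killing_gene <= 0:
            raise ConfigError("barcodes_per_killing_gene must be > 0")
        if self.generations < 1:
            raise ConfigError("generations must be >= 1")
        if not -1.0 <= self.fitness_effect <= 0.0:
            raise ConfigError("fitness_effect must be in [-1, 0]")
        if not -1.0 <= self.killing_effect <= -0.8:
            raise ConfigError("killing_effect must be in [-1, -0.8]")
        if self.replicates_per_line < 1 or self.sequencing_depth <= 0:
            raise ConfigError("need >= 1 replicate and positive depth")
        if not 0.0 <= self.essential_fraction <= 1.0:
            raise ConfigError("essential_fraction must be in [0, 1]")
        if self.effective_per_gene < 1:
            raise ConfigError("effective_per_gene must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_lines"] = list(self.cell_lines)
        return d


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, tag)))


def _barcodes(n: int, length: int = 20) -> list[str]:
    """n distinct barcodes: index written in base 4 over a fixed width.

    Uniqueness holds by construction (distinct integers, fixed width).
    """
    if n > 4**length:
        raise ConfigError("barcode space exhausted")
    out = []
    for i in range(n):
        digits = []
        x = i
        for _ in range(length):
            digits.append(x % 4)
            x //= 4
        out.append("".join(_BASES[d] for d in reversed(digits)))
    return out


def generate_library(config: SimConfig) -> ScreenLibrary:
    """Screen library: targets, killing pseudo-genes and NTC records."""
    rows = []
    for g in range(config.n_target_genes):
        gene = f"gene{g + 1:04d}"
        for s in range(config.shrnas_per_gene):
            rows.append((f"{gene}_sh{s + 1}", gene, "target"))
    for i in range(config.n_killing):
        gene = f"{KILLING_GENE_PREFIX}{i // config.barcodes_per_killing_gene + 1}"
        rows.append((f"{gene}_bc{i % config.barcodes_per_killing_gene + 1}", gene, "killing"))
    for i in range(config.n_ntc):
        rows.append((f"ntc_{i + 1:03d}", NTC_GENE, "ntc"))
    df = pd.DataFrame(rows, columns=["shrna_id", "gene", "role"])
    df.insert(1, "barcode", _barcodes(len(df)))
    return ScreenLibrary(df)


@dataclass(frozen=True)
class ScreenTruth:
    """Planted per-shRNA fitness effects and gene-level labels.

    ``fitness``: DataFrame indexed by shrna_id with one column per cell
    line, values in [-1, 0]. ``genes``: gene, essential_<line> flags,
    preferential_line ('' when none).
    """

    fitness: pd.DataFrame
    genes: pd.DataFrame
    effect_threshold: float = -0.2

    def __post_init__(self) -> None:
        if ((self.fitness < -1) | (self.fitness > 0)).any().any():
            raise ConfigError("fitness effects must be in [-1, 0]")
        for line in self.fitness.columns:
            col = f"essential_{line}"
            if col not in self.genes.columns:
                continue
            for gene in self.genes.loc[self.genes[col], "gene"]:
                mask = self.fitness.index.str.startswith(f"{gene}_")
                n_eff = int((self.fitness.loc[mask, line] <= self.effect_threshold).sum())
                if n_eff < 3:
                    raise ConfigError(
                        f"gene {gene} flagged essential in {line} but only "
                        f"{n_eff} shRNAs carry an effect"
                    )

    def essential_genes(self, line: str) -> set[str]:
        return set(self.genes.loc[self.genes[f"essential_{line}"], "gene"])

    def preferential_genes(self, line: str) -> set[str]:
        labels = self.genes["preferential_line"].fillna("").str.split(";")
        return set(self.genes.loc[labels.apply(lambda ls: line in ls), "gene"])


def generate_truth(library: ScreenLibrary, config: SimConfig) -> ScreenTruth:
    """Plant fitness effects consistent with the config.

    A fraction of target genes is essential in every line with
    ``fitness_effect`` on ``effective_per_gene`` of their shRNAs; the first
    ``n_preferential`` essential genes get an extra ``delta`` in every
    non-reference line (reference = first cell line). Killing shRNAs carry
    ``killing_effect`` everywhere; NTCs are neutral.
    """
    rng = _rng(config.seed, 1)
    lines = list(config.cell_lines)
    roles = library.roles()
    genes = library.genes()
    fitness = pd.DataFrame(0.0, index=library.shrna_ids, columns=lines)
    fitness.index.name = "shrna_id"
    fitness.loc[roles == "killing", :] = config.killing_effect

    target_mask = roles == "target"
    ids_by_gene = {
        gene: list(sub.index) for gene, sub in genes[target_mask].groupby(genes[target_mask])
    }
    target_genes = sorted(ids_by_gene)
    n_ess = int(round(config.essential_fraction * len(target_genes)))
    ess = sorted(rng.choice(target_genes, size=n_ess, replace=False)) if n_ess else []
    n_pref = min(config.n_preferential, len(ess))
    pref = ess[:n_pref]

    gene_rows = []
    for gene in target_genes:
        ids = ids_by_gene[gene]
        is_ess = gene in ess
        if is_ess:
            n_eff = min(config.effective_per_gene, len(ids))
            eff_ids = sorted(rng.choice(ids, size=n_eff, replace=False))
            fitness.loc[eff_ids, :] = config.fitness_effect
            if gene in pref:
                for line in lines[1:]:
                    fitness.loc[eff_ids, line] = np.clip(
                        config.fitness_effect + config.delta, -1.0, 0.0
                    )
        row = {"gene": gene, "preferential_line": ""}
        for line in lines:
            row[f"essential_{line}"] = is_ess
        if gene in pref and len(lines) > 1:
            row["preferential_line"] = ";".join(lines[1:])
        gene_rows.append(row)
    return ScreenTruth(fitness=fitness, genes=pd.DataFrame(gene_rows))


def simulate_screen_counts(
    library: ScreenLibrary, truth: ScreenTruth, config: SimConfig
) -> tuple[CountMatrix, SampleMeta]:
    """Multinomial barcode counts after exponential clone growth.

    Per (cell line, replicate): initial clone abundances are log-normal
    with ``abundance_sigma``; the input sample is a multinomial draw of
    ``sequencing_depth`` reads from those abundances, and the final sample
    draws from abundances scaled by 2^(G * (1 + f)) per shRNA. The expected
    final/input abundance ratio relative to a neutral shRNA is 2^(G * f).
    """
    if config.sequencing_depth <= 0:
        raise ConfigError("sequencing depth must be > 0")
    missing = library.shrna_ids.difference(truth.fitness.index)
    if len(missing):
        raise ConfigError(f"truth missing shRNAs: {sorted(missing)[:10]}")
    for line in config.cell_lines:
        if line not in truth.fitness.columns:
            raise ConfigError(f"truth missing cell line {line!r}")
    rng = _rng(config.seed, 2)
    ids = library.shrna_ids
    n = len(ids)
    meta_rows = []
    data: dict[str, np.ndarray] = {}
    for line in config.cell_lines:
        f = truth.fitness.loc[ids, line].to_numpy()
        growth = 2.0 ** (config.generations * (1.0 + f))
        for rep in range(1, config.replicates_per_line + 1):
            abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
            p_input = abundance / abundance.sum()
            final_abundance = abundance * growth
            p_final = final_abundance / final_abundance.sum()
            sid_in = f"{line}__input__r{rep}"
            sid_fin = f"{line}__final__r{rep}"
            data[sid_in] = rng.multinomial(config.sequencing_depth, p_input)
            data[sid_fin] = rng.multinomial(config.sequencing_depth, p_final)
            meta_rows.append((sid_in, line, "input", rep))
            meta_rows.append((sid_fin, line, "final", rep))
    meta = SampleMeta(
        pd.DataFrame(meta_rows, columns=["sample_id", "cell_line", "timepoint", "replicate"])
    )
    values = pd.DataFrame(data, index=ids)
    values.index.name = "shrna_id"
    return CountMatrix(values, meta), meta


# ---------------------------------------------------------------------------
# Single-cell expression fixture


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_genes: int = 500
    clusters: tuple[str, ...] = ("C1", "C2", "C3")
    genotypes: tuple[str, ...] = ("WT", "URE")
    cells_per_group: int = 50
    signature_sizes: dict = field(default_factory=lambda: {"sig3": 50})
    # (signature, genotype) -> log2 shift applied to that signature's genes
    effects: dict = field(default_factory=dict)
    base_mean: float = 1.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.cells_per_group <= 0:
            raise ConfigError("n_genes and cells_per_group must be > 0")
        if sum(self.signature_sizes.values()) > self.n_genes:
            raise ConfigError("signatures exceed the gene universe")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigError("dropout_rate must be in [0, 1]")


def generate_expression_fixture(
    config: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Counts matrix (cells x genes), cell annotation, signature sets.

    Counts are Poisson around per-gene log-normal baselines, with 2^shift
    multipliers planted on signature genes per genotype; cluster k's cells
    get pseudotime uniform in [k, k+1); Bernoulli dropout zeroes entries.
    """
    rng = _rng(config.seed, 3)
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    signatures: dict[str, list[str]] = {}
    cursor = 0
    for name, size in config.signature_sizes.items():
        signatures[name] = genes[cursor : cursor + size]
        cursor += size

    base = config.base_mean * rng.lognormal(mean=0.0, sigma=0.5, size=config.n_genes)
    rows, ann_rows = [], []
    cell_idx = 0
    for ci, cluster in enumerate(config.clusters):
        for genotype in config.genotypes:
            mult = np.ones(config.n_genes)
            for (sig, geno), shift in config.effects.items():
                if geno == genotype and sig in signatures:
                    gidx = [genes.index(g) for g in signatures[sig]]
                    mult[gidx] *= 2.0**shift
            lam = base * mult
            for _ in range(config.cells_per_group):
                counts = rng.poisson(lam)
                if config.dropout_rate > 0:
                    counts = counts * (rng.random(config.n_genes) >= config.dropout_rate)
                rows.append(counts)
                ann_rows.append(
                    (
                        f"cell{cell_idx + 1:05d}",
                        cluster,
                        genotype,
                        ci + rng.random(),
                    )
                )
                cell_idx += 1
    ann = pd.DataFrame(ann_rows, columns=["cell_id", "cluster", "genotype", "pseudotime"])
    expr = pd.DataFrame(
        np.vstack(rows), index=pd.Index(ann["cell_id"], name="cell_id"), columns=genes
    )
    return expr, ann.set_index("cell_id"), signatures


# ---------------------------------------------------------------------------
# Genomic fixture


@dataclass(frozen=True)
class GenomicSimConfig:
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 60_000_000, "chr2": 60_000_000})
    signatures: tuple[str, ...] = ("sig1", "sig2", "sig3", "sig4")
    genes_per_signature: int = 25
    peaks_per_gene: int = 2
    n_background_peaks: int = 400
    peak_width: int = 400
    cobind_fraction: float = 0.5
    half_width: int = 50_000
    shifted_signature: str | None = "sig3"
    shift: float = 1.0
    shifted_fraction: float = 1.0
    stat_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cobind_fraction <= 1.0:
            raise ConfigError("cobind_fraction must be in [0, 1]")
        if not 0.0 <= self.shifted_fraction <= 1.0:
            raise ConfigError("shifted_fraction must be in [0, 1]")
        if self.peak_width <= 0 or self.half_width < 0:
            raise ConfigError("peak_width must be > 0 and half_width >= 0")
        spacing = 2 * self.half_width + 100_000
        n_genes = len(self.signatures) * self.genes_per_signature
        capacity = sum(max(0, l - spacing) // spacing for l in self.chrom_lengths.values())
        if n_genes > capacity:
            raise ConfigError("chromosomes too short for the requested TSS layout")


@dataclass(frozen=True)
class GenomicTruth:
    """Bookkeeping of the planted fixture for recovery tests."""

    cobound_ids: set
    window_members: dict  # signature -> set of in-window tf region_ids
    shifted_ids: set


def generate_genomic_fixture(
    config: GenomicSimConfig,
) -> tuple[PeakSet, PeakSet, pd.DataFrame, pd.Series, GenomicTruth]:
    """TF peaks, partner peaks, TSS table, per-region stats and truth.

    Gene TSSs are laid out so their windows never overlap; each gene gets
    ``peaks_per_gene`` TF peaks inside its window plus shared background
    peaks outside all windows. A ``cobind_fraction`` of TF peaks receives a
    coinciding partner peak. Per-region statistics are N(0, stat_sd), with
    ``shift`` added to the non-cobound in-window peaks of the shifted
    signature.
    """
    rng = _rng(config.seed, 4)
    spacing = 2 * config.half_width + 100_000
    chroms = list(config.chrom_lengths)
    # TSS layout: round-robin across chromosomes at fixed spacing
    tss_rows = []
    slot = {c: spacing for c in chroms}
    gi = 0
    for sig in config.signatures:
        for _ in range(config.genes_per_signature):
            placed = False
            for c in chroms:
                if slot[c] + spacing < config.chrom_lengths[c]:
                    tss_rows.append(
                        (f"sgene{gi + 1:04d}", c, slot[c] + 1, "+", sig)  # 1-based tss
                    )
                    slot[c] += spacing
                    placed = True
                    break
            if not placed:
                raise ConfigError("ran out of chromosome space for TSSs")
            gi += 1
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "tss", "strand", "signature"])
    tss["tss0"] = tss["tss"] - 1

    # TF peaks inside windows, offset grid keeps peaks disjoint within a window
    peak_rows = []
    window_members: dict[str, set] = {s: set() for s in config.signatures}
    pid = 0
    for _, g in tss.iterrows():
        for k in range(config.peaks_per_gene):
            offset = int((k + 1) * config.half_width / (config.peaks_per_gene + 1))
            start = g["tss0"] - config.half_width + 2 * offset
            rid = f"tf_{pid + 1:05d}"
            peak_rows.append((g["chrom"], start, start + config.peak_width, rid))
            window_members[g["signature"]].add(rid)
            pid += 1
    # background peaks between windows, well clear of any TSS window
    bg_per_chrom = -(-config.n_background_peaks // len(chroms))
    placed_bg = 0
    for c in chroms:
        hi = config.chrom_lengths[c]
        pos = spacing // 2
        while placed_bg < config.n_background_peaks and pos + config.peak_width < hi:
            in_window = (
                (tss["chrom"] == c)
                & (tss["tss0"] - config.half_width <= pos + config.peak_width)
                & (tss["tss0"] + config.half_width >= pos)
            ).any()
            if not in_window:
                rid = f"tf_{pid + 1:05d}"
                peak_rows.append((c, pos, pos + config.peak_width, rid))
                pid += 1
                placed_bg += 1
                if placed_bg % bg_per_chrom == 0:
                    break
            pos += spacing
    tf_df = (
        pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "region_id"])
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    tf = PeakSet(tf_df, chrom_lengths=config.chrom_lengths)

    # partner peaks coincide with a random subset of tf peaks
    n_cobound = int(round(config.cobind_fraction * len(tf)))
    cobound_idx = np.sort(rng.choice(len(tf), size=n_cobound, replace=False))
    cobound_ids = set(tf.intervals.iloc[cobound_idx]["region_id"])
    partner_df = tf.intervals.iloc[cobound_idx][["chrom", "start", "end"]].copy()
    partner_df["region_id"] = [f"partner_{i + 1:05d}" for i in range(len(partner_df))]
    if partner_df.empty:
        # keep a valid, non-empty partner set far from every window
        partner_df = pd.DataFrame(
            [{"chrom": chroms[0], "start": 10, "end": 10 + config.peak_width, "region_id": "partner_00001"}]
        )
    partner = PeakSet(partner_df.reset_index(drop=True), chrom_lengths=config.chrom_lengths)

    stats = pd.Series(
        rng.normal(0.0, config.stat_sd, size=len(tf)), index=tf.region_ids, name="stat"
    )
    shifted_ids: set = set()
    if config.shifted_signature is not None and config.shift != 0.0:
        candidates = sorted(window_members.get(config.shifted_signature, set()) - cobound_ids)
        n_shift = int(round(config.shifted_fraction * len(candidates)))
        shifted_ids = set(
            rng.choice(candidates, size=n_shift, replace=False) if n_shift else []
        )
        stats.loc[sorted(shifted_ids)] += config.shift
    truth = GenomicTruth(
        cobound_ids=cobound_ids, window_members=window_members, shifted_ids=shifted_ids
    )
    return tf, partner, tss.drop(columns="tss0"), stats, truth
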