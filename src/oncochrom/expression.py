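"""Expression integration: differential-expression filtering, expression
quintiles, metagene occupancy profiles, per-gene H3K27me3 changes, change
anti-correlation and gene-set overlap.

Gene tables are pandas DataFrames with columns
(gene_id, chrom, start, end, strand, wt_expression, mut_expression,
log2_fc, fdr[, de_status, quintile, germline_specific]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .track_io import BinnedTrack, _require_same_grid

QUINTILES = ("I", "II", "III", "IV", "V")
DE_UP = "up"
DE_DOWN = "down"
DE_NS = "ns"

GENE_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand",
    "wt_expression", "mut_expression", "log2_fc", "fdr",
]


def de_filter(table: pd.DataFrame, fc_threshold: float = 2.0, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Label genes up/down/ns using strict thresholds: fold change > 2 (or
    < 1/2 for downregulation) and FDR < 0.05. Boundary genes are ns."""
    for col in ("log2_fc", "fdr"):
        if col not in table.columns:
            raise ValidationError(f"gene table missing column {col!r}")
    lfc_cut = np.log2(fc_threshold)
    out = table.copy()
    sig = out["fdr"] < fdr_threshold
    out["de_status"] = DE_NS
    out.loc[sig & (out["log2_fc"] > lfc_cut), "de_status"] = DE_UP
    out.loc[sig & (out["log2_fc"] < -lfc_cut), "de_status"] = DE_DOWN
    return out


def assign_quintiles(table: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by wild-type expression (ascending, ties broken by gene id)
    and split into five groups; remainders go to the lowest quintiles.
    Quintile I is the lowest-expressed fifth."""
    if "wt_expression" not in table.columns:
        raise ValidationError("gene table missing column 'wt_expression'")
    if len(table) == 0:
        raise ValidationError("cannot assign quintiles to an empty gene table")
    out = table.copy()
    order = out.sort_values(["wt_expression", "gene_id"], kind="mergesort").index
    n = len(out)
    base, rem = divmod(n, 5)
    sizes = [base + (1 if i < rem else 0) for i in range(5)]
    labels = np.empty(n, dtype=object)
    pos = 0
    for q, size in zip(QUINTILES, sizes):
        labels[pos : pos + size] = q
        pos += size
    out.loc[order, "quintile"] = labels
    return out


@dataclass(frozen=True)
class MetageneProfile:
    """Mean occupancy along a common gene-relative axis: optional native-bin
    flanks around a gene body rescaled to a fixed number of slots."""

    positions: tuple[str, ...]  # labels: u<i>, b<j>, d<i>
    means: np.ndarray
    group: str
    n_genes: int
    body_slots: int
    flank_bins: int


def _lookup(track: BinnedTrack, chrom: str, pos: float) -> float:
    """Track value at a base position, clipped into the chromosome."""
    n = track.values[chrom].size
    b = int(min(max(pos, 0), track.assembly.length(chrom) - 1) // track.bin_size)
    return float(track.values[chrom][min(b, n - 1)])


def gene_body_profile(track: BinnedTrack, chrom: str, start: int, end: int,
                      body_slots: int, flank_bp: int) -> np.ndarray:
    """Single-gene profile: flank bins at native resolution, then the body
    rescaled to body_slots by sampling the bin under each slot's center."""
    n_flank = flank_bp // track.bin_size
    up = [
        _lookup(track, chrom, start - flank_bp + (i + 0.5) * track.bin_size)
        for i in range(n_flank)
    ]
    body = [
        _lookup(track, chrom, start + (j + 0.5) * (end - start) / body_slots)
        for j in range(body_slots)
    ]
    down = [
        _lookup(track, chrom, end + (i + 0.5) * track.bin_size)
        for i in range(n_flank)
    ]
    return np.array(up + body + down)


def metagene(
    track: BinnedTrack,
    genes: pd.DataFrame,
    group: str = "all",
    body_slots: int = 100,
    flank_bp: int = 500,
) -> MetageneProfile:
    """Average occupancy profile over a gene group.

    Strand is ignored: the marks analyzed are not strand-resolved.
    """
    if len(genes) == 0:
        raise ValidationError(f"metagene group {group!r} is empty")
    n_flank = flank_bp // track.bin_size
    profiles = np.zeros((len(genes), 2 * n_flank + body_slots))
    for i, row in enumerate(genes.itertuples(index=False)):
        if row.chrom not in track.assembly:
            raise ValidationError(f"gene {row.gene_id} on unknown chromosome {row.chrom!r}")
        if not (0 <= row.start < row.end <= track.assembly.length(row.chrom)):
            raise ValidationError(f"gene {row.gene_id} outside the assembly")
        profiles[i] = gene_body_profile(
            track, row.chrom, row.start, row.end, body_slots, flank_bp
        )
    positions = (
        tuple(f"u{i}" for i in range(n_flank))
        + tuple(f"b{j}" for j in range(body_slots))
        + tuple(f"d{i}" for i in range(n_flank))
    )
    return MetageneProfile(
        positions, profiles.mean(axis=0), group, len(genes), body_slots, n_flank
    )


def quintile_metagenes(track: BinnedTrack, table: pd.DataFrame, **kw) -> dict[str, MetageneProfile]:
    if "quintile" not in table.columns:
        raise ValidationError("assign_quintiles first")
    return {
        q: metagene(track, table[table["quintile"] == q], group=q, **kw)
        for q in QUINTILES
    }


def gene_body_bins(track: BinnedTrack, start: int, end: int) -> slice:
    """Bins overlapping [start, end); a gene shorter than one bin yields its
    single overlapping bin."""
    b0 = start // track.bin_size
    b1 = max(-(-end // track.bin_size), b0 + 1)
    return slice(b0, b1)


def delta_k27me3(wt: BinnedTrack, mut: BinnedTrack, genes: pd.DataFrame) -> pd.Series:
    """Per-gene mean(mut) - mean(wt) over gene-body bins."""
    _require_same_grid(wt, mut)
    deltas = {}
    for row in genes.itertuples(index=False):
        sl = gene_body_bins(wt, row.start, row.end)
        deltas[row.gene_id] = float(
            mut.values[row.chrom][sl].mean() - wt.values[row.chrom][sl].mean()
        )
    return pd.Series(deltas, name="delta_k27me3")


@dataclass(frozen=True)
class CorrelationReport:
    spearman: float
    pearson: float
    p_spearman: float  # permutation p, two-sided
    n: int
    n_permutations: int
    defined: bool = True


def correlate_changes(
    delta_expr,
    delta_k27,
    n_permutations: int = 999,
    seed: int = 0,
) -> CorrelationReport:
    """Spearman (primary) and Pearson correlation between expression and
    H3K27me3 changes, with a seeded permutation p-value."""
    a = np.asarray(delta_expr, dtype=float)
    b = np.asarray(delta_k27, dtype=float)
    if a.size != b.size:
        raise ValidationError("vectors must be aligned")
    if a.size < 3:
        raise ValidationError("need at least 3 pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationReport(float("nan"), float("nan"), float("nan"),
                                 int(a.size), n_permutations, defined=False)
    rho = float(stats.spearmanr(a, b).statistic)
    r = float(stats.pearsonr(a, b).statistic)
    rng = np.random.default_rng(seed)
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(rb)
        rho_p = np.corrcoef(ra, perm)[0, 1]
        if abs(rho_p) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return CorrelationReport(rho, r, float(p), int(a.size), n_permutations)


@dataclass(frozen=True)
class QuintileFractions:
    fractions: pd.Series  # indexed I..V, sums to 1 over DE genes
    n_de: int

    @property
    def empty(self) -> bool:
        return self.n_de == 0


def quintile_fractions(table: pd.DataFrame) -> QuintileFractions:
    """Fraction of differentially expressed genes falling in each quintile."""
    for col in ("de_status", "quintile"):
        if col not in table.columns:
            raise ValidationError(f"gene table missing column {col!r}")
    de = table[table["de_status"].isin([DE_UP, DE_DOWN])]
    counts = pd.Series(
        {q: int((de["quintile"] == q).sum()) for q in QUINTILES}, name="n_de"
    )
    n = int(counts.sum())
    if n == 0:
        return QuintileFractions(pd.Series(np.nan, index=list(QUINTILES)), 0)
    return QuintileFractions(counts / n, n)


@dataclass(frozen=True)
class OverlapCounts:
    only_a: int
    intersection: int
    only_b: int


def gene_set_overlap(de_genes, reference_set) -> OverlapCounts:
    """Three disjoint counts of a two-set Venn; duplicate ids are collapsed
    with a warning."""
    a_list, b_list = list(de_genes), list(reference_set)
    a, b = set(a_list), set(b_list)
    if len(a) != len(a_list) or len(b) != len(b_list):
        warnings.warn("duplicate gene ids collapsed in overlap computation", stacklevel=2)
    return OverlapCounts(len(a - b), len(a & b), len(b - a))
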