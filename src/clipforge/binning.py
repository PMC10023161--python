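"""Fixed-width genomic bins, stranded fragment counting and gene-level CPM.

The genome is tiled into 200-bp non-overlapping bins (a shorter terminal
bin per chromosome).  A fragment increments every bin it overlaps, after
exclusion of fragments touching rRNA/tRNA genes (strand-aware) or lying on
a mitochondrial contig; per-sample totals count retained fragments, and
FPM = count * 1e6 / total.  Gene-level counting is union-mode and
strand-agnostic: a fragment overlapping exactly one gene span counts for
that gene, ambiguous fragments count for none; CPM normalises by the total
of gene-assigned fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import Annotation, BLACKLIST_BIOTYPES

logger = logging.getLogger(__name__)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BinningError(ValueError):
    pass


@dataclass
class BinGrid:
    """Tiling of a genome into fixed-width bins.

    Bins are ordered by chromosome (insertion order of ``chrom_sizes``)
    then position; ``offset[chrom]`` is the global index of that
    chromosome's first bin.
    """

    chrom_sizes: dict[str, int]
    width: int = 200

    def __post_init__(self) -> None:
        if self.width < 1:
            raise BinningError("bin width must be >= 1")
        for c, L in self.chrom_sizes.items():
            if L < 1:
                raise BinningError(f"chromosome {c} has non-positive length")
        self.offset: dict[str, int] = {}
        n = 0
        for c, L in self.chrom_sizes.items():
            self.offset[c] = n
            n += -(-L // self.width)
        self.n_bins = n

    def n_bins_of(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.width)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c, L in self.chrom_sizes.items():
            starts = np.arange(0, L, self.width)
            ends = np.minimum(starts + self.width, L)
            rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": ends}))
        df = pd.concat(rows, ignore_index=True)
        df["index"] = np.arange(len(df))
        return df

    def bin_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global index range [lo, hi) of bins overlapping [start, end)."""
        off = self.offset[chrom]
        lo = off + max(start, 0) // self.width
        hi = off + min((end - 1) // self.width, self.n_bins_of(chrom) - 1) + 1
        return lo, hi

    def bin_index(self, chrom: str, pos: int) -> int:
        return self.offset[chrom] + pos // self.width


def make_bins(chrom_sizes: dict[str, int], width: int = 200) -> BinGrid:
    """Tile each chromosome into ceil(L/width) bins; last bin ends at L."""
    return BinGrid(dict(chrom_sizes), width)


@dataclass
class BinCountMatrix:
    """Per-bin fragment counts for a set of samples with per-sample totals."""

    grid: BinGrid
    samples: list[str] = field(default_factory=list)
    counts: np.ndarray | None = None  # n_bins x n_samples, int
    totals: dict[str, int] = field(default_factory=dict)
    excluded: dict[str, int] = field(default_factory=dict)
    unknown_chrom: dict[str, int] = field(default_factory=dict)

    def add_sample(
        self, name: str, column: np.ndarray, total: int,
        excluded: int = 0, unknown: int = 0,
    ) -> None:
        column = np.asarray(column, dtype=np.int64).reshape(-1, 1)
        if column.shape[0] != self.grid.n_bins:
            raise BinningError("column length does not match the bin grid")
        self.counts = (
            column if self.counts is None else np.hstack([self.counts, column])
        )
        self.samples.append(name)
        self.totals[name] = int(total)
        self.excluded[name] = int(excluded)
        self.unknown_chrom[name] = int(unknown)

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.samples.index(sample)]

    def fpm(self, sample: str) -> np.ndarray:
        """Fragments per million mapped fragments (per-sample total)."""
        total = self.totals[sample]
        if total == 0:
            return np.zeros(self.grid.n_bins)
        return self.column(sample) * 1e6 / total

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame().drop(columns="index")
        for s in self.samples:
            df[s] = self.column(s)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_bedgraph(self, sample: str, path: str | Path) -> None:
        df = self.grid.to_frame().drop(columns="index")
        df["fpm"] = self.fpm(sample)
        df[df["fpm"] > 0].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BED6_COLUMNS,
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "name": str, "score": str, "strand": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise BinningError(f"malformed BED file {path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=BED6_COLUMNS)
    bad = df["strand"].isin(["+", "-"])
    if not bad.all():
        line = int(np.flatnonzero(~bad.values)[0]) + 1
        raise BinningError(f"malformed BED line {line} in {path}: bad strand")
    return df


def _blacklist_mask(
    fragments: pd.DataFrame, annotation: Annotation, biotypes: frozenset[str]
) -> np.ndarray:
    """True for fragments overlapping a blacklist gene (strand-aware) or on
    a mitochondrial contig."""
    mask = fragments["chrom"].isin(annotation.mito_chroms).to_numpy()
    bl = annotation.blacklist_intervals(biotypes)
    for (chrom, strand), ivs in bl.items():
        sel = (
            (fragments["chrom"] == chrom) & (fragments["strand"] == strand)
        ).to_numpy()
        if not sel.any():
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        fs = fragments.loc[sel, "start"].to_numpy()
        fe = fragments.loc[sel, "end"].to_numpy()
        # intervals are merged/disjoint: a fragment overlaps one iff the
        # last interval starting before its end extends past its start
        idx = np.searchsorted(starts, fe, side="left") - 1
        hit = (idx >= 0) & (ends[np.maximum(idx, 0)] > fs)
        m = mask[sel]
        m |= hit
        mask[sel] = m
    return mask


def count_fragments_in_bins(
    fragments: pd.DataFrame,
    grid: BinGrid,
    annotation: Annotation,
    blacklist_biotypes: frozenset[str] = BLACKLIST_BIOTYPES,
) -> tuple[np.ndarray, int, int, int]:
    """Count fragments per bin for one sample.

    Returns ``(column, total_retained, n_excluded, n_unknown_chrom)``.  A
    retained fragment increments every bin it overlaps; the sample total is
    the number of retained fragments, not bin increments.
    """
    col = np.zeros(grid.n_bins, dtype=np.int64)
    if fragments.empty:
        return col, 0, 0, 0
    known = fragments["chrom"].isin(grid.chrom_sizes).to_numpy()
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("%d fragments on unknown chromosomes skipped", n_unknown)
    frags = fragments.loc[known]
    excl = _blacklist_mask(frags, annotation, blacklist_biotypes)
    n_excluded = int(excl.sum())
    frags = frags.loc[~excl]
    w = grid.width
    for chrom, sub in frags.groupby("chrom", sort=False):
        off = grid.offset[chrom]
        nbins = grid.n_bins_of(chrom)
        b0 = np.maximum(sub["start"].to_numpy(np.int64) // w, 0)
        b1 = np.minimum((sub["end"].to_numpy(np.int64) - 1) // w, nbins - 1)
        k = 0
        while True:
            live = b0 + k <= b1
            if not live.any():
                break
            np.add.at(col, off + b0[live] + k, 1)
            k += 1
    return col, int(len(frags)), n_excluded, n_unknown


def build_count_matrix(
    fragments_by_sample: dict[str, pd.DataFrame],
    grid: BinGrid,
    annotation: Annotation,
    blacklist_biotypes: frozenset[str] = BLACKLIST_BIOTYPES,
) -> BinCountMatrix:
    mat = BinCountMatrix(grid)
    for name, frags in fragments_by_sample.items():
        col, total, excl, unk = count_fragments_in_bins(
            frags, grid, annotation, blacklist_biotypes
        )
        mat.add_sample(name, col, total, excl, unk)
    return mat


# ---------------------------------------------------------------------------
# gene-level CPM (union counting, strand-agnostic)
# ---------------------------------------------------------------------------

def gene_level_cpm(
    fragments_by_sample: dict[str, pd.DataFrame], annotation: Annotation
) -> pd.DataFrame:
    """Union-mode, strand-agnostic gene counting and CPM per sample.

    A fragment overlapping exactly one gene's span counts for that gene;
    fragments overlapping two or more genes are ambiguous and counted for
    none.  CPM normalises each sample by its total of gene-assigned
    fragments, so assigned CPM sums to 1e6.
    """
    spans: dict[str, IntervalTree] = {}
    for gid in annotation.gene_ids():
        chrom, s, e, _ = annotation.gene_span(gid)
        spans.setdefault(chrom, IntervalTree()).addi(s, e, gid)
    genes = annotation.gene_ids()
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for sample, frags in fragments_by_sample.items():
        counts = dict.fromkeys(genes, 0)
        for chrom, sub in frags.groupby("chrom", sort=False):
            tree = spans.get(chrom)
            if tree is None:
                continue
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                hits = tree.overlap(s, e)
                if len(hits) == 1:
                    counts[next(iter(hits)).data] += 1
        vec = np.array([counts[g] for g in genes], dtype=float)
        total = vec.sum()
        out[f"{sample}_count"] = vec.astype(int)
        out[f"{sample}_cpm"] = vec * 1e6 / total if total > 0 else 0.0
    return out.reset_index()
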