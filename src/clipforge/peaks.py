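"""From bin counts to enriched regions.

The cascade mirrors a bin-based CLIP peak-calling protocol:

1. per IP sample, fit a ZTNB on non-zero bins and call significant bins at
   a BH-adjusted conditional upper-tail p < alpha;
2. drop IP significant bins whose FPM is below the upper quartile of the
   host gene's Input FPM distribution;
3. merge surviving bins of both IP replicates into candidate regions;
4. per candidate and per IP, test fold enrichment over Input with a
   Yates-corrected chi-square on the 2x2 fragment table, falling back to a
   two-sided Fisher exact test when any observed or expected cell is
   below 5; BH across candidates per IP;
5. select regions with log2 fold enrichment > 2 and FDR < 0.05 in both
   IPs (strict inequalities);
6. remove regions on transcripts that host IgG-enriched regions, and
   regions whose host gene has Input CPM > IP CPM in both IP samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import Annotation, assign_host, classify_region
from .binning import BinCountMatrix, BinGrid
from .ztnb import ZtnbFit, fit_ztnb, ztnb_upper_tail

logger = logging.getLogger(__name__)


class PeakCallingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise PeakCallingError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def peak_enrichment_test(
    peak_count_ip: int, total_ip: int, peak_count_input: int, total_input: int
) -> tuple[float, float, str]:
    """Fold enrichment of a region in IP over Input with its p-value.

    FE = (peak_ip/total_ip) / (max(peak_input, 1)/total_input); the
    pseudocount keeps FE finite when the Input count is zero while the test
    table keeps the true zero.  The p-value comes from the Yates-corrected
    chi-square on [[peak_ip, total_ip-peak_ip], [peak_input,
    total_input-peak_input]], or from the two-sided Fisher exact test when
    any observed or expected cell is below 5.

    Returns ``(log2FE, p, branch)`` with branch in {"chi2", "fisher"}.
    """
    if total_ip <= 0 or total_input <= 0:
        raise PeakCallingError("totals must be positive")
    if peak_count_ip > total_ip or peak_count_input > total_input:
        raise PeakCallingError("region count exceeds sample total")
    a, b = peak_count_ip, total_ip - peak_count_ip
    c, d = peak_count_input, total_input - peak_count_input
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    fe = (peak_count_ip / total_ip) / (max(peak_count_input, 1) / total_input)
    log2fe = math.log2(fe) if fe > 0 else -math.inf
    if table.min() < 5 or expected.min() < 5:
        p = float(stats.fisher_exact(table.astype(int), alternative="two-sided")[1])
        branch = "fisher"
    else:
        p = float(stats.chi2_contingency(table, correction=True)[1])
        branch = "chi2"
    return log2fe, p, branch


# ---------------------------------------------------------------------------
# bin-level significance
# ---------------------------------------------------------------------------

@dataclass
class SignificantBins:
    sample: str
    indices: np.ndarray  # global bin indices, significant only
    pvalues: np.ndarray  # aligned with indices
    padj: np.ndarray
    fit: ZtnbFit
    alpha: float


def call_significant_bins(
    matrix: BinCountMatrix, sample: str, alpha: float = 0.05
) -> SignificantBins:
    """ZTNB significance call on one sample's non-zero bins.

    Fits the ZTNB to the non-zero bin counts, assigns each non-zero bin its
    conditional upper-tail p, and declares significance at BH-adjusted
    p < alpha.  Zero-count bins are never significant.
    """
    col = matrix.column(sample)
    nz = np.flatnonzero(col > 0)
    if nz.size < 10:
        raise PeakCallingError(
            f"sample {sample}: only {nz.size} non-zero bins; need >= 10 to fit"
        )
    fit = fit_ztnb(col[nz])
    if not fit.converged:
        raise PeakCallingError(f"sample {sample}: ZTNB fit did not converge")
    p = ztnb_upper_tail(col[nz], fit)
    padj = bh_adjust(p)
    keep = padj < alpha
    return SignificantBins(
        sample=sample, indices=nz[keep], pvalues=p[keep], padj=padj[keep],
        fit=fit, alpha=alpha,
    )


def gene_upper_quartile_filter(
    sig: SignificantBins,
    matrix: BinCountMatrix,
    annotation: Annotation,
    input_sample: str = "Input",
    comparator: str = "ip",
) -> SignificantBins:
    """Per-gene Input upper-quartile filter on IP significant bins.

    For each gene, Q3 is the linear-interpolation upper quartile of the
    Input FPM over all bins overlapping the gene span.  A significant bin
    hosted by a gene is dropped when its own FPM (the IP sample's under the
    default ``comparator="ip"``, the Input's under ``"input"``) is strictly
    below Q3; kept at equality, and bins outside any gene are kept.
    """
    if comparator not in ("ip", "input"):
        raise PeakCallingError("comparator must be 'ip' or 'input'")
    grid = matrix.grid
    input_fpm = matrix.fpm(input_sample)
    own_fpm = matrix.fpm(sig.sample) if comparator == "ip" else input_fpm

    q3: dict[str, float] = {}
    gene_bins: dict[str, tuple[int, int]] = {}
    for gid in annotation.gene_ids():
        chrom, s, e, _ = annotation.gene_span(gid)
        if chrom not in grid.chrom_sizes:
            continue
        lo, hi = grid.bin_range(chrom, s, e)
        gene_bins[gid] = (lo, hi)
        q3[gid] = float(np.percentile(input_fpm[lo:hi], 75))

    drop = np.zeros(sig.indices.size, dtype=bool)
    for gid, (lo, hi) in gene_bins.items():
        inside = (sig.indices >= lo) & (sig.indices < hi)
        if inside.any():
            drop[inside] |= own_fpm[sig.indices[inside]] < q3[gid]
    keep = ~drop
    return SignificantBins(
        sample=sig.sample, indices=sig.indices[keep], pvalues=sig.pvalues[keep],
        padj=sig.padj[keep], fit=sig.fit, alpha=sig.alpha,
    )


def merge_significant_bins(
    sig_bins_by_sample: list[np.ndarray], grid: BinGrid, gap: int = 0
) -> list[tuple[str, int, int]]:
    """Merge the union of significant bins into maximal candidate regions.

    Bins from all listed samples are pooled; bins on the same chromosome
    closer than or adjoining within ``gap`` base pairs are joined.
    """
    pooled = np.unique(np.concatenate([np.asarray(x) for x in sig_bins_by_sample]))
    if pooled.size == 0:
        return []
    frame = grid.to_frame()
    rows = frame.iloc[pooled]
    out: list[tuple[str, int, int]] = []
    cur = None
    for chrom, s, e in zip(rows["chrom"], rows["start"], rows["end"]):
        if cur is not None and chrom == cur[0] and s <= cur[2] + gap:
            cur = (cur[0], cur[1], max(cur[2], int(e)))
        else:
            if cur is not None:
                out.append(cur)
            cur = (chrom, int(s), int(e))
    out.append(cur)
    return out


# ---------------------------------------------------------------------------
# region-level bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    summit: int
    counts: dict[str, int]
    log2fe_ip1: float
    log2fe_ip2: float
    p_ip1: float
    p_ip2: float
    fdr_ip1: float = math.nan
    fdr_ip2: float = math.nan
    host_gene: str | None = None
    host_transcript: str | None = None
    biotype_assigned: str | None = None
    region_class: str = "intergenic"
    passes_thresholds: bool = False
    igg_filtered: bool = False
    cpm_filtered: bool = False

    @property
    def selected(self) -> bool:
        return self.passes_thresholds and not self.igg_filtered and not self.cpm_filtered

    @property
    def mean_log2fe(self) -> float:
        return 0.5 * (self.log2fe_ip1 + self.log2fe_ip2)

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class RegionCounter:
    """Fragment counting and per-base coverage over arbitrary regions."""

    def __init__(self, fragments_by_sample: dict[str, pd.DataFrame]):
        self._data: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self.totals: dict[str, int] = {}
        for sample, df in fragments_by_sample.items():
            per_chrom = {}
            for chrom, sub in df.groupby("chrom", sort=False):
                per_chrom[chrom] = (
                    sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64)
                )
            self._data[sample] = per_chrom
            self.totals[sample] = len(df)

    def count(self, sample: str, chrom: str, start: int, end: int) -> int:
        arrs = self._data[sample].get(chrom)
        if arrs is None:
            return 0
        s, e = arrs
        return int(((s < end) & (e > start)).sum())

    def coverage(self, sample: str, chrom: str, start: int, end: int) -> np.ndarray:
        cov = np.zeros(end - start, dtype=np.int64)
        arrs = self._data[sample].get(chrom)
        if arrs is None:
            return cov
        s, e = arrs
        hit = (s < end) & (e > start)
        for fs, fe in zip(s[hit], e[hit]):
            cov[max(fs - start, 0) : max(min(fe, end) - start, 0)] += 1
        return cov

    def fpm_at(self, sample: str, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Per-base FPM of single positions (fragments covering each base)."""
        total = self.totals[sample] or 1
        arrs = self._data[sample].get(chrom)
        if arrs is None:
            return np.zeros(len(positions))
        s, e = arrs
        out = np.array([((s <= p) & (e > p)).sum() for p in positions], dtype=float)
        return out * 1e6 / total


def region_summit(
    counter: RegionCounter, chrom: str, start: int, end: int,
    ip_samples: tuple[str, str] = ("IP1", "IP2"),
) -> int:
    """Leftmost position of maximal combined IP FPM within the region."""
    cov = np.zeros(end - start, dtype=float)
    for s in ip_samples:
        total = counter.totals[s] or 1
        cov += counter.coverage(s, chrom, start, end) * 1e6 / total
    return start + int(np.argmax(cov))


# ---------------------------------------------------------------------------
# selection and filters
# ---------------------------------------------------------------------------

def select_enriched_regions(
    regions: list[EnrichedRegion],
    min_log2fe: float = 2.0,
    max_fdr: float = 0.05,
) -> list[EnrichedRegion]:
    """Flag regions passing log2FE > min and FDR < max in both IPs (strict)."""
    for r in regions:
        r.passes_thresholds = (
            r.log2fe_ip1 > min_log2fe
            and r.log2fe_ip2 > min_log2fe
            and r.fdr_ip1 < max_fdr
            and r.fdr_ip2 < max_fdr
        )
    return [r for r in regions if r.passes_thresholds]


def igg_transcript_filter(
    regions: list[EnrichedRegion],
    igg_regions: list[tuple[str, int, int]],
    annotation: Annotation,
) -> int:
    """Remove regions on transcripts hosting any IgG-enriched region.

    Transcript-level removal: every transcript overlapping an IgG-enriched
    region taints all selected regions that overlap it.  Returns the number
    of regions flagged.
    """
    tainted: set[str] = set()
    for chrom, s, e in igg_regions:
        for t in annotation.overlapping(chrom, s, e):
            tainted.add(t.transcript_id)
    n = 0
    for r in regions:
        if any(
            t.transcript_id in tainted
            for t in annotation.overlapping(r.chrom, r.start, r.end)
        ):
            r.igg_filtered = True
            n += 1
    return n


def input_cpm_filter(
    regions: list[EnrichedRegion],
    gene_cpm: pd.DataFrame,
    input_sample: str = "Input",
    ip_samples: tuple[str, str] = ("IP1", "IP2"),
) -> int:
    """Remove regions whose host gene has Input CPM > IP CPM in both IPs."""
    cpm = gene_cpm.set_index("gene_id")
    n = 0
    for r in regions:
        if r.host_gene is None:
            continue
        if r.host_gene not in cpm.index:
            logger.warning("gene %s missing from CPM table; region kept", r.host_gene)
            continue
        row = cpm.loc[r.host_gene]
        inp = row[f"{input_sample}_cpm"]
        if all(inp > row[f"{s}_cpm"] for s in ip_samples):
            r.cpm_filtered = True
            n += 1
    return n


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def enriched_regions_for_sample(
    matrix: BinCountMatrix,
    counter: RegionCounter,
    annotation: Annotation,
    ip_samples: list[str],
    input_sample: str = "Input",
    alpha: float = 0.05,
    min_log2fe: float = 2.0,
    max_fdr: float = 0.05,
    gap: int = 0,
    quartile_filter: bool = True,
    quartile_comparator: str = "ip",
) -> list[tuple[str, int, int]]:
    """Generic significance -> merge -> enrichment -> selection pass.

    Used for the IgG control with ``ip_samples=["IgG"]`` (selection then
    requires the thresholds in that single sample).  Returns the selected
    intervals only.
    """
    sigs = []
    for s in ip_samples:
        sig = call_significant_bins(matrix, s, alpha)
        if quartile_filter:
            sig = gene_upper_quartile_filter(
                sig, matrix, annotation, input_sample, quartile_comparator
            )
        sigs.append(sig)
    candidates = merge_significant_bins(
        [s.indices for s in sigs], matrix.grid, gap
    )
    if not candidates:
        return []
    stats_per_sample = {}
    for s in ip_samples:
        fe_p = [
            peak_enrichment_test(
                counter.count(s, *c), counter.totals[s],
                counter.count(input_sample, *c), counter.totals[input_sample],
            )[:2]
            for c in candidates
        ]
        fdr = bh_adjust([p for _, p in fe_p])
        stats_per_sample[s] = ([fe for fe, _ in fe_p], fdr)
    out = []
    for i, c in enumerate(candidates):
        if all(
            stats_per_sample[s][0][i] > min_log2fe
            and stats_per_sample[s][1][i] < max_fdr
            for s in ip_samples
        ):
            out.append(c)
    return out


def call_peaks(
    matrix: BinCountMatrix,
    fragments_by_sample: dict[str, pd.DataFrame],
    annotation: Annotation,
    gene_cpm: pd.DataFrame | None = None,
    ip_samples: tuple[str, str] = ("IP1", "IP2"),
    input_sample: str = "Input",
    igg_sample: str | None = "IgG",
    alpha: float = 0.05,
    min_log2fe: float = 2.0,
    max_fdr: float = 0.05,
    gap: int = 0,
    quartile_comparator: str = "ip",
) -> tuple[list[EnrichedRegion], dict[str, int]]:
    """Run the full peak-calling cascade.

    Returns all candidate regions (with threshold/filter flags set; use
    ``r.selected``) and an attrition table of record counts per stage.
    """
    attrition: dict[str, int] = {}
    counter = RegionCounter(fragments_by_sample)

    sigs = {}
    for s in ip_samples:
        sig = call_significant_bins(matrix, s, alpha)
        attrition[f"sig_bins_{s}"] = sig.indices.size
        sig = gene_upper_quartile_filter(
            sig, matrix, annotation, input_sample, quartile_comparator
        )
        attrition[f"sig_bins_{s}_after_quartile"] = sig.indices.size
        sigs[s] = sig

    candidates = merge_significant_bins(
        [sigs[s].indices for s in ip_samples], matrix.grid, gap
    )
    attrition["candidate_regions"] = len(candidates)

    regions: list[EnrichedRegion] = []
    per_ip: dict[str, list[tuple[float, float]]] = {s: [] for s in ip_samples}
    for c in candidates:
        for s in ip_samples:
            fe, p, _ = peak_enrichment_test(
                counter.count(s, *c), counter.totals[s],
                counter.count(input_sample, *c), counter.totals[input_sample],
            )
            per_ip[s].append((fe, p))
    fdr = {s: bh_adjust([p for _, p in per_ip[s]]) for s in ip_samples}

    ip1, ip2 = ip_samples
    for i, (chrom, start, end) in enumerate(candidates):
        counts = {
            s: counter.count(s, chrom, start, end)
            for s in {input_sample, *ip_samples, *( [igg_sample] if igg_sample else [] )}
        }
        host, bclass = assign_host((chrom, start, end), annotation)
        regions.append(
            EnrichedRegion(
                chrom=chrom, start=start, end=end,
                summit=region_summit(counter, chrom, start, end, ip_samples),
                counts=counts,
                log2fe_ip1=per_ip[ip1][i][0], log2fe_ip2=per_ip[ip2][i][0],
                p_ip1=per_ip[ip1][i][1], p_ip2=per_ip[ip2][i][1],
                fdr_ip1=float(fdr[ip1][i]), fdr_ip2=float(fdr[ip2][i]),
                host_gene=host.gene_id if host else None,
                host_transcript=host.transcript_id if host else None,
                biotype_assigned=bclass,
                region_class=classify_region((chrom, start, end), host),
            )
        )

    selected = select_enriched_regions(regions, min_log2fe, max_fdr)
    attrition["pass_thresholds"] = len(selected)

    if igg_sample is not None and igg_sample in matrix.samples:
        try:
            igg_regions = enriched_regions_for_sample(
                matrix, counter, annotation, [igg_sample], input_sample,
                alpha, min_log2fe, max_fdr, gap, quartile_filter=False,
            )
        except PeakCallingError as exc:
            logger.warning("IgG significance skipped: %s", exc)
            igg_regions = []
        attrition["igg_enriched_regions"] = len(igg_regions)
        attrition["igg_filtered"] = igg_transcript_filter(
            selected, igg_regions, annotation
        )

    if gene_cpm is not None:
        attrition["cpm_filtered"] = input_cpm_filter(
            selected, gene_cpm, input_sample, ip_samples
        )

    attrition["selected"] = sum(r.selected for r in regions)
    return regions, attrition


def regions_to_frame(regions: list[EnrichedRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {
            "chrom": r.chrom, "start": r.start, "end": r.end, "summit": r.summit,
            "log2fe_ip1": r.log2fe_ip1, "log2fe_ip2": r.log2fe_ip2,
            "p_ip1": r.p_ip1, "p_ip2": r.p_ip2,
            "fdr_ip1": r.fdr_ip1, "fdr_ip2": r.fdr_ip2,
            "host_gene": r.host_gene, "host_transcript": r.host_transcript,
            "biotype_assigned": r.biotype_assigned, "region_class": r.region_class,
            "passes_thresholds": r.passes_thresholds,
            "igg_filtered": r.igg_filtered, "cpm_filtered": r.cpm_filtered,
            "selected": r.selected,
        }
        for s, v in r.counts.items():
            row[f"count_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
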