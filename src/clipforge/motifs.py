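"""Motif scanning, over-representation and positional enrichment.

Sequences are handled as sense-strand RNA: reference windows are
reverse-complemented for minus-strand hosts and transcribed T->U.  The
default motif is the MATR3 consensus UUCUU; IUPAC ambiguity codes are
supported.  Over-representation compares the fraction of 100-nt
summit-centred peak windows containing a motif with length-matched control
windows drawn from expressed RNA precursors (two-sided Fisher, BH across
motifs).  Positional enrichment slides a 10-nt window (centred on each
offset from the summit) over peaks and controls, testing containment per
offset with a two-sided Fisher test under Bonferroni correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation
from .peaks import EnrichedRegion, RegionCounter, bh_adjust
from .simulate import revcomp

IUPAC_RNA = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}

DEFAULT_MOTIF = "UUCUU"
LOG2_OR_CAP = 8.0


class MotifError(ValueError):
    pass


def _get_ref(genome, chrom: str, start: int, end: int) -> str:
    """Reference substring from a dict-of-bytearray or pyfaidx-like object."""
    seq = genome[chrom][start:end]
    if isinstance(seq, (bytes, bytearray)):
        return seq.decode()
    return str(seq)


def rna_window(
    genome, chrom: str, strand: str, start: int, end: int
) -> str:
    """Sense-strand RNA sequence of a reference interval."""
    seq = _get_ref(genome, chrom, start, end).upper()
    if strand == "-":
        seq = revcomp(seq)
    return seq.replace("T", "U")


def scan_motif(sequence: str, motif: str = DEFAULT_MOTIF) -> list[int]:
    """All (overlapping) match offsets of an IUPAC RNA motif, 0-based."""
    motif = motif.upper().replace("T", "U")
    if len(motif) < 3:
        raise MotifError("motifs must be at least 3 nt long")
    try:
        pattern = "".join(IUPAC_RNA[c] for c in motif)
    except KeyError as exc:
        raise MotifError(f"bad motif symbol {exc}") from exc
    seq = sequence.upper().replace("T", "U")
    return [m.start() for m in re.finditer(f"(?={pattern})", seq)]


def contains_motif(sequence: str, motif: str = DEFAULT_MOTIF) -> bool:
    return bool(scan_motif(sequence, motif))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class SummitWindow:
    peak_id: str
    chrom: str
    strand: str
    summit: int
    sequence: str  # sense-strand RNA
    truncated: bool = False


def extract_summit_windows(
    peaks: list[EnrichedRegion], genome, width: int = 100
) -> list[SummitWindow]:
    """Sense-strand RNA windows of ``width`` nt centred on peak summits.

    Windows reaching past a contig end are truncated (no padding) and
    flagged.  Peaks without a host transcript use the reference (+) strand.
    """
    half = width // 2
    out = []
    for i, p in enumerate(peaks):
        contig_len = len(genome[p.chrom])
        if not 0 <= p.summit < contig_len:
            raise MotifError(f"summit {p.summit} outside contig {p.chrom}")
        lo, hi = p.summit - half, p.summit + (width - half)
        truncated = lo < 0 or hi > contig_len
        strand = _peak_strand(p)
        out.append(
            SummitWindow(
                peak_id=f"peak_{i}", chrom=p.chrom, strand=strand, summit=p.summit,
                sequence=rna_window(
                    genome, p.chrom, strand, max(lo, 0), min(hi, contig_len)
                ),
                truncated=truncated,
            )
        )
    return out


def _peak_strand(peak: EnrichedRegion) -> str:
    return getattr(peak, "host_strand", None) or "+"


def attach_host_strands(
    peaks: list[EnrichedRegion], annotation: Annotation
) -> None:
    """Record the host transcript's strand on each peak (default '+')."""
    for p in peaks:
        strand = "+"
        if p.host_transcript is not None:
            strand = annotation.by_transcript_id[p.host_transcript].strand
        p.host_strand = strand


@dataclass
class ControlRegion:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def sample_control_regions(
    peaks: list[EnrichedRegion],
    gene_cpm: pd.DataFrame,
    annotation: Annotation,
    n_per_peak: int = 10,
    seed: int = 0,
    length: int = 100,
    input_sample: str = "Input",
) -> list[ControlRegion]:
    """Length-matched control windows from expressed RNA precursors.

    For each peak, ``n_per_peak`` windows are drawn uniformly (gene chosen
    uniformly among genes with Input CPM > 0 whose precursor span fits the
    window, then position uniform within the span).  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    cpm = gene_cpm.set_index("gene_id")[f"{input_sample}_cpm"]
    expressed = sorted(g for g, v in cpm.items() if v > 0)
    spans = {}
    for g in expressed:
        chrom, s, e, strand = annotation.gene_span(g)
        if e - s >= length:
            spans[g] = (chrom, s, e, strand)
    if not spans:
        raise MotifError("no expressed gene long enough for control windows")
    genes = sorted(spans)
    out = []
    for _ in peaks:
        for _ in range(n_per_peak):
            g = genes[int(rng.integers(len(genes)))]
            chrom, s, e, strand = spans[g]
            start = int(rng.integers(s, e - length + 1))
            out.append(ControlRegion(g, chrom, strand, start, start + length))
    return out


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def _haldane_log2_or(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """log2 odds ratio with 0.5 continuity correction on zero cells, capped."""
    capped = min(a, b, c, d) == 0
    if capped:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    val = float(np.log2((a * d) / (b * c)))
    val = float(np.clip(val, -LOG2_OR_CAP, LOG2_OR_CAP))
    return val, capped


def motif_overrepresentation(
    peak_sequences: list[str],
    control_sequences: list[str],
    motif_set: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Presence/absence Fisher test per motif, peaks vs controls.

    Each window counts once (contains >= 1 occurrence or not).  Reports the
    two-sided Fisher p, BH-adjusted p across the motif set, and a capped
    Haldane-corrected log2 odds ratio.
    """
    if not peak_sequences or not control_sequences:
        raise MotifError("peak and control sets must both be non-empty")
    if motif_set is None:
        motif_set = {"MATR3_UUCUU": DEFAULT_MOTIF}
    rows = []
    for motif_id, consensus in motif_set.items():
        a = sum(contains_motif(s, consensus) for s in peak_sequences)
        b = len(peak_sequences) - a
        c = sum(contains_motif(s, consensus) for s in control_sequences)
        d = len(control_sequences) - c
        p = float(stats.fisher_exact([[a, b], [c, d]], "two-sided")[1])
        log2or, capped = _haldane_log2_or(a, b, c, d)
        rows.append(
            {
                "motif_id": motif_id, "consensus": consensus,
                "peaks_with_motif": a, "peaks_total": len(peak_sequences),
                "controls_with_motif": c, "controls_total": len(control_sequences),
                "log2_odds_ratio": log2or, "or_capped": capped, "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# positional enrichment
# ---------------------------------------------------------------------------

@dataclass
class PositionalEnrichmentProfile:
    offsets: np.ndarray
    log2_odds_ratio: np.ndarray
    fisher_p: np.ndarray
    bonferroni_significant: np.ndarray
    median_fpm: np.ndarray | None = None
    n_offsets_tested: int = 0
    skipped_offsets: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "offset": self.offsets,
                "log2_odds_ratio": self.log2_odds_ratio,
                "fisher_p": self.fisher_p,
                "bonferroni_significant": self.bonferroni_significant,
            }
        )
        if self.median_fpm is not None:
            df["median_fpm"] = self.median_fpm
        return df


def top_peaks(
    peaks: list[EnrichedRegion], n: int = 500
) -> list[EnrichedRegion]:
    """Top peaks ranked by average log2 fold enrichment over the two IPs."""
    ranked = sorted(peaks, key=lambda p: (-p.mean_log2fe, p.chrom, p.start))
    return ranked[:n]


def _window_rna(
    genome, chrom: str, strand: str, anchor: int, offset: int, window: int
) -> str | None:
    """Sense-strand RNA of the ``window``-nt window centred at RNA offset
    ``offset`` from ``anchor``; None when it falls off the contig.

    An RNA-coordinate offset +d lies downstream in transcription direction,
    i.e. at reference position anchor+d on plus-strand hosts and anchor-d
    on minus-strand hosts.
    """
    center = anchor + offset if strand == "+" else anchor - offset
    half = window // 2
    lo, hi = center - half, center + (window - half)
    if lo < 0 or hi > len(genome[chrom]):
        return None
    return rna_window(genome, chrom, strand, lo, hi)


def positional_enrichment(
    peaks: list[EnrichedRegion],
    controls: list[ControlRegion],
    genome,
    motif: str = DEFAULT_MOTIF,
    window: int = 10,
    max_offset: int = 50,
    counter: RegionCounter | None = None,
    ip_samples: tuple[str, str] = ("IP1", "IP2"),
) -> PositionalEnrichmentProfile:
    """Per-offset motif containment test around peak summits.

    For each offset d in [-max_offset, +max_offset], the 10-nt window
    centred on summit+d (RNA coordinates) of every peak and on center+d of
    every control region is scored for motif containment; a two-sided
    Fisher test compares peaks with controls, Bonferroni-corrected over the
    number of offsets.  With ``counter`` given, the median combined IP FPM
    at summit+d over peaks is recorded alongside.
    """
    if not peaks or not controls:
        raise MotifError("need non-empty peak and control sets")
    offsets = np.arange(-max_offset, max_offset + 1)
    n_off = len(offsets)
    log2or = np.zeros(n_off)
    pvals = np.ones(n_off)
    skipped = []
    for i, d in enumerate(offsets):
        pk = [
            _window_rna(genome, p.chrom, _peak_strand(p), p.summit, int(d), window)
            for p in peaks
        ]
        ct = [
            _window_rna(genome, c.chrom, c.strand, c.center, int(d), window)
            for c in controls
        ]
        pk = [s for s in pk if s is not None]
        ct = [s for s in ct if s is not None]
        if not pk or not ct:
            skipped.append(int(d))
            continue
        a = sum(contains_motif(s, motif) for s in pk)
        b = len(pk) - a
        c = sum(contains_motif(s, motif) for s in ct)
        e = len(ct) - c
        pvals[i] = float(stats.fisher_exact([[a, b], [c, e]], "two-sided")[1])
        log2or[i], _ = _haldane_log2_or(a, b, c, e)
    signif = pvals < 0.05 / n_off

    median_fpm = None
    if counter is not None:
        median_fpm = coverage_profile(peaks, counter, max_offset, ip_samples)
    return PositionalEnrichmentProfile(
        offsets=offsets, log2_odds_ratio=log2or, fisher_p=pvals,
        bonferroni_significant=signif, median_fpm=median_fpm,
        n_offsets_tested=n_off, skipped_offsets=skipped,
    )


def coverage_profile(
    peaks: list[EnrichedRegion],
    counter: RegionCounter,
    max_offset: int = 50,
    ip_samples: tuple[str, str] = ("IP1", "IP2"),
) -> np.ndarray:
    """Median over peaks of combined IP FPM at each offset from the summit.

    Offsets follow RNA orientation (positive = downstream of the summit on
    the host strand).
    """
    offsets = np.arange(-max_offset, max_offset + 1)
    per_peak = np.zeros((len(peaks), len(offsets)))
    for j, p in enumerate(peaks):
        sign = 1 if _peak_strand(p) == "+" else -1
        pos = p.summit + sign * offsets
        pos = np.clip(pos, 0, None)
        for s in ip_samples:
            per_peak[j] += counter.fpm_at(s, p.chrom, pos)
    return np.median(per_peak, axis=0)
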