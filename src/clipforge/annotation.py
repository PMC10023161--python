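"""Transcript models, GTF input/output and peak annotation.

The annotation universe is a set of stranded transcripts with biotype and
exon/CDS/UTR structure.  Peaks are assigned a host transcript by biotype
priority (protein_coding > lncRNA > other) and a region class by feature
priority (CDS > 3'UTR > 5'UTR > exon > intron; no host means intergenic).

All coordinates are 0-based half-open internally; GTF is written and read
1-based inclusive.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

Interval = tuple[int, int]

#: biotypes whose fragments are excluded before binning, plus anything on a
#: mitochondrial contig
BLACKLIST_BIOTYPES = frozenset({"rRNA", "tRNA", "Mt"})

#: host-assignment priority; lower rank wins
BIOTYPE_PRIORITY = {"protein_coding": 0, "lncRNA": 1}

REGION_CLASSES = ("CDS", "3UTR", "5UTR", "exon", "intron", "intergenic")


class AnnotationError(ValueError):
    """Raised for structurally inconsistent transcript models."""


@dataclass
class TranscriptModel:
    """A stranded transcript with exon/CDS/UTR structure.

    ``exons`` are sorted, pairwise disjoint, genomic-coordinate intervals
    within ``span``.  ``cds`` is empty for non-coding transcripts; ``utr5``
    and ``utr3`` are derived from exons minus CDS, oriented by strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    biotype: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        if self.strand not in "+-":
            raise AnnotationError(f"transcript {self.transcript_id}: bad strand")
        for (s, e) in self.exons + self.cds:
            if s >= e:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty interval [{s},{e})"
                )
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.start = self.exons[0][0]
        self.end = self.exons[-1][1]
        self.utr5, self.utr3 = self._derive_utrs()

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def _derive_utrs(self) -> tuple[list[Interval], list[Interval]]:
        if not self.cds:
            return [], []
        cds_lo = self.cds[0][0]
        cds_hi = self.cds[-1][1]
        left: list[Interval] = []
        right: list[Interval] = []
        for (s, e) in self.exons:
            if s < cds_lo:
                left.append((s, min(e, cds_lo)))
            if e > cds_hi:
                right.append((max(s, cds_hi), e))
        return (left, right) if self.strand == "+" else (right, left)

    def introns(self) -> list[Interval]:
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        ]

    def overlap_bp(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


class Annotation:
    """Indexed collection of transcripts (interval trees per chromosome)."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: list[TranscriptModel] = list(transcripts)
        self.by_transcript_id = {t.transcript_id: t for t in self.transcripts}
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        for t in self.transcripts:
            self.by_gene.setdefault(t.gene_id, []).append(t)
        self._trees: dict[str, IntervalTree] = {}
        for i, t in enumerate(self.transcripts):
            self._trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, i)
        # contigs carrying Mt-biotype genes count as mitochondrial, as does
        # any contig whose name starts with "chrM"
        self.mito_chroms = {t.chrom for t in self.transcripts if t.biotype == "Mt"}
        self.mito_chroms |= {c for c in self._trees if c.startswith("chrM")}

    def __len__(self) -> int:
        return len(self.transcripts)

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [t for t in hits if t.strand == strand]
        return hits

    def gene_span(self, gene_id: str) -> tuple[str, int, int, str]:
        ts = self.by_gene[gene_id]
        return (
            ts[0].chrom,
            min(t.start for t in ts),
            max(t.end for t in ts),
            ts[0].strand,
        )

    def gene_ids(self) -> list[str]:
        return sorted(self.by_gene)

    def blacklist_intervals(
        self, biotypes: frozenset[str] = BLACKLIST_BIOTYPES
    ) -> dict[tuple[str, str], list[Interval]]:
        """Merged gene spans of blacklist biotypes, keyed by (chrom, strand)."""
        raw: dict[tuple[str, str], list[Interval]] = {}
        for t in self.transcripts:
            if t.biotype in biotypes:
                raw.setdefault((t.chrom, t.strand), []).append((t.start, t.end))
        out = {}
        for key, ivs in raw.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[key] = [(s, e) for s, e in merged]
        return out


# ---------------------------------------------------------------------------
# host assignment and region classification
# ---------------------------------------------------------------------------

def biotype_class(biotype: str) -> str:
    """Collapse a biotype to the reporting classes protein_coding/lncRNA/other."""
    if biotype in ("protein_coding", "lncRNA"):
        return biotype
    return "other"


def assign_host(
    peak: tuple[str, int, int], annotation: Annotation
) -> tuple[TranscriptModel | None, str | None]:
    """Pick the host transcript of a peak by biotype priority.

    Among transcripts overlapping the peak by >=1 bp, protein_coding beats
    lncRNA beats everything else; ties within a class go to the larger
    overlap, then to the lexicographically smallest transcript_id.  Returns
    ``(None, None)`` for intergenic peaks.
    """
    chrom, start, end = peak
    hits = annotation.overlapping(chrom, start, end)
    if not hits:
        return None, None
    best = min(
        hits,
        key=lambda t: (
            BIOTYPE_PRIORITY.get(t.biotype, 2),
            -t.overlap_bp(start, end),
            t.transcript_id,
        ),
    )
    return best, biotype_class(best.biotype)


def classify_region(
    peak: tuple[str, int, int], host: TranscriptModel | None
) -> str:
    """Region class of a peak within its host transcript.

    Priority over features overlapped by >=1 bp: CDS > 3'UTR > 5'UTR > exon
    (exons of non-coding transcripts) > intron.  A peak with no host is
    intergenic.
    """
    if host is None:
        return "intergenic"
    _, start, end = peak

    def any_overlap(ivs: Sequence[Interval]) -> bool:
        return any(min(e, end) > max(s, start) for s, e in ivs)

    if host.is_coding:
        if any_overlap(host.cds):
            return "CDS"
        if any_overlap(host.utr3):
            return "3UTR"
        if any_overlap(host.utr5):
            return "5UTR"
    elif any_overlap(host.exons):
        return "exon"
    if any_overlap(host.introns()):
        return "intron"
    if any_overlap(host.exons):
        # coding-transcript exonic overlap not classifiable as CDS/UTR can
        # only arise from inconsistent structure; UTR+CDS partition exons
        raise AnnotationError(
            f"transcript {host.transcript_id}: exonic overlap outside CDS/UTR partition"
        )
    # peak overlaps the span but neither exons nor introns: impossible for a
    # well-formed model, since span = exons ∪ introns
    raise AnnotationError(f"transcript {host.transcript_id}: structure gap")


def annotate_peaks(
    peaks: Iterable[tuple[str, int, int]], annotation: Annotation
) -> list[dict]:
    """Annotate peaks with host transcript, biotype class and region class."""
    out = []
    for i, (chrom, start, end) in enumerate(peaks):
        host, bclass = assign_host((chrom, start, end), annotation)
        rclass = classify_region((chrom, start, end), host)
        out.append(
            {
                "peak_id": f"peak_{i}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "host_gene": host.gene_id if host else None,
                "host_transcript": host.transcript_id if host else None,
                "biotype_assigned": bclass,
                "region_class": rclass,
            }
        )
    return out


# ---------------------------------------------------------------------------
# GTF input/output
# ---------------------------------------------------------------------------

def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF (1-based inclusive) with gene_biotype attributes."""
    lines = []
    for t in sorted(
        transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)
    ):
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_biotype "{t.biotype}";'
        )

        def row(feature: str, s: int, e: int) -> str:
            return (
                f"{t.chrom}\tclipforge\t{feature}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}"
            )

        lines.append(row("gene", t.start, t.end))
        lines.append(row("transcript", t.start, t.end))
        for s, e in t.exons:
            lines.append(row("exon", s, e))
        for s, e in t.cds:
            lines.append(row("CDS", s, e))
        for s, e in t.utr5:
            lines.append(row("five_prime_utr", s, e))
        for s, e in t.utr3:
            lines.append(row("three_prime_utr", s, e))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path) -> Annotation:
    """Load an Annotation from GTF via gffutils (in-memory database)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    transcripts = []
    for tr in db.features_of_type("transcript"):
        tid = tr.attributes["transcript_id"][0]
        gid = tr.attributes["gene_id"][0]
        biotype = tr.attributes.get("gene_biotype", ["other"])[0]
        exons = []
        cds = []
        for child in db.children(tr, featuretype=("exon", "CDS")):
            iv = (child.start - 1, child.end)  # to 0-based half-open
            if child.featuretype == "exon":
                exons.append(iv)
            else:
                cds.append(iv)
        transcripts.append(
            TranscriptModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=tr.seqid,
                strand=tr.strand,
                biotype=biotype,
                exons=exons,
                cds=cds,
            )
        )
    return Annotation(transcripts)


def read_gtf_text(text: str) -> Annotation:
    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_gtf(name)
    finally:
        Path(name).unlink(missing_ok=True)
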