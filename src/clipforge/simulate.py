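"""Synthetic CLIP experiment with known ground truth.

Builds a toy annotated genome (protein-coding, lncRNA, rRNA/tRNA and
mitochondrial genes with exon-intron-CDS-UTR structure), plants IP-enriched
peaks shared by two replicates and UUCUU motifs at peak summits, and draws
stranded sequencing fragments per sample (Input, IP1, IP2, IgG) and per
condition (WT, KO) from a negative-binomial background proportional to gene
expression.

The generator defines the study conditions of every downstream statistical
check: background depth, overdispersion, enrichment levels, replicate
structure, the sticky-transcript IgG control and the KO loss/gain fates are
all encoded here, and the emitted truth table is the oracle that recovery
statistics are scored against.

Design notes
------------
* Coordinates are 0-based half-open internally; BED output is 0-based
  half-open, GTF 1-based inclusive.
* Peaks are placed on whole 200-bp bins fully inside a host gene, on genes
  with at least median expression: CLIP can only detect binding on
  transcripts that are expressed enough to yield coverage.
* Fragment strand equals host-gene strand; intergenic fragments get a
  random strand.
* KO silences the pCharme-like lncRNA, reverts ko_fate=loss peaks to E=1
  and switches ko_fate=gain peaks (E=1 in WT) on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .annotation import Annotation, TranscriptModel, write_gtf

logger = logging.getLogger(__name__)

MITO_CHROM = "chrM_toy"
MITO_LENGTH = 16_000
MOTIF_DNA = "TTCTT"  # DNA template of the UUCUU RNA consensus, sense strand

CONDITIONS = ("WT", "KO")
SAMPLES = ("Input", "IP1", "IP2", "IgG")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic CLIP experiment.

    Defaults are the study conditions used throughout the test suite; see
    docs/methods.md for the rationale behind each value.
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (600_000, 600_000)
    n_coding_genes: int = 60
    n_lncRNA_genes: int = 10
    n_blacklist_genes: int = 6
    expression_lognormal_mu_sigma: tuple[float, float] = (0.0, 0.3)
    background_nb_dispersion: float = 100.0  # NB size; var = mu + mu^2/size
    mean_bin_fragments: float = 8.0  # intronic-bin mean at median expression
    exon_boost: float = 3.0
    peak_enrichment_levels: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0)
    peaks_per_level: int = 3
    peak_width_bins: int = 1
    bin_width: int = 200
    fragment_length_range: tuple[int, int] = (30, 60)
    motif_plant_fraction: float = 0.9
    ko_loss_fraction: float = 0.5
    ko_gain_fraction: float = 0.1
    igg_sticky_transcripts: int = 2
    igg_scale: float = 0.08
    ip_scale: float = 1.0
    input_scale: float = 2.0
    intergenic_bin_rate: float = 0.02

    def validate(self) -> None:
        if self.bin_width < 1:
            raise SimulationError("bin_width must be >= 1")
        if any(L < 10 * self.bin_width for L in self.chrom_lengths):
            raise SimulationError("each chromosome must be >= 10 bin widths long")
        for name in ("motif_plant_fraction", "ko_loss_fraction", "ko_gain_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.background_nb_dispersion <= 0:
            raise SimulationError("background_nb_dispersion must be > 0")
        if any(e <= 1 for e in self.peak_enrichment_levels):
            raise SimulationError("peak enrichment levels must exceed 1")
        lo, hi = self.fragment_length_range
        if not (1 <= lo <= hi):
            raise SimulationError("bad fragment_length_range")
        for name in (
            "n_coding_genes",
            "n_lncRNA_genes",
            "n_blacklist_genes",
            "peaks_per_level",
            "igg_sticky_transcripts",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")

    def chrom_sizes(self) -> dict[str, int]:
        sizes = {f"chr{i + 1}": L for i, L in enumerate(self.chrom_lengths)}
        sizes[MITO_CHROM] = MITO_LENGTH
        return sizes


@dataclass
class PlantedPeak:
    gene_id: str
    chrom: str
    start: int
    end: int
    summit: int
    strand: str
    enrichment: float  # planted factor E; the KO-side E for ko_fate=gain
    motif_planted: bool = False
    ko_fate: str = "retained"  # retained | loss | gain

    def enrichment_in(self, condition: str) -> float:
        if self.ko_fate == "gain":
            return self.enrichment if condition == "KO" else 1.0
        if self.ko_fate == "loss" and condition == "KO":
            return 1.0
        return self.enrichment


@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment; the acceptance oracle."""

    planted_peaks: list[PlantedPeak] = field(default_factory=list)
    igg_sticky: list[str] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)
    pcharme_gene: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(p) for p in self.planted_peaks])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def wt_active_peaks(self, min_enrichment: float = 1.0) -> list[PlantedPeak]:
        return [
            p
            for p in self.planted_peaks
            if p.enrichment_in("WT") >= max(min_enrichment, 1.0 + 1e-9)
        ]


# ---------------------------------------------------------------------------
# genome and annotation construction
# ---------------------------------------------------------------------------

def _gene_structure(
    rng: np.random.Generator, kind: str, pcharme: bool = False
) -> tuple[list[int], list[int], bool]:
    """Return (exon lengths, intron lengths, coding flag) for one gene."""
    if kind == "coding":
        n_ex = int(rng.integers(3, 7))
        exons = rng.integers(150, 401, n_ex).tolist()
        introns = rng.integers(400, 2501, n_ex - 1).tolist()
        return exons, introns, True
    if kind == "lncRNA":
        if pcharme:
            # intron-1-retaining nuclear lncRNA: long first intron
            return [500, 600, 700], [6000, 500], False
        n_ex = int(rng.integers(2, 5))
        exons = rng.integers(200, 501, n_ex).tolist()
        introns = rng.integers(300, 1501, n_ex - 1).tolist()
        return exons, introns, False
    # blacklist rRNA/tRNA and mitochondrial genes: single exon
    return [int(rng.integers(200, 1501))], [], False


def _make_transcript(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    biotype: str,
    start: int,
    exon_lens: list[int],
    intron_lens: list[int],
    coding: bool,
) -> TranscriptModel:
    exons: list[tuple[int, int]] = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    cds: list[tuple[int, int]] = []
    if coding:
        first, last = exons[0], exons[-1]
        cds_lo = first[0] + int(rng.integers(60, min(140, exon_lens[0] - 40)))
        cds_hi = last[1] - int(rng.integers(60, min(140, exon_lens[-1] - 40)))
        for s, e in exons:
            lo, hi = max(s, cds_lo), min(e, cds_hi)
            if lo < hi:
                cds.append((lo, hi))
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=gene_id + ".t1",
        chrom=chrom,
        strand=strand,
        biotype=biotype,
        exons=exons,
        cds=cds,
    )


def build_toy_genome(
    config: SimulationConfig,
) -> tuple[dict[str, bytearray], Annotation, SimulationTruth]:
    """Build genome sequences, annotation and the truth skeleton.

    Returns uniform-random nucleotide sequences (mutable, so that motif
    planting can edit them in place), a fully structured annotation, and a
    SimulationTruth with expression levels, planted peaks (motif flags
    unset) and IgG sticky transcripts.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 100])
    sizes = config.chrom_sizes()
    main_chroms = [c for c in sizes if c != MITO_CHROM]

    # gene roster, dealt round-robin over the main chromosomes
    roster: list[tuple[str, str, str]] = []  # (gene_id, kind, biotype)
    for i in range(config.n_coding_genes):
        roster.append((f"gene_pc_{i:03d}", "coding", "protein_coding"))
    for i in range(config.n_lncRNA_genes):
        roster.append((f"gene_lnc_{i:03d}", "lncRNA", "lncRNA"))
    for i in range(config.n_blacklist_genes):
        biotype = "rRNA" if i % 2 == 0 else "tRNA"
        roster.append((f"gene_bl_{i:03d}", "blacklist", biotype))
    order = rng.permutation(len(roster))

    transcripts: list[TranscriptModel] = []
    cursors = {c: int(rng.integers(1000, 3000)) for c in main_chroms}
    strand_flip = 0
    for chrom_idx, ridx in enumerate(order):
        gene_id, kind, biotype = roster[ridx]
        chrom = main_chroms[chrom_idx % len(main_chroms)]
        pcharme = gene_id == "gene_lnc_000"
        exon_lens, intron_lens, coding = _gene_structure(rng, kind, pcharme)
        strand = "+" if strand_flip % 2 == 0 else "-"
        strand_flip += 1
        start = cursors[chrom]
        t = _make_transcript(
            rng, gene_id, chrom, strand, biotype, start, exon_lens, intron_lens, coding
        )
        if t.end > sizes[chrom] - 500:
            raise SimulationError(
                f"chromosome {chrom} too short to host gene {gene_id} "
                f"(needs end {t.end}, length {sizes[chrom]})"
            )
        transcripts.append(t)
        cursors[chrom] = t.end + int(rng.integers(2000, 6001))

    # two mitochondrial-like genes on the dedicated contig
    pos = 1000
    for i in range(2):
        exon_lens, intron_lens, coding = _gene_structure(rng, "blacklist")
        t = _make_transcript(
            rng,
            f"gene_mt_{i:03d}",
            MITO_CHROM,
            "+" if i % 2 == 0 else "-",
            "Mt",
            pos,
            exon_lens,
            intron_lens,
            coding,
        )
        transcripts.append(t)
        pos = t.end + 2000

    annotation = Annotation(transcripts)

    # expression: relative abundance per gene, lognormal; the pCharme-like
    # lncRNA is the most abundant lncRNA (set above the drawn maximum)
    mu, sigma = config.expression_lognormal_mu_sigma
    truth = SimulationTruth(pcharme_gene="gene_lnc_000")
    drawn = {}
    for t in sorted(transcripts, key=lambda t: t.gene_id):
        if t.biotype in ("protein_coding", "lncRNA"):
            drawn[t.gene_id] = float(rng.lognormal(mu, sigma))
        else:
            drawn[t.gene_id] = 1.0
    if truth.pcharme_gene in drawn:
        hi = max(
            v
            for g, v in drawn.items()
            if g.startswith("gene_pc_") or g.startswith("gene_lnc_")
        )
        drawn[truth.pcharme_gene] = 1.2 * hi
    truth.expression = drawn

    _plant_peaks(rng, config, annotation, truth)
    _pick_sticky(rng, config, annotation, truth)

    genome = {
        chrom: bytearray(
            rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L).tobytes()
        )
        for chrom, L in sizes.items()
    }
    return genome, annotation, truth


def _plant_peaks(
    rng: np.random.Generator,
    config: SimulationConfig,
    annotation: Annotation,
    truth: SimulationTruth,
) -> None:
    """Place bin-aligned peaks on expressed genes and assign KO fates."""
    w = config.bin_width
    wb = config.peak_width_bins
    expr = truth.expression
    eligible = [
        t
        for t in annotation.transcripts
        if t.biotype in ("protein_coding", "lncRNA")
    ]
    med = float(np.median([expr[t.gene_id] for t in eligible])) if eligible else 0.0
    eligible = sorted(
        (t for t in eligible if expr[t.gene_id] >= med), key=lambda t: t.gene_id
    )
    if not eligible:
        return

    occupied: dict[str, list[tuple[int, int]]] = {}

    def try_place(t: TranscriptModel) -> tuple[int, int] | None:
        b_lo = -(-t.start // w)  # first bin fully inside the gene
        b_hi = t.end // w - wb
        if b_hi < b_lo:
            return None
        # binding sites sit on exon-overlapping bins: at the simulated depth
        # only exonic-level coverage makes the planted enrichment
        # identifiable, mirroring the coverage dependence of real CLIP
        exonic_bins = [
            b
            for b in range(b_lo, b_hi + 1)
            if any(b * w < e and (b + wb) * w > s for s, e in t.exons)
        ]
        if not exonic_bins:
            return None
        for _ in range(20):
            b = exonic_bins[int(rng.integers(len(exonic_bins)))]
            s, e = b * w, (b + wb) * w
            clashes = [
                iv for iv in occupied.get(t.gene_id, []) if s < iv[1] + w and e > iv[0] - w
            ]
            if not clashes:
                occupied.setdefault(t.gene_id, []).append((s, e))
                return s, e
        return None

    def plant(level: float, fate: str) -> None:
        for _ in range(60):
            t = eligible[int(rng.integers(len(eligible)))]
            placed = try_place(t)
            if placed is not None:
                s, e = placed
                truth.planted_peaks.append(
                    PlantedPeak(
                        gene_id=t.gene_id,
                        chrom=t.chrom,
                        start=s,
                        end=e,
                        summit=(s + e) // 2,
                        strand=t.strand,
                        enrichment=level,
                        ko_fate=fate,
                    )
                )
                return
        warnings.warn(f"could not place a peak at enrichment {level}")

    for level in config.peak_enrichment_levels:
        for _ in range(config.peaks_per_level):
            plant(level, "retained")

    # KO fates: a fraction of the WT-active peaks lose enrichment in KO;
    # additional peaks with E=1 in WT acquire enrichment in KO (gain)
    n = len(truth.planted_peaks)
    n_loss = int(round(config.ko_loss_fraction * n))
    for idx in rng.choice(n, size=n_loss, replace=False):
        truth.planted_peaks[idx].ko_fate = "loss"
    n_gain = int(round(config.ko_gain_fraction * n))
    levels = list(config.peak_enrichment_levels)
    for i in range(n_gain):
        plant(levels[i % len(levels)], "gain")


def _pick_sticky(
    rng: np.random.Generator,
    config: SimulationConfig,
    annotation: Annotation,
    truth: SimulationTruth,
) -> None:
    peaked = {p.gene_id for p in truth.planted_peaks}
    pool = sorted(
        t.gene_id
        for t in annotation.transcripts
        if t.biotype in ("protein_coding", "lncRNA")
        and t.gene_id not in peaked
        and t.gene_id != truth.pcharme_gene
    )
    k = min(config.igg_sticky_transcripts, len(pool))
    truth.igg_sticky = sorted(
        pool[i] for i in rng.choice(len(pool), size=k, replace=False)
    )


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def revcomp(seq: str | bytes) -> str:
    if isinstance(seq, str):
        seq = seq.encode()
    return seq.translate(_COMPLEMENT)[::-1].decode()


def plant_motif_sites(
    genome: dict[str, bytearray],
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, bytearray]:
    """Write the UUCUU consensus at a fraction of peak summits.

    The DNA template TTCTT is written centred on the summit ([summit-2,
    summit+3)) on the sense strand of the host gene: plus-strand hosts get
    TTCTT on the reference, minus-strand hosts its reverse complement AAGAA.
    Edits the genome in place and sets motif_planted flags in the truth.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 101])
    n = len(truth.planted_peaks)
    k = int(round(config.motif_plant_fraction * n))
    if k == 0:
        return genome
    chosen = sorted(rng.choice(n, size=k, replace=False))
    half = len(MOTIF_DNA) // 2
    for idx in chosen:
        p = truth.planted_peaks[idx]
        s = p.summit - half
        e = s + len(MOTIF_DNA)
        if s < 0 or e > len(genome[p.chrom]):
            warnings.warn(
                f"summit {p.summit} too close to the end of {p.chrom}; motif skipped"
            )
            continue
        word = MOTIF_DNA if p.strand == "+" else revcomp(MOTIF_DNA)
        genome[p.chrom][s:e] = word.encode()
        p.motif_planted = True
    return genome


# ---------------------------------------------------------------------------
# fragment simulation
# ---------------------------------------------------------------------------

def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, size: float
) -> np.ndarray:
    """Vectorised NB(mean, size) draw; mean 0 yields 0."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def _emit_fragments(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    bin_starts: np.ndarray,
    counts: np.ndarray,
    width: int,
    frag_range: tuple[int, int],
    strand: str | None,
) -> pd.DataFrame:
    """Turn per-bin counts into BED6-style fragment rows.

    Each fragment starts uniformly inside its bin; length is uniform in
    frag_range, clipped at the contig end.  The number of emitted fragments
    equals the sum of counts (conservation).
    """
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"]
        )
    starts = np.repeat(bin_starts, counts) + rng.integers(0, width, size=total)
    lens = rng.integers(frag_range[0], frag_range[1] + 1, size=total)
    ends = np.minimum(starts + lens, chrom_len)
    starts = np.minimum(starts, chrom_len - 1)
    if strand is None:
        strands = np.where(rng.integers(0, 2, size=total) == 0, "+", "-")
    else:
        strands = np.full(total, strand)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "name": ".",
            "score": 0,
            "strand": strands,
        }
    )


def _emit_anchored(
    rng: np.random.Generator,
    chrom: str,
    chrom_len: int,
    anchor: int,
    count: int,
    frag_range: tuple[int, int],
    strand: str,
) -> pd.DataFrame:
    """Fragments that all cover ``anchor`` (start uniform in (anchor-L, anchor])."""
    lens = rng.integers(frag_range[0], frag_range[1] + 1, size=count)
    starts = anchor - rng.integers(0, lens)
    starts = np.clip(starts, 0, chrom_len - 1)
    ends = np.minimum(starts + lens, chrom_len)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "name": ".",
            "score": 0,
            "strand": np.full(count, strand),
        }
    )


def simulate_clip_experiment(
    genome: dict[str, bytearray],
    annotation: Annotation,
    truth: SimulationTruth,
    config: SimulationConfig,
    condition: str = "WT",
) -> dict[str, pd.DataFrame]:
    """Draw stranded fragments for Input, IP1, IP2 and IgG in one condition.

    Per gene, the expected fragment count of a bin is
    ``mean_bin_fragments * expression * exon_boost^(exonic) * overlap_frac``;
    counts are NB with the configured dispersion.  IP replicates multiply
    bins inside planted peaks by the condition-specific enrichment E with
    independent redraws per replicate; IgG is globally scaled down except on
    sticky transcripts; KO silences the pCharme-like gene.
    """
    if condition not in CONDITIONS:
        raise SimulationError(f"unknown condition {condition!r}; use WT or KO")
    config.validate()
    w = config.bin_width
    sizes = {c: len(seq) for c, seq in genome.items()}
    cond_code = CONDITIONS.index(condition)

    expr = dict(truth.expression)
    if condition == "KO" and truth.pcharme_gene in expr:
        expr[truth.pcharme_gene] = 0.0
    sticky = set(truth.igg_sticky)

    # per-gene bin grids and baseline (Input-scale) expectations
    gene_bins: list[tuple[TranscriptModel, np.ndarray, np.ndarray]] = []
    covered: dict[str, set[int]] = {c: set() for c in sizes}
    for t in sorted(annotation.transcripts, key=lambda t: t.transcript_id):
        b0, b1 = t.start // w, (t.end - 1) // w
        bins = np.arange(b0, b1 + 1)
        bstarts = bins * w
        bends = np.minimum(bstarts + w, sizes[t.chrom])
        frac = (np.minimum(bends, t.end) - np.maximum(bstarts, t.start)) / w
        exonic = np.zeros(len(bins), dtype=bool)
        for s, e in t.exons:
            exonic |= (bstarts < e) & (bends > s)
        lam = config.mean_bin_fragments * expr.get(t.gene_id, 0.0) * frac
        lam[exonic] *= config.exon_boost
        gene_bins.append((t, bstarts, lam))
        covered[t.chrom].update(bins.tolist())

    # condition-specific peak lookup: (chrom, bin_start) -> (E, summit)
    peak_info: dict[tuple[str, int], tuple[float, int]] = {}
    for p in truth.planted_peaks:
        E = p.enrichment_in(condition)
        for bs in range(p.start, p.end, w):
            key = (p.chrom, bs)
            if key not in peak_info or E > peak_info[key][0]:
                peak_info[key] = (E, p.summit)

    out: dict[str, pd.DataFrame] = {}
    for sample in SAMPLES:
        rng = np.random.default_rng([config.seed, 7, cond_code, SAMPLES.index(sample)])
        frames = []
        for t, bstarts, lam in gene_bins:
            scale = config.input_scale
            if sample in ("IP1", "IP2"):
                scale = config.ip_scale
            elif sample == "IgG":
                scale = 1.0 if t.gene_id in sticky else config.igg_scale
            mean = lam * scale
            counts = _nb_draw(rng, mean, config.background_nb_dispersion)
            frames.append(
                _emit_fragments(
                    rng,
                    t.chrom,
                    sizes[t.chrom],
                    bstarts,
                    counts,
                    w,
                    config.fragment_length_range,
                    t.strand,
                )
            )
            if sample in ("IP1", "IP2") and peak_info:
                # bound-site signal on top of background: the extra
                # (E-1)-fold fragments all span the crosslink site, so IP
                # coverage piles up at the planted summit as in real CLIP
                for j, bs in enumerate(bstarts):
                    info = peak_info.get((t.chrom, int(bs)))
                    if info is None or info[0] <= 1.0:
                        continue
                    E, summit = info
                    n_sig = int(
                        _nb_draw(
                            rng,
                            np.array([mean[j] * (E - 1.0)]),
                            config.background_nb_dispersion,
                        )[0]
                    )
                    if n_sig:
                        frames.append(
                            _emit_anchored(
                                rng, t.chrom, sizes[t.chrom], summit, n_sig,
                                config.fragment_length_range, t.strand,
                            )
                        )
        # intergenic background at a low flat rate, random strand
        inter_scale = {"Input": config.input_scale, "IP1": config.ip_scale,
                       "IP2": config.ip_scale, "IgG": config.igg_scale}[sample]
        for chrom, L in sizes.items():
            nbins = -(-L // w)
            free = np.array(
                sorted(set(range(nbins)) - covered[chrom]), dtype=np.int64
            )
            if len(free) == 0:
                continue
            mean = np.full(len(free), config.intergenic_bin_rate * inter_scale)
            counts = _nb_draw(rng, mean, config.background_nb_dispersion)
            frames.append(
                _emit_fragments(
                    rng, chrom, L, free * w, counts, w,
                    config.fragment_length_range, None,
                )
            )
        frames = [f for f in frames if not f.empty]
        df = pd.concat(frames, ignore_index=True)
        df = df.astype({"start": np.int64, "end": np.int64, "score": np.int64})
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        df["name"] = [f"frag_{i}" for i in range(len(df))]
        out[sample] = df
        logger.info("%s/%s: %d fragments", condition, sample, len(df))
    return out


# ---------------------------------------------------------------------------
# output writers and the one-call convenience wrapper
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, bytearray], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom].decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments.to_csv(path, sep="\t", header=False, index=False)


def simulate_to_dir(
    config: SimulationConfig, outdir: str | Path, condition: str = "WT"
) -> dict[str, Path]:
    """Run the full generator and write FASTA/GTF/BED/truth/config files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = build_toy_genome(config)
    plant_motif_sites(genome, truth, config)
    frags = simulate_clip_experiment(genome, annotation, truth, config, condition)
    paths: dict[str, Path] = {}
    paths["fasta"] = outdir / "genome.fa"
    write_fasta(genome, paths["fasta"])
    paths["gtf"] = outdir / "annotation.gtf"
    write_gtf(annotation.transcripts, paths["gtf"])
    for sample, df in frags.items():
        p = outdir / f"{condition}_{sample}.bed"
        write_bed(df, p)
        paths[f"bed_{sample}"] = p
    paths["truth"] = outdir / "truth.tsv"
    truth.write_tsv(paths["truth"])
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    sizes = {c: len(s) for c, s in genome.items()}
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for c, L in sizes.items():
            fh.write(f"{c}\t{L}\n")
    return paths


def evaluate_recovery(
    selected: Iterable[tuple[str, int, int]],
    truth: SimulationTruth,
    min_enrichment: float = 8.0,
) -> dict[str, float]:
    """Sensitivity/precision of selected regions against planted peaks.

    Sensitivity: fraction of WT-active planted peaks with enrichment >=
    min_enrichment overlapped (>= 1 bp) by a selected region.  Precision:
    fraction of selected regions overlapping any WT-active planted peak.
    """
    selected = list(selected)
    strong = truth.wt_active_peaks(min_enrichment)
    any_active = truth.wt_active_peaks(1.0)

    def hits(peak: PlantedPeak) -> bool:
        return any(
            c == peak.chrom and s < peak.end and e > peak.start
            for c, s, e in selected
        )

    sens = float(np.mean([hits(p) for p in strong])) if strong else float("nan")
    if selected:
        prec = float(
            np.mean(
                [
                    any(
                        p.chrom == c and s < p.end and e > p.start
                        for p in any_active
                    )
                    for c, s, e in selected
                ]
            )
        )
    else:
        prec = float("nan")
    return {
        "sensitivity": sens,
        "precision": prec,
        "n_selected": float(len(selected)),
        "n_strong_truth": float(len(strong)),
    }
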