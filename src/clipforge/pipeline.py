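"""End-to-end pipeline: count -> callpeaks -> annotate -> motif -> diffbind -> enrich.

A single PipelineConfig (YAML-loadable, unknown keys rejected) carries the
input paths and every stage threshold; `run_pipeline` executes the stages
in order, writes per-stage TSV outputs into the output directory and
returns a machine-readable manifest with record counts per stage, the seed
and package version.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from .annotation import read_gtf
from .binning import build_count_matrix, gene_level_cpm, make_bins, read_bed6
from .differential import (
    differential_binding,
    differential_to_frame,
    gain_loss_distribution,
    genes_with_class,
    overlap_enrichment,
)
from .motifs import (
    attach_host_strands,
    extract_summit_windows,
    motif_overrepresentation,
    positional_enrichment,
    sample_control_regions,
    top_peaks,
)
from .peaks import RegionCounter, call_peaks, regions_to_frame

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Paths and stage parameters of one pipeline run.

    The thresholds default to the selection rules used throughout: 200-bp
    bins, bin-call alpha 0.05, log2FE > 2 and FDR < 0.05 in both IPs,
    UUCUU motif, top 500 peaks, 10-nt positional windows over offsets
    +/-50, 10 control regions per peak.
    """

    genome_fasta: str = ""
    gtf: str = ""
    fragments: dict[str, str] = field(default_factory=dict)  # sample -> BED6
    ko_fragments: dict[str, str] = field(default_factory=dict)
    deg_table: str = ""  # optional TSV: gene_id, class in {up, down, invariant}
    outdir: str = "clipforge_out"
    bin_width: int = 200
    alpha: float = 0.05
    min_log2fe: float = 2.0
    max_fdr: float = 0.05
    motif: str = "UUCUU"
    top_n: int = 500
    window: int = 10
    max_offset: int = 50
    n_controls: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.bin_width < 1:
            raise PipelineConfigError("bin_width must be >= 1")
        if not 0 < self.alpha < 1 or not 0 < self.max_fdr < 1:
            raise PipelineConfigError("alpha and max_fdr must be in (0, 1)")
        if self.min_log2fe < 0:
            raise PipelineConfigError("min_log2fe must be >= 0")
        if self.top_n < 1 or self.window < 1 or self.max_offset < 0:
            raise PipelineConfigError("top_n/window/max_offset out of domain")
        if self.n_controls < 1:
            raise PipelineConfigError("n_controls must be >= 1")
        for path in [self.genome_fasta, self.gtf, *self.fragments.values(),
                     *self.ko_fragments.values()]:
            if path and not Path(path).exists():
                raise PipelineConfigError(f"missing input file: {path}")
        for s in ("Input", "IP1", "IP2"):
            if s not in self.fragments:
                raise PipelineConfigError(f"fragments must include sample {s}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    annotation = read_gtf(config.gtf)
    genome = Fasta(config.genome_fasta)
    chrom_sizes = {name: len(genome[name]) for name in genome.keys()}
    grid = make_bins(chrom_sizes, config.bin_width)

    # -- count ------------------------------------------------------------
    fragments = {s: read_bed6(p) for s, p in config.fragments.items()}
    matrix = build_count_matrix(fragments, grid, annotation)
    matrix.write_tsv(outdir / "bin_counts.tsv")
    cpm = gene_level_cpm(fragments, annotation)
    cpm.to_csv(outdir / "gene_cpm.tsv", sep="\t", index=False)
    manifest["stages"]["count"] = {
        "n_bins": grid.n_bins,
        "totals": dict(matrix.totals),
        "excluded": dict(matrix.excluded),
        "n_genes": len(cpm),
    }

    # -- callpeaks --------------------------------------------------------
    regions, attrition = call_peaks(
        matrix, fragments, annotation, gene_cpm=cpm,
        igg_sample="IgG" if "IgG" in fragments else None,
        alpha=config.alpha, min_log2fe=config.min_log2fe, max_fdr=config.max_fdr,
    )
    peaks_df = regions_to_frame(regions)
    peaks_df.to_csv(outdir / "peaks_all.tsv", sep="\t", index=False)
    selected = [r for r in regions if r.selected]
    peaks_df[peaks_df["selected"]].to_csv(
        outdir / "peaks_selected.tsv", sep="\t", index=False
    )
    manifest["stages"]["callpeaks"] = attrition

    # -- annotate ---------------------------------------------------------
    summary = (
        peaks_df[peaks_df["selected"]]
        .groupby(["biotype_assigned", "region_class"], dropna=False)
        .size()
        .reset_index(name="n_peaks")
    )
    summary.to_csv(outdir / "peak_annotation_summary.tsv", sep="\t", index=False)
    manifest["stages"]["annotate"] = {"n_annotated": len(selected)}

    # -- motif ------------------------------------------------------------
    counter = RegionCounter(fragments)
    motif_stage: dict = {"n_selected": len(selected)}
    if selected:
        attach_host_strands(selected, annotation)
        tops = top_peaks(selected, config.top_n)
        windows = extract_summit_windows(tops, genome, width=100)
        controls = sample_control_regions(
            tops, cpm, annotation, n_per_peak=config.n_controls, seed=config.seed
        )
        over = motif_overrepresentation(
            [w.sequence for w in windows],
            [
                w
                for w in (
                    _control_sequence(genome, c) for c in controls
                )
            ],
            {"MATR3_UUCUU": config.motif},
        )
        over.to_csv(outdir / "motif_overrepresentation.tsv", sep="\t", index=False)
        profile = positional_enrichment(
            tops, controls, genome, motif=config.motif, window=config.window,
            max_offset=config.max_offset, counter=counter,
        )
        profile.to_frame().to_csv(
            outdir / "motif_positional.tsv", sep="\t", index=False
        )
        motif_stage.update(
            n_top=len(tops), n_controls=len(controls),
            n_offsets=profile.n_offsets_tested,
        )
    manifest["stages"]["motif"] = motif_stage

    # -- diffbind (optional) ----------------------------------------------
    gain_genes: set[str] = set()
    loss_genes: set[str] = set()
    if config.ko_fragments and selected:
        ko_frags = {s: read_bed6(p) for s, p in config.ko_fragments.items()}
        ko_counter = RegionCounter(ko_frags)
        peak_ids = [f"peak_{i}" for i in range(len(selected))]
        wt_counts = [
            [counter.count(s, *r.interval()) for s in ("IP1", "IP2")]
            for r in selected
        ]
        ko_counts = [
            [ko_counter.count(s, *r.interval()) for s in ("IP1", "IP2")]
            for r in selected
        ]
        libs = {
            "WT_IP1": counter.totals["IP1"], "WT_IP2": counter.totals["IP2"],
            "KO_IP1": ko_counter.totals["IP1"], "KO_IP2": ko_counter.totals["IP2"],
        }
        diff = differential_binding(peak_ids, wt_counts, ko_counts, libs,
                                    fdr_threshold=config.max_fdr)
        diff_df = differential_to_frame(diff)
        diff_df.to_csv(outdir / "differential_binding.tsv", sep="\t", index=False)
        hosts = {pid: r.host_gene for pid, r in zip(peak_ids, selected)}
        gain_genes = genes_with_class(diff, hosts, "Gain")
        loss_genes = genes_with_class(diff, hosts, "Loss")
        manifest["stages"]["diffbind"] = {
            "n_consensus": len(diff),
            "n_gain": sum(r.klass == "Gain" for r in diff),
            "n_loss": sum(r.klass == "Loss" for r in diff),
        }

    # -- enrich (optional) ------------------------------------------------
    if config.deg_table and selected:
        degs = pd.read_csv(config.deg_table, sep="\t")
        deg_classes = dict(zip(degs["gene_id"], degs["class"]))
        targets = {r.host_gene for r in selected if r.host_gene is not None}
        cpm_idx = cpm.set_index("gene_id")
        universe = set(cpm_idx.index[cpm_idx["Input_cpm"] > 0]) | set(deg_classes)
        rows = []
        for klass in sorted(set(deg_classes.values())):
            members = {g for g, c in deg_classes.items() if c == klass}
            res = overlap_enrichment(targets & universe, members, universe)
            rows.append(
                {
                    "class": klass, "n_class": res.n_class,
                    "n_targets_in_class": res.n_targets_in_class,
                    "percentage": res.percentage,
                    "odds_ratio": res.odds_ratio, "p": res.p,
                }
            )
        pd.DataFrame(rows).to_csv(
            outdir / "target_deg_enrichment.tsv", sep="\t", index=False
        )
        dist, loss_p = gain_loss_distribution(gain_genes, loss_genes, deg_classes)
        dist.to_csv(outdir / "gain_loss_distribution.tsv", sep="\t", index=False)
        manifest["stages"]["enrich"] = {
            "n_deg_classes": len(rows), "loss_in_down_fisher_p": loss_p,
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _control_sequence(genome, control) -> str:
    from .motifs import rna_window

    return rna_window(genome, control.chrom, control.strand, control.start, control.end)
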