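import numpy as np
import pytest

from clipforge.annotation import Annotation, TranscriptModel
from clipforge.binning import build_count_matrix, gene_level_cpm, make_bins
from clipforge.peaks import call_peaks
from clipforge.simulate import (
    SimulationConfig,
    build_toy_genome,
    plant_motif_sites,
    simulate_clip_experiment,
)


@pytest.fixture(scope="session")
def wt_run():
    """One full WT simulation + peak-calling pass, shared across tests."""
    cfg = SimulationConfig(seed=1)
    genome, annotation, truth = build_toy_genome(cfg)
    plant_motif_sites(genome, truth, cfg)
    fragments = simulate_clip_experiment(genome, annotation, truth, cfg, "WT")
    grid = make_bins({c: len(s) for c, s in genome.items()}, cfg.bin_width)
    matrix = build_count_matrix(fragments, grid, annotation)
    cpm = gene_level_cpm(fragments, annotation)
    regions, attrition = call_peaks(
        matrix, fragments, annotation, gene_cpm=cpm
    )
    return {
        "config": cfg,
        "genome": genome,
        "annotation": annotation,
        "truth": truth,
        "fragments": fragments,
        "grid": grid,
        "matrix": matrix,
        "cpm": cpm,
        "regions": regions,
        "attrition": attrition,
        "selected": [r for r in regions if r.selected],
    }


@pytest.fixture()
def toy_annotation():
    """Two-gene annotation on one 10 kb chromosome, plus an rRNA gene."""
    coding = TranscriptModel(
        gene_id="gA",
        transcript_id="gA.t1",
        chrom="chr1",
        strand="+",
        biotype="protein_coding",
        exons=[(1000, 1400), (2000, 2400), (3000, 3400)],
        cds=[(1200, 1400), (2000, 2400), (3000, 3100)],
    )
    lnc = TranscriptModel(
        gene_id="gB",
        transcript_id="gB.t1",
        chrom="chr1",
        strand="-",
        biotype="lncRNA",
        exons=[(5000, 5600), (6400, 6800)],
    )
    rrna = TranscriptModel(
        gene_id="gR",
        transcript_id="gR.t1",
        chrom="chr1",
        strand="+",
        biotype="rRNA",
        exons=[(8000, 8500)],
    )
    return Annotation([coding, lnc, rrna])
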