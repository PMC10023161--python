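"""WT-vs-KO differential binding and target/DEG overlap statistics.

Differential binding re-counts WT-selected consensus peaks in the IP
replicates of both conditions, normalises by library size, estimates a
single common negative-binomial dispersion across peaks by moment matching
on the replicate pairs, and applies a two-sided NB exact test per peak
(conditioning on the pooled WT+KO count, edgeR-style: the p-value sums the
conditional probabilities of all outcomes no more likely than the observed
one).  BH across peaks; significant peaks are classed Gain (more binding
in KO) or Loss (less binding in KO).

Overlap statistics are plain 2x2 Fisher tests on gene sets (targets vs a
DEG class within a universe), reported with the percentage of the class
that are targets — the headline arithmetic of target/DEG comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .peaks import bh_adjust


class DifferentialError(ValueError):
    pass


@dataclass
class DifferentialPeakResult:
    peak_id: str
    norm_mean_wt: float
    norm_mean_ko: float
    log2fc: float  # KO vs WT
    p: float
    fdr: float = np.nan
    klass: str = "NS"  # Gain | Loss | NS


def estimate_common_dispersion(
    wt: np.ndarray, ko: np.ndarray
) -> float:
    """Moment-matching common NB dispersion phi (var = m + phi m^2).

    For duplicate counts x1, x2 with common mean m, E[(x1-x2)^2/2] =
    m + phi m^2; phi is estimated by pooling the excess over all
    peak-condition pairs, clipped at zero.
    """
    num = 0.0
    den = 0.0
    for pair in (wt, ko):
        x1, x2 = pair[:, 0], pair[:, 1]
        m = (x1 + x2) / 2.0
        num += float((((x1 - x2) ** 2) / 2.0 - m).sum())
        den += float((m**2).sum())
    if den <= 0:
        return 0.0
    return max(num / den, 0.0)


def _nb_exact_p(a: int, b: int, phi: float) -> float:
    """Two-sided exact test of a == b for summed duplicate NB counts.

    Under the null both condition sums share mean (a+b)/2 and size
    2/phi (two replicates each of size 1/phi); conditional on s = a+b the
    p-value sums P(B=j | s) over outcomes no more likely than the observed.
    phi = 0 is the Poisson limit, where the conditional law is
    Binomial(s, 1/2).
    """
    s = a + b
    if s == 0:
        return 1.0
    j = np.arange(s + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(j, s, 0.5)
    else:
        size = 2.0 / phi
        mean = s / 2.0
        pr = size / (size + mean)
        lg = stats.nbinom.logpmf(j, size, pr) + stats.nbinom.logpmf(s - j, size, pr)
        logp = lg - special.logsumexp(lg)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[b]
    return float(min(probs[probs <= obs * (1 + 1e-12)].sum(), 1.0))


def differential_binding(
    peak_ids: list[str],
    wt_counts: np.ndarray,
    ko_counts: np.ndarray,
    library_sizes: dict[str, int] | None = None,
    wt_samples: tuple[str, str] = ("WT_IP1", "WT_IP2"),
    ko_samples: tuple[str, str] = ("KO_IP1", "KO_IP2"),
    fdr_threshold: float = 0.05,
    fixed_dispersion: float | None = None,
) -> list[DifferentialPeakResult]:
    """Classify consensus peaks as Gain/Loss/NS between conditions.

    ``wt_counts`` and ``ko_counts`` are (n_peaks x 2) raw fragment counts
    over the consensus peaks in the two IP replicates of each condition;
    ``library_sizes`` maps sample names to total mapped fragments.  Counts
    are scaled to the mean library size, a common dispersion is estimated
    (unless ``fixed_dispersion`` is given), and each peak receives a
    two-sided NB exact p, BH-adjusted across peaks.
    """
    wt = np.asarray(wt_counts, dtype=float)
    ko = np.asarray(ko_counts, dtype=float)
    if wt.shape != (len(peak_ids), 2) or ko.shape != (len(peak_ids), 2):
        raise DifferentialError("need 2 replicates per condition for every peak")
    if library_sizes is None:
        library_sizes = {s: 1 for s in (*wt_samples, *ko_samples)}
    libs = np.array(
        [library_sizes[s] for s in (*wt_samples, *ko_samples)], dtype=float
    )
    if (libs <= 0).any():
        raise DifferentialError("library sizes must be positive")
    ref = libs.mean()
    wt_n = wt * (ref / libs[:2])
    ko_n = ko * (ref / libs[2:])

    phi = (
        fixed_dispersion
        if fixed_dispersion is not None
        else estimate_common_dispersion(wt_n, ko_n)
    )

    results = []
    pvals = []
    for i, pid in enumerate(peak_ids):
        a = int(round(wt_n[i].sum()))
        b = int(round(ko_n[i].sum()))
        p = _nb_exact_p(a, b, phi)
        pvals.append(p)
        m_wt, m_ko = wt_n[i].mean(), ko_n[i].mean()
        log2fc = float(np.log2((b + 0.5) / (a + 0.5)))
        results.append(
            DifferentialPeakResult(
                peak_id=pid, norm_mean_wt=float(m_wt), norm_mean_ko=float(m_ko),
                log2fc=log2fc, p=p,
            )
        )
    fdr = bh_adjust(pvals)
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        if q < fdr_threshold and r.log2fc > 0:
            r.klass = "Gain"
        elif q < fdr_threshold and r.log2fc < 0:
            r.klass = "Loss"
    return results


def differential_to_frame(results: list[DifferentialPeakResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [r.peak_id for r in results],
            "norm_mean_wt": [r.norm_mean_wt for r in results],
            "norm_mean_ko": [r.norm_mean_ko for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "class": [r.klass for r in results],
        }
    )


# ---------------------------------------------------------------------------
# gene-set overlap statistics
# ---------------------------------------------------------------------------

@dataclass
class OverlapEnrichmentResult:
    n_targets_in_class: int
    n_class: int
    n_targets: int
    n_universe: int
    percentage: float  # 100 * targets-in-class / class size
    odds_ratio: float
    p: float
    degenerate: bool = False

    @property
    def table(self) -> list[list[int]]:
        a = self.n_targets_in_class
        return [
            [a, self.n_class - a],
            [self.n_targets - a, self.n_universe - self.n_class - self.n_targets + a],
        ]


def overlap_enrichment(
    target_genes: set[str], class_genes: set[str], universe_genes: set[str]
) -> OverlapEnrichmentResult:
    """Two-sided Fisher test of target enrichment within a gene class.

    The 2x2 table partitions the universe by target membership and class
    membership.  The reported percentage (share of the class bound) only
    depends on targets and class; the p-value also depends on the universe.
    """
    if not class_genes or not universe_genes:
        raise DifferentialError("class and universe must be non-empty")
    if not class_genes <= universe_genes or not target_genes <= universe_genes:
        raise DifferentialError("targets and class must be subsets of the universe")
    a = len(target_genes & class_genes)
    b = len(class_genes) - a
    c = len(target_genes) - a
    d = len(universe_genes) - len(class_genes) - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], "two-sided")
    degenerate = not np.isfinite(odds)
    return OverlapEnrichmentResult(
        n_targets_in_class=a, n_class=len(class_genes),
        n_targets=len(target_genes), n_universe=len(universe_genes),
        percentage=100.0 * a / len(class_genes),
        odds_ratio=float(odds), p=float(p), degenerate=degenerate,
    )


def gain_loss_distribution(
    gain_genes: set[str],
    loss_genes: set[str],
    deg_classes: dict[str, str],
) -> tuple[pd.DataFrame, float]:
    """Distribution of Gain/Loss peak-carrying genes across DEG classes.

    ``deg_classes`` maps gene_id to a class label (e.g. down/invariant/up).
    Returns per-class counts and percentages of genes carrying >= 1 Gain
    (resp. Loss) peak, plus the two-sided Fisher p for enrichment of Loss
    carriers among down-class genes versus the rest.
    """
    classes = sorted(set(deg_classes.values()))
    rows = []
    for k in classes:
        members = {g for g, c in deg_classes.items() if c == k}
        n = len(members)
        ng = len(members & gain_genes)
        nl = len(members & loss_genes)
        rows.append(
            {
                "class": k, "n_genes": n,
                "n_gain": ng, "pct_gain": 100.0 * ng / n if n else 0.0,
                "n_loss": nl, "pct_loss": 100.0 * nl / n if n else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    down = {g for g, c in deg_classes.items() if c == "down"}
    rest = set(deg_classes) - down
    a = len(down & loss_genes)
    b = len(down) - a
    c = len(rest & loss_genes)
    d = len(rest) - c
    if down and rest:
        p = float(stats.fisher_exact([[a, b], [c, d]], "two-sided")[1])
    else:
        p = 1.0
    if not loss_genes:
        p = 1.0
    return df, p


def genes_with_class(
    diff_results: list[DifferentialPeakResult],
    peak_hosts: dict[str, str | None],
    klass: str,
) -> set[str]:
    """Genes carrying at least one differential peak of the given class."""
    return {
        peak_hosts[r.peak_id]
        for r in diff_results
        if r.klass == klass and peak_hosts.get(r.peak_id) is not None
    }
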