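"""Target-gene calling, per-species summaries, and ChIP-peak annotation.

A gene is a target of the transcription factor if at least one motif hit
overlaps its introns, exons, or the 10 kb window upstream of the TSS; the
gene's affinity score is the best (maximum) hit score among those hits.
Per-species statistics are the target-gene ratio (targets / all genes) and
the mean affinity over target genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, RegionSet, derive_regions
from .motif import MotifHit, PositionWeightMatrix, scan, score_distribution

PEAK_CLASSES = (
    "5'UTR",
    "Coding Exon",
    "3'UTR",
    "Intron",
    "UpStream",
    "DownStream",
    "Distal_Region",
)


@dataclass(frozen=True)
class GeneTargetCall:
    gene_id: str
    is_target: bool
    n_hits: int
    affinity: float | None  # best contributing hit score; None when no hits

    def __post_init__(self):
        if self.is_target != (self.n_hits >= 1):
            raise ValueError("is_target must equal n_hits >= 1")


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    hibernator: int
    n_genes: int
    n_targets: int
    target_ratio: float
    mean_affinity: float | None


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def call_target(hits: Sequence[MotifHit], regions: RegionSet) -> GeneTargetCall:
    """Count hits overlapping (>= 1 bp) any labeled region of the gene."""
    contributing = [
        h
        for h in hits
        if h.seq_id == regions.chrom
        and any(_overlaps((h.start, h.end), iv) for _, iv in regions.labeled())
    ]
    n = len(contributing)
    return GeneTargetCall(
        gene_id=regions.gene_id,
        is_target=n >= 1,
        n_hits=n,
        affinity=max(h.score for h in contributing) if n else None,
    )


def call_targets(
    hits: Sequence[MotifHit],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    upstream_kb: float = 10.0,
) -> list[GeneTargetCall]:
    """Target call for every gene, with hits bucketed by chromosome first."""
    by_chrom: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.seq_id, []).append(h)
    calls = []
    for gene in genes:
        regions = derive_regions(gene, chrom_sizes[gene.chrom], upstream_kb)
        calls.append(call_target(by_chrom.get(gene.chrom, []), regions))
    return calls


def summarize_species(
    calls: Sequence[GeneTargetCall], species: str, hibernator: int
) -> SpeciesSummary:
    if not calls:
        raise ValueError("no gene calls to summarize")
    affinities = [c.affinity for c in calls if c.is_target]
    n_targets = len(affinities)
    return SpeciesSummary(
        species=species,
        hibernator=int(hibernator),
        n_genes=len(calls),
        n_targets=n_targets,
        target_ratio=n_targets / len(calls),
        mean_affinity=float(np.mean(affinities)) if n_targets else None,
    )


def threshold_sweep(
    pwm: PositionWeightMatrix,
    sequences: Mapping[str, str],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    thresholds: Sequence[float],
    species: str = "species",
    hibernator: int = 0,
    upstream_kb: float = 10.0,
    two_strand: bool = True,
) -> dict[float, SpeciesSummary]:
    """Re-call targets at several scan p-value thresholds.

    The scan runs once at the loosest threshold; stricter thresholds filter
    the hit list, which is equivalent to independent scans and guarantees
    the target ratio is monotone in the threshold.
    """
    if not thresholds:
        return {}
    dist = score_distribution(pwm)
    loosest = max(thresholds)
    all_hits = scan(pwm, sequences, pval_upper=loosest, two_strand=two_strand, dist=dist)
    out = {}
    for t in thresholds:
        hits = [h for h in all_hits if h.pvalue <= t]
        calls = call_targets(hits, genes, chrom_sizes, upstream_kb)
        out[t] = summarize_species(calls, species, hibernator)
    return out


@dataclass(frozen=True)
class PeakAnnotationSummary:
    counts: dict[str, int]
    ratios: dict[str, float]
    n_peaks: int


def _classify_midpoint(
    mid: int, genes_on_chrom: Sequence[GeneModel], distal: int
) -> str:
    """Class of one midpoint under the fixed precedence order."""
    best = len(PEAK_CLASSES) - 1  # Distal_Region
    for g in genes_on_chrom:
        if g.start <= mid < g.end:
            if any(a <= mid < b for a, b in g.utr5):
                cls = "5'UTR"
            elif any(a <= mid < b for a, b in g.cds):
                cls = "Coding Exon"
            elif any(a <= mid < b for a, b in g.utr3):
                cls = "3'UTR"
            elif any(a <= mid < b for a, b in g.exons):
                # exon without CDS/UTR sub-annotation
                cls = "Coding Exon"
            else:
                cls = "Intron"
        else:
            # flank: upstream/downstream of the gene, strand-aware
            if g.strand == "+":
                upstream_side = mid < g.start
                dist = g.start - mid if upstream_side else mid - g.end + 1
            else:
                upstream_side = mid >= g.end
                dist = mid - g.end + 1 if upstream_side else g.start - mid
            if dist > distal:
                continue
            cls = "UpStream" if upstream_side else "DownStream"
        best = min(best, PEAK_CLASSES.index(cls))
    return PEAK_CLASSES[best]


def annotate_peaks(
    peaks: Sequence[tuple[str, int, int]],
    genes: Sequence[GeneModel],
    distal_kb: float = 20.0,
) -> PeakAnnotationSummary:
    """Assign each peak (by midpoint) to one genomic class.

    Precedence: 5'UTR > Coding Exon > 3'UTR > Intron > UpStream > DownStream
    > Distal_Region (further than ``distal_kb`` from every gene).
    """
    distal = int(round(distal_kb * 1000))
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    counts = {c: 0 for c in PEAK_CLASSES}
    for chrom, start, end in peaks:
        if end <= start:
            raise ValueError(f"malformed peak interval: {chrom}:{start}-{end}")
        mid = (start + end) // 2
        counts[_classify_midpoint(mid, by_chrom.get(chrom, []), distal)] += 1
    n = sum(counts.values())
    ratios = {c: (counts[c] / n if n else math.nan) for c in PEAK_CLASSES}
    return PeakAnnotationSummary(counts=counts, ratios=ratios, n_peaks=n)


def read_bed_peaks(path) -> list[tuple[str, int, int]]:
    """Read BED3+ peak intervals."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            peaks.append((f[0], int(f[1]), int(f[2])))
    return peaks


def calls_to_table(calls: Iterable[GeneTargetCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "is_target": int(c.is_target),
                "n_hits": c.n_hits,
                "affinity": c.affinity if c.affinity is not None else np.nan,
            }
            for c in calls
        ]
    )


def summaries_to_table(summaries: Iterable[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "hibernator": s.hibernator,
                "n_genes": s.n_genes,
                "n_targets": s.n_targets,
                "target_ratio": s.target_ratio,
                "mean_affinity": s.mean_affinity
                if s.mean_affinity is not None
                else np.nan,
            }
            for s in summaries
        ]
    )
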