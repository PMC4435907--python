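"""End-to-end convenience wrappers: genome -> scan -> target calls -> traits."""

from __future__ import annotations

import numpy as np

from .motif import PositionFrequencyMatrix, build_background, pfm_to_pwm, scan
from .simulate import SyntheticCohort, SyntheticGenome, example_pfm
from .targets import SpeciesSummary, call_targets, summarize_species
from .traits import TraitTable


def analyze_genome(
    genome: SyntheticGenome,
    pfm: PositionFrequencyMatrix | None = None,
    pval_upper: float = 5e-7,
    species: str = "species",
    bg_pseudo: float = 0.01,
    pseudocount: float = 1.0,
    decimals: int = 1,
) -> SpeciesSummary:
    """Scan one species genome and summarise its target genes.

    The background model is estimated from the species' own scanned
    sequences, so affinity scores are per-species log-odds.
    """
    if pfm is None:
        pfm = example_pfm()
    bg = build_background(genome.sequences.values(), bg_pseudo=bg_pseudo)
    pwm = pfm_to_pwm(pfm, bg, pseudocount=pseudocount, decimals=decimals)
    hits = scan(pwm, genome.sequences, pval_upper=pval_upper, two_strand=True)
    sizes = {name: len(seq) for name, seq in genome.sequences.items()}
    calls = call_targets(hits, genome.genes, sizes, upstream_kb=genome.recipe.upstream_kb)
    return summarize_species(calls, species=species, hibernator=genome.recipe.hibernator)


def analyze_cohort(
    cohort: SyntheticCohort,
    pfm: PositionFrequencyMatrix | None = None,
    pval_upper: float = 5e-7,
    statistic: str = "mean_affinity",
) -> tuple[list[SpeciesSummary], TraitTable]:
    """Per-species summaries plus the trait table for a chosen statistic.

    ``statistic`` is ``mean_affinity`` or ``target_ratio``; species with no
    target genes contribute a mean affinity of NaN and are dropped from the
    trait table (they keep their row in the summaries).
    """
    if statistic not in ("mean_affinity", "target_ratio"):
        raise ValueError("statistic must be mean_affinity or target_ratio")
    summaries = [
        analyze_genome(cohort.genomes[sp], pfm=pfm, pval_upper=pval_upper, species=sp)
        for sp in cohort.species
    ]
    species, hib, values = [], [], []
    for s in summaries:
        v = s.target_ratio if statistic == "target_ratio" else s.mean_affinity
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        species.append(s.species)
        hib.append(s.hibernator)
        values.append(v)
    table = TraitTable(species=species, hibernator=np.array(hib), value=np.array(values))
    return summaries, table
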