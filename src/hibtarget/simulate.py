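"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its recipe and seed and returns a
machine-readable truth table alongside the data: planted motif sites and
intended target labels for genomes, intended classes for ChIP peaks, true
branch-wise ω for codon alignments, and the true liability/value correlation
for trait tables.  Scaled-down genome sizes keep cohort experiments fast;
the per-gene structure (exons, introns, UTRs, an upstream promoter region)
is regular rather than drawn from realistic genome statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .codonmodel import (
    CodonAlignment,
    CodonModelParams,
    N_CODONS,
    SENSE_CODONS,
    _EigenQ,
)
from .genome import GeneModel, write_gff3
from .motif import BASES, PositionFrequencyMatrix, reverse_complement
from .phylo import phylo_covariance, pure_birth_tree


def example_pfm() -> PositionFrequencyMatrix:
    """A nuclear-receptor-style DR1 matrix (consensus AGGTCAAAGGTCA core).

    Emulates the shape of ChIP-derived nuclear-receptor matrices: a strong
    direct-repeat core (consensus base at 85 of 100 observations per column),
    a near-uniform spacer, and moderately informative 5' flanking columns
    (55 of 100).  Width 20, total information content about 16 bits, so
    thresholded hits span a graded score range rather than collapsing onto
    the consensus score.
    """
    strong = "AGGTCANAGGTCA"
    flank = "CAAAACT"
    cols = []
    for b in flank:
        col = [15, 15, 15, 15]
        col[BASES.index(b)] = 55
        cols.append(col)
    for b in strong:
        if b == "N":
            cols.append([28, 24, 24, 24])
        else:
            col = [5, 5, 5, 5]
            col[BASES.index(b)] = 85
            cols.append(col)
    return PositionFrequencyMatrix(np.array(cols, dtype=float).T)


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str
    region: str  # upstream | exon | intron
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str


@dataclass
class GenomeRecipe:
    """Scaled-down single-chromosome genome with planted motif sites.

    ``site_rates`` give the expected (Poisson) number of planted sites per
    gene in each region kind; ``strength`` interpolates between sampling
    site bases from the PFM columns (0) and always planting the consensus
    base (1).
    """

    n_genes: int = 20
    chrom_length: int = 600_000
    n_exons: int = 4
    exon_length: int = 200
    intron_length: int = 1_500
    utr_length: int = 50
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    site_rates: dict = field(
        default_factory=lambda: {"upstream": 0.5, "exon": 0.0, "intron": 0.2}
    )
    strength: float = 0.75
    upstream_kb: float = 10.0
    hibernator: int = 0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if any(v < 0 for v in self.site_rates.values()):
            raise ValueError("site rates must be >= 0")
        if min(self.n_genes, self.exon_length, self.intron_length) <= 0:
            raise ValueError("counts and lengths must be positive")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    planted: list[PlantedSite]
    target_truth: dict[str, bool]
    recipe: GenomeRecipe

    def write(self, fasta_path, gff3_path, truth_path=None) -> None:
        with open(fasta_path, "w") as fh:
            for name in sorted(self.sequences):
                seq = self.sequences[name]
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_gff3(self.genes, gff3_path)
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                json.dump(
                    {
                        "planted": [asdict(s) for s in self.planted],
                        "target_truth": self.target_truth,
                    },
                    fh,
                    indent=1,
                )


def _sample_site(
    pfm: PositionFrequencyMatrix, strength: float, rng: np.random.Generator
) -> str:
    probs = pfm.counts / pfm.column_totals
    consensus = np.argmax(pfm.counts, axis=0)
    out = []
    for j in range(pfm.width):
        if rng.random() < strength:
            out.append(BASES[consensus[j]])
        else:
            out.append(BASES[rng.choice(4, p=probs[:, j])])
    return "".join(out)


def generate_genome(
    recipe: GenomeRecipe, pfm: PositionFrequencyMatrix | None = None
) -> SyntheticGenome:
    """One chromosome of i.i.d. background with regular, non-overlapping
    genes and motif sites planted into the designated gene regions."""
    if pfm is None:
        pfm = example_pfm()
    rng = np.random.default_rng(recipe.seed)
    chrom = "chr1"
    upstream = int(round(recipe.upstream_kb * 1000))
    gene_span = (
        recipe.n_exons * recipe.exon_length
        + (recipe.n_exons - 1) * recipe.intron_length
    )
    slot = recipe.chrom_length // recipe.n_genes
    margin = 2_000
    # each gene plus its strand-side upstream window must fit its own slot,
    # so truth labels cannot leak between neighbouring genes
    if gene_span + 2 * upstream + margin > slot:
        raise ValueError(
            f"cannot place {recipe.n_genes} genes of span {gene_span} "
            f"plus {upstream} bp upstream in {recipe.chrom_length} bp"
        )
    comp = np.asarray(recipe.composition)
    if np.allclose(comp, 0.25):
        codes = rng.integers(0, 4, size=recipe.chrom_length)
    else:
        codes = rng.choice(4, size=recipe.chrom_length, p=comp)

    genes: list[GeneModel] = []
    planted: list[PlantedSite] = []
    target_truth: dict[str, bool] = {}
    base_arr = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    seq_arr = base_arr[codes].copy()

    for g in range(recipe.n_genes):
        gene_id = f"g{g + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        # keep the upstream window inside the slot on either strand
        lo = g * slot + upstream
        hi = (g + 1) * slot - upstream - gene_span
        start = int(rng.integers(lo, max(lo + 1, hi)))
        exons = []
        pos = start
        for _ in range(recipe.n_exons):
            exons.append((pos, pos + recipe.exon_length))
            pos += recipe.exon_length + recipe.intron_length
        end = exons[-1][1]
        utr = recipe.utr_length
        if strand == "+":
            utr5 = [(exons[0][0], exons[0][0] + utr)]
            utr3 = [(exons[-1][1] - utr, exons[-1][1])]
        else:
            utr5 = [(exons[-1][1] - utr, exons[-1][1])]
            utr3 = [(exons[0][0], exons[0][0] + utr)]
        cds = []
        for a, b in exons:
            lo_c = max(a, utr3[0][1] if strand == "-" else utr5[0][1]) if a == exons[0][0] else a
            hi_c = min(b, utr5[0][0] if strand == "-" else utr3[0][0]) if b == exons[-1][1] else b
            if hi_c > lo_c:
                cds.append((lo_c, hi_c))
        gene = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
        )
        genes.append(gene)

        regions = {
            "upstream": [
                (start - upstream, start) if strand == "+" else (end, end + upstream)
            ],
            "exon": exons,
            "intron": gene.introns,
        }
        any_site = False
        for kind, intervals in regions.items():
            rate = recipe.site_rates.get(kind, 0.0)
            if rate <= 0 or not intervals:
                continue
            n_sites = rng.poisson(rate)
            for _ in range(n_sites):
                iv = intervals[int(rng.integers(len(intervals)))]
                if iv[1] - iv[0] <= pfm.width:
                    continue
                s0 = int(rng.integers(iv[0], iv[1] - pfm.width))
                site = _sample_site(pfm, recipe.strength, rng)
                site_strand = "+" if rng.random() < 0.5 else "-"
                written = site if site_strand == "+" else reverse_complement(site)
                seq_arr[s0 : s0 + pfm.width] = np.frombuffer(
                    written.encode(), dtype=np.uint8
                )
                planted.append(
                    PlantedSite(
                        gene_id=gene_id,
                        region=kind,
                        chrom=chrom,
                        start=s0,
                        end=s0 + pfm.width,
                        strand=site_strand,
                        sequence=written,
                    )
                )
                any_site = True
        target_truth[gene_id] = any_site

    return SyntheticGenome(
        sequences={chrom: seq_arr.tobytes().decode()},
        genes=genes,
        planted=planted,
        target_truth=target_truth,
        recipe=recipe,
    )


@dataclass
class CohortRecipe:
    """A tree-structured cohort of species genomes with a hibernator uplift.

    Defaults emulate the study design the package targets: 64 mammalian
    species of which 16 hibernate, with hibernators receiving both a higher
    planted-site rate and stronger (closer-to-consensus) sites.
    """

    n_species: int = 64
    n_hibernators: int = 16
    tree: dendropy.Tree | None = None
    base: GenomeRecipe = field(default_factory=GenomeRecipe)
    rate_uplift: float = 0.5  # added to each per-region planting rate
    strength_uplift: float = 0.15  # added to planting strength (capped at 1)
    seed: int = 0

    def __post_init__(self):
        if self.rate_uplift < 0 or self.strength_uplift < 0:
            raise ValueError("uplifts must be >= 0")
        if not 0 < self.n_hibernators < self.n_species:
            raise ValueError("need both hibernators and non-hibernators")


@dataclass
class SyntheticCohort:
    tree: dendropy.Tree
    species: list[str]
    hibernator: dict[str, int]
    genomes: dict[str, SyntheticGenome]
    recipe: CohortRecipe


def generate_cohort(
    recipe: CohortRecipe, pfm: PositionFrequencyMatrix | None = None
) -> SyntheticCohort:
    """Per-species genomes on a (possibly simulated) tree.

    Hibernator status is clumped on the tree (contiguous tips in tree order)
    so the binary trait carries phylogenetic signal, as a real hibernation
    trait does.
    """
    rng = np.random.default_rng(recipe.seed)
    tree = recipe.tree or pure_birth_tree(recipe.n_species, seed=recipe.seed)
    taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(taxa) != recipe.n_species and recipe.tree is not None:
        recipe.n_species = len(taxa)
    # clumped assignment: a random contiguous block of tips in tree order
    start = int(rng.integers(len(taxa) - recipe.n_hibernators + 1))
    hib_set = set(taxa[start : start + recipe.n_hibernators])
    genomes = {}
    hib = {}
    for k, sp in enumerate(taxa):
        is_h = int(sp in hib_set)
        hib[sp] = is_h
        base = recipe.base
        rates = dict(base.site_rates)
        strength = base.strength
        if is_h:
            # uplift only where the base process is active (zero-rate regions stay off)
            rates = {
                kind: (v + recipe.rate_uplift if v > 0 else v)
                for kind, v in rates.items()
            }
            strength = min(1.0, strength + recipe.strength_uplift)
        sub = GenomeRecipe(
            n_genes=base.n_genes,
            chrom_length=base.chrom_length,
            n_exons=base.n_exons,
            exon_length=base.exon_length,
            intron_length=base.intron_length,
            utr_length=base.utr_length,
            composition=base.composition,
            site_rates=rates,
            strength=strength,
            upstream_kb=base.upstream_kb,
            hibernator=is_h,
            seed=int(rng.integers(2**31 - 1)),
        )
        genomes[sp] = generate_genome(sub, pfm=pfm)
    return SyntheticCohort(
        tree=tree, species=taxa, hibernator=hib, genomes=genomes, recipe=recipe
    )


def simulate_codon_alignment(
    tree: dendropy.Tree,
    params: CodonModelParams,
    n_codons: int,
    seed: int,
    branch_classes: Mapping[int, int] | None = None,
) -> CodonAlignment:
    """Simulate codon columns down the tree under the GY94 branch model.

    The root draws from π; each branch applies exp(Q_class · t).  Stop codons
    cannot arise because the state space is the 61 sense codons.
    """
    rng = np.random.default_rng(seed)
    pi = params.pi
    root_states = rng.choice(N_CODONS, size=n_codons, p=pi / pi.sum())
    states = {id(tree.seed_node): root_states}
    eigen_cache: dict[float, _EigenQ] = {}
    out_taxa, out_seqs = [], []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        cls = (branch_classes or {}).get(id(node), 0)
        omega = params.omegas.get(cls, params.omegas.get(0, 1.0))
        if omega not in eigen_cache:
            eigen_cache[omega] = _EigenQ(params.kappa, omega, pi)
        t = node.edge.length or 0.0
        P = eigen_cache[omega].transition(t)
        Pcum = np.cumsum(P, axis=1)
        parent_states = states[id(node.parent_node)]
        u = rng.random(n_codons)
        child = (Pcum[parent_states] < u[:, None]).sum(axis=1)
        child = np.minimum(child, N_CODONS - 1)
        states[id(node)] = child
        if node.is_leaf():
            out_taxa.append(node.taxon.label)
            out_seqs.append("".join(SENSE_CODONS[s] for s in child))
    return CodonAlignment(out_taxa, out_seqs)


def simulate_threshold_traits(
    tree: dendropy.Tree, r: float, seed: int, max_tries: int = 100
):
    """Bivariate Brownian (liability, value) tips with correlation ``r``;
    the binary state is liability > 0.  Returns (TraitTable, truth dict)."""
    from .traits import TraitTable

    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    taxa, C = phylo_covariance(tree)
    Lc = np.linalg.cholesky(C + 1e-12 * np.eye(len(taxa)))
    R = np.array([[1.0, r], [r, 1.0]])
    Lr = np.linalg.cholesky(R + 1e-12 * np.eye(2))
    for k in range(max_tries):
        rng = np.random.default_rng((seed + k) % 2**31)
        Z = rng.standard_normal((len(taxa), 2))
        Y = Lc @ Z @ Lr.T
        liability, value = Y[:, 0], Y[:, 1]
        binary = (liability > 0).astype(int)
        if 0 < binary.sum() < len(taxa):
            table = TraitTable(species=taxa, hibernator=binary, value=value)
            truth = {
                "r": r,
                "seed_used": (seed + k) % 2**31,
                "liability": dict(zip(taxa, liability.tolist())),
            }
            return table, truth
    raise RuntimeError(
        f"could not draw a non-constant binary trait in {max_tries} tries"
    )


def generate_chip_peaks(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    class_mix: Mapping[str, float],
    n_peaks: int,
    seed: int,
    width: int = 200,
    distal_kb: float = 20.0,
) -> tuple[list[tuple[str, int, int]], list[str]]:
    """Peaks whose midpoints fall in requested genomic classes.

    Returns (peaks, intended classes); placement is validated against the
    same precedence rules the annotator uses, so the truth table is exact.
    """
    from .targets import PEAK_CLASSES, _classify_midpoint

    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise ValueError("class mix must sum to 1")
    unknown = set(class_mix) - set(PEAK_CLASSES)
    if unknown:
        raise ValueError(f"unknown peak classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    distal = int(round(distal_kb * 1000))
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    def candidates(cls: str) -> list[tuple[str, int, int]]:
        out = []
        for g in genes:
            if cls == "5'UTR":
                out += [(g.chrom, a, b) for a, b in g.utr5]
            elif cls == "Coding Exon":
                out += [(g.chrom, a, b) for a, b in g.cds]
            elif cls == "3'UTR":
                out += [(g.chrom, a, b) for a, b in g.utr3]
            elif cls == "Intron":
                out += [(g.chrom, a, b) for a, b in g.introns]
            elif cls == "UpStream":
                if g.strand == "+":
                    out.append((g.chrom, max(0, g.start - distal), g.start))
                else:
                    out.append((g.chrom, g.end, min(chrom_sizes[g.chrom], g.end + distal)))
            elif cls == "DownStream":
                if g.strand == "+":
                    out.append((g.chrom, g.end, min(chrom_sizes[g.chrom], g.end + distal)))
                else:
                    out.append((g.chrom, max(0, g.start - distal), g.start))
        if cls == "Distal_Region":
            for chrom, size in chrom_sizes.items():
                blocked = sorted(
                    (max(0, g.start - distal), min(size, g.end + distal))
                    for g in by_chrom.get(chrom, [])
                )
                pos = 0
                for a, b in blocked:
                    if a - pos > 2 * width:
                        out.append((chrom, pos + width, a - width))
                    pos = max(pos, b)
                if size - pos > 2 * width:
                    out.append((chrom, pos + width, size - width))
        return [iv for iv in out if iv[2] > iv[1]]

    cand = {}
    for cls, frac in class_mix.items():
        if frac > 0:
            cand[cls] = candidates(cls)
            if not cand[cls]:
                raise ValueError(f"requested class {cls!r} absent from annotation")
    classes = [c for c in PEAK_CLASSES if class_mix.get(c, 0) > 0]
    probs = np.array([class_mix[c] for c in classes])
    peaks, intended = [], []
    for _ in range(n_peaks):
        cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
        for _try in range(200):
            chrom, a, b = cand[cls][int(rng.integers(len(cand[cls])))]
            mid = int(rng.integers(a, b))
            if _classify_midpoint(mid, by_chrom.get(chrom, []), distal) == cls:
                half = width // 2
                peaks.append((chrom, max(0, mid - half), mid + (width - half)))
                intended.append(cls)
                break
        else:
            raise RuntimeError(f"could not place a peak of class {cls!r}")
    return peaks, intended


def write_bed3(peaks: Sequence[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        for chrom, a, b in peaks:
            fh.write(f"{chrom}\t{a}\t{b}\n")
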