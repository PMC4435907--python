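"""Gene models, per-gene genomic regions, and TSS-anchored regulatory windows.

Coordinates are 0-based half-open throughout; GFF3 output/input converts
to/from the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

Interval = tuple[int, int]

WINDOW_KINDS = ("TSS_Around", "TSS_Up", "TSS_Body")
WINDOW_SIZES_KB = (2.5, 5.0, 7.5, 10.0)


def _check_intervals(ivs: Sequence[Interval], what: str) -> list[Interval]:
    ivs = sorted((int(a), int(b)) for a, b in ivs)
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"{what} interval with end <= start: ({a}, {b})")
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 < b1:
            raise ValueError(f"{what} intervals overlap: ({a1},{b1}) ({a2},{b2})")
    return ivs


@dataclass
class GeneModel:
    """One canonical transcript per gene.

    ``tss`` is the transcription start: the leftmost exon start on the +
    strand, the base just left of the rightmost exon end on the − strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        self.exons = _check_intervals(self.exons, "exon")
        self.cds = _check_intervals(self.cds, "CDS")
        self.utr5 = _check_intervals(self.utr5, "5'UTR")
        self.utr3 = _check_intervals(self.utr3, "3'UTR")
        if not self.exons:
            raise ValueError("gene must have at least one exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end (the last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[Interval]:
        return [
            (b1, a2) for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]) if a2 > b1
        ]


@dataclass
class RegionSet:
    """Labeled intervals of one gene used for target calling."""

    gene_id: str
    chrom: str
    upstream: list[Interval]
    exon: list[Interval]
    intron: list[Interval]

    def labeled(self) -> list[tuple[str, Interval]]:
        out = [("upstream", iv) for iv in self.upstream]
        out += [("exon", iv) for iv in self.exon]
        out += [("intron", iv) for iv in self.intron]
        return out


def derive_regions(
    gene: GeneModel, chrom_length: int, upstream_kb: float = 10.0
) -> RegionSet:
    """Upstream window (strand-aware, clipped to the chromosome), exons, introns."""
    span = int(round(upstream_kb * 1000))
    if gene.end > chrom_length:
        raise ValueError("gene extends beyond chromosome length")
    if gene.strand == "+":
        up = (max(0, gene.start - span), gene.start)
    else:
        up = (gene.end, min(chrom_length, gene.end + span))
    upstream = [up] if up[1] > up[0] else []
    return RegionSet(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        upstream=upstream,
        exon=list(gene.exons),
        intron=gene.introns,
    )


@dataclass(frozen=True)
class RegulatoryWindow:
    gene_id: str
    kind: str
    size_kb: float
    chrom: str
    start: int
    end: int


def make_windows(
    gene: GeneModel, kind: str, size_kb: float, chrom_length: int | None = None
) -> RegulatoryWindow:
    """TSS-anchored window: upstream (TSS_Up), centered (TSS_Around) or into
    the gene body (TSS_Body); strand-oriented, clipped at chromosome bounds."""
    if kind not in WINDOW_KINDS:
        raise ValueError(f"kind must be one of {WINDOW_KINDS}")
    if size_kb <= 0:
        raise ValueError("size_kb must be positive")
    size = int(round(size_kb * 1000))
    tss = gene.tss
    sign = 1 if gene.strand == "+" else -1
    if kind == "TSS_Up":
        lo, hi = tss - sign * size, tss
    elif kind == "TSS_Body":
        lo, hi = tss, tss + sign * size
    else:  # TSS_Around
        lo, hi = tss - sign * (size // 2), tss + sign * (size - size // 2)
    start, end = (lo, hi) if lo <= hi else (hi + 1, lo + 1)
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return RegulatoryWindow(gene.gene_id, kind, size_kb, gene.chrom, start, end)


# ---------------------------------------------------------------------------
# annotation IO


def _gff3_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


_GFF_EXONIC = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene/mRNA/exon/CDS/UTR features).

    When a gene carries several mRNA isoforms the longest transcript (by
    exonic span) is taken as canonical.
    """
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            chrom, _, ftype, start1, end1, _, strand, _, attrs = f[:9]
            start0, end = int(start1) - 1, int(end1)
            a = _gff3_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID", a.get("gene_id"))
                genes[gid] = {"chrom": chrom, "strand": strand, "transcripts": []}
            elif ftype in ("mRNA", "transcript"):
                tid = a.get("ID")
                parent = a.get("Parent")
                transcripts[tid] = {
                    "gene": parent,
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "utr5": [],
                    "utr3": [],
                }
                if parent in genes:
                    genes[parent]["transcripts"].append(tid)
            elif ftype in _GFF_EXONIC:
                for parent in (a.get("Parent") or "").split(","):
                    if parent in transcripts:
                        transcripts[parent][_GFF_EXONIC[ftype]].append((start0, end))
    out = []
    for gid, g in genes.items():
        tids = g["transcripts"]
        if not tids:
            continue
        best = max(
            tids,
            key=lambda t: (
                max(e for _, e in transcripts[t]["exons"])
                - min(s for s, _ in transcripts[t]["exons"])
                if transcripts[t]["exons"]
                else 0
            ),
        )
        t = transcripts[best]
        if not t["exons"]:
            continue
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=t["chrom"],
                strand=t["strand"],
                exons=t["exons"],
                cds=t["cds"],
                utr5=t["utr5"],
                utr3=t["utr3"],
            )
        )
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = g.gene_id
            fh.write(
                f"{g.chrom}\thibtarget\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}\n"
            )
            tid = f"{gid}.t1"
            fh.write(
                f"{g.chrom}\thibtarget\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={gid}\n"
            )
            for kind, key in (
                ("exon", "exons"),
                ("CDS", "cds"),
                ("five_prime_UTR", "utr5"),
                ("three_prime_UTR", "utr3"),
            ):
                for s, e in getattr(g, key):
                    fh.write(
                        f"{g.chrom}\thibtarget\t{kind}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tParent={tid}\n"
                    )


def read_bed12(path) -> list[GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd taken as the CDS)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            cds = []
            if thick_e > thick_s:
                for a, b in exons:
                    lo, hi = max(a, thick_s), min(b, thick_e)
                    if hi > lo:
                        cds.append((lo, hi))
            out.append(
                GeneModel(
                    gene_id=name, chrom=chrom, strand=strand, exons=exons, cds=cds
                )
            )
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, n = line.split()[:2]
                sizes[name] = int(n)
    return sizes
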