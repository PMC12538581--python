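"""Annotated-genome model: gene features, split-gene merging, intergenic regions.

All coordinates are 0-based half-open on the forward strand.  GenBank input
(1-based inclusive) is converted on read; BED output stays 0-based half-open
and GFF3 output is emitted 1-based inclusive.

The central preprocessing step for insertion-site selection is the handling of
split genes: phage genes interrupted by intron-encoded ORFs (e.g. homing
endonucleases) are annotated as multi-part ``join`` locations.  Such a locus is
collapsed to one contiguous span so that no spurious "intergenic" space opens
up between its parts, and any gene nested wholly inside the collapsed span is
flagged *interior* — it still exists as annotation but does not break
intergenic space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: default extension of the promoter search space into flanking genes, in bp
DEFAULT_EXTENSION = 50

Span = tuple[int, int]


@dataclass
class GeneFeature:
    """One gene locus on the forward coordinate frame.

    ``parts`` holds the original (possibly multi-part) annotation spans;
    for a plain single-span gene it is ``[(start, end)]``.  ``interior``
    marks genes nested inside a merged split-gene locus; interior genes are
    excluded from intergenic computation.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    parts: list[Span] = field(default_factory=list)
    interior: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid span ({self.start}, {self.end})"
            )
        if not self.parts:
            self.parts = [(self.start, self.end)]
        self.parts = sorted(self.parts)
        for (a1, b1), (a2, b2) in zip(self.parts, self.parts[1:]):
            if a2 < b1:
                raise ValueError(f"gene {self.gene_id!r}: overlapping parts")

    @property
    def is_split(self) -> bool:
        return len(self.parts) > 1

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A single-contig genome sequence plus its ordered gene features."""

    seq_id: str
    sequence: str
    genes: list[GeneFeature]
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        self.sequence = self.sequence.upper()
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        seen: set[str] = set()
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(f"gene {g.gene_id!r} exceeds genome length")
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            seen.add(g.gene_id)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def coding_genes(self) -> list[GeneFeature]:
        """Genes that delimit intergenic space (non-interior)."""
        return [g for g in self.genes if not g.interior]

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_seq(self, gene: GeneFeature | str) -> str:
        """Strand-aware gene sequence (reverse-complemented for − genes)."""
        if isinstance(gene, str):
            gene = self.gene(gene)
        s = self.sequence[gene.start : gene.end]
        return s if gene.strand == "+" else reverse_complement(s)


@dataclass
class IntergenicRegion:
    """A maximal span between gene bodies, extended into the flanking genes.

    The core span may be zero-width when two genes abut.  ``ext_start`` /
    ``ext_end`` widen the core by the extension E, clamped to genome bounds.
    """

    region_id: str
    core_start: int
    core_end: int
    ext_start: int
    ext_end: int
    upstream_gene_id: str | None = None
    downstream_gene_id: str | None = None
    wraps: bool = False

    def __post_init__(self) -> None:
        if not self.wraps and self.core_start > self.core_end:
            raise ValueError(f"region {self.region_id!r}: inverted core span")

    def contains(self, start: int, end: int) -> bool:
        """Whether a footprint lies within the extended span."""
        return self.ext_start <= start and end <= self.ext_end


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_genome(genbank_path: str | Path) -> AnnotatedGenome:
    """Parse a single-record GenBank flat file into an :class:`AnnotatedGenome`.

    Every CDS feature becomes one :class:`GeneFeature` (falling back to
    ``gene`` features if the record carries no CDS).  Multi-part ``join``
    locations are preserved in ``parts``; coordinates are converted from
    GenBank 1-based inclusive to 0-based half-open.
    """
    record = SeqIO.read(str(genbank_path), "genbank")
    try:
        sequence = str(record.seq)
    except UndefinedSequenceError as exc:
        raise ValueError(f"{genbank_path}: record has no sequence") from exc
    if not sequence:
        raise ValueError(f"{genbank_path}: record has no sequence")

    feats = [f for f in record.features if f.type == "CDS"]
    if not feats:
        feats = [f for f in record.features if f.type == "gene"]
    if not feats:
        raise ValueError(f"{genbank_path}: no annotations")

    genes: list[GeneFeature] = []
    used_ids: set[str] = set()
    for i, feat in enumerate(feats):
        if feat.location is None or feat.location.strand not in (1, -1):
            raise ValueError(f"feature #{i}: unknown strand")
        q = feat.qualifiers
        gene_id = (
            q.get("locus_tag", q.get("gene", q.get("protein_id", [f"cds_{i:04d}"])))
        )[0]
        if gene_id in used_ids:
            k = 2
            while f"{gene_id}_{k}" in used_ids:
                k += 1
            gene_id = f"{gene_id}_{k}"
        used_ids.add(gene_id)
        parts = sorted((int(p.start), int(p.end)) for p in feat.location.parts)
        genes.append(
            GeneFeature(
                gene_id=gene_id,
                start=parts[0][0],
                end=parts[-1][1],
                strand="+" if feat.location.strand == 1 else "-",
                product=q.get("product", [""])[0],
                parts=parts,
            )
        )
    topology = record.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    return AnnotatedGenome(
        seq_id=record.id or record.name, sequence=sequence, genes=genes, topology=topology
    )


def merge_split_genes(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Collapse multi-part genes to their contiguous hull.

    Any other gene fully contained inside a collapsed hull is flagged
    ``interior`` and creates no intergenic boundary.  Idempotent.
    """
    L = len(genome)
    hulls: list[Span] = []
    merged: list[GeneFeature] = []
    for g in genome.genes:
        if g.is_split:
            lo = min(a for a, _ in g.parts)
            hi = max(b for _, b in g.parts)
            if hi > L:
                raise ValueError(
                    f"gene {g.gene_id!r}: parts span beyond the end of a linear genome"
                )
            hulls.append((lo, hi))
            merged.append(replace(g, start=lo, end=hi, parts=[(lo, hi)]))
        else:
            merged.append(replace(g, parts=list(g.parts)))
    out: list[GeneFeature] = []
    for g in merged:
        inside = any(
            lo <= g.start and g.end <= hi and (g.start, g.end) != (lo, hi)
            for lo, hi in hulls
        )
        out.append(replace(g, interior=g.interior or inside))
    return replace(genome, genes=out)


def _union_spans(spans: Iterable[Span]) -> list[Span]:
    spans = sorted(spans)
    out: list[Span] = []
    for a, b in spans:
        # strict overlap merges; abutting spans stay separate so the
        # zero-width gap between them survives as a degenerate region
        if out and a < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def extract_intergenic_regions(
    genome: AnnotatedGenome, extension: int = DEFAULT_EXTENSION
) -> list[IntergenicRegion]:
    """Compute extended intergenic regions.

    Core spans are the maximal intervals not covered by any non-interior gene
    body.  For linear genomes the terminal spans (before the first and after
    the last gene) are included; for circular genomes the two terminal spans
    are fused into one wrap-around region.  Each region carries coordinates
    widened by ``extension`` into the flanking genes, clamped to genome
    bounds, plus the flanking gene ids.
    """
    if extension < 0:
        raise ValueError("extension must be non-negative")
    L = len(genome)
    covered = _union_spans((g.start, g.end) for g in genome.coding_genes)
    if not covered:
        return [
            IntergenicRegion("ig_0000", 0, L, 0, L)
        ]

    # boundary lookup: which gene body ends/starts at a given coordinate
    end_at = {}
    start_at = {}
    for g in genome.coding_genes:
        end_at.setdefault(g.end, g.gene_id)
        start_at.setdefault(g.start, g.gene_id)

    cores: list[tuple[int, int, bool]] = []  # (start, end, wraps)
    prev = 0
    for a, b in covered:
        if a >= prev:
            cores.append((prev, a, False))
        prev = max(prev, b)
    if prev <= L:
        cores.append((prev, L, False))

    if genome.topology == "circular":
        head = cores[0] if cores and cores[0][0] == 0 else None
        tail = cores[-1] if cores and cores[-1][1] == L else None
        if head is not None and tail is not None and head is not tail:
            cores = cores[1:-1] + [(tail[0], head[1], True)]

    regions: list[IntergenicRegion] = []
    for i, (a, b, wraps) in enumerate(cores):
        if not wraps and (a, b) == (0, L):
            continue  # fully covered complement edge case
        if a == b and (a == 0 or b == L):
            continue  # gene touching the genome edge leaves no terminal region
        if wraps:
            ext_start = (a - extension) % L
            ext_end = (b + extension) % L
        else:
            ext_start = max(0, a - extension)
            ext_end = min(L, b + extension)
        regions.append(
            IntergenicRegion(
                region_id=f"ig_{i:04d}",
                core_start=a,
                core_end=b,
                ext_start=ext_start,
                ext_end=ext_end,
                upstream_gene_id=end_at.get(a),
                downstream_gene_id=start_at.get(b),
                wraps=wraps,
            )
        )
    return regions


def reverse_complement_genome(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Mirror a genome: reverse-complement the sequence and reflect features."""
    L = len(genome)
    genes = [
        replace(
            g,
            start=L - g.end,
            end=L - g.start,
            strand="-" if g.strand == "+" else "+",
            parts=sorted((L - b, L - a) for a, b in g.parts),
        )
        for g in genome.genes
    ]
    return replace(genome, sequence=reverse_complement(genome.sequence), genes=genes)


# ---------------------------------------------------------------------------
# interchange formats


def write_regions_bed(
    regions: Sequence[IntergenicRegion], genome: AnnotatedGenome, path: str | Path
) -> None:
    """Write intergenic cores as BED6 (extended span kept in the name column)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{genome.seq_id}\t{r.core_start}\t{r.core_end}\t"
                f"{r.region_id}|ext:{r.ext_start}-{r.ext_end}\t0\t.\n"
            )


def read_regions_bed(path: str | Path) -> list[IntergenicRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            region_id, ext = name.split("|ext:")
            ext_start, ext_end = (int(x) for x in ext.split("-"))
            regions.append(
                IntergenicRegion(region_id, start, end, ext_start, ext_end)
            )
    return regions


def write_genes_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            if g.interior:
                attrs += ";interior=true"
            fh.write(
                f"{genome.seq_id}\tphagesite\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\t{attrs}\n"
            )


def to_seqrecord(genome: AnnotatedGenome) -> SeqRecord:
    """Build a Biopython SeqRecord (for GenBank output)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.seq_id,
        name=genome.seq_id[:16].replace(" ", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
            "date": "01-JAN-2000",  # fixed for byte-stable output
        },
    )
    for g in genome.genes:
        record.features.append(
            SeqFeature(
                FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers={"locus_tag": [g.gene_id], "product": [g.product]},
            )
        )
    return record


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    SeqIO.write(to_seqrecord(genome), str(path), "genbank")
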