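"""Homologous-recombination donor construct design.

A donor is a linear fragment: left homology arm + payload cassette (RBS +
coding sequence, oriented to the selected gene's strand) + optional duplicated
RBS context + right homology arm.  Arms are 200–400 bp windows copied verbatim
from the reference around the insertion point.

RBS-preservation rule: when the intergenic distance d from the selected
gene's stop to the next gene's start (in reading direction) is below the RBS
window (20 bp), the last (20 − d) bases of the selected gene are duplicated
and appended after the payload, so the downstream gene keeps an intact 20 bp
of native upstream context after integration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genome_model import AnnotatedGenome, GeneFeature, reverse_complement
from .ipr_engine import InsertionSite

logger = logging.getLogger(__name__)

#: ribosome binding site prepended to payloads
DEFAULT_RBS = "GAGGAGGTAAATATAT"
DEFAULT_ARM_MIN = 200
DEFAULT_ARM_MAX = 400
DEFAULT_RBS_WINDOW = 20
DEFAULT_AVOID_KEYWORDS = ("hypothetical", "unknown")


@dataclass
class PayloadCassette:
    """RBS + payload CDS, in reading orientation."""

    payload_seq: str
    rbs_seq: str = DEFAULT_RBS
    name: str = "payload"

    def __post_init__(self) -> None:
        self.payload_seq = self.payload_seq.upper()
        self.rbs_seq = self.rbs_seq.upper()
        if not self.payload_seq:
            raise ValueError("payload must be non-empty")

    @property
    def cassette_seq(self) -> str:
        return self.rbs_seq + self.payload_seq


@dataclass
class DonorConstruct:
    """A designed donor fragment with provenance coordinates.

    ``insert_seq`` is the inserted unit (cassette oriented to the site's
    strand, plus any duplicated context) in *forward-frame* sequence;
    ``full_seq`` = left_arm + insert_seq + right_arm.  ``duplicated_context``
    is recorded in reading orientation.
    """

    site_id: str
    insertion_pos: int
    strand: str
    left_arm: str
    right_arm: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    insert_seq: str
    duplicated_context: str
    cassette_name: str
    arm_len_range: tuple[int, int] = (DEFAULT_ARM_MIN, DEFAULT_ARM_MAX)

    @property
    def full_seq(self) -> str:
        return self.left_arm + self.insert_seq + self.right_arm


def _shrink_for_avoided_genes(
    length: int,
    window_of: "callable",
    genes: Sequence[GeneFeature],
    keywords: Sequence[str],
    arm_min: int,
    side: str,
) -> int:
    """Best-effort arm shortening so no avoid-listed gene is fully contained."""
    while True:
        a, b = window_of(length)
        contained = [
            g
            for g in genes
            if a <= g.start and g.end <= b
            and any(k in g.product.lower() for k in keywords)
        ]
        if not contained:
            return length
        # shrink just enough to push the nearest contained gene past the arm edge
        if side == "left":
            new_len = b - max(g.start for g in contained) - 1
        else:
            new_len = min(g.end for g in contained) - a - 1
        if new_len < arm_min:
            warnings.warn(
                f"{side} arm cannot avoid fully containing an "
                f"unannotated-function gene without dropping below {arm_min} bp; "
                "keeping the longer arm"
            )
            return length
        length = new_len


def design_donor(
    site: InsertionSite,
    genome: AnnotatedGenome,
    cassette: PayloadCassette,
    arm_min: int = DEFAULT_ARM_MIN,
    arm_max: int = DEFAULT_ARM_MAX,
    rbs_window: int = DEFAULT_RBS_WINDOW,
    avoid_keywords: Sequence[str] = DEFAULT_AVOID_KEYWORDS,
) -> DonorConstruct:
    """Design the donor fragment for one insertion site.

    Arms start at ``arm_max`` and shrink toward ``arm_min`` at genome edges
    (below ``arm_min`` is a hard error) and, best-effort, to avoid fully
    containing genes of unannotated function.  For − strand sites the
    cassette is reverse-complemented; all coordinates stay on the forward
    frame.
    """
    seq = genome.sequence
    L = len(seq)
    pos = site.position
    gene = genome.gene(site.selected_gene_id)
    if gene.strand != site.strand:
        raise ValueError("site strand does not match its selected gene")

    d = site.downstream_gap
    dup_len = max(0, rbs_window - d) if d < rbs_window else 0
    dup_len = min(dup_len, len(gene))
    if site.strand == "+":
        dup_reading = seq[gene.end - dup_len : gene.end] if dup_len else ""
        insert_seq = cassette.cassette_seq + dup_reading
    else:
        dup_fwd = seq[gene.start : gene.start + dup_len] if dup_len else ""
        dup_reading = reverse_complement(dup_fwd)
        insert_seq = dup_fwd + reverse_complement(cassette.cassette_seq)

    left_len = min(arm_max, pos)
    right_len = min(arm_max, L - pos)
    if left_len < arm_min or right_len < arm_min:
        raise ValueError(
            f"site {site.site_id}: homology arm would be shorter than {arm_min} bp "
            "at the genome edge"
        )
    genes = genome.coding_genes
    left_len = _shrink_for_avoided_genes(
        left_len, lambda n: (pos - n, pos), genes, avoid_keywords, arm_min, "left"
    )
    right_len = _shrink_for_avoided_genes(
        right_len, lambda n: (pos, pos + n), genes, avoid_keywords, arm_min, "right"
    )

    left_arm = seq[pos - left_len : pos]
    right_arm = seq[pos : pos + right_len]
    for junction in (left_arm[-20:], right_arm[:20]):
        if junction and junction in cassette.cassette_seq:
            warnings.warn(
                f"site {site.site_id}: payload contains an arm junction sequence "
                "verbatim; recombinant screening may be ambiguous"
            )
    return DonorConstruct(
        site_id=site.site_id,
        insertion_pos=pos,
        strand=site.strand,
        left_arm=left_arm,
        right_arm=right_arm,
        left_span=(pos - left_len, pos),
        right_span=(pos, pos + right_len),
        insert_seq=insert_seq,
        duplicated_context=dup_reading,
        cassette_name=cassette.name,
        arm_len_range=(arm_min, arm_max),
    )


def apply_edit_in_silico(genome: AnnotatedGenome, donor: DonorConstruct) -> AnnotatedGenome:
    """Return the recombinant genome produced by homologous recombination.

    Both arms are verified base-by-base against the reference at their
    recorded spans before editing; annotations downstream of the insertion
    point are shifted and an annotation for the payload cassette is added.
    """
    seq = genome.sequence
    for name, arm, (a, b) in (
        ("left", donor.left_arm, donor.left_span),
        ("right", donor.right_arm, donor.right_span),
    ):
        ref = seq[a:b]
        if ref != arm:
            offset = next(i for i, (x, y) in enumerate(zip(ref, arm)) if x != y)
            raise ValueError(
                f"{name} arm mismatches reference at span ({a}, {b}), "
                f"first mismatch at offset {offset}"
            )

    pos = donor.insertion_pos
    ins = donor.insert_seq
    n = len(ins)
    new_genes: list[GeneFeature] = []
    for g in genome.genes:
        if g.start >= pos:
            new_genes.append(
                replace(
                    g,
                    start=g.start + n,
                    end=g.end + n,
                    parts=[(a + n, b + n) for a, b in g.parts],
                )
            )
        elif g.end <= pos:
            new_genes.append(replace(g, parts=list(g.parts)))
        else:
            logger.warning(
                "gene %s spans the insertion point and is disrupted by the edit",
                g.gene_id,
            )
            new_genes.append(
                replace(g, end=g.end + n, parts=[(g.start, g.end + n)])
            )

    dup = len(donor.duplicated_context)
    if donor.strand == "+":
        cass_span = (pos, pos + n - dup)
    else:
        cass_span = (pos + dup, pos + n)
    payload_id = donor.cassette_name
    existing = {g.gene_id for g in new_genes}
    if payload_id in existing:
        payload_id = f"{payload_id}_{donor.site_id}"
    new_genes.append(
        GeneFeature(
            gene_id=payload_id,
            start=cass_span[0],
            end=cass_span[1],
            strand=donor.strand,
            product="inserted payload cassette",
        )
    )
    return replace(
        genome,
        sequence=seq[:pos] + ins + seq[pos:],
        genes=new_genes,
        seq_id=f"{genome.seq_id}_{donor.site_id}",
    )


# ---------------------------------------------------------------------------
# output


def write_donors_fasta(donors: Sequence[DonorConstruct], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(d.full_seq),
            id=d.site_id,
            description=(
                f"donor strand={d.strand} insertion_pos={d.insertion_pos} "
                f"arms={d.left_span[0]}-{d.left_span[1]},"
                f"{d.right_span[0]}-{d.right_span[1]} "
                f"dup={len(d.duplicated_context)}"
            ),
        )
        for d in donors
    ]
    SeqIO.write(records, str(path), "fasta")


def donor_manifest(donors: Sequence[DonorConstruct]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "site_id": d.site_id,
                "insertion_pos": d.insertion_pos,
                "strand": d.strand,
                "left_arm_start": d.left_span[0],
                "left_arm_end": d.left_span[1],
                "right_arm_start": d.right_span[0],
                "right_arm_end": d.right_span[1],
                "duplicated_bp": len(d.duplicated_context),
                "donor_length": len(d.full_seq),
            }
            for d in donors
        ]
    )
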