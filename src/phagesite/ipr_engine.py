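"""Intergenic Promoter Regions: clustering, cumulative weighted scoring,
ranking, and insertion-site selection.

An IPR is the set of predicted promoters of one strand falling inside one
extended intergenic region.  Its score is the cumulative exponentially
weighted score of its members,

    IPR score = Σ_i exp(s_i),

used as a proxy for the expression level a payload would experience if
integrated downstream.  Insertion sites are placed immediately after the stop
of the first gene downstream of an IPR in the IPR's reading direction, on the
same strand; when a temporal-class table (early/middle/late transcription) is
supplied, the top-ranked site per class is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genome_model import AnnotatedGenome, GeneFeature, IntergenicRegion
from .promoter_scoring import PromoterPrediction, WeightingScheme

logger = logging.getLogger(__name__)


@dataclass
class IPR:
    """A strand-aware cluster of promoter predictions in one intergenic region."""

    ipr_id: str
    region_id: str
    strand: str
    span_start: int
    span_end: int
    members: list[PromoterPrediction] = field(default_factory=list)
    ipr_score: float = 0.0


@dataclass
class InsertionSite:
    """A payload integration point immediately 3' of a selected gene's stop."""

    site_id: str
    position: int
    driving_ipr: str
    selected_gene_id: str
    strand: str
    temporal_class: str = "unknown"
    downstream_gap: int = 0
    ipr_score: float = 0.0


def build_iprs(
    regions: Sequence[IntergenicRegion],
    predictions: Sequence[PromoterPrediction],
    scheme: WeightingScheme | None = None,
) -> list[IPR]:
    """Cluster predictions into at most two IPRs (one per strand) per region.

    A prediction joins a region when its footprint lies within the region's
    extended span; a footprint contained in two overlapping extended regions
    is assigned to the region containing its midpoint (logged).  Regions
    with no members yield no IPR.
    """
    scheme = scheme or WeightingScheme()
    assignments: dict[tuple[str, str], list[PromoterPrediction]] = {}
    for p in predictions:
        containing = [r for r in regions if not r.wraps and r.contains(p.start, p.end)]
        if len(containing) > 1:
            # extended spans of neighboring regions can overlap inside a short
            # gene; resolve to the region whose core is nearest the midpoint
            mid = p.midpoint
            containing = sorted(
                containing,
                key=lambda r: abs((r.core_start + r.core_end) / 2 - mid),
            )[:1]
            logger.info(
                "prediction at (%d, %d) overlaps multiple extended regions; "
                "assigned by midpoint to %s",
                p.start,
                p.end,
                containing[0].region_id if containing else "none",
            )
        if not containing:
            continue
        assignments.setdefault((containing[0].region_id, p.strand), []).append(p)

    region_order = {r.region_id: i for i, r in enumerate(regions)}
    iprs: list[IPR] = []
    for (region_id, strand), members in sorted(
        assignments.items(), key=lambda kv: (region_order[kv[0][0]], kv[0][1])
    ):
        members = sorted(members, key=lambda p: (p.start, p.end))
        iprs.append(
            IPR(
                ipr_id=f"ipr_{region_id}_{'fwd' if strand == '+' else 'rev'}",
                region_id=region_id,
                strand=strand,
                span_start=min(p.start for p in members),
                span_end=max(p.end for p in members),
                members=members,
                ipr_score=sum(scheme.weight(p.score) for p in members),
            )
        )
    return iprs


def rank_iprs(iprs: Sequence[IPR]) -> list[IPR]:
    """Descending by cumulative score; ties broken by smaller span start."""
    return sorted(iprs, key=lambda i: (-i.ipr_score, i.span_start))


def _first_downstream_gene(
    ipr: IPR, genes: Sequence[GeneFeature], max_distance: int | None
) -> GeneFeature | None:
    """First same-strand gene whose 5' boundary is at/after the IPR hull in
    the IPR's reading direction."""
    if ipr.strand == "+":
        cands = [g for g in genes if g.strand == "+" and g.start >= ipr.span_start]
        cands.sort(key=lambda g: g.start)
        if max_distance is not None:
            cands = [g for g in cands if g.start - ipr.span_end <= max_distance]
    else:
        cands = [g for g in genes if g.strand == "-" and g.end <= ipr.span_end]
        cands.sort(key=lambda g: -g.end)
        if max_distance is not None:
            cands = [g for g in cands if ipr.span_start - g.end <= max_distance]
    return cands[0] if cands else None


def _downstream_gap(gene: GeneFeature, genes: Sequence[GeneFeature], genome_length: int) -> int:
    """Distance from the gene's stop to the next gene in reading direction."""
    if gene.strand == "+":
        nxt = [g.start for g in genes if g.start >= gene.end and g.gene_id != gene.gene_id]
        return (min(nxt) if nxt else genome_length) - gene.end
    nxt = [g.end for g in genes if g.end <= gene.start and g.gene_id != gene.gene_id]
    return gene.start - (max(nxt) if nxt else 0)


def select_insertion_sites(
    iprs: Sequence[IPR],
    genome: AnnotatedGenome,
    temporal_classes: Mapping[str, str] | None = None,
    per_class: int = 1,
    top_n: int | None = None,
    max_distance: int | None = None,
) -> list[InsertionSite]:
    """Turn ranked IPRs into insertion sites.

    For each IPR the first same-orientation downstream gene is located; IPRs
    with no such gene are skipped.  The site is the point just past that
    gene's stop (``end`` for + genes, ``start`` for − genes).  With a
    temporal-class table the top ``per_class`` sites per class are returned,
    otherwise the global top ``top_n`` (all when None).  A gene is used at
    most once, by the highest-ranking IPR that selects it.
    """
    genes = genome.coding_genes
    L = len(genome)
    used_genes: set[str] = set()
    sites: list[InsertionSite] = []
    for ipr in rank_iprs(iprs):
        gene = _first_downstream_gene(ipr, genes, max_distance)
        if gene is None or gene.gene_id in used_genes:
            continue
        used_genes.add(gene.gene_id)
        cls = (temporal_classes or {}).get(gene.gene_id, "unknown")
        sites.append(
            InsertionSite(
                site_id=f"site_{gene.gene_id}",
                position=gene.end if gene.strand == "+" else gene.start,
                driving_ipr=ipr.ipr_id,
                selected_gene_id=gene.gene_id,
                strand=gene.strand,
                temporal_class=cls,
                downstream_gap=_downstream_gap(gene, genes, L),
                ipr_score=ipr.ipr_score,
            )
        )

    if temporal_classes is not None:
        chosen: list[InsertionSite] = []
        for cls in dict.fromkeys(temporal_classes.values()):  # stable class order
            class_sites = [s for s in sites if s.temporal_class == cls][:per_class]
            if not class_sites:
                logger.warning("no insertion site found for temporal class %r", cls)
            chosen.extend(class_sites)
        return chosen
    return sites if top_n is None else sites[:top_n]


# ---------------------------------------------------------------------------
# reports


def ranking_table(
    iprs: Sequence[IPR], sites: Sequence[InsertionSite] | None = None
) -> pd.DataFrame:
    """Ranked IPR report (one row per IPR, highest score first)."""
    site_by_ipr = {s.driving_ipr: s for s in sites or []}
    rows = []
    for rank, ipr in enumerate(rank_iprs(iprs), start=1):
        s = site_by_ipr.get(ipr.ipr_id)
        rows.append(
            {
                "rank": rank,
                "ipr_id": ipr.ipr_id,
                "region_id": ipr.region_id,
                "strand": ipr.strand,
                "span_start": ipr.span_start,
                "span_end": ipr.span_end,
                "n_members": len(ipr.members),
                "ipr_score": round(ipr.ipr_score, 4),
                "selected_gene": s.selected_gene_id if s else "",
                "temporal_class": s.temporal_class if s else "",
            }
        )
    return pd.DataFrame(rows)


def sites_table(sites: Sequence[InsertionSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "position": s.position,
                "strand": s.strand,
                "driving_ipr": s.driving_ipr,
                "selected_gene": s.selected_gene_id,
                "temporal_class": s.temporal_class,
                "downstream_gap": s.downstream_gap,
                "ipr_score": round(s.ipr_score, 4),
            }
            for s in sites
        ]
    )


def write_iprs_gff3(
    iprs: Sequence[IPR], genome: AnnotatedGenome, path: str | Path
) -> None:
    """IPR hulls as GFF3, score column carrying the cumulative weighted score."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ipr in rank_iprs(iprs):
            fh.write(
                f"{genome.seq_id}\tphagesite\tpromoter_region\t"
                f"{ipr.span_start + 1}\t{ipr.span_end}\t{ipr.ipr_score:.4f}\t"
                f"{ipr.strand}\t.\tID={ipr.ipr_id};region={ipr.region_id};"
                f"n_members={len(ipr.members)}\n"
            )
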