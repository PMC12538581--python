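"""Synthetic annotated genomes with planted promoter clusters.

The generator emulates the statistical structure the pipeline assumes:
non-overlapping genes separated by intergenic gaps, σ70 consensus-like
promoter motifs concentrated in chosen intergenic regions, and a matching
prediction table whose scores are drawn from a truncated normal per planted
cluster (skewed toward 1 for strong clusters).  Temporal expression classes
(early / middle / late) are assigned by genome thirds, mimicking the block
structure of phage transcriptional programs.

Everything is reproducible from the config seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_model import (
    AnnotatedGenome,
    GeneFeature,
    extract_intergenic_regions,
    reverse_complement,
    write_genbank,
)
from .promoter_scoring import PromoterPrediction, write_predictions_table

_MOTIF_35 = "TTGACA"
_MOTIF_10 = "TATAAT"
_SPACER = 17
MOTIF_LEN = len(_MOTIF_35) + _SPACER + len(_MOTIF_10)  # 29 bp planted footprint

TEMPORAL_CLASSES = ("early", "middle", "late")


@dataclass(frozen=True)
class PlantedIpr:
    """One planted promoter cluster: which intergenic region, how many
    motifs, and the score distribution of their simulated predictions."""

    region_index: int
    strand: str = "+"
    n_promoters: int = 3
    score_mean: float = 0.9
    score_sd: float = 0.05


@dataclass
class SimConfig:
    genome_length: int = 30_000
    n_genes: int = 12
    gene_len_range: tuple[int, int] = (800, 1600)
    intergenic_len_range: tuple[int, int] = (180, 320)
    planted_iprs: list[PlantedIpr] = field(default_factory=list)
    seed: int = 0
    gc_content: float = 0.35
    strand_pattern: str = "operon"  # plus | alternating | operon | random

    def validate(self) -> None:
        gmax = self.gene_len_range[1]
        imax = self.intergenic_len_range[1]
        if self.n_genes * gmax + (self.n_genes + 1) * imax > self.genome_length:
            raise ValueError("infeasible config: genes and gaps cannot fit the genome")
        if self.intergenic_len_range[0] < MOTIF_LEN:
            raise ValueError(
                f"minimum intergenic length must be >= {MOTIF_LEN} bp to plant motifs"
            )
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.strand_pattern not in ("plus", "alternating", "operon", "random"):
            raise ValueError(f"unknown strand_pattern {self.strand_pattern!r}")


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to [0, 1] by rejection (clipped as fallback)."""
    if sd == 0:
        return float(np.clip(mean, 0.0, 1.0))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if 0.0 <= x <= 1.0:
            return float(x)
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def simulate_genome(
    cfg: SimConfig,
) -> tuple[AnnotatedGenome, list[PromoterPrediction], dict[str, str]]:
    """Generate (genome, planted prediction list, gene → temporal-class map)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length

    base_p = np.array(
        [
            (1 - cfg.gc_content) / 2,  # A
            cfg.gc_content / 2,  # C
            cfg.gc_content / 2,  # G
            (1 - cfg.gc_content) / 2,  # T
        ]
    )
    seq = rng.choice(np.array(list("ACGT")), size=L, p=base_p)

    # gene placement: leading gap, then alternating gene/gap blocks
    genes: list[GeneFeature] = []
    pos = int(rng.integers(*cfg.intergenic_len_range, endpoint=True))
    strand = "+"
    for i in range(cfg.n_genes):
        glen = int(rng.integers(*cfg.gene_len_range, endpoint=True))
        if cfg.strand_pattern == "alternating":
            strand = "+" if i % 2 == 0 else "-"
        elif cfg.strand_pattern == "operon":
            if i > 0 and rng.random() < 0.25:
                strand = "-" if strand == "+" else "+"
        elif cfg.strand_pattern == "random":
            strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneFeature(
                gene_id=f"g{i:03d}",
                start=pos,
                end=pos + glen,
                strand=strand,
                product=f"simulated protein {i}",
            )
        )
        pos += glen + int(rng.integers(*cfg.intergenic_len_range, endpoint=True))

    genome = AnnotatedGenome(
        seq_id=f"synthetic_{cfg.seed}", sequence="".join(seq), genes=genes
    )
    regions = extract_intergenic_regions(genome, extension=0)

    predictions: list[PromoterPrediction] = []
    chars = list(genome.sequence)
    for planted in cfg.planted_iprs:
        if not (0 <= planted.region_index < len(regions)):
            raise ValueError(
                f"planted region index {planted.region_index} out of range "
                f"(genome has {len(regions)} intergenic regions)"
            )
        r = regions[planted.region_index]
        width = r.core_end - r.core_start
        n = planted.n_promoters
        if width < n * MOTIF_LEN:
            raise ValueError(
                f"region {r.region_id} ({width} bp) too short for {n} planted motifs"
            )
        step = (width - MOTIF_LEN) / max(1, n - 1) if n > 1 else 0.0
        for k in range(n):
            p = r.core_start + int(round(k * step))
            spacer = "".join(rng.choice(np.array(list("ACGT")), size=_SPACER))
            motif = _MOTIF_35 + spacer + _MOTIF_10
            planted_seq = motif if planted.strand == "+" else reverse_complement(motif)
            chars[p : p + MOTIF_LEN] = list(planted_seq)
            predictions.append(
                PromoterPrediction(
                    strand=planted.strand,
                    start=p,
                    end=p + MOTIF_LEN,
                    motif_seq=motif,
                    score=_truncnorm01(rng, planted.score_mean, planted.score_sd),
                    source="external_table",
                )
            )
    genome.sequence = "".join(chars)

    # temporal classes as contiguous blocks of the gene order (genome thirds
    # of the annotated span), so each class is non-empty for >= 3 genes
    classes = {}
    n_genes = len(genome.genes)
    for i, g in enumerate(genome.genes):
        third = min(2, 3 * i // max(1, n_genes))
        classes[g.gene_id] = TEMPORAL_CLASSES[third]

    predictions.sort(key=lambda p: (p.start, p.end, p.strand))
    return genome, predictions, classes


def write_fixture(
    genome: AnnotatedGenome,
    predictions: list[PromoterPrediction],
    classes: dict[str, str],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write genome (GenBank), prediction table (TSV) and class table (TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.gb",
        "predictions": outdir / "predictions.tsv",
        "classes": outdir / "classes.tsv",
    }
    write_genbank(genome, paths["genome"])
    write_predictions_table(predictions, paths["predictions"], len(genome))
    with open(paths["classes"], "w") as fh:
        fh.write("gene_id\ttemporal_class\n")
        for gid, cls in classes.items():
            fh.write(f"{gid}\t{cls}\n")
    return paths
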