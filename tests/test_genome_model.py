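"""Genome parsing, split-gene merging and intergenic-region extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from phagesite.genome_model import (
    AnnotatedGenome,
    GeneFeature,
    extract_intergenic_regions,
    merge_split_genes,
    read_genome,
    read_regions_bed,
    reverse_complement,
    reverse_complement_genome,
    write_regions_bed,
)

from conftest import make_genome, random_gene_layout, random_sequence


def _write_genbank(tmp_path, length, locations, name="toy.gb"):
    record = SeqRecord(
        Seq(random_sequence(length, seed=7)),
        id="toy",
        name="toy",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for i, loc in enumerate(locations):
        record.features.append(
            SeqFeature(loc, type="CDS", qualifiers={"locus_tag": [f"g{i:03d}"]})
        )
    path = tmp_path / name
    SeqIO.write(record, str(path), "genbank")
    return path


def intergenic_mask_oracle(length, spans):
    """Per-base coverage complement: maximal uncovered runs as (start, end)."""
    mask = np.zeros(length, dtype=bool)
    for a, b in spans:
        mask[a:b] = True
    out, start = [], None
    for i in range(length):
        if not mask[i] and start is None:
            start = i
        elif mask[i] and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, length))
    return out


class TestReadGenome:
    def test_one_based_to_half_open_conversion(self, tmp_path):
        # GenBank 1..300, 401..700, 801..1000 become (0,300), (400,700), (800,1000)
        path = _write_genbank(
            tmp_path,
            1000,
            [
                FeatureLocation(0, 300, strand=1),
                FeatureLocation(400, 700, strand=1),
                FeatureLocation(800, 1000, strand=1),
            ],
        )
        text = path.read_text()
        assert "1..300" in text and "401..700" in text  # file really is 1-based
        genome = read_genome(path)
        assert [(g.start, g.end) for g in genome.genes] == [
            (0, 300),
            (400, 700),
            (800, 1000),
        ]
        assert all(g.strand == "+" for g in genome.genes)

    def test_join_location_preserved_as_parts(self, tmp_path):
        loc = CompoundLocation(
            [FeatureLocation(99, 200, strand=1), FeatureLocation(300, 400, strand=1)]
        )
        genome = read_genome(_write_genbank(tmp_path, 600, [loc]))
        (gene,) = genome.genes
        assert gene.parts == [(99, 200), (300, 400)]
        assert (gene.start, gene.end) == (99, 400)
        assert gene.is_split

    def test_record_without_annotations_rejected(self, tmp_path):
        path = _write_genbank(tmp_path, 500, [])
        with pytest.raises(ValueError, match="no annotations"):
            read_genome(path)

    def test_minus_strand_feature(self, tmp_path):
        genome = read_genome(
            _write_genbank(tmp_path, 500, [FeatureLocation(100, 400, strand=-1)])
        )
        assert genome.genes[0].strand == "-"


class TestMergeSplitGenes:
    def test_nested_gene_flagged_interior(self):
        # split gene A spanning a nested gene B: A collapses to its hull,
        # B stays as annotation but creates no intergenic boundary
        genome = make_genome(600, [])
        genome.genes = [
            GeneFeature("A", 99, 400, "+", parts=[(99, 200), (300, 400)]),
            GeneFeature("B", 210, 290, "+"),
        ]
        merged = merge_split_genes(genome)
        a = merged.gene("A")
        b = merged.gene("B")
        assert (a.start, a.end) == (99, 400) and not a.is_split
        assert b.interior
        cores = [
            (r.core_start, r.core_end)
            for r in extract_intergenic_regions(merged, extension=0)
        ]
        assert cores == [(0, 99), (400, 600)]

    def test_identity_without_multipart_genes(self):
        genome = make_genome(1000, [(0, 300, "+"), (400, 700, "-")])
        merged = merge_split_genes(genome)
        assert [(g.start, g.end, g.interior) for g in merged.genes] == [
            (g.start, g.end, False) for g in genome.genes
        ]

    def test_independent_hulls(self):
        genome = make_genome(2000, [])
        genome.genes = [
            GeneFeature("A", 10, 300, "+", parts=[(10, 100), (200, 300)]),
            GeneFeature("B", 500, 900, "-", parts=[(500, 600), (700, 900)]),
        ]
        merged = merge_split_genes(genome)
        # oracle: hull over parts
        for g in genome.genes:
            expect = (min(a for a, _ in g.parts), max(b for _, b in g.parts))
            got = merged.gene(g.gene_id)
            assert (got.start, got.end) == expect

    def test_idempotence(self):
        genome = make_genome(600, [])
        genome.genes = [
            GeneFeature("A", 99, 400, "+", parts=[(99, 200), (300, 400)]),
            GeneFeature("B", 210, 290, "+"),
        ]
        once = merge_split_genes(genome)
        twice = merge_split_genes(once)
        assert [(g.start, g.end, g.interior) for g in once.genes] == [
            (g.start, g.end, g.interior) for g in twice.genes
        ]


class TestIntergenicRegions:
    def test_hand_computed_cores_and_extensions(self):
        genome = make_genome(1000, [(0, 300, "+"), (400, 700, "+")])
        regions = extract_intergenic_regions(genome, extension=50)
        assert [(r.core_start, r.core_end) for r in regions] == [(300, 400), (700, 1000)]
        assert [(r.ext_start, r.ext_end) for r in regions] == [(250, 450), (650, 1000)]
        assert regions[0].upstream_gene_id == "g000"
        assert regions[0].downstream_gene_id == "g001"

    def test_abutting_genes_yield_zero_width_core(self):
        genome = make_genome(600, [(0, 300, "+"), (300, 600, "+")])
        regions = extract_intergenic_regions(genome, extension=50)
        zero = [r for r in regions if r.core_start == r.core_end]
        assert len(zero) == 1
        assert (zero[0].core_start, zero[0].core_end) == (300, 300)
        assert (zero[0].ext_start, zero[0].ext_end) == (250, 350)

    def test_genome_tiled_by_genes_has_no_regions(self):
        genome = make_genome(600, [(0, 400, "+"), (200, 600, "-")])
        assert extract_intergenic_regions(genome) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_mask_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(5_000, 50_000))
        layout = random_gene_layout(rng, L, max_genes=20)
        genome = make_genome(L, layout, seq="A" * L)
        regions = extract_intergenic_regions(genome, extension=50)
        got = [(r.core_start, r.core_end) for r in regions]
        assert got == intergenic_mask_oracle(L, [(a, b) for a, b, _ in layout])

    @pytest.mark.parametrize("seed", range(3))
    def test_tiling_and_extension_bound(self, seed):
        rng = np.random.default_rng(100 + seed)
        L = int(rng.integers(2_000, 20_000))
        layout = random_gene_layout(rng, L, max_genes=15)
        genome = make_genome(L, layout, seq="A" * L)
        regions = extract_intergenic_regions(genome, extension=50)
        covered = np.zeros(L, dtype=int)
        for a, b, _ in layout:
            covered[a:b] += 1
        for r in regions:
            covered[r.core_start : r.core_end] += 1
            # extension reaches at most 50 bp into any flanking gene
            assert r.core_start - r.ext_start <= 50
            assert r.ext_end - r.core_end <= 50
        assert (covered >= 1).all()  # union of gene bodies and cores is [0, L)
        cores = sorted((r.core_start, r.core_end) for r in regions)
        for (a1, b1), (a2, b2) in zip(cores, cores[1:]):
            assert b1 <= a2  # pairwise disjoint

    def test_circular_wraparound_region(self):
        genome = make_genome(
            1000, [(100, 400, "+"), (500, 900, "+")], topology="circular"
        )
        regions = extract_intergenic_regions(genome, extension=50)
        wrap = [r for r in regions if r.wraps]
        assert len(wrap) == 1
        assert (wrap[0].core_start, wrap[0].core_end) == (900, 100)

    def test_bed_round_trip(self, tmp_path):
        genome = make_genome(1000, [(0, 300, "+"), (400, 700, "+")])
        regions = extract_intergenic_regions(genome, extension=50)
        path = tmp_path / "regions.bed"
        write_regions_bed(regions, genome, path)
        back = read_regions_bed(path)
        assert [
            (r.region_id, r.core_start, r.core_end, r.ext_start, r.ext_end)
            for r in regions
        ] == [
            (r.region_id, r.core_start, r.core_end, r.ext_start, r.ext_end)
            for r in back
        ]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 4_000), st.integers(20, 400)),
        min_size=1,
        max_size=12,
    )
)
def test_tiling_holds_for_arbitrary_overlapping_genes(raw):
    """Union of non-interior gene bodies and cores tiles [0, L) even when
    annotations overlap (coverage-union semantics, no error)."""
    L = 5_000
    spans = sorted((a, min(L, a + w)) for a, w in raw)
    genome = AnnotatedGenome(
        "h",
        "A" * L,
        [GeneFeature(f"g{i}", a, b, "+") for i, (a, b) in enumerate(spans)],
    )
    regions = extract_intergenic_regions(genome, extension=50)
    covered = np.zeros(L, dtype=bool)
    for a, b in spans:
        covered[a:b] = True
    for r in regions:
        covered[r.core_start : r.core_end] = True
    assert covered.all()


def test_reverse_complement_genome_is_involution():
    genome = make_genome(1000, [(0, 300, "+"), (400, 700, "-")])
    back = reverse_complement_genome(reverse_complement_genome(genome))
    assert back.sequence == genome.sequence
    assert [(g.start, g.end, g.strand) for g in back.genes] == [
        (g.start, g.end, g.strand) for g in genome.genes
    ]


def test_gene_seq_is_strand_aware():
    genome = make_genome(100, [(10, 40, "-")])
    fwd = genome.sequence[10:40]
    assert genome.gene_seq("g000") == reverse_complement(fwd)
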