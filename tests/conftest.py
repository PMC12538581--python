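import numpy as np
import pytest

from phagesite.genome_model import AnnotatedGenome, GeneFeature

_RNG_BASES = np.array(list("ACGT"))


def random_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_RNG_BASES, size=length))


def make_genome(length, genes, seq=None, seq_id="toy", topology="linear"):
    """Build a toy genome; ``genes`` is a list of (start, end, strand) or
    (start, end, strand, product) tuples."""
    feats = []
    for i, g in enumerate(genes):
        start, end, strand = g[:3]
        product = g[3] if len(g) > 3 else f"protein {i}"
        feats.append(
            GeneFeature(f"g{i:03d}", start, end, strand, product=product)
        )
    return AnnotatedGenome(
        seq_id=seq_id,
        sequence=seq if seq is not None else random_sequence(length, seed=length),
        genes=feats,
        topology=topology,
    )


def random_gene_layout(rng, genome_length, max_genes, min_gap=1, min_len=50, max_len=2000):
    """Non-overlapping random gene spans with positive gaps between them."""
    spans = []
    pos = int(rng.integers(min_gap, 300))
    while len(spans) < max_genes:
        length = int(rng.integers(min_len, max_len))
        if pos + length + min_gap >= genome_length:
            break
        spans.append((pos, pos + length, "+" if rng.random() < 0.5 else "-"))
        pos += length + int(rng.integers(min_gap, 400))
    return spans


@pytest.fixture
def payload_fasta(tmp_path):
    path = tmp_path / "payload.fa"
    path.write_text(
        ">nluc synthetic reporter payload\n"
        + "ATGGTCTTCACACTCGAAGATTTCGTTGGGGACTGGCGACAGACAGCCGGCTACAACCTG" * 8
        + "\n"
    )
    return path
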