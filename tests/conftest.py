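import numpy as np
import pytest

from hopkit.annotmerge import AnnotationHit, GeneModel


def make_gene(gene_id, scaffold="s1", strand="+", exons=((0, 100),),
              source="primary_evidence", hits=(), labels=()):
    return GeneModel(
        gene_id=gene_id,
        scaffold=scaffold,
        strand=strand,
        exons=[tuple(e) for e in exons],
        source=source,
        hits=list(hits),
        labels=set(labels),
    )


def make_hit(db="uniprot", subject="P1", description="some protein",
             pident=90.0, evalue=1e-20):
    return AnnotationHit(
        database=db, subject=subject, description=description,
        percent_identity=pident, evalue=evalue,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gene_set(rng, n, scaffolds=("s1", "s2"), max_pos=50_000,
                    source="primary_evidence", prefix="g"):
    """Random single/multi-exon gene models for overlap-oracle tests."""
    genes = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        n_exons = int(rng.integers(1, 4))
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(50, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(20, 200))
        genes.append(
            GeneModel(
                gene_id=f"{prefix}{i}",
                scaffold=str(rng.choice(list(scaffolds))),
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
                source=source,
            )
        )
    return genes
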