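"""Gene-model merging, annotation classification, and repeat-model removal.

A genome annotated by two pipelines — one evidence-based (transcript-derived
models), one ab initio — needs a single non-redundant gene set. The merge
rule gives the evidence-based source priority: an ab initio model is dropped
whenever any of its exons overlaps an evidence-based model on the same
scaffold and strand. Remaining models are classified by their similarity to
curated proteins (UniProt) and domain families (Pfam), and models whose best
hit looks like a transposable element are removed.

Coordinates are 0-based half-open internally; GFF3 I/O converts to and from
the 1-based closed convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "AnnotationHit",
    "GeneModel",
    "merge_gene_models",
    "classify_annotations",
    "annotation_summary",
    "filter_repeat_associated",
    "default_repeat_keywords",
    "read_gff3",
    "write_gff3",
    "read_hits_tsv",
]

SOURCE_PRIMARY = "primary_evidence"
SOURCE_SECONDARY = "secondary_abinitio"


@dataclass(frozen=True)
class AnnotationHit:
    """One similarity-search hit of a gene model against a reference
    database (``uniprot`` or ``pfam``)."""

    database: str
    subject: str
    description: str
    percent_identity: float
    evalue: float

    def __post_init__(self) -> None:
        if self.database not in ("uniprot", "pfam"):
            raise ValueError(f"unknown database {self.database!r}")
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent identity must be in [0, 100]")


@dataclass
class GeneModel:
    """A stranded, exon-structured gene model on one scaffold.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]
    source: str = SOURCE_PRIMARY
    hits: list[AnnotationHit] = field(default_factory=list)
    labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon {s}-{e}")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"{self.gene_id}: exons unsorted or overlapping"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def best_hit(self) -> AnnotationHit | None:
        """Lowest e-value hit; ties by higher identity, then subject id."""
        if not self.hits:
            return None
        return min(
            self.hits,
            key=lambda h: (h.evalue, -h.percent_identity, h.subject),
        )


def _exon_overlap_bp(a: GeneModel, b: GeneModel) -> int:
    total = 0
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def merge_gene_models(
    primary: list[GeneModel],
    secondary: list[GeneModel],
    min_overlap_bp: int = 1,
) -> list[GeneModel]:
    """Merge two gene-model sets with priority to the first.

    A secondary model is dropped iff it shares at least ``min_overlap_bp``
    bases of exon overlap with any primary model on the same scaffold and
    strand. All primary models are retained. Output sorted by coordinate.
    """
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for g in primary:
        by_key.setdefault((g.scaffold, g.strand), []).append(g)
    for genes in by_key.values():
        genes.sort(key=lambda g: g.start)

    kept = list(primary)
    for g in secondary:
        candidates = by_key.get((g.scaffold, g.strand), [])
        # sorted sweep: only primaries whose span can reach g matter
        overlap = sum(
            _exon_overlap_bp(g, p)
            for p in candidates
            if p.start < g.end and g.start < p.end
        )
        if overlap < min_overlap_bp:
            kept.append(g)
    kept.sort(key=lambda g: (g.scaffold, g.start, g.end, g.gene_id))
    return kept


def classify_annotations(genes: list[GeneModel]) -> dict[str, str]:
    """Partition genes into {uniprot_only, pfam_only, both, neither} by the
    databases their hits come from. Exhaustive and mutually exclusive."""
    out = {}
    for g in genes:
        dbs = {h.database for h in g.hits}
        if dbs >= {"uniprot", "pfam"}:
            out[g.gene_id] = "both"
        elif "uniprot" in dbs:
            out[g.gene_id] = "uniprot_only"
        elif "pfam" in dbs:
            out[g.gene_id] = "pfam_only"
        else:
            out[g.gene_id] = "neither"
    return out


def annotation_summary(
    genes: list[GeneModel], subset_scaffolds: set[str] | None = None
) -> pd.DataFrame:
    """Category counts overall and (optionally) on a scaffold subset,
    with the subset percentage per category.

    The canonical use is quantifying how much of the annotated gene space
    lies on the chromosome-scale scaffolds (e.g. the 10 largest).
    """
    cats = classify_annotations(genes)
    rows = []
    categories = ["uniprot_only", "pfam_only", "both", "neither"]
    by_id = {g.gene_id: g for g in genes}
    for cat in categories:
        ids = [gid for gid, c in cats.items() if c == cat]
        row = {"category": cat, "n_genes": len(ids)}
        if subset_scaffolds is not None:
            n_sub = sum(
                1 for gid in ids if by_id[gid].scaffold in subset_scaffolds
            )
            row["n_subset"] = n_sub
            row["subset_percent"] = (
                100.0 * n_sub / len(ids) if ids else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def default_repeat_keywords() -> list[str]:
    """Repeat-association keywords shipped as package data (editable without
    touching code)."""
    text = (
        resources.files("hopkit") / "data" / "repeat_keywords.txt"
    ).read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def filter_repeat_associated(
    genes: list[GeneModel], keywords: list[str] | None = None
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Split genes into (kept, removed) by repeat-like best-hit description.

    A gene is removed iff the description of its best-ranked hit contains
    any keyword as a case-insensitive substring. Genes without hits are
    kept. Idempotent by construction.
    """
    if keywords is None:
        keywords = default_repeat_keywords()
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    kept, removed = [], []
    for g in genes:
        best = g.best_hit()
        desc = best.description.lower() if best else ""
        if best and any(k in desc for k in lowered):
            removed.append(g)
        else:
            kept.append(g)
    return kept, removed


# ---- GFF3 and hit-table I/O ----------------------------------------------

_GFF_ATTR = re.compile(r"([^=;]+)=([^;]*)")


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene + exon features, converting internal 0-based half-open
    intervals to GFF3 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.start, g.gene_id)):
            src = "hopkit"
            fh.write(
                f"{g.scaffold}\t{src}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};source_set={g.source}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\t{src}\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};"
                    f"Parent={g.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3."""
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            scaffold, _, ftype, start, end, _, strand, _, attr_s = cols
            attrs = dict(_GFF_ATTR.findall(attr_s))
            start0, end0 = int(start) - 1, int(end)
            if ftype == "gene":
                gid = attrs["ID"]
                genes[gid] = GeneModel(
                    gene_id=gid,
                    scaffold=scaffold,
                    strand=strand,
                    exons=[(start0, end0)],  # placeholder, replaced below
                    source=attrs.get("source_set", SOURCE_PRIMARY),
                )
            elif ftype == "exon":
                exons.setdefault(attrs["Parent"], []).append((start0, end0))
    out = []
    for gid, g in genes.items():
        ex = sorted(exons.get(gid, g.exons))
        out.append(
            GeneModel(
                gene_id=gid,
                scaffold=g.scaffold,
                strand=g.strand,
                exons=ex,
                source=g.source,
            )
        )
    out.sort(key=lambda g: (g.scaffold, g.start, g.gene_id))
    return out


def read_hits_tsv(path: str | Path) -> dict[str, list[AnnotationHit]]:
    """Read a hit table (columns: gene, db, subject, pident, evalue,
    description) into a gene -> hits mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "subject": str})
    out: dict[str, list[AnnotationHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene, []).append(
            AnnotationHit(
                database=row.db,
                subject=row.subject,
                description=str(row.description),
                percent_identity=float(row.pident),
                evalue=float(row.evalue),
            )
        )
    return out
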