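"""Synthetic-data generators for every pipeline stage, with known ground
truth.

The generators emulate the study conditions the downstream modules were
built for: codon pairs diverged to target Ks values drawn from a
three-component mixture (Ks-scale component means 0.027 / 0.251 / 1.616),
collinear syntenic blocks with controllable terpene/defense label
co-occurrence and inter-anchor LTR insertions, diploid k-mer spectra at
~5% heterozygosity, and a 281-offspring bi-parental mapping population
carrying a sex-linked marker subset on one designated scaffold.

Reproducibility: one global seed fans out to per-generator child streams
through fixed offsets, so each generator is bit-reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codon import (
    SENSE_CODONS,
    SYN_DIFFS,
    SYN_NEIGHBORS,
    SYN_SITES,
    indices_to_seq,
)
from .annotmerge import GeneModel
from .genmap import GenotypeMatrix
from .genomeprofile import KmerHistogram, ScaffoldSet
from .synteny import HomologyPair, SyntenicBlock

__all__ = [
    "SimConfig",
    "GenomeSpec",
    "BlockSpec",
    "LabelSpec",
    "PopgenSpec",
    "KmerSpec",
    "DivergentPair",
    "SyntenyDataset",
    "simulate_genome",
    "simulate_divergent_pairs",
    "simulate_synteny_dataset",
    "simulate_block_labels",
    "simulate_kmer_histogram",
    "simulate_mapping_population",
    "write_fasta",
    "write_kmer_histogram",
]

# fixed child-stream offsets: (seed, offset) seeds an independent generator
_STREAMS = {
    "genome": 1,
    "pairs": 2,
    "synteny": 3,
    "kmer": 4,
    "popgen": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class GenomeSpec:
    n_scaffolds: int = 1
    scaffold_length: int = 100_000
    n_genes: int = 50
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.scaffold_length < 1:
            raise ValueError("counts must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")


@dataclass(frozen=True)
class BlockSpec:
    n_blocks: int = 100
    anchors_per_block: int = 10
    ltr_rate: float = 0.5  # probability of an LTR insertion per gap
    n_scaffolds: int = 10
    noise_genes_per_gap: int = 2

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.anchors_per_block < 2:
            raise ValueError("need >= 1 block with >= 2 anchors")
        _check_fraction("ltr_rate", self.ltr_rate)


@dataclass(frozen=True)
class LabelSpec:
    p_terpene: float = 0.15
    p_defense: float = 0.3
    dependence: float = 0.0  # 0 = independent, 1 = fully coupled

    def __post_init__(self) -> None:
        for name in ("p_terpene", "p_defense", "dependence"):
            _check_fraction(name, getattr(self, name))


@dataclass(frozen=True)
class PopgenSpec:
    n_offspring: int = 281
    n_markers: int = 2000
    sex_linked_fraction: float = 0.02
    n_scaffolds: int = 10
    sex_scaffold_index: int = 2  # third largest scaffold, 0-based
    genotype_error: float = 0.0
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_offspring < 4 or self.n_markers < 1:
            raise ValueError("population too small")
        for name in ("sex_linked_fraction", "genotype_error", "missing_rate"):
            _check_fraction(name, getattr(self, name))
        if not 0 <= self.sex_scaffold_index < self.n_scaffolds:
            raise ValueError("sex_scaffold_index out of range")


@dataclass(frozen=True)
class KmerSpec:
    genome_size: int = 1_000_000
    heterozygosity: float = 0.05
    coverage: float = 30.0
    error_rate: float = 0.0048
    k: int = 21

    def __post_init__(self) -> None:
        if self.genome_size < 1 or self.coverage <= 0 or self.k < 1:
            raise ValueError("invalid k-mer spec")
        _check_fraction("heterozygosity", self.heterozygosity)
        _check_fraction("error_rate", self.error_rate)


@dataclass(frozen=True)
class SimConfig:
    """Global configuration: one seed plus per-stage parameter groups.

    Component defaults place the three Ks mixture components at the
    duplication/divergence peaks observed in hop (0.027, 0.251, 1.616 on
    the Ks scale, sd 0.35 in ln units, weights 0.3/0.5/0.2)."""

    seed: int = 0
    n_pairs: int = 500
    ks_components: tuple[tuple[float, float, float], ...] = (
        (0.027, 0.35, 0.3),
        (0.251, 0.35, 0.5),
        (1.616, 0.35, 0.2),
    )
    codon_length: int = 300
    max_ks: float = 5.0  # right-tail truncation of Ks draws
    genome_spec: GenomeSpec = field(default_factory=GenomeSpec)
    block_spec: BlockSpec = field(default_factory=BlockSpec)
    label_spec: LabelSpec = field(default_factory=LabelSpec)
    popgen_spec: PopgenSpec = field(default_factory=PopgenSpec)
    kmer_spec: KmerSpec = field(default_factory=KmerSpec)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be >= 0")
        if self.n_pairs < 1 or self.codon_length < 1:
            raise ValueError("counts must be positive")
        weights = [w for _, _, w in self.ks_components]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        for ks, sd, w in self.ks_components:
            if ks < 0 or sd < 0 or w < 0:
                raise ValueError("component parameters must be >= 0")
            if ks > self.max_ks:
                raise ValueError(
                    f"component mean Ks={ks} beyond saturation bound "
                    f"{self.max_ks}"
                )


# ---- genome + gene models -------------------------------------------------

def simulate_genome(
    config: SimConfig,
) -> tuple[ScaffoldSet, list[GeneModel]]:
    """I.i.d.-composition scaffolds with non-overlapping stranded gene
    models. Deterministic for a fixed seed; raises if the scaffolds cannot
    hold the requested genes."""
    spec = config.genome_spec
    rng = _rng(config.seed, "genome")
    bases = np.array(list("ACGT"))
    records = []
    for i in range(spec.n_scaffolds):
        seq = "".join(
            rng.choice(bases, size=spec.scaffold_length, p=spec.base_probs)
        )
        records.append((f"scaffold_{i + 1}", seq))
    scaffolds = ScaffoldSet(records)

    genes: list[GeneModel] = []
    per_scaffold = [
        spec.n_genes // spec.n_scaffolds
        + (1 if i < spec.n_genes % spec.n_scaffolds else 0)
        for i in range(spec.n_scaffolds)
    ]
    gid = 0
    for (scaf_id, _), n_here in zip(records, per_scaffold):
        if n_here == 0:
            continue
        slot = spec.scaffold_length // n_here
        if slot < 200:
            raise ValueError(
                f"scaffold_length={spec.scaffold_length} too small for "
                f"{n_here} genes on {scaf_id}"
            )
        cursor = 0
        for _ in range(n_here):
            n_exons = int(rng.integers(1, 4))
            exon_lens = rng.integers(150, 601, size=n_exons)
            intron_lens = rng.integers(50, 201, size=max(n_exons - 1, 0))
            span = int(exon_lens.sum() + intron_lens.sum())
            if span >= slot:  # shrink to a single exon that fits the slot
                n_exons = 1
                exon_lens = np.array([min(600, slot // 2)])
                intron_lens = np.array([], dtype=int)
                span = int(exon_lens[0])
            start = int(rng.integers(cursor, cursor + slot - span + 1))
            exons = []
            pos = start
            for j, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if j < n_exons - 1:
                    pos += int(intron_lens[j])
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{gid:05d}",
                    scaffold=scaf_id,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                )
            )
            cursor += slot
    return scaffolds, genes


# ---- divergent codon pairs ------------------------------------------------

@dataclass
class DivergentPair:
    pair_id: str
    seq_a: str
    seq_b: str
    ks_true: float  # the target drawn from the mixture
    ks_realized: float  # NG86 Ks of the emitted pair
    component: int


def _required_ps(ks: float) -> float:
    """Invert the Jukes–Cantor correction: the raw synonymous mismatch
    proportion corresponding to a target Ks."""
    return 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))


def _diverge_pair(
    ancestor: np.ndarray, target_ks: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Apply strictly synonymous single-nucleotide substitutions to the two
    descendants of ``ancestor`` until the realized NG86 Ks first reaches
    ``target_ks``; returns the state (pre- or post-crossing) closest to the
    target."""
    a = ancestor.copy()
    b = ancestor.copy()
    if target_ks <= 0:
        return a, b, 0.0

    # site counts drift between synonymous codons; track both lineages
    s_a = float(SYN_SITES[a].sum())
    s_b = float(SYN_SITES[b].sum())
    sd = float(SYN_DIFFS[a, b].sum())

    def realized() -> float:
        ps = sd / (0.5 * (s_a + s_b))
        if ps >= 0.75:
            return math.inf
        return -0.75 * math.log1p(-4.0 * ps / 3.0)

    ks_now = realized()
    best = (a.copy(), b.copy(), ks_now)
    max_steps = 500 * a.size
    for _ in range(max_steps):
        if ks_now >= target_ks:
            break
        i = int(rng.integers(a.size))
        on_a = rng.random() < 0.5
        seq = a if on_a else b
        neighbors = SYN_NEIGHBORS[seq[i]]
        if not neighbors:
            continue
        new_codon = neighbors[int(rng.integers(len(neighbors)))]
        old = seq[i]
        if on_a:
            s_a += SYN_SITES[new_codon] - SYN_SITES[old]
            sd += SYN_DIFFS[new_codon, b[i]] - SYN_DIFFS[old, b[i]]
            a[i] = new_codon
        else:
            s_b += SYN_SITES[new_codon] - SYN_SITES[old]
            sd += SYN_DIFFS[a[i], new_codon] - SYN_DIFFS[a[i], old]
            b[i] = new_codon
        ks_now = realized()
        if abs(ks_now - target_ks) < abs(best[2] - target_ks):
            best = (a.copy(), b.copy(), ks_now)
    else:
        raise RuntimeError(
            f"could not reach Ks={target_ks:.3f}: synonymous divergence "
            "saturated"
        )
    return best


def simulate_divergent_pairs(config: SimConfig) -> list[DivergentPair]:
    """Codon-aligned CDS pairs whose realized NG86 Ks matches ln-normal
    mixture draws.

    For each pair a component is drawn by weight, ln(Ks_true) ~
    Normal(ln(component Ks), sd); draws are truncated at ``config.max_ks``
    (the saturation bound). Substitutions are strictly synonymous under the
    standard genetic code, so no stop codons are ever introduced and the
    estimator's model assumptions hold exactly.
    """
    if config.codon_length < 50:
        raise ValueError("codon_length must be >= 50")
    rng = _rng(config.seed, "pairs")
    means = np.array([c[0] for c in config.ks_components])
    sds = np.array([c[1] for c in config.ks_components])
    weights = np.array([c[2] for c in config.ks_components])

    pairs = []
    for i in range(config.n_pairs):
        comp = int(rng.choice(len(weights), p=weights))
        mu, sd = means[comp], sds[comp]
        if mu <= 0 or sd == 0:
            ks_true = float(mu)
        else:
            ks_true = float(np.exp(rng.normal(np.log(mu), sd)))
        ks_true = min(ks_true, config.max_ks)
        ancestor = rng.integers(len(SENSE_CODONS), size=config.codon_length)
        a, b, ks_real = _diverge_pair(ancestor, ks_true, rng)
        pairs.append(
            DivergentPair(
                pair_id=f"pair_{i + 1:05d}",
                seq_a=indices_to_seq(a),
                seq_b=indices_to_seq(b),
                ks_true=ks_true,
                ks_realized=ks_real,
                component=comp,
            )
        )
    return pairs


# ---- synteny dataset ------------------------------------------------------

def simulate_block_labels(
    n_blocks: int,
    p_terpene: float,
    p_defense: float,
    dependence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_blocks, 2) boolean matrix of (terpene, defense) block labels.

    With ``dependence`` = 0 labels are independent Bernoulli draws; with
    probability ``dependence`` a block instead draws a single shared
    Bernoulli(max(p_t, p_d)) outcome for both labels, which induces
    positive co-occurrence while keeping marginals close to nominal."""
    coupled = rng.random(n_blocks) < dependence
    shared = rng.random(n_blocks) < max(p_terpene, p_defense)
    terp = np.where(coupled, shared, rng.random(n_blocks) < p_terpene)
    defe = np.where(coupled, shared, rng.random(n_blocks) < p_defense)
    return np.column_stack([terp, defe])


@dataclass
class SyntenyDataset:
    genes_a: list[GeneModel]
    genes_b: list[GeneModel]
    pairs: list[HomologyPair]
    true_blocks: list[SyntenicBlock]
    repeat_intervals: list[tuple[str, int, int]]  # genome A, BED convention
    block_labels: list[set[str]]
    truth: pd.DataFrame
    per_scaffold_label_counts: dict[str, dict[str, int]]


_GENE_LEN = 3000
_GENE_PITCH = 5000


def simulate_synteny_dataset(config: SimConfig) -> SyntenyDataset:
    """Two gene complements related by collinear blocks, with homology
    pairs, tandem noise genes, per-block terpene/defense labels, and LTR
    intervals in inter-anchor gaps of genome A."""
    bs = config.block_spec
    ls = config.label_spec
    rng = _rng(config.seed, "synteny")

    labels_mat = simulate_block_labels(
        bs.n_blocks, ls.p_terpene, ls.p_defense, ls.dependence, rng
    )

    # block b lives on (A scaffold b % n, B scaffold (b // n) % n) so that
    # consecutive blocks on one A scaffold pair with different B scaffolds
    # and chaining cannot merge neighbours
    n_scaf = bs.n_scaffolds
    a_layout: dict[str, list] = {f"A_chr{i + 1}": [] for i in range(n_scaf)}
    b_layout: dict[str, list] = {f"B_chr{i + 1}": [] for i in range(n_scaf)}

    blocks_meta = []
    for b in range(bs.n_blocks):
        scaf_a = f"A_chr{b % n_scaf + 1}"
        scaf_b = f"B_chr{(b // n_scaf) % n_scaf + 1}"
        orientation = "same" if rng.random() < 0.5 else "inverted"
        anchors = [
            (f"ga_{b:04d}_{i:03d}", f"gb_{b:04d}_{i:03d}")
            for i in range(bs.anchors_per_block)
        ]
        blocks_meta.append((b, scaf_a, scaf_b, orientation, anchors))
        a_layout[scaf_a].append((b, [x for x, _ in anchors]))
        b_side = [y for _, y in anchors]
        if orientation == "inverted":
            b_side = b_side[::-1]
        b_layout[scaf_b].append((b, b_side))

    genes_a: list[GeneModel] = []
    genes_b: list[GeneModel] = []
    repeat_intervals: list[tuple[str, int, int]] = []
    noise_counter = 0

    def _emit(
        layout: dict[str, list],
        out: list[GeneModel],
        genome_tag: str,
        with_ltr: bool,
    ) -> dict[str, tuple[int, int]]:
        nonlocal noise_counter
        coords: dict[str, tuple[int, int]] = {}
        for scaf, entries in layout.items():
            pos = 0

            def _place(gid: str) -> None:
                nonlocal pos
                start = pos
                out.append(
                    GeneModel(
                        gene_id=gid,
                        scaffold=scaf,
                        strand="+" if rng.random() < 0.5 else "-",
                        exons=[(start, start + _GENE_LEN)],
                    )
                )
                coords[gid] = (start, start + _GENE_LEN)
                pos += _GENE_PITCH

            for block_idx, gene_ids in entries:
                for j, gid in enumerate(gene_ids):
                    _place(gid)
                    if with_ltr and j < len(gene_ids) - 1:
                        if rng.random() < bs.ltr_rate:
                            gap_s = coords[gid][1]
                            gap_e = pos  # next gene start
                            length = int(rng.integers(200, gap_e - gap_s))
                            off = int(
                                rng.integers(0, gap_e - gap_s - length + 1)
                            )
                            repeat_intervals.append(
                                (scaf, gap_s + off, gap_s + off + length)
                            )
                # tandem noise genes between blocks
                for _ in range(bs.noise_genes_per_gap):
                    noise_counter += 1
                    _place(f"noise_{genome_tag}_{noise_counter:05d}")
        return coords

    _emit(a_layout, genes_a, "a", with_ltr=True)
    _emit(b_layout, genes_b, "b", with_ltr=False)

    pairs = [
        HomologyPair(ga, gb)
        for _, _, _, _, anchors in blocks_meta
        for ga, gb in anchors
    ]

    by_id = {g.gene_id: g for g in genes_a + genes_b}
    block_labels: list[set[str]] = []
    true_blocks: list[SyntenicBlock] = []
    per_scaffold: dict[str, dict[str, int]] = {}
    truth_rows = []
    for (b, scaf_a, scaf_b, orientation, anchors) in blocks_meta:
        terp, defe = labels_mat[b]
        labels_here = set()
        for flag, label in ((terp, "terpene"), (defe, "defense")):
            if flag:
                labels_here.add(label)
                ga, gb = anchors[int(rng.integers(len(anchors)))]
                for gid in (ga, gb):
                    gene = by_id[gid]
                    if label not in gene.labels:
                        gene.labels.add(label)
                        per_scaffold.setdefault(gene.scaffold, {}).setdefault(
                            label, 0
                        )
                        per_scaffold[gene.scaffold][label] += 1
        block_labels.append(labels_here)
        true_blocks.append(
            SyntenicBlock(
                block_id=str(b),
                scaffold_a=scaf_a,
                scaffold_b=scaf_b,
                anchors=anchors,
                orientation=orientation,
            )
        )
        truth_rows.append(
            {
                "block_id": b,
                "scaffold_a": scaf_a,
                "scaffold_b": scaf_b,
                "orientation": orientation,
                "n_anchors": len(anchors),
                "has_terpene": bool(terp),
                "has_defense": bool(defe),
            }
        )
    return SyntenyDataset(
        genes_a=genes_a,
        genes_b=genes_b,
        pairs=pairs,
        true_blocks=true_blocks,
        repeat_intervals=repeat_intervals,
        block_labels=block_labels,
        truth=pd.DataFrame(truth_rows),
        per_scaffold_label_counts=per_scaffold,
    )


# ---- k-mer histogram ------------------------------------------------------

def simulate_kmer_histogram(config: SimConfig) -> KmerHistogram:
    """Diploid k-mer spectrum: an error spike at low depth, a heterozygous
    peak near coverage/2 (two haplotype-specific k-mers per heterozygous
    locus), and a homozygous peak near coverage, all with Poisson spread.

    A locus overlaps a heterozygous site with probability 1-(1-h)^k; the
    resulting non-error k-mer mass is genome_size × coverage."""
    ks = config.kmer_spec
    rng = _rng(config.seed, "kmer")
    g, c = ks.genome_size, ks.coverage
    f_het = 1.0 - (1.0 - ks.heterozygosity) ** ks.k
    n_het = int(round(g * f_het))
    n_hom = g - n_het

    depths = [rng.poisson(c, size=n_hom)]
    if n_het:
        depths.append(rng.poisson(c / 2.0, size=2 * n_het))
    n_err = int(round(g * c * ks.error_rate * ks.k))
    if n_err:
        depths.append(1 + rng.poisson(0.05, size=n_err))
    all_depths = np.concatenate(depths)
    counts = np.bincount(all_depths)
    bins = [(d, int(counts[d])) for d in range(1, len(counts)) if counts[d]]
    return KmerHistogram(k=ks.k, bins=bins)


# ---- mapping population ---------------------------------------------------

def simulate_mapping_population(
    config: SimConfig,
) -> tuple[GenotypeMatrix, dict]:
    """Bi-parental mapping population with a sex-linked marker subset.

    Ordinary markers segregate test-cross 1:1 (A:H) or F2-type 1:2:1
    (A:H:B), assigned to scaffolds round-robin. Sex-linked markers sit on
    the designated scaffold and predict sex exactly, apart from an optional
    genotyping error rate (male-heterogametic coding: males H, females A).
    """
    ps = config.popgen_spec
    rng = _rng(config.seed, "popgen")
    n, m = ps.n_offspring, ps.n_markers
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    scaffold_names = [f"Scaffold_{i + 1}" for i in range(ps.n_scaffolds)]
    sex_scaffold = scaffold_names[ps.sex_scaffold_index]

    n_sex = int(round(ps.sex_linked_fraction * m))
    geno = np.empty((m, n), dtype="<U1")
    scaffolds = []
    is_sex_linked = np.zeros(m, dtype=bool)
    for i in range(m):
        if i < n_sex:
            is_sex_linked[i] = True
            scaffolds.append(sex_scaffold)
            row = np.where(sex == "male", "H", "A")
            if ps.genotype_error > 0:
                flip = rng.random(n) < ps.genotype_error
                row = np.where(
                    flip, np.where(row == "H", "A", "H"), row
                )
            geno[i] = row
        else:
            scaffolds.append(scaffold_names[i % ps.n_scaffolds])
            if rng.random() < 0.5:  # test-cross 1:1
                geno[i] = np.where(rng.random(n) < 0.5, "A", "H")
            else:  # F2-type 1:2:1
                u = rng.random(n)
                geno[i] = np.where(u < 0.25, "A", np.where(u < 0.75, "H", "B"))
        if ps.missing_rate > 0:
            miss = rng.random(n) < ps.missing_rate
            geno[i] = np.where(miss, "-", geno[i])
    gm = GenotypeMatrix(
        marker_ids=[f"marker_{i + 1:05d}" for i in range(m)],
        individual_ids=[f"offspring_{j + 1:04d}" for j in range(n)],
        genotypes=geno,
        sex=sex.tolist(),
        scaffolds=scaffolds,
    )
    truth = {
        "sex_scaffold": sex_scaffold,
        "sex_linked_markers": [
            gm.marker_ids[i] for i in range(m) if is_sex_linked[i]
        ],
    }
    return gm, truth


# ---- writers --------------------------------------------------------------

def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """FASTA with 60-column wrapping."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def write_kmer_histogram(hist: KmerHistogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        for depth, count in hist.bins:
            fh.write(f"{depth}\t{count}\n")


def write_pair_fasta(pairs: list[DivergentPair], path: str | Path) -> None:
    """Codon-aligned pairs as consecutive FASTA records (<id>_a, <id>_b)."""
    records = []
    for p in pairs:
        records.append((f"{p.pair_id}_a", p.seq_a))
        records.append((f"{p.pair_id}_b", p.seq_b))
    write_fasta(records, path)
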