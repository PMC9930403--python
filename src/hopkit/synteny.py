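"""Syntenic block detection, MCScanX collinearity I/O, and block content
statistics.

A syntenic block is a run of homologous gene pairs (anchors) whose order is
conserved between two genomic segments — the footprint of shared ancestry
within a genome (duplication) or between genomes (speciation). Blocks can
either be ingested from an MCScanX ``.collinearity`` file or detected here
by dynamic-programming chaining of homology match points in gene-rank
space. The chaining score is plain anchor count; MCScanX's e-value-weighted
scoring is deliberately not reproduced since downstream statistics consume
block membership only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotmerge import GeneModel

__all__ = [
    "HomologyPair",
    "SyntenicBlock",
    "SyntenyConfig",
    "parse_collinearity",
    "write_collinearity",
    "detect_blocks",
    "block_stats",
    "scaffold_feature_counts",
    "read_bed",
]


@dataclass(frozen=True)
class HomologyPair:
    gene_a: str
    gene_b: str
    score: float = 0.0


@dataclass
class SyntenicBlock:
    block_id: str
    scaffold_a: str
    scaffold_b: str
    anchors: list[tuple[str, str]]
    orientation: str = "same"  # or "inverted"
    ks: list[float] | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class SyntenyConfig:
    """``min_anchors=5`` mirrors MCScanX's default MATCH_SIZE; the
    visualisation-style preset uses 10 (MATCH_SIZE 9, i.e. >= 10 anchors).
    ``max_gap`` is in gene-index units on both axes."""

    min_anchors: int = 5
    max_gap: int = 25

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")


VISUALIZATION_PRESET = SyntenyConfig(min_anchors=10, max_gap=25)


# ---- MCScanX collinearity dialect ----------------------------------------

_HEADER = re.compile(
    r"^##\s*Alignment\s+(\S+):\s*score=(\S+)\s+e_value=(\S+)\s+N=(\d+)\s+"
    r"(\S+)&(\S+)\s+(plus|minus)"
)


def parse_collinearity(path: str | Path) -> list[SyntenicBlock]:
    """Parse an MCScanX ``.collinearity`` file.

    Each ``## Alignment`` header opens a block with exactly N anchor lines
    of the form ``n-k: geneA\\tgeneB\\te-value``; other ``#`` lines are
    comments. An anchor-count mismatch against the header N is a hard
    parse error reporting the offending line number.
    """
    blocks: list[SyntenicBlock] = []
    current: SyntenicBlock | None = None
    expected = 0

    def _close(lineno: int) -> None:
        if current is not None and current.n_anchors != expected:
            raise ValueError(
                f"line {lineno}: block {current.block_id} has "
                f"{current.n_anchors} anchors, header says N={expected}"
            )
        if current is not None:
            blocks.append(current)

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            m = _HEADER.match(line)
            if m:
                _close(lineno)
                aln_id, _score, _ev, n, chr_a, chr_b, orient = m.groups()
                current = SyntenicBlock(
                    block_id=aln_id,
                    scaffold_a=chr_a,
                    scaffold_b=chr_b,
                    anchors=[],
                    orientation="same" if orient == "plus" else "inverted",
                )
                expected = int(n)
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if current is None:
                raise ValueError(f"line {lineno}: anchor before any header")
            fields = line.split(":", 1)
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: malformed anchor line")
            parts = fields[1].split()
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: malformed anchor line")
            current.anchors.append((parts[0], parts[1]))
    _close(lineno)
    return blocks


def write_collinearity(blocks: list[SyntenicBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("############### Parameters ###############\n")
        fh.write("# written by hopkit\n")
        for b in blocks:
            orient = "plus" if b.orientation == "same" else "minus"
            fh.write(
                f"## Alignment {b.block_id}: score=0 e_value=0 "
                f"N={b.n_anchors} {b.scaffold_a}&{b.scaffold_b} {orient}\n"
            )
            for i, (ga, gb) in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i}:\t{ga}\t{gb}\t0\n")


# ---- block detection ------------------------------------------------------

def _gene_ranks(genes: list[GeneModel]) -> dict[str, tuple[str, int]]:
    """gene id -> (scaffold, rank along scaffold by start coordinate)."""
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    ranks = {}
    for scaf, gs in by_scaffold.items():
        for i, g in enumerate(sorted(gs, key=lambda g: (g.start, g.gene_id))):
            ranks[g.gene_id] = (scaf, i)
    return ranks


def _chain_points(
    points: list[tuple[int, int, int]], max_gap: int, inverted: bool
):
    """Best chain (max anchor count) of match points monotone increasing in
    the first coordinate and increasing (or decreasing when ``inverted``)
    in the second, with rank gaps <= max_gap on both axes. Returns the list
    of point indices in chain order. O(n^2)."""
    pts = sorted(
        range(len(points)),
        key=lambda i: (points[i][0], -points[i][1] if inverted else points[i][1]),
    )
    n = len(pts)
    best_len = [1] * n
    prev = [-1] * n
    for j in range(n):
        aj, bj, _ = points[pts[j]]
        for i in range(j):
            ai, bi, _ = points[pts[i]]
            if ai >= aj:
                continue
            if inverted:
                if bi <= bj or bi - bj > max_gap:
                    continue
            else:
                if bi >= bj or bj - bi > max_gap:
                    continue
            if aj - ai > max_gap:
                continue
            if best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    if not pts:
        return []
    end = max(range(n), key=lambda j: best_len[j])
    chain = []
    while end != -1:
        chain.append(pts[end])
        end = prev[end]
    return chain[::-1]


def _collapse_tandem(
    genes: list[GeneModel], ranks: dict[str, tuple[str, int]]
) -> dict[str, str]:
    """Map each gene to the first member of its tandem array (consecutive
    same-scaffold genes sharing a ``family`` label member)."""
    rep: dict[str, str] = {}
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for gs in by_scaffold.values():
        gs.sort(key=lambda g: ranks[g.gene_id][1])
        prev = None
        for g in gs:
            fam = next((l for l in g.labels if l.startswith("family:")), None)
            if (
                prev is not None
                and fam is not None
                and fam in prev.labels
            ):
                rep[g.gene_id] = rep[prev.gene_id]
            else:
                rep[g.gene_id] = g.gene_id
            prev = g
    return rep


def detect_blocks(
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    pairs: list[HomologyPair],
    cfg: SyntenyConfig | None = None,
    collapse_tandem: bool = False,
) -> list[SyntenicBlock]:
    """Detect collinear blocks by greedy iterated DP chaining.

    Homology pairs become match points in (rank_a, rank_b) space per
    scaffold pair; the longest monotone chain (same or inverted
    orientation) with gaps <= ``cfg.max_gap`` is extracted, its points
    removed, and the process repeats until the best chain falls below
    ``cfg.min_anchors``. Each match point joins at most one block.
    """
    cfg = cfg or SyntenyConfig()
    ranks_a = _gene_ranks(genes_a)
    ranks_b = _gene_ranks(genes_b)
    if collapse_tandem:
        rep_a = _collapse_tandem(genes_a, ranks_a)
        rep_b = _collapse_tandem(genes_b, ranks_b)
    else:
        rep_a = rep_b = None

    by_scafpair: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    pair_names: dict[tuple[str, str], list[tuple[str, str]]] = {}
    seen = set()
    for idx, p in enumerate(pairs):
        ga = rep_a.get(p.gene_a, p.gene_a) if rep_a else p.gene_a
        gb = rep_b.get(p.gene_b, p.gene_b) if rep_b else p.gene_b
        if ga not in ranks_a or gb not in ranks_b:
            raise KeyError(f"homology pair references unknown gene: {p}")
        if (ga, gb) in seen:
            continue
        seen.add((ga, gb))
        sa, ra = ranks_a[ga]
        sb, rb = ranks_b[gb]
        by_scafpair.setdefault((sa, sb), []).append((ra, rb, idx))
        pair_names.setdefault((sa, sb), []).append((ga, gb))

    blocks: list[SyntenicBlock] = []
    counter = 0
    for (sa, sb) in sorted(by_scafpair):
        points = by_scafpair[(sa, sb)]
        names = pair_names[(sa, sb)]
        active = list(range(len(points)))
        while True:
            sub = [points[i] for i in active]
            best_chain, best_orient = [], "same"
            for inverted in (False, True):
                chain = _chain_points(sub, cfg.max_gap, inverted)
                if len(chain) > len(best_chain):
                    best_chain = chain
                    best_orient = "inverted" if inverted else "same"
            if len(best_chain) < cfg.min_anchors:
                break
            chosen = [active[i] for i in best_chain]
            blocks.append(
                SyntenicBlock(
                    block_id=str(counter),
                    scaffold_a=sa,
                    scaffold_b=sb,
                    anchors=[names[i] for i in chosen],
                    orientation=best_orient,
                )
            )
            counter += 1
            used = set(best_chain)
            active = [a for i, a in enumerate(active) if i not in used]
    return blocks


# ---- block content statistics ---------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (scaffold, start, end) intervals from BED (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.split()
            out.append((cols[0], int(cols[1]), int(cols[2])))
    return out


def _union_coverage(
    intervals: list[tuple[int, int]], window: tuple[int, int]
) -> int:
    """Bases of ``window`` covered by the union of ``intervals``."""
    ws, we = window
    clipped = sorted(
        (max(s, ws), min(e, we)) for s, e in intervals if s < we and e > ws
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def block_stats(
    blocks: list[SyntenicBlock],
    genes: list[GeneModel],
    repeat_intervals: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Per-block content record: anchor count, spans, inter-anchor gaps,
    LTR coverage of the gaps, and member-gene labels.

    Spans and gaps are measured on the A-side scaffold; the LTR fraction is
    union interval coverage of inter-anchor bases (no double counting).
    Spans are reported 1-based closed.
    """
    by_id = {g.gene_id: g for g in genes}
    repeats_by_scaf: dict[str, list[tuple[int, int]]] = {}
    for scaf, s, e in repeat_intervals or []:
        repeats_by_scaf.setdefault(scaf, []).append((s, e))

    rows = []
    for b in blocks:
        members_a = []
        labels: set[str] = set()
        for ga, gb in b.anchors:
            for gid in (ga, gb):
                if gid not in by_id:
                    raise KeyError(
                        f"block {b.block_id} references unknown gene {gid}"
                    )
            members_a.append(by_id[ga])
            labels |= by_id[ga].labels | by_id[gb].labels
        members_a.sort(key=lambda g: g.start)
        gaps = [
            (members_a[i].end, members_a[i + 1].start)
            for i in range(len(members_a) - 1)
            if members_a[i + 1].start > members_a[i].end
        ]
        gap_total = sum(e - s for s, e in gaps)
        ivs = repeats_by_scaf.get(b.scaffold_a, [])
        covered = sum(_union_coverage(ivs, gap) for gap in gaps)
        rows.append(
            {
                "block_id": b.block_id,
                "scaffold_a": b.scaffold_a,
                "scaffold_b": b.scaffold_b,
                "n_anchors": b.n_anchors,
                "orientation": b.orientation,
                "span_a_start": members_a[0].start + 1,
                "span_a_end": members_a[-1].end,
                "gap_bases": gap_total,
                "ltr_bases": covered,
                "ltr_fraction": covered / gap_total if gap_total else 0.0,
                "labels": ",".join(sorted(l for l in labels
                                          if not l.startswith("family:"))),
            }
        )
    return pd.DataFrame(rows)


def scaffold_feature_counts(
    blocks: list[SyntenicBlock], genes: list[GeneModel], label: str
) -> pd.DataFrame:
    """Per-scaffold count of ``label``-carrying genes inside blocks.

    A gene is counted once per scaffold even when it belongs to several
    (possibly overlapping) blocks. Sorted descending by count.
    """
    by_id = {g.gene_id: g for g in genes}
    seen: dict[str, set[str]] = {}
    for b in blocks:
        for ga, gb in b.anchors:
            for gid in (ga, gb):
                g = by_id.get(gid)
                if g is not None and label in g.labels:
                    seen.setdefault(g.scaffold, set()).add(gid)
    rows = [
        {"scaffold": scaf, "n_genes": len(ids)}
        for scaf, ids in seen.items()
    ]
    df = pd.DataFrame(rows, columns=["scaffold", "n_genes"])
    return df.sort_values(
        ["n_genes", "scaffold"], ascending=[False, True]
    ).reset_index(drop=True)
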