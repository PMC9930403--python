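"""Hypergeometric term enrichment with Benjamini–Hochberg correction, and
the observed-vs-expected co-occurrence statistic for feature classes in
syntenic blocks.

The co-occurrence question: given N syntenic blocks of which n_A carry one
feature class (say terpene-synthase genes) and n_B another (defense
response), do more blocks carry *both* than independence predicts? The
expected count under block-level independence is n_A·n_B/N; significance is
the hypergeometric upper tail with fixed margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentRow",
    "CooccurrenceResult",
    "hypergeom_enrichment",
    "bh_fdr",
    "block_cooccurrence",
    "read_term_map",
]

FDR_THRESHOLD = 0.05


@dataclass
class EnrichmentRow:
    term: str
    k_obs: int
    n_selection: int
    k_term: int
    m_universe: int
    expected: float
    p: float
    q: float


@dataclass
class CooccurrenceResult:
    n_blocks: int
    n_a: int
    n_b: int
    observed_both: int
    expected_both: float
    ratio: float
    p: float


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j>=i} p_(j)·m/j, clipped to 1; stable under ties.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _upper_tail(k: int, m: int, k_term: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n)."""
    return float(stats.hypergeom.sf(k - 1, m, k_term, n))


def hypergeom_enrichment(
    term_map: dict[str, set[str]],
    selection: set[str],
    universe: set[str],
    depletion: bool = False,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment of terms in a gene selection.

    ``term_map`` maps term -> genes carrying it. For each term with at
    least one universe gene, p = P(X >= k_obs) under
    Hypergeometric(M, K_term, n); q-values by BH over all tested terms.
    With ``depletion`` the lower tail P(X <= k_obs) is used instead.
    """
    if not selection <= universe:
        raise ValueError("selection must be a subset of the universe")
    m = len(universe)
    n = len(selection)
    rows = []
    for term in sorted(term_map):
        members = term_map[term] & universe
        k_term = len(members)
        if k_term < 1:
            continue
        k_obs = len(members & selection)
        if depletion:
            p = float(stats.hypergeom.cdf(k_obs, m, k_term, n))
        else:
            p = _upper_tail(k_obs, m, k_term, n)
        rows.append(
            EnrichmentRow(
                term=term,
                k_obs=k_obs,
                n_selection=n,
                k_term=k_term,
                m_universe=m,
                expected=n * k_term / m,
                p=p,
                q=float("nan"),
            )
        )
    if rows:
        qs = bh_fdr([r.p for r in rows])
        for r, q in zip(rows, qs):
            r.q = float(q)
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term, "k": r.k_obs, "n": r.n_selection,
                "K": r.k_term, "M": r.m_universe, "expected": r.expected,
                "p": r.p, "q": r.q,
            }
            for r in rows
        ]
    )


def block_cooccurrence(
    block_labels: list[set[str]], label_a: str, label_b: str
) -> CooccurrenceResult:
    """Observed vs independence-expected count of blocks carrying both
    labels.

    expected = n_A·n_B/N (block-level marginal rates); p is the
    hypergeometric upper tail of drawing >= observed A-labelled blocks
    among the n_B B-labelled blocks out of N.
    """
    n = len(block_labels)
    if n == 0:
        raise ValueError("no blocks")
    n_a = sum(1 for ls in block_labels if label_a in ls)
    n_b = sum(1 for ls in block_labels if label_b in ls)
    both = sum(1 for ls in block_labels if label_a in ls and label_b in ls)
    expected = n_a * n_b / n
    return CooccurrenceResult(
        n_blocks=n,
        n_a=n_a,
        n_b=n_b,
        observed_both=both,
        expected_both=expected,
        ratio=both / expected if expected > 0 else float("nan"),
        p=_upper_tail(both, n, n_a, n_b),
    )


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> term -> gene-set mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                     dtype=str)
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.term, set()).add(row.gene)
    return out
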