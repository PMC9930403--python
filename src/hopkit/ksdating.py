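"""Ks estimation, log-scale mixture modelling, and divergence dating.

The workflow mirrors the standard paranome/ortholog Ks analysis used to date
whole-genome duplications and speciation events in plants:

1. per-pair synonymous divergence (Ks) by Nei–Gojobori (1986) counting with
   Jukes–Cantor correction,
2. a filter to the informative range (allelic variants below, saturation
   above),
3. a Gaussian finite mixture fitted to ln(Ks) by EM, with the number of
   components selected by the integrated complete-data likelihood (ICL),
4. conversion of a component mean Ks to an absolute date via T = Ks/(2λ),
   where λ is the assumed synonymous substitution rate per site per year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._codon import (
    NONSYN_DIFFS,
    NONSYN_SITES,
    SYN_DIFFS,
    SYN_SITES,
    codons_to_indices,
)

__all__ = [
    "CodonAlignment",
    "KsEstimate",
    "LogKsMixture",
    "DivergenceEstimate",
    "ClockLRTResult",
    "ks_ng86",
    "filter_ks",
    "fit_log_ks_mixture",
    "select_primary_component",
    "divergence_time",
    "clock_lrt",
    "jukes_cantor",
]

VARIANCE_FLOOR = 1e-6
LOW_CODON_THRESHOLD = 30


@dataclass
class CodonAlignment:
    """A pre-aligned, in-frame coding sequence pair."""

    pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.pair_id}: unequal sequence lengths")
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.pair_id}: length not divisible by 3")


@dataclass
class KsEstimate:
    pair_id: str
    ks: float  # nan when saturated
    ka: float
    syn_sites: float
    nonsyn_sites: float
    codons_used: int
    flags: frozenset[str] = frozenset()


@dataclass
class LogKsMixture:
    """A K-component Gaussian mixture on ln(Ks), sorted by mean."""

    k: int
    weights: np.ndarray
    means: np.ndarray  # natural-log Ks scale
    sds: np.ndarray
    log_likelihood: float
    bic: float
    icl: float
    n: int

    @property
    def ks_means(self) -> np.ndarray:
        """Component means back-transformed to the Ks scale."""
        return np.exp(self.means)

    def responsibilities(self, log_values: np.ndarray) -> np.ndarray:
        dens = self.weights * stats.norm.pdf(
            log_values[:, None], self.means, self.sds
        )
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total


@dataclass
class DivergenceEstimate:
    ks: float
    lam: float  # substitutions per synonymous site per year
    t_mya: float


@dataclass
class ClockLRTResult:
    lnl_strict: float
    lnl_relaxed: float
    statistic: float
    df: int
    p: float
    nesting_violation: bool = False


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4)·ln(1 - 4p/3); nan for p >= 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ks_ng86(aln: CodonAlignment) -> KsEstimate:
    """Nei–Gojobori (1986) Ks/Ka for one codon-aligned pair.

    Site counts enumerate all single-nucleotide changes per codon under the
    standard genetic code (stops excluded) and are averaged across the two
    sequences; multi-difference codons are averaged over minimal mutational
    pathways. Proportions are Jukes–Cantor corrected; ps >= 3/4 flags
    saturation with Ks undefined. Codons containing gaps, ambiguity codes or
    stops in either sequence are masked out.
    """
    ia = codons_to_indices(aln.seq_a)
    ib = codons_to_indices(aln.seq_b)
    valid = (ia >= 0) & (ib >= 0)
    n_used = int(valid.sum())
    if n_used == 0:
        raise ValueError(f"{aln.pair_id}: no valid codon pairs")
    ia, ib = ia[valid], ib[valid]

    s_sites = 0.5 * (SYN_SITES[ia].sum() + SYN_SITES[ib].sum())
    n_sites = 0.5 * (NONSYN_SITES[ia].sum() + NONSYN_SITES[ib].sum())
    sd = SYN_DIFFS[ia, ib].sum()
    nd = NONSYN_DIFFS[ia, ib].sum()

    flags = set()
    if n_used < LOW_CODON_THRESHOLD:
        flags.add("low_codons")

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if np.isnan(ks) or np.isnan(ka):
        flags.add("saturated")
    return KsEstimate(
        pair_id=aln.pair_id,
        ks=float(ks),
        ka=float(ka),
        syn_sites=float(s_sites),
        nonsyn_sites=float(n_sites),
        codons_used=n_used,
        flags=frozenset(flags),
    )


def filter_ks(
    estimates: list[KsEstimate], lo: float = 0.01, hi: float = 2.0
) -> list[KsEstimate]:
    """Retain estimates with lo <= Ks <= hi (inclusive).

    The defaults bracket the informative range: the lower bound removes
    allelic variants, the upper bound avoids saturated comparisons. Saturated
    or undefined estimates are always dropped.
    """
    if lo > hi:
        raise ValueError(f"lo={lo} > hi={hi}")
    kept = [
        e
        for e in estimates
        if "saturated" not in e.flags
        and np.isfinite(e.ks)
        and lo <= e.ks <= hi
    ]
    if estimates and not kept:
        warnings.warn("all Ks estimates removed by filter", stacklevel=2)
    return kept


# ---- mixture modelling ---------------------------------------------------

def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator):
    """k-means++-style seeding of component means; weights uniform, sds from
    a hard assignment to the nearest seed."""
    means = np.empty(k)
    means[0] = rng.choice(x)
    for j in range(1, k):
        d2 = np.min((x[:, None] - means[None, :j]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            means[j:] = means[0]
            break
        means[j] = rng.choice(x, p=d2 / total)
    assign = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
    sds = np.empty(k)
    global_sd = max(np.std(x), np.sqrt(VARIANCE_FLOOR))
    for j in range(k):
        member = x[assign == j]
        sds[j] = np.std(member) if member.size > 1 else global_sd
    sds = np.maximum(sds, np.sqrt(VARIANCE_FLOOR))
    weights = np.full(k, 1.0 / k)
    return weights, means, sds


def _em_fit(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 1000,
    tol: float = 1e-8,
):
    """One EM run on 1-D data with unequal variances. Returns
    (weights, means, sds, logL). logL is checked to be non-decreasing."""
    n = x.size
    weights, means, sds = _kmeanspp_init(x, k, rng)
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E step in a numerically safe log formulation
        log_dens = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi)
            - np.log(sds)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        )
        m = log_dens.max(axis=1, keepdims=True)
        log_total = m + np.log(np.exp(log_dens - m).sum(axis=1, keepdims=True))
        ll = float(log_total.sum())
        if ll + 1e-9 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        resp = np.exp(log_dens - log_total)
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, VARIANCE_FLOOR))
        if prev_ll > -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    return weights, means, sds, prev_ll


def _model_from_fit(weights, means, sds, ll, x) -> LogKsMixture:
    order = np.argsort(means)
    weights, means, sds = weights[order], means[order], sds[order]
    n = x.size
    k = means.size
    n_params = 3 * k - 1
    bic = 2.0 * ll - n_params * np.log(n)
    model = LogKsMixture(
        k=k,
        weights=weights,
        means=means,
        sds=sds,
        log_likelihood=ll,
        bic=float(bic),
        icl=float("nan"),
        n=n,
    )
    resp = model.responsibilities(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(resp > 0, resp * np.log(resp), 0.0).sum()
    model.icl = float(bic - 2.0 * ent)
    return model


def fit_log_ks_mixture(
    ks_values,
    k_range=range(1, 6),
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[dict[int, LogKsMixture], LogKsMixture]:
    """Fit Gaussian mixtures to ln(Ks) for each K and select by ICL.

    For each K the best of ``n_restarts`` EM runs (by log-likelihood) is
    kept; BIC = 2·logL - m·ln(n) with m = 3K-1 free parameters, and
    ICL = BIC - 2·Σ ẑ·ln ẑ penalises overlapping components. Returns
    (per-K models, model with maximal ICL).
    """
    x = np.log(np.asarray(ks_values, dtype=float))
    if x.size < 10:
        raise ValueError("need at least 10 positive Ks values")
    if not np.all(np.isfinite(x)):
        raise ValueError("Ks values must be positive and finite")
    rng = np.random.default_rng(seed)

    if np.ptp(x) == 0:  # degenerate: all values identical
        model = _model_from_fit(
            np.array([1.0]),
            np.array([x[0]]),
            np.array([np.sqrt(VARIANCE_FLOOR)]),
            float(
                stats.norm.logpdf(x, x[0], np.sqrt(VARIANCE_FLOOR)).sum()
            ),
            x,
        )
        return {1: model}, model

    models: dict[int, LogKsMixture] = {}
    for k in k_range:
        best = None
        for _ in range(n_restarts):
            child = np.random.default_rng(rng.integers(2**31))
            try:
                fit = _em_fit(x, k, child)
            except AssertionError:
                continue
            if best is None or fit[3] > best[3]:
                best = fit
        if best is None:
            continue
        models[k] = _model_from_fit(*best, x)
    selected = max(models.values(), key=lambda m: m.icl)
    return models, selected


def select_primary_component(model: LogKsMixture, ks_values) -> int:
    """Index of the component whose mean is nearest the modal ln(Ks) peak.

    The mode is the midpoint of the highest-count histogram bin with
    Freedman–Diaconis bin width; ties in distance resolve to the smaller
    mean (the more recent event).
    """
    x = np.log(np.asarray(ks_values, dtype=float))
    edges = np.histogram_bin_edges(x, bins="fd")
    counts, edges = np.histogram(x, bins=edges)
    top = int(np.argmax(counts))
    mode = 0.5 * (edges[top] + edges[top + 1])
    dist = np.abs(model.means - mode)
    # argmin returns the first (smallest-mean) index on exact ties because
    # means are sorted ascending
    return int(np.argmin(np.round(dist, 12)))


def divergence_time(ks: float, lam: float) -> DivergenceEstimate:
    """Date a duplication/divergence event: T = Ks/(2λ), reported in mya."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return DivergenceEstimate(ks=ks, lam=lam, t_mya=ks / (2.0 * lam) / 1e6)


def lambda_sensitivity(ks: float, lambdas) -> list[DivergenceEstimate]:
    """Divergence dates for one Ks under a set of candidate λ values."""
    return [divergence_time(ks, lam) for lam in lambdas]


def clock_lrt(lnl_strict: float, lnl_relaxed: float, df: int) -> ClockLRTResult:
    """Likelihood-ratio test of a strict vs relaxed molecular clock:
    LRT = -2(ln Ls - ln Lg), chi-squared with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not (np.isfinite(lnl_strict) and np.isfinite(lnl_relaxed)):
        raise ValueError("log-likelihoods must be finite")
    statistic = -2.0 * (lnl_strict - lnl_relaxed)
    violation = statistic < 0
    if violation:
        warnings.warn(
            "relaxed-clock likelihood below strict-clock likelihood: "
            "models may not be nested as assumed",
            stacklevel=2,
        )
    p = float(stats.chi2.sf(statistic, df)) if statistic >= 0 else 1.0
    return ClockLRTResult(
        lnl_strict=lnl_strict,
        lnl_relaxed=lnl_relaxed,
        statistic=float(statistic),
        df=df,
        p=p,
        nesting_violation=bool(violation),
    )
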