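"""Assembly summary statistics, oligonucleotide composition, and k-mer-based
genome profiling.

Three independent views of an assembly:

* contiguity and base content (N50/N90, GC%, how much of the assembly the
  largest scaffolds carry),
* observed-vs-expected short-word composition — plant genomes typically show
  CG (CpG) depletion and CHH enrichment (H = A, C or T), the trinucleotide
  contexts relevant to plant DNA methylation,
* a simplified diploid k-mer spectrum model recovering haploid genome size,
  heterozygosity and the error component from a (depth, count) histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ScaffoldSet",
    "OligoReport",
    "KmerHistogram",
    "KmerProfile",
    "assembly_stats",
    "oligo_composition",
    "kmer_profile",
    "read_fasta",
    "read_kmer_histogram",
]

_H = "ACT"  # IUPAC H: not G


def _ratio(obs: float, exp: float) -> float:
    """observed/expected; an unobservable word (expected 0) that is indeed
    absent has ratio 0, not NaN."""
    if exp > 0:
        return obs / exp
    return 0.0 if obs == 0 else float("nan")


@dataclass
class ScaffoldSet:
    """Ordered (id, sequence) records over the {A,C,G,T,N} alphabet."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate scaffold ids")
        if any(not seq for _, seq in self.records):
            raise ValueError("empty sequence")


@dataclass
class OligoReport:
    mono_freq: dict[str, float]
    dinuc: pd.DataFrame  # word, observed, expected, ratio
    trinuc_classes: pd.DataFrame  # class, observed, expected, ratio


@dataclass
class KmerHistogram:
    k: int
    bins: list[tuple[int, int]]  # (depth >= 1, count >= 0)

    def __post_init__(self) -> None:
        depths = [d for d, _ in self.bins]
        if any(d < 1 for d in depths):
            raise ValueError("depths must be >= 1")
        if any(b >= a for a, b in zip(depths[1:], depths)):
            raise ValueError("depths must be strictly increasing")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        d = np.array([d for d, _ in self.bins])
        c = np.array([c for _, c in self.bins], dtype=float)
        return d, c


@dataclass
class KmerProfile:
    genome_size_bp: float
    heterozygosity: float
    error_kmer_fraction: float
    hom_peak_depth: int
    het_peak_depth: int | None
    het_peak_found: bool
    notes: list[str] = field(default_factory=list)


def read_fasta(path: str | Path) -> ScaffoldSet:
    from Bio import SeqIO

    return ScaffoldSet(
        [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    )


def read_kmer_histogram(path: str | Path, k: int = 21) -> KmerHistogram:
    """Two-column whitespace-delimited (depth, count) file."""
    arr = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return KmerHistogram(k=k, bins=[(int(d), int(c)) for d, c in arr])


# ---- assembly statistics --------------------------------------------------

def assembly_stats(scaffolds: ScaffoldSet, top_k: int = 10) -> dict:
    """Contiguity/content summary.

    N50 is the length of the scaffold at which the length-sorted cumulative
    sum first reaches 50% of the total (N90 analogous). GC% is computed
    over non-N bases.
    """
    if not scaffolds.records:
        raise ValueError("empty scaffold set")
    lengths = np.array(sorted(
        (len(s) for _, s in scaffolds.records), reverse=True
    ))
    total = int(lengths.sum())
    cum = np.cumsum(lengths)

    def n_stat(frac: float) -> int:
        return int(lengths[np.searchsorted(cum, frac * total)])

    gc = n_count = 0
    for _, seq in scaffolds.records:
        gc += seq.count("G") + seq.count("C")
        n_count += seq.count("N")
    non_n = total - n_count
    top = min(top_k, len(lengths))
    return {
        "n_scaffolds": len(lengths),
        "total_length": total,
        "n50": n_stat(0.5),
        "n90": n_stat(0.9),
        "gc_percent": 100.0 * gc / non_n if non_n else float("nan"),
        "n_percent": 100.0 * n_count / total,
        "top_k": top,
        "top_k_fraction": float(cum[top - 1] / total),
        "cumulative_lengths": cum.tolist(),
    }


# ---- oligonucleotide composition -----------------------------------------

def _window_counts(seq: str, w: int) -> tuple[dict[str, int], int]:
    """Counts of ACGT-only windows of width w on the given strand, plus the
    number of valid windows; windows containing N (or any non-ACGT
    character) are skipped."""
    counts: dict[str, int] = {}
    valid = 0
    n = len(seq)
    i = 0
    while i + w <= n:
        word = seq[i:i + w]
        ok = all(c in "ACGT" for c in word)
        if ok:
            counts[word] = counts.get(word, 0) + 1
            valid += 1
        i += 1
    return counts, valid


def oligo_composition(scaffolds: ScaffoldSet) -> OligoReport:
    """Observed vs expected di- and trinucleotide composition.

    Expected counts use a zero-order (mononucleotide product) null:
    E[w] = (number of valid windows) × Π mono_freq(base). Counting is on
    the given strand only — no reverse-complement folding. Trinucleotides
    are aggregated into methylation-context classes (CG-containing, CHG,
    CHH; H ∈ {A,C,T}).
    """
    mono: dict[str, int] = {b: 0 for b in "ACGT"}
    di_counts: dict[str, int] = {}
    tri_counts: dict[str, int] = {}
    di_windows = tri_windows = 0
    total_non_n = 0
    for _, seq in scaffolds.records:
        for b in "ACGT":
            mono[b] += seq.count(b)
        d, nw = _window_counts(seq, 2)
        for w, c in d.items():
            di_counts[w] = di_counts.get(w, 0) + c
        di_windows += nw
        t, nw = _window_counts(seq, 3)
        for w, c in t.items():
            tri_counts[w] = tri_counts.get(w, 0) + c
        tri_windows += nw
    total_non_n = sum(mono.values())
    if total_non_n < 3:
        raise ValueError("need at least 3 non-N bases")
    freq = {b: mono[b] / total_non_n for b in "ACGT"}

    di_rows = []
    for w in ("".join(p) for p in product("ACGT", repeat=2)):
        obs = di_counts.get(w, 0)
        exp = di_windows * freq[w[0]] * freq[w[1]]
        di_rows.append({
            "word": w, "observed": obs, "expected": exp,
            "ratio": _ratio(obs, exp),
        })

    def class_words(name: str):
        if name == "CG_containing":
            return [
                "".join(w) for w in product("ACGT", repeat=3)
                if "CG" in "".join(w)
            ]
        if name == "CHG":
            return [f"C{h}G" for h in _H]
        if name == "CHH":
            return [f"C{h1}{h2}" for h1 in _H for h2 in _H]
        raise KeyError(name)

    tri_rows = []
    for name in ("CG_containing", "CHG", "CHH"):
        words = class_words(name)
        obs = sum(tri_counts.get(w, 0) for w in words)
        exp = sum(
            tri_windows * freq[w[0]] * freq[w[1]] * freq[w[2]]
            for w in words
        )
        tri_rows.append({
            "class": name, "observed": obs, "expected": exp,
            "ratio": _ratio(obs, exp),
        })
    return OligoReport(
        mono_freq=freq,
        dinuc=pd.DataFrame(di_rows),
        trinuc_classes=pd.DataFrame(tri_rows),
    )


# ---- k-mer profile --------------------------------------------------------

def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-bin moving average with edge replication."""
    padded = np.concatenate([y[:1], y, y[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def _local_extrema(y: np.ndarray):
    """Indices of local maxima and minima on a smoothed series; plateau
    ties resolve toward higher depth (rightmost index)."""
    maxima, minima = [], []
    n = len(y)
    for i in range(n):
        left = y[i - 1] if i > 0 else -np.inf
        right = y[i + 1] if i < n - 1 else -np.inf
        if y[i] >= left and y[i] > right:
            maxima.append(i)
        left = y[i - 1] if i > 0 else np.inf
        right = y[i + 1] if i < n - 1 else np.inf
        if y[i] <= left and y[i] < right:
            minima.append(i)
    return maxima, minima


def kmer_profile(hist: KmerHistogram) -> KmerProfile:
    """Genome size, heterozygosity, and error content from a k-mer
    spectrum.

    The error region is everything below the first local minimum (the
    trough after the low-depth error spike). The homozygous peak is the
    highest-count local maximum beyond the trough (ties toward higher
    depth); genome size = Σ(depth × count over non-error bins) divided by
    the homozygous peak depth.

    Heterozygosity comes from the heterozygous k-mer mass fraction m: the
    non-error histogram is decomposed by nonnegative least squares into two
    fixed-mean Poisson components at the het and hom peak depths, giving
    m = het mass / total mass; since a k-mer overlaps a heterozygous site
    with probability 1-(1-h)^k, the estimate is h = 1-(1-m)^(1/k), whose
    small-h first-order form is the familiar m/k.
    """
    depth, count = hist.arrays()
    if count.sum() == 0:
        raise ValueError("empty histogram")
    smooth = _smooth3(count)
    maxima, minima = _local_extrema(smooth)

    trough_candidates = [
        i for i in minima
        if any(j > i and smooth[j] > smooth[i] for j in maxima)
    ]
    if not trough_candidates:
        raise ValueError(
            "no k-mer peak found above the error trough; cannot estimate "
            "genome size"
        )
    trough = trough_candidates[0]
    # noise filter: spurious maxima in the sparse right tail are far below
    # the real peaks
    tallest = max(smooth[i] for i in maxima if i > trough)
    signal_maxima = [
        i for i in maxima if i > trough and smooth[i] >= 0.05 * tallest
    ]
    if not signal_maxima:
        raise ValueError("no local maximum beyond the error trough")
    # highest count, ties toward higher depth
    top_i = max(signal_maxima, key=lambda i: (smooth[i], depth[i]))

    non_error = depth > depth[trough]
    mass = float((depth[non_error] * count[non_error]).sum())
    total_mass = float((depth * count).sum())
    d = depth[non_error].astype(float)
    c = count[non_error]

    def _nnls_at(mu: float):
        design = np.column_stack([
            stats.poisson.pmf(d, mu / 2.0),
            stats.poisson.pmf(d, mu),
        ])
        coef, resid = optimize.nnls(design, c)
        return coef, resid

    def _fit_near(mu0: float):
        res = optimize.minimize_scalar(
            lambda mu: _nnls_at(mu)[1],
            bounds=(0.8 * mu0, 1.2 * mu0),
            method="bounded",
        )
        return float(res.fun), float(res.x)

    # The tallest peak is the homozygous one in a mostly homozygous genome
    # but the *heterozygous* (half-coverage) one when heterozygosity is
    # high; at moderate coverage the homozygous peak can even reduce to a
    # shoulder with no local maximum. Decide by fitting the tied
    # two-Poisson model (het mean = hom mean / 2) under both readings of
    # the top peak and keeping the better fit; ties prefer the
    # top-is-homozygous reading.
    fit_hom = _fit_near(float(depth[top_i]))
    fit_het = _fit_near(2.0 * float(depth[top_i]))
    if fit_het[0] < 0.95 * fit_hom[0]:
        mu_hom = fit_het[1]
        het_i = top_i
    else:
        mu_hom = fit_hom[1]
        halves = [
            i for i in signal_maxima
            if 0.4 * depth[top_i] <= depth[i] <= 0.6 * depth[top_i]
        ]
        het_i = (
            max(halves, key=lambda i: (smooth[i], depth[i]))
            if halves else None
        )
    hom_depth = int(round(mu_hom))
    het_found = het_i is not None
    het_depth = int(depth[het_i]) if het_found else None

    coef, _ = _nnls_at(mu_hom)
    genome_size = mass / mu_hom

    het_mass = coef[0] * mu_hom / 2.0
    hom_mass = coef[1] * mu_hom
    m = het_mass / (het_mass + hom_mass) if (het_mass + hom_mass) > 0 else 0.0
    heterozygosity = 1.0 - (1.0 - min(m, 1.0 - 1e-12)) ** (1.0 / hist.k)
    notes = []
    if not het_found:
        notes.append("no distinct heterozygous peak detected")
    return KmerProfile(
        genome_size_bp=genome_size,
        heterozygosity=float(heterozygosity),
        error_kmer_fraction=float(1.0 - mass / total_mass),
        hom_peak_depth=hom_depth,
        het_peak_depth=het_depth,
        het_peak_found=het_found,
        notes=notes,
    )
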