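"""Standard-genetic-code tables for Nei–Gojobori (1986) site and difference
counting.

All quantities are precomputed once at import over the 61 sense codons:

* per-codon synonymous/nonsynonymous site counts (nonsense changes excluded
  by renormalising each position over its sense outcomes, so every codon
  contributes exactly 3 sites),
* per-codon-pair synonymous/nonsynonymous difference counts, averaged over
  the minimal mutational pathways that avoid stop codons,
* the synonymous single-nucleotide neighbourhood of each codon (used by the
  sequence simulator to apply strictly synonymous substitutions).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

_BASES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in _table.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = {c: _table.forward_table[c] for c in SENSE_CODONS}

N_SENSE = len(SENSE_CODONS)  # 61


def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Each position contributes one site, split by the fraction of its three
    single-nucleotide changes that are synonymous; changes to stop codons are
    ignored (removed from both numerator and denominator).
    """
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if AMINO_ACID[alt] == AMINO_ACID[codon]:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _step_type(c_from: str, c_to: str) -> float:
    """1.0 if the single-nucleotide step is synonymous, else 0.0.

    Steps into or out of a stop codon count as nonsynonymous (only reachable
    on the all-pathways fallback).
    """
    if c_from in STOP_CODONS or c_to in STOP_CODONS:
        return 0.0
    return 1.0 if AMINO_ACID[c_from] == AMINO_ACID[c_to] else 0.0


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between two
    sense codons over minimal mutational pathways.

    Pathways passing through a stop codon are discarded; if every pathway is
    discarded (possible only for some 2–3-step pairs) all pathways are used
    with stop steps counted as nonsynonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = c1
        syn = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                through_stop = True
            syn += _step_type(cur, nxt)
            cur = nxt
        paths.append((through_stop, syn))
    valid = [syn for stop, syn in paths if not stop]
    if valid:
        mean_syn = float(np.mean(valid))
    else:
        mean_syn = float(np.mean([syn for _, syn in paths]))
    return mean_syn, len(diff_pos) - mean_syn


# ---- module-level tables -------------------------------------------------

SYN_SITES = np.empty(N_SENSE)
NONSYN_SITES = np.empty(N_SENSE)
for _i, _c in enumerate(SENSE_CODONS):
    SYN_SITES[_i], NONSYN_SITES[_i] = _codon_sites(_c)

SYN_DIFFS = np.zeros((N_SENSE, N_SENSE))
NONSYN_DIFFS = np.zeros((N_SENSE, N_SENSE))
for _i, _c1 in enumerate(SENSE_CODONS):
    for _j in range(_i + 1, N_SENSE):
        _sd, _nd = _pair_differences(_c1, SENSE_CODONS[_j])
        SYN_DIFFS[_i, _j] = SYN_DIFFS[_j, _i] = _sd
        NONSYN_DIFFS[_i, _j] = NONSYN_DIFFS[_j, _i] = _nd

# codon index -> tuple of codon indices reachable by one synonymous
# single-nucleotide change
SYN_NEIGHBORS: tuple[tuple[int, ...], ...] = tuple(
    tuple(
        CODON_INDEX[c[:pos] + b + c[pos + 1:]]
        for pos in range(3)
        for b in _BASES
        if b != c[pos]
        and c[:pos] + b + c[pos + 1:] not in STOP_CODONS
        and AMINO_ACID[c[:pos] + b + c[pos + 1:]] == AMINO_ACID[c]
    )
    for c in SENSE_CODONS
)


def codons_to_indices(seq: str) -> np.ndarray:
    """Codon index array for an in-frame sequence; -1 marks codons that are
    stops or contain non-ACGT characters."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    seq = seq.upper()
    return np.array(
        [CODON_INDEX.get(seq[i:i + 3], -1) for i in range(0, len(seq), 3)],
        dtype=np.int64,
    )


def indices_to_seq(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)
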