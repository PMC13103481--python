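"""Codon tables shared by the sequence simulator and the NG86 estimator.

Everything here is precomputed once at import: codon indexing, the standard
genetic code, per-codon synonymous site fractions, single-nucleotide mutation
outcomes, and the pathway-averaged synonymous/nonsynonymous difference counts
for every codon pair.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

BASES = "TCAG"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: all 64 codons in TCAG-major order
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(c.replace("U", "T") for c in _table.stop_codons)

#: amino acid per codon, "*" for stops
AMINO = {}
for _c in CODONS:
    AMINO[_c] = "*" if _c in STOP_CODONS else _table.forward_table[_c]

SENSE_CODON_IDS = np.array(
    [CODON_INDEX[c] for c in CODONS if c not in STOP_CODONS], dtype=np.int64
)

# mutation outcome kinds
SYN, NONSYN, STOP = 0, 1, 2


def _alternatives(base: str) -> list[str]:
    return [b for b in BASES if b != base]


def _single_changes(codon: str, pos: int):
    """Yield (new_codon, kind) for the 3 single-nucleotide changes at pos."""
    for alt in _alternatives(codon[pos]):
        new = codon[:pos] + alt + codon[pos + 1:]
        if new in STOP_CODONS:
            yield new, STOP
        elif AMINO[new] == AMINO[codon]:
            yield new, SYN
        else:
            yield new, NONSYN


# SYN_SITES[i]: NG86 synonymous site count of codon i (changes to stop codons
# count as nonsynonymous, so syn + nonsyn sites always total 3 per codon).
SYN_SITES = np.full(64, np.nan)
for _c in CODONS:
    if _c in STOP_CODONS:
        continue
    s = 0.0
    for pos in range(3):
        n_syn = sum(1 for _, kind in _single_changes(_c, pos) if kind == SYN)
        s += n_syn / 3.0
    SYN_SITES[CODON_INDEX[_c]] = s

# MUT_NEW[i, pos, k] / MUT_KIND[i, pos, k]: outcome of mutating codon i at
# position pos to its k-th alternative base (alternatives in TCAG order).
MUT_NEW = np.zeros((64, 3, 3), dtype=np.int64)
MUT_KIND = np.zeros((64, 3, 3), dtype=np.int64)
for _c in CODONS:
    i = CODON_INDEX[_c]
    for pos in range(3):
        for k, (new, kind) in enumerate(_single_changes(_c, pos)):
            MUT_NEW[i, pos, k] = CODON_INDEX[new]
            MUT_KIND[i, pos, k] = kind


def _pathways(a: str, b: str):
    """All minimal mutational pathways from codon a to codon b.

    Each pathway is a list of (syn?, intermediate codon) steps; pathways that
    pass through a stop codon are excluded. Returns (sd, nd) lists, one entry
    per admissible pathway.
    """
    diff = [p for p in range(3) if a[p] != b[p]]
    results = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            new = cur[:pos] + b[pos] + cur[pos + 1:]
            if new in STOP_CODONS:
                ok = False
                break
            if AMINO[new] == AMINO[cur]:
                sd += 1
            else:
                nd += 1
            cur = new
        if ok:
            results.append((sd, nd))
    return results


# Pathway-averaged difference counts per ordered codon pair. PAIR_OK is False
# where every minimal pathway passes through a stop codon (such codon pairs
# are skipped entirely by the estimator).
PAIR_SD = np.zeros((64, 64))
PAIR_ND = np.zeros((64, 64))
PAIR_OK = np.zeros((64, 64), dtype=bool)
for _a in CODONS:
    if _a in STOP_CODONS:
        continue
    ia = CODON_INDEX[_a]
    for _b in CODONS:
        if _b in STOP_CODONS:
            continue
        ib = CODON_INDEX[_b]
        paths = _pathways(_a, _b)
        if paths:
            PAIR_SD[ia, ib] = float(np.mean([p[0] for p in paths]))
            PAIR_ND[ia, ib] = float(np.mean([p[1] for p in paths]))
            PAIR_OK[ia, ib] = True


def encode_codons(seq: str) -> np.ndarray:
    """Map an in-frame DNA string to an array of codon indices.

    Raises ValueError on length not divisible by 3 or non-ACGT characters
    (gap codons are handled upstream).
    """
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    try:
        idx = [CODON_INDEX[seq[i:i + 3]] for i in range(0, len(seq), 3)]
    except KeyError as e:
        raise ValueError(f"non-ACGT codon in sequence: {e}") from None
    return np.asarray(idx, dtype=np.int64)


def decode_codons(idx: np.ndarray) -> str:
    return "".join(CODONS[i] for i in idx)
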