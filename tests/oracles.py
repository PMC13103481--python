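"""Independent brute-force oracles used by the tests.

These are deliberately naive re-derivations from first principles — direct
enumeration, no shared tables with the package — so that agreement with the
implementation is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def codon_syn_sites(codon: str) -> float:
    """Fraction-weighted synonymous site count of one codon (stops count
    as nonsynonymous changes)."""
    total = 0.0
    for pos in range(3):
        n_syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            new = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[new] != "*" and GENETIC_CODE[new] == GENETIC_CODE[codon]:
                n_syn += 1
        total += n_syn / 3.0
    return total


def codon_pair_diffs(a: str, b: str):
    """Pathway-averaged (syn, nonsyn) differences between two sense codons.

    Returns None when every minimal pathway passes through a stop codon.
    """
    positions = [p for p in range(3) if a[p] != b[p]]
    per_path = []
    for order in itertools.permutations(positions):
        cur = a
        sd = nd = 0
        valid = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                valid = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            per_path.append((sd, nd))
    if not per_path:
        return None
    return (
        sum(p[0] for p in per_path) / len(per_path),
        sum(p[1] for p in per_path) / len(per_path),
    )


def ng86_oracle(seq_a: str, seq_b: str):
    """Naive NG86: returns (S, N, Sd, Nd, Ks or None)."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        diffs = codon_pair_diffs(ca, cb)
        if diffs is None:
            continue
        n_codons += 1
        s = (codon_syn_sites(ca) + codon_syn_sites(cb)) / 2.0
        S += s
        Sd += diffs[0]
        Nd += diffs[1]
    N = 3.0 * n_codons - S
    pS = Sd / S if S else 0.0
    ks = None if pS >= 0.75 else -0.75 * math.log(1.0 - 4.0 * pS / 3.0)
    return S, N, Sd, Nd, ks


def set_partitions(items, k):
    """All partitions of ``items`` into exactly k non-empty groups."""
    items = list(items)

    def rec(i, groups):
        if i == len(items):
            if len(groups) == k:
                yield [set(g) for g in groups]
            return
        # place items[i] into an existing group or open a new one
        for g in groups:
            g.append(items[i])
            yield from rec(i + 1, groups)
            g.pop()
        if len(groups) < k:
            groups.append([items[i]])
            yield from rec(i + 1, groups)
            groups.pop()

    yield from rec(0, [])


def best_partition(cmap, unitigs, k):
    """Exhaustive-search partition maximizing total within-group density."""

    def objective(groups):
        links = 0
        pair_bp2 = 0.0
        for g in groups:
            gs = sorted(g)
            for i in range(len(gs)):
                for j in range(i + 1, len(gs)):
                    links += cmap.get(gs[i], gs[j])
                    pair_bp2 += cmap.lengths[gs[i]] * cmap.lengths[gs[j]]
        return links / pair_bp2 if pair_bp2 else 0.0

    best, best_obj = None, -1.0
    for groups in set_partitions(unitigs, k):
        obj = objective(groups)
        if obj > best_obj:
            best, best_obj = groups, obj
    return best, best_obj
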