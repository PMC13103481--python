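"""Polyploid Hi-C haplotype-group phasing.

The phasing stage mirrors a modified ALLHiC-style workflow operating on one
homologous chromosome group at a time: Hi-C contacts between allelic unitigs
(unitigs carrying copies of the same reference gene, hence from different
haplotypes) are pruned; the remaining contacts drive clustering into K
haplotype groups; unitigs with large sequence overlaps inside one group are
deduplicated by keeping the member with the higher Hi-C link density; and
ungrouped unitigs are rescued into the strongest-contact group they do not
conflict with. Link density is defined as summed link counts between a
unitig and a reference set, divided by the unitig's length in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ContactMap",
    "OverlapRecord",
    "OverlapSet",
    "Grouping",
    "link_density",
    "prune_allelic",
    "partition_groups",
    "dedup_overlaps",
    "rescue_ungrouped",
    "assign_by_alignment",
    "detect_collapse",
    "phasing_accuracy",
]


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class ContactMap:
    """Symmetric sparse unitig x unitig Hi-C link counts plus unitig lengths."""

    def __init__(self, lengths: dict[str, int], counts: dict[tuple[str, str], int] | None = None):
        for u, ln in lengths.items():
            if ln <= 0:
                raise ValueError(f"unitig {u} has non-positive length {ln}")
        self.lengths = dict(lengths)
        self._counts: dict[tuple[str, str], int] = {}
        if counts:
            for (a, b), c in counts.items():
                self.set(a, b, c)

    @property
    def unitigs(self) -> list[str]:
        return sorted(self.lengths)

    def get(self, a: str, b: str) -> int:
        return self._counts.get(_key(a, b), 0)

    def set(self, a: str, b: str, count: int) -> None:
        if a == b:
            raise ValueError(f"self-pair contact for {a}")
        if a not in self.lengths or b not in self.lengths:
            raise KeyError(f"unknown unitig in pair ({a}, {b})")
        if count < 0:
            raise ValueError(f"negative count for ({a}, {b})")
        k = _key(a, b)
        if count == 0:
            self._counts.pop(k, None)
        else:
            self._counts[k] = int(count)

    def pairs(self):
        """Iterate (a, b, count) over stored nonzero pairs, sorted."""
        for (a, b) in sorted(self._counts):
            yield a, b, self._counts[(a, b)]

    def copy(self) -> "ContactMap":
        return ContactMap(self.lengths, dict(self._counts))

    def links_between(self, unitig: str, group) -> int:
        return sum(self.get(unitig, m) for m in group if m != unitig)

    def __eq__(self, other) -> bool:
        return (isinstance(other, ContactMap)
                and self.lengths == other.lengths
                and self._counts == other._counts)


@dataclass(frozen=True)
class OverlapRecord:
    """One pairwise unitig alignment (the 12 mandatory PAF columns)."""

    query: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int
    aln_len: int
    mapq: int

    @property
    def identity(self) -> float:
        return self.n_match / self.aln_len if self.aln_len else 0.0


class OverlapSet:
    """Unitig overlap records with large-overlap queries."""

    def __init__(self, records: list[OverlapRecord]):
        self.records = list(records)
        self._by_pair: dict[tuple[str, str], list[OverlapRecord]] = {}
        for r in self.records:
            if r.aln_len > min(r.query_len, r.target_len):
                raise ValueError(
                    f"overlap {r.aln_len} exceeds shorter unitig for "
                    f"({r.query}, {r.target})"
                )
            self._by_pair.setdefault(_key(r.query, r.target), []).append(r)

    def overlap_len(self, a: str, b: str) -> int:
        recs = self._by_pair.get(_key(a, b), [])
        return max((r.aln_len for r in recs), default=0)

    def is_large(self, a: str, b: str, lengths: dict[str, int],
                 large_frac: float = 0.5, min_identity: float = 0.9) -> bool:
        """True if a and b share an overlap covering >= large_frac of the
        shorter unitig at >= min_identity."""
        shorter = min(lengths[a], lengths[b])
        for r in self._by_pair.get(_key(a, b), []):
            if r.aln_len >= large_frac * shorter and r.identity >= min_identity:
                return True
        return False


@dataclass
class Grouping:
    """K haplotype groups plus an ungrouped pool for one chromosome group."""

    groups: list[set[str]]
    ungrouped: set[str] = field(default_factory=set)

    def all_unitigs(self) -> set[str]:
        out = set(self.ungrouped)
        for g in self.groups:
            out |= g
        return out

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.groups + [self.ungrouped]:
            if seen & g:
                raise ValueError(f"unitigs in multiple groups: {seen & g}")
            seen |= g

    def copy(self) -> "Grouping":
        return Grouping([set(g) for g in self.groups], set(self.ungrouped))


def link_density(cmap: ContactMap, unitig: str, group) -> float:
    """Summed links from ``unitig`` to ``group`` members per bp of ``unitig``."""
    if unitig not in cmap.lengths:
        raise KeyError(f"unknown unitig {unitig}")
    return cmap.links_between(unitig, group) / cmap.lengths[unitig]


def prune_allelic(cmap: ContactMap, alleles: dict[str, set[str]]) -> ContactMap:
    """Zero all contacts among each gene's allelic unitig set.

    Returns a new map; idempotent and never increases any count.
    """
    out = cmap.copy()
    for unitig_set in alleles.values():
        us = sorted(u for u in unitig_set if u in out.lengths)
        for i in range(len(us)):
            for j in range(i + 1, len(us)):
                out.set(us[i], us[j], 0)
    return out


def partition_objective(cmap: ContactMap, clusters) -> float:
    """Global within-group link density of a partition.

    Total link count over all within-group unitig pairs, divided by the
    summed length products of those pairs (links per bp^2); zero when no
    within-group pair exists. Hi-C link counts scale with the sizes of the
    interacting regions, so this normalization keeps the intra/background
    contrast independent of unitig length, and the single global ratio
    avoids the degenerate optima that per-group ratio sums admit (isolating
    one dense pair as its own group).
    """
    links = 0
    pair_bp2 = 0.0
    for c in clusters:
        us = sorted(c)
        for i in range(len(us)):
            for j in range(i + 1, len(us)):
                links += cmap.get(us[i], us[j])
                pair_bp2 += cmap.lengths[us[i]] * cmap.lengths[us[j]]
    return links / pair_bp2 if pair_bp2 else 0.0


def partition_groups(cmap: ContactMap, K: int, unitigs=None) -> Grouping:
    """Cluster unitigs into K groups by Hi-C link density.

    Greedy agglomerative clustering with average-density linkage (links
    between two clusters over the summed length products of their cross
    pairs), followed by a deterministic local-move refinement that
    maximizes the sum of within-group link densities. Ties break on the
    lexicographically smallest member id.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    ids = sorted(unitigs) if unitigs is not None else cmap.unitigs
    if len(ids) < K:
        raise ValueError(f"cannot form {K} groups from {len(ids)} unitigs")
    clusters: list[set[str]] = [{u} for u in ids]

    def linkage(x, y) -> float:
        links = sum(cmap.get(a, b) for a in x for b in y)
        pair_bp2 = sum(cmap.lengths[a] * cmap.lengths[b] for a in x for b in y)
        return links / pair_bp2

    while len(clusters) > K:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = linkage(clusters[i], clusters[j])
                tie = (min(clusters[i]), min(clusters[j]))
                if best is None or (-d, tie) < (best[0], best[1]):
                    best = (-d, tie, i, j)
        _, _, i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]

    # local refinement: move single unitigs between clusters while the
    # objective improves; deterministic sweep order
    improved = True
    while improved:
        improved = False
        for u in ids:
            src = next(k for k, c in enumerate(clusters) if u in c)
            if len(clusters[src]) == 1:
                continue
            base = partition_objective(cmap, clusters)
            best_gain, best_dst = 1e-12, None
            for dst in range(len(clusters)):
                if dst == src:
                    continue
                clusters[src].remove(u)
                clusters[dst].add(u)
                gain = partition_objective(cmap, clusters) - base
                clusters[dst].remove(u)
                clusters[src].add(u)
                if gain > best_gain:
                    best_gain, best_dst = gain, dst
            if best_dst is not None:
                clusters[src].remove(u)
                clusters[best_dst].add(u)
                improved = True

    clusters.sort(key=min)
    return Grouping(groups=clusters)


@dataclass(frozen=True)
class RemovalLogEntry:
    group_index: int
    removed: str
    kept: str
    removed_density: float
    kept_density: float
    overlap_len: int


def dedup_overlaps(
    grouping: Grouping,
    cmap: ContactMap,
    overlaps: OverlapSet,
    large_frac: float = 0.5,
    min_identity: float = 0.9,
):
    """Remove the lower-density member of each large-overlap pair in a group.

    Overlapping in-group pairs are processed in descending overlap length
    (ties on ids); for each pair still co-grouped, the member with the lower
    link density to the rest of the group moves to the ungrouped pool.
    Densities are recomputed after every removal. Returns (new grouping,
    removal log).
    """
    if not 0 < large_frac <= 1:
        raise ValueError("large_frac must be in (0, 1]")
    g = grouping.copy()
    log: list[RemovalLogEntry] = []
    for gi, group in enumerate(g.groups):
        cand = []
        for a in sorted(group):
            for b in sorted(group):
                if a < b and overlaps.is_large(a, b, cmap.lengths, large_frac, min_identity):
                    cand.append((-overlaps.overlap_len(a, b), a, b))
        for neg_ov, a, b in sorted(cand):
            if a not in group or b not in group:
                continue
            da = link_density(cmap, a, group - {a})
            db = link_density(cmap, b, group - {b})
            # on equal density drop the lexicographically larger id
            drop, keep, dd, dk = (
                (b, a, db, da) if db < da or (db == da and b > a) else (a, b, da, db)
            )
            group.remove(drop)
            g.ungrouped.add(drop)
            log.append(RemovalLogEntry(gi, drop, keep, dd, dk, -neg_ov))
    return g, log


def rescue_ungrouped(
    grouping: Grouping,
    cmap: ContactMap,
    overlaps: OverlapSet,
    large_frac: float = 0.5,
    min_identity: float = 0.9,
) -> Grouping:
    """Place ungrouped unitigs into the strongest non-conflicting group.

    Ungrouped unitigs are processed in descending order of their best
    group-contact signal (link density against any group, computed on the
    input grouping; ties on unitig id). Each is tried against candidate
    groups in descending density order (ties on group index) and joins the
    first group where it has no large overlap with any member; unitigs with
    zero contact signal, or conflicting with every group, stay ungrouped.
    Placements update the groups seen by subsequent unitigs.
    """
    g = grouping.copy()
    pool = sorted(g.ungrouped)
    best0 = {
        u: max(link_density(cmap, u, grp) for grp in g.groups) for u in pool
    }
    for u in sorted(pool, key=lambda u: (-best0[u], u)):
        dens = [(link_density(cmap, u, grp), gi) for gi, grp in enumerate(g.groups)]
        if max(d for d, _ in dens) == 0:
            continue
        for d, gi in sorted(dens, key=lambda t: (-t[0], t[1])):
            if d == 0:
                break
            grp = g.groups[gi]
            conflict = any(
                overlaps.is_large(u, m, cmap.lengths, large_frac, min_identity)
                for m in grp
            )
            if not conflict:
                grp.add(u)
                g.ungrouped.remove(u)
                break
    return g


def assign_by_alignment(hits: dict[str, list[tuple[str, float]]]) -> dict[str, str | None]:
    """Assign each unitig to its best-scoring chromosome.

    ``hits[unitig]`` lists (chromosome, score); the argmax-score chromosome
    wins, ties break to the lowest chromosome id, and unitigs with no hits
    map to None.
    """
    out: dict[str, str | None] = {}
    for u, hlist in hits.items():
        if not hlist:
            out[u] = None
            continue
        out[u] = min(hlist, key=lambda h: (-h[1], h[0]))[0]
    return out


def detect_collapse(window_depths, median_depth: float, fold: float = 1.75):
    """Flag windows whose depth reaches ``fold`` times the genome median.

    ``window_depths`` is an iterable of (chrom, start, end, depth). Returns
    (flagged windows, flagged fraction). Used to check that an assembly
    region is not a collapsed repeat: single-copy regions sit near the
    median while collapsed ones show multiplied mapping depth.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if median_depth == 0:
        raise ValueError("genome median depth is zero")
    windows = list(window_depths)
    flagged = [w for w in windows if w[3] >= fold * median_depth]
    frac = len(flagged) / len(windows) if windows else 0.0
    return flagged, frac


def phasing_accuracy(grouping: Grouping, truth_haplotype: dict[str, int],
                     lengths: dict[str, int]) -> float:
    """Length-weighted fraction of correctly grouped unitigs.

    Group labels are arbitrary, so the best group-to-haplotype matching
    (Hungarian assignment on length weights) is used. Ungrouped unitigs do
    not enter the denominator.
    """
    haps = sorted({truth_haplotype[u] for g in grouping.groups for u in g})
    if not haps:
        return 0.0
    hap_idx = {h: i for i, h in enumerate(haps)}
    W = np.zeros((len(grouping.groups), len(haps)))
    total = 0
    for gi, g in enumerate(grouping.groups):
        for u in g:
            W[gi, hap_idx[truth_haplotype[u]]] += lengths[u]
            total += lengths[u]
    rows, cols = linear_sum_assignment(W, maximize=True)
    return float(W[rows, cols].sum() / total)
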