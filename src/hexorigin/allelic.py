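"""Allelic gene pairing across haplotypes and multiplicity classification.

Orthologous (allelic) gene pairs between haplotypes are selected from scored
similarity hits by a c-score filter (a relaxation of reciprocal best hits),
chained into collinear blocks on gene-rank coordinates, reduced to one-to-one
pairs, and finally merged across all haplotype pairs into allelic loci:
connected components of the pair graph carrying at most one gene per
haplotype. Loci are classified by allele multiplicity (sextuple ... double);
genes in no retained pair are singletons.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["AllelicLocus", "cscore_pairs", "build_loci", "MULTIPLICITY_CLASSES"]

MULTIPLICITY_CLASSES = {
    6: "sextuple",
    5: "quintuple",
    4: "quadruple",
    3: "triple",
    2: "double",
    1: "singleton",
}

HIT_COLUMNS = [
    "gene_a", "hap_a", "chrom_a", "rank_a",
    "gene_b", "hap_b", "chrom_b", "rank_b", "score",
]


@dataclass
class AllelicLocus:
    locus_id: str
    members: dict[int, str]  # haplotype -> gene id

    @property
    def multiplicity(self) -> int:
        return len(self.members)

    @property
    def klass(self) -> str:
        return MULTIPLICITY_CLASSES[self.multiplicity]


def cscore_pairs(
    hits: pd.DataFrame,
    cscore: float = 0.7,
    dist: int = 20,
    min_size: int = 4,
) -> pd.DataFrame:
    """One-to-one allelic gene pairs per haplotype pair.

    Three filters applied in sequence within each (hap_a, hap_b):

    1. c-score: a hit (i, j) is kept iff
       score(i, j) >= cscore * max(best score of i, best score of j);
       cscore = 1.0 reduces to reciprocal best hits.
    2. collinearity: kept hits on one chromosome pair, sorted by rank,
       are chained into blocks where consecutive hits differ by <= ``dist``
       gene ranks on both haplotypes; blocks with fewer than ``min_size``
       hits are dropped.
    3. one-to-one: surviving hits are taken in descending score, keeping a
       hit only if neither gene is already paired.
    """
    if not 0 < cscore <= 1:
        raise ValueError("cscore must be in (0, 1]")
    if dist < 1 or min_size < 1:
        raise ValueError("dist and min_size must be >= 1")
    if (hits["score"] < 0).any():
        raise ValueError("hit scores must be non-negative")

    kept_frames = []
    for (_, _), sub in hits.groupby(["hap_a", "hap_b"], sort=True):
        sub = sub.reset_index(drop=True)
        best_a = sub.groupby("gene_a")["score"].max()
        best_b = sub.groupby("gene_b")["score"].max()
        thresh = cscore * pd.DataFrame({
            "a": best_a.reindex(sub["gene_a"]).to_numpy(),
            "b": best_b.reindex(sub["gene_b"]).to_numpy(),
        }).max(axis=1).to_numpy()
        sub = sub[sub["score"].to_numpy() >= thresh]

        # collinear chaining on gene ranks, per chromosome pair
        surviving = []
        for (_, _), blk in sub.groupby(["chrom_a", "chrom_b"], sort=True):
            blk = blk.sort_values(["rank_a", "rank_b", "gene_a", "gene_b"])
            block_rows: list[pd.Series] = []
            prev = None
            for _, row in blk.iterrows():
                if prev is not None and (
                    abs(row["rank_a"] - prev["rank_a"]) <= dist
                    and abs(row["rank_b"] - prev["rank_b"]) <= dist
                ):
                    block_rows.append(row)
                else:
                    if len(block_rows) >= min_size:
                        surviving.extend(block_rows)
                    block_rows = [row]
                prev = row
            if len(block_rows) >= min_size:
                surviving.extend(block_rows)
        if not surviving:
            continue
        surv = pd.DataFrame(surviving)

        surv = surv.sort_values(
            ["score", "gene_a", "gene_b"], ascending=[False, True, True]
        )
        used_a: set = set()
        used_b: set = set()
        rows = []
        for _, row in surv.iterrows():
            if row["gene_a"] in used_a or row["gene_b"] in used_b:
                continue
            used_a.add(row["gene_a"])
            used_b.add(row["gene_b"])
            rows.append(row)
        kept_frames.append(pd.DataFrame(rows))

    if not kept_frames:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return pd.concat(kept_frames, ignore_index=True)[HIT_COLUMNS]


def build_loci(pairs: pd.DataFrame, gene_haplotype: dict[str, int]):
    """Merge one-to-one pairs into allelic loci and take the census.

    Loci are connected components of the pair graph. A component holding two
    genes of one haplotype is repaired by iteratively dropping its
    lowest-score edge (ties on endpoint ids) until every component is valid.
    ``gene_haplotype`` supplies the gene universe; genes in no surviving
    pair are singletons. Returns (loci, census) where census maps
    multiplicity class name -> count.
    """
    G = nx.Graph()
    G.add_nodes_from(gene_haplotype)
    for _, row in pairs.iterrows():
        G.add_edge(row["gene_a"], row["gene_b"], score=float(row["score"]))

    def invalid(component) -> bool:
        haps = [gene_haplotype[g] for g in component]
        return len(haps) != len(set(haps))

    queue = [c for c in nx.connected_components(G) if len(c) > 1]
    while queue:
        comp = queue.pop()
        if not invalid(comp):
            continue
        edges = sorted(
            G.subgraph(comp).edges(data="score"),
            key=lambda e: (e[2], min(e[0], e[1]), max(e[0], e[1])),
        )
        u, v, _ = edges[0]
        G.remove_edge(u, v)
        for piece in nx.connected_components(G.subgraph(comp)):
            if len(piece) > 1:
                queue.append(set(piece))

    loci: list[AllelicLocus] = []
    census = {name: 0 for name in MULTIPLICITY_CLASSES.values()}
    comps = sorted(nx.connected_components(G), key=min)
    for i, comp in enumerate(comps):
        if len(comp) == 1:
            census["singleton"] += 1
            continue
        members = {gene_haplotype[g]: g for g in comp}
        loci.append(AllelicLocus(locus_id=f"locus{i:06d}", members=members))
        census[MULTIPLICITY_CLASSES[len(comp)]] += 1
    return loci, census
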