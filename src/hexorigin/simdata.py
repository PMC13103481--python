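"""Truth-annotated synthetic hexaploid data generator.

Emulates the evolutionary scenario of a natural allohexaploid formed from a
diploid ancestor (subgenome A, haplotypes 1-2) and an autotetraploid ancestor
(subgenome B, haplotypes 3-6): the two ancestral species diverge t_div years
ago, the tetraploid forms by a whole-genome duplication at t_wgdt (WGDt), and
hybridization plus chromosome doubling produce the hexaploid at t_wgdh
(WGDh). Coding sequences evolve along this event tree with synonymous sites
mutating at rate r_syn per site per year and nonsynonymous sites at
omega * r_syn, using a Jukes-Cantor proposal scheme consistent with the NG86
estimator applied downstream.

On top of the sequences the module fabricates the assembly-stage inputs of a
Hi-C phasing pipeline — unitigs, block-structured contact counts, allelic
unitig overlaps (PAF), an allele table — and a negative-binomial expression
matrix with subgenome dominance and allele-specific effects, all with full
ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codon import (
    MUT_KIND,
    MUT_NEW,
    NONSYN,
    SENSE_CODON_IDS,
    STOP,
    decode_codons,
)
from .phasing import ContactMap, OverlapRecord, OverlapSet

__all__ = [
    "HistoryParams",
    "SimTruth",
    "simulate_haplotype_cds",
    "fragment_and_contacts",
    "simulate_expression",
    "SUBGENOME_A",
    "SUBGENOME_B",
]

SUBGENOME_A = (1, 2)
SUBGENOME_B = (3, 4, 5, 6)
HAPLOTYPES = SUBGENOME_A + SUBGENOME_B


@dataclass(frozen=True)
class HistoryParams:
    """Event times and mutational parameters of the hexaploid scenario.

    Times are years before present; t_div > t_wgdt > t_wgdh >= 0. The default
    CDS length (1500 codons) is chosen so that the per-gene clock resolution
    (one synonymous substitution over ~1125 synonymous sites, i.e. dKs ~9e-4)
    resolves the most recent event at Ks ~ 0.003.
    """

    t_div: float = 7.9e6
    t_wgdt: float = 0.88e6
    t_wgdh: float = 0.44e6
    r_syn: float = 3.39e-9
    omega: float = 0.2
    n_genes: int = 500
    codons_per_gene: int = 1500
    seed: int = 0
    #: which B-haplotype pairs coalesce at t_wgdh (the rest split at t_wgdt)
    b_topology: tuple = ((3, 4), (5, 6))

    def validate(self) -> None:
        if not (self.t_div > self.t_wgdt > self.t_wgdh >= 0):
            raise ValueError(
                "event times must satisfy t_div > t_wgdt > t_wgdh >= 0, got "
                f"{self.t_div}, {self.t_wgdt}, {self.t_wgdh}"
            )
        if self.r_syn <= 0:
            raise ValueError("r_syn must be positive")
        if not 0 <= self.omega <= 1:
            raise ValueError("omega must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.codons_per_gene < 10:
            raise ValueError(
                "codons_per_gene < 10 makes per-gene Ks numerically unstable"
            )
        flat = sorted(h for pair in self.b_topology for h in pair)
        if flat != sorted(SUBGENOME_B) or any(len(p) != 2 for p in self.b_topology):
            raise ValueError(
                f"b_topology must pair up haplotypes {SUBGENOME_B}, got "
                f"{self.b_topology}"
            )


@dataclass
class SimTruth:
    """Ground truth emitted by the generator, used only for recovery tests.

    Coordinates are 0-based half-open. ``gene_haplotype`` maps each gene copy
    id to its haplotype of origin; ``unitigs`` maps unitig id to
    (haplotype, chromosome, start, end).
    """

    params: HistoryParams
    gene_haplotype: dict[str, int] = field(default_factory=dict)
    unitigs: dict[str, tuple[int, str, int, int]] = field(default_factory=dict)
    gene_unitig: dict[str, str] = field(default_factory=dict)
    ase_effects: dict[str, float] = field(default_factory=dict)  # copy id -> signed log2
    dominance_log2: float = 0.0

    def coalescence_time(self, hap_a: int, hap_b: int) -> float:
        """Divergence time of two haplotype copies under the event tree."""
        p = self.params
        if hap_a == hap_b:
            return 0.0
        a_in_A = hap_a in SUBGENOME_A
        b_in_A = hap_b in SUBGENOME_A
        if a_in_A != b_in_A:
            return p.t_div
        if a_in_A:
            return p.t_wgdh
        for pair in p.b_topology:
            if hap_a in pair and hap_b in pair:
                return p.t_wgdh
        return p.t_wgdt


def _evolve(seq: np.ndarray, t_years: float, params: HistoryParams,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve a codon-index array for t_years; returns a new array.

    Nucleotide sites receive mutation proposals at rate r_syn per year; the
    proposed target base is uniform among the 3 alternatives (Jukes-Cantor).
    Synonymous proposals always fix, nonsynonymous ones with probability
    omega, stop-creating ones never — so the fixed synonymous rate per NG86
    synonymous site is exactly r_syn.
    """
    seq = seq.copy()
    n_sites = 3 * seq.size
    lam = params.r_syn * t_years * n_sites
    n_events = rng.poisson(lam) if lam > 0 else 0
    if n_events == 0:
        return seq
    sites = rng.integers(0, n_sites, size=n_events)
    alts = rng.integers(0, 3, size=n_events)
    accept_u = rng.random(size=n_events)
    for s, k, u in zip(sites, alts, accept_u):
        ci, pos = divmod(int(s), 3)
        cur = seq[ci]
        kind = MUT_KIND[cur, pos, k]
        if kind == STOP:
            continue
        if kind == NONSYN and u >= params.omega:
            continue
        seq[ci] = MUT_NEW[cur, pos, k]
    return seq


def simulate_haplotype_cds(params: HistoryParams):
    """Simulate six per-haplotype CDS sets along the hexaploid event tree.

    Returns (cds, truth) where ``cds[hap][copy_id]`` is a DNA string. Copy
    ids are ``g{i:05d}_h{hap}``; all six copies of gene i descend from one
    random ancestral CDS. Deterministic under ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    p = params
    (b1a, b1b), (b2a, b2b) = p.b_topology

    cds: dict[int, dict[str, str]] = {h: {} for h in HAPLOTYPES}
    truth = SimTruth(params=params)
    for i in range(p.n_genes):
        gene = f"g{i:05d}"
        anc = rng.choice(SENSE_CODON_IDS, size=p.codons_per_gene)
        # subgenome A lineage: root -> WGDh split -> hap1, hap2
        a_anc = _evolve(anc, p.t_div - p.t_wgdh, p, rng)
        tips = {
            1: _evolve(a_anc, p.t_wgdh, p, rng),
            2: _evolve(a_anc, p.t_wgdh, p, rng),
        }
        # subgenome B lineage: root -> WGDt split -> two WGDh splits
        b_anc = _evolve(anc, p.t_div - p.t_wgdt, p, rng)
        for pair in ((b1a, b1b), (b2a, b2b)):
            mid = _evolve(b_anc, p.t_wgdt - p.t_wgdh, p, rng)
            for hap in pair:
                tips[hap] = _evolve(mid, p.t_wgdh, p, rng)
        for hap in HAPLOTYPES:
            copy_id = f"{gene}_h{hap}"
            cds[hap][copy_id] = decode_codons(tips[hap])
            truth.gene_haplotype[copy_id] = hap
    return cds, truth


def fragment_and_contacts(
    truth: SimTruth,
    lambda_intra: float = 20.0,
    lambda_allelic: float = 4.0,
    lambda_bg: float = 1.0,
    n_unitigs_per_hap: int = 10,
    geneless_fraction: float = 0.2,
    overlap_fraction: float = 0.7,
    overlap_identity: float = 0.97,
    gene_spacing_bp: int = 3000,
    seed: int = 0,
):
    """Cut each haplotype into unitigs and draw block-structured contacts.

    Contact counts are Poisson with base rate ``lambda_intra`` for
    same-haplotype unitig pairs, ``lambda_allelic`` for cross-haplotype pairs
    sharing a gene in the allele table, ``lambda_bg`` otherwise; each pair's
    rate is scaled by its length product relative to the mean unitig length
    squared, emulating the coverage dependence of Hi-C link counts (so
    length-normalized link densities keep the intra/background contrast). Allelic unitig pairs are
    emitted as PAF-style overlaps spanning ``overlap_fraction`` of the
    shorter unitig. ``geneless_fraction`` of the unitigs on each haplotype
    carry no gene (rescue fodder); these are positioned between gene blocks.

    Returns (contact_map, overlaps, allele_table, hits) where hits maps
    gene-less unitigs to (chromosome, score) alignment evidence. Updates
    ``truth.unitigs`` and ``truth.gene_unitig`` in place.
    """
    if not lambda_intra > lambda_allelic >= lambda_bg >= 0:
        raise ValueError(
            "need lambda_intra > lambda_allelic >= lambda_bg >= 0, got "
            f"{lambda_intra}, {lambda_allelic}, {lambda_bg}"
        )
    if n_unitigs_per_hap < 2:
        raise ValueError("each haplotype chromosome needs >= 2 unitigs")
    p = truth.params
    rng = np.random.default_rng(seed)
    n_free = int(round(geneless_fraction * n_unitigs_per_hap))
    n_genic = n_unitigs_per_hap - n_free
    if n_genic < 1 or p.n_genes < n_genic:
        raise ValueError(
            f"cannot place {p.n_genes} genes on {n_genic} gene-carrying unitigs"
        )

    lengths: dict[str, int] = {}
    allele_table: dict[str, set[str]] = {f"g{i:05d}": set() for i in range(p.n_genes)}
    hits: dict[str, list[tuple[str, float]]] = {}
    chrom = "chr1"
    for hap in HAPLOTYPES:
        # split the gene list into n_genic consecutive blocks (same cuts
        # would be fine, but varied cuts per haplotype exercise more paths)
        cuts = np.sort(
            rng.choice(np.arange(1, p.n_genes), size=n_genic - 1, replace=False)
        ) if n_genic > 1 else np.array([], dtype=int)
        blocks = np.split(np.arange(p.n_genes), cuts)
        slots = ["genic"] * n_genic + ["free"] * n_free
        order = rng.permutation(len(slots))
        pos = 0
        genic_i = 0
        for k, slot_idx in enumerate(order):
            uid = f"utg_h{hap}_{k:03d}"
            if slots[slot_idx] == "genic":
                block = blocks[genic_i]
                genic_i += 1
                length = int(block.size) * gene_spacing_bp
                for gi in block:
                    gene = f"g{gi:05d}"
                    copy_id = f"{gene}_h{hap}"
                    truth.gene_unitig[copy_id] = uid
                    allele_table[gene].add(uid)
            else:
                length = int(rng.integers(1, 4)) * gene_spacing_bp
                hits[uid] = [(chrom, float(length) * overlap_identity)]
            lengths[uid] = length
            truth.unitigs[uid] = (hap, chrom, pos, pos + length)
            pos += length

    # allelic pairs = cross-haplotype unitig pairs sharing >= 1 gene
    allelic_pairs = set()
    for unitig_set in allele_table.values():
        us = sorted(unitig_set)
        for i in range(len(us)):
            for j in range(i + 1, len(us)):
                allelic_pairs.add((us[i], us[j]))

    ids = sorted(lengths)
    mean_len = float(np.mean([lengths[u] for u in ids]))
    counts: dict[tuple[str, str], int] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if truth.unitigs[a][0] == truth.unitigs[b][0]:
                lam = lambda_intra
            elif (a, b) in allelic_pairs:
                lam = lambda_allelic
            else:
                lam = lambda_bg
            lam *= (lengths[a] * lengths[b]) / (mean_len * mean_len)
            c = int(rng.poisson(lam)) if lam > 0 else 0
            if c > 0:
                counts[(a, b)] = c
    cmap = ContactMap(lengths, counts)

    records = []
    for a, b in sorted(allelic_pairs):
        shorter = min(lengths[a], lengths[b])
        ov = int(round(overlap_fraction * shorter))
        records.append(OverlapRecord(
            query=a, query_len=lengths[a], query_start=0, query_end=ov,
            strand="+",
            target=b, target_len=lengths[b], target_start=0, target_end=ov,
            n_match=int(round(overlap_identity * ov)), aln_len=ov,
            mapq=60,
        ))
    overlaps = OverlapSet(records)
    return cmap, overlaps, allele_table, hits


def simulate_expression(
    truth: SimTruth,
    mu: float = 200.0,
    dispersion: float = 10.0,
    dominance_log2: float = 1.0,
    ase_fraction: float = 0.2,
    ase_log2: float = 2.0,
    n_timepoints: int = 4,
    n_reps: int = 3,
    seed: int = 0,
):
    """Negative-binomial counts per gene copy per sample.

    Subgenome-B copies get a ``dominance_log2`` mean shift; a random
    ``ase_fraction`` of loci get +/- ``ase_log2`` on one randomly chosen
    allele (constant across timepoints). Samples are named ``DAF{t}_R{r}``
    (days after flooding x replicate). Returns a pandas DataFrame of counts
    (gene copies x samples); the planted effects are stored in
    ``truth.ase_effects`` and ``truth.dominance_log2``.
    """
    import pandas as pd

    if mu <= 0 or dispersion <= 0:
        raise ValueError("mu and dispersion must be positive")
    if not 0 <= ase_fraction <= 1:
        raise ValueError("ase_fraction must be in [0, 1]")
    p = truth.params
    rng = np.random.default_rng(seed)

    genes = [f"g{i:05d}" for i in range(p.n_genes)]
    n_ase = int(round(ase_fraction * p.n_genes))
    ase_loci = rng.choice(p.n_genes, size=n_ase, replace=False)
    truth.ase_effects = {}
    truth.dominance_log2 = dominance_log2
    for gi in ase_loci:
        hap = int(rng.choice(HAPLOTYPES))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.ase_effects[f"{genes[gi]}_h{hap}"] = sign * ase_log2

    samples = [f"DAF{t}_R{r + 1}" for t in range(n_timepoints) for r in range(n_reps)]
    rows = []
    index = []
    for gene in genes:
        for hap in HAPLOTYPES:
            copy_id = f"{gene}_h{hap}"
            m = mu
            if hap in SUBGENOME_B:
                m *= 2.0 ** dominance_log2
            m *= 2.0 ** truth.ase_effects.get(copy_id, 0.0)
            # numpy NB: n = size (dispersion), p = n / (n + mean)
            prob = dispersion / (dispersion + m)
            rows.append(rng.negative_binomial(dispersion, prob, size=len(samples)))
            index.append(copy_id)
    return pd.DataFrame(rows, index=index, columns=samples)
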