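"""Published summary statistics of the hexaploid Actinidia valvata 'DE'
haplotype-resolved assembly, used as reference inputs for consistency
arithmetic (the raw sequencing data itself is out of scope here).
"""

from __future__ import annotations

#: annotated protein-coding genes per haplotype (hap1..hap6)
GENES_PER_HAPLOTYPE = (30352, 29975, 26322, 25649, 25371, 24892)

#: genes shared with at least one other haplotype, per haplotype
SHARED_GENES_PER_HAPLOTYPE = (29640, 29070, 25806, 25184, 24932, 24343)

#: allelic locus census by multiplicity (sextuple .. double), plus singletons
ALLELIC_LOCUS_CENSUS = {
    "sextuple": 7023,
    "quintuple": 7372,
    "quadruple": 7845,
    "triple": 6005,
    "double": 8383,
    "singleton": 17402,
}

#: sextuple loci with a significant allele-specific expression pattern
ASE_SEXTUPLE_LOCI = 6233

#: neutral synonymous substitution rate used for clock dating (per site/year)
SYNONYMOUS_RATE = 3.39e-9

#: reported Ks peak positions of the allelic-pair distributions
KS_PEAKS = {
    "wgdh": 0.003,        # hexaploid-forming duplication, hap1 x hap2
    "wgdt": 0.006,        # tetraploid-forming duplication, within hap3..6
    "divergence_lo": 0.051,  # subgenome A x B divergence peak range
    "divergence_hi": 0.056,
}


def total_annotated_genes() -> int:
    return sum(GENES_PER_HAPLOTYPE)


def total_shared_genes() -> int:
    return sum(SHARED_GENES_PER_HAPLOTYPE)
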