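# hexorigin

Origin analysis of a hexaploid genome: Hi-C haplotype-group phasing,
allelic gene pairing, synonymous-substitution (Ks) dating of
polyploidization events, and allele-specific expression (ASE) analysis —
built as a tested, reusable pipeline and exercised end to end on a
synthetic hexaploid benchmark with known truth.

## The problem

Natural polyploids like the hexaploid kiwifruit relative *Actinidia
valvata* (2n = 6x) carry six haploid chromosome complements whose history —
which haplotypes came from which ancestor, and when the duplications
happened — must be reconstructed from the genome itself. The analysis has
four computational cores, each implemented here as a library module:

* **`phasing`** — assign assembly unitigs to haplotype groups from Hi-C
  contacts: prune contacts between *allelic* unitigs (unitigs carrying
  copies of the same reference gene), cluster the rest by link density,
  remove the lower-density member of any large-overlap pair within a group,
  and rescue ungrouped unitigs into the strongest non-conflicting group.
* **`allelic`** — pair orthologous genes across haplotypes with a c-score
  filter (score(i,j) ≥ c·max(best(i), best(j)); c = 1 is reciprocal best
  hits), collinear block chaining, and one-to-one reduction; merge pairs
  into allelic loci classified by multiplicity (sextuple … double,
  singleton).
* **`ksclock`** — Nei–Gojobori (1986) Ks with Jukes–Cantor correction,
  Ks = −(3/4)·ln(1 − (4/3)·pS); per-category kernel density estimates and
  peak detection; molecular-clock dating **T = Ks/(2r)** with
  r = 3.39 × 10⁻⁹ synonymous substitutions/site/year; exhaustive 2 + 4
  subgenome partitioning from the 6 × 6 median-Ks matrix.
* **`ase`** — TPM normalization; per-timepoint allele contrasts
  (|log2FC| > 1 of mean TPM and exact binomial p < 0.05 on pooled counts);
  ASE census over sextuple loci; inconsistent-ASE detection (dominant
  allele switching between timepoints); subgenome dominance summaries.

The **`simdata`** module generates the benchmark: six haplotypes descending
from a diploid ancestor (subgenome A, haplotypes 1–2) and an autotetraploid
ancestor (subgenome B, haplotypes 3–6) that diverged ~7.9 Mya, with the
tetraploid-forming duplication at 0.88 Mya and hexaploidization at
0.44 Mya; block-structured Hi-C contacts; unitig overlaps; and
negative-binomial expression with planted subgenome dominance and allele
effects. `pipeline` composes everything, and `cli` exposes the
`hexorigin` command. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```sh
hexorigin demo --seed 1 --n-genes 200 --out demo_run
```

runs the full synthetic benchmark (simulate → phase → pair → ksdate → ase)
and prints:

```
phasing accuracy: 1.0000
WGDh: Ks peak 0.0026 -> 0.38 Mya
WGDt: Ks peak 0.0057 -> 0.84 Mya
A-B divergence: Ks peak 0.0539 -> 7.95 Mya
ASE loci: 100.00%
report: demo_run/report.json
```

Reading the numbers: all 60 simulated unitigs were returned to their true
haplotype group (length-weighted accuracy 1.0). The Ks distribution of
hap1 × hap2 allelic pairs peaks at 0.0026, dating the hexaploid-forming
duplication (WGDh) to 0.38 Mya against a planted 0.44 Mya — peak dating of
very recent events runs slightly low because the peak of a skewed
distribution sits below its mean. The cross pairs within subgenome B date
the tetraploid event (WGDt, planted 0.88 Mya) to 0.84 Mya, and the A × B
pairs date the ancestral divergence (planted 7.9 Mya) to 7.95 Mya. All 200
loci are called ASE because the generator plants a 2-fold subgenome-B
dominance shift on top of per-allele effects, so nearly every locus has at
least one significant allele pair — the same mechanism that drives high
ASE fractions in real polyploid expression data. Individual stages are
also available as `hexorigin simulate | phase | pair | ksdate | ase`; run
any of them with `--help`.

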