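# Methods

`hexorigin` re-implements, as a tested library, the computational core of a
polyploid-origin analysis for a natural allohexaploid: Hi-C haplotype-group
phasing of assembly unitigs, allelic gene pairing across the six haplotypes,
synonymous-substitution (Ks) dating of the polyploidization events, and
allele-specific expression (ASE) / subgenome-dominance analysis. The study
system is the hexaploid kiwifruit relative *Actinidia valvata* 'DE', whose
six haplotypes derive from a diploid ancestor (subgenome A, haplotypes 1–2)
and an autotetraploid ancestor (subgenome B, haplotypes 3–6). Because the
raw sequencing data is out of scope, every stage is exercised on a synthetic
hexaploid generator with complete ground truth; this note records the models,
the defaults and their rationale, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## Evolutionary model of the generator

The generator evolves each ancestral coding sequence along a fixed species
tree with three events (times in years before present):

* `t_div` — divergence of the A and B ancestors (default 7.9 Myr, the
  midpoint of the 7.52–8.26 Myr range implied by the Ks peak interval
  0.051–0.056);
* `t_wgdt` — the tetraploid-forming duplication within the B lineage
  (default 0.88 Myr, Ks ≈ 0.006);
* `t_wgdh` — the hexaploid-forming hybridization/doubling (default
  0.44 Myr, Ks ≈ 0.003).

Haplotypes 1 and 2 split at `t_wgdh`; within subgenome B, two haplotype
pairs (default (3,4) and (5,6); configurable, since the within-B branching
order is not observable from the published peaks) split at `t_wgdh` after a
common split at `t_wgdt`.

Mutation uses a Jukes–Cantor proposal process chosen for internal
consistency with the NG86 estimator applied downstream: each nucleotide site
receives proposals at rate `r_syn` per year (default 3.39 × 10⁻⁹/synonymous
site/year, the neutral rate used for clock dating); the proposed base is
uniform among the three alternatives; synonymous proposals always fix,
nonsynonymous ones fix with probability `omega` (default 0.2), and
proposals creating a stop codon are rejected. Rejection (rather than
redrawing another target base) keeps the fixed synonymous rate per NG86
synonymous site *exactly* `r_syn`: redrawing would concentrate the stop
codon's proposal mass onto the remaining alternatives and inflate the
synonymous rate at stop-adjacent sites relative to the NG86 site counting.
Under this scheme E[Ks] between two copies separated for time T is 2·r·T,
which the tests verify by law-of-large-numbers checks.

`codons_per_gene` defaults to 1500. This is deliberately longer than a
typical plant CDS: per-gene Ks is quantized in steps of one synonymous
difference over S ≈ 1125 synonymous sites (ΔKs ≈ 9 × 10⁻⁴), and the most
recent event sits at Ks ≈ 0.003, so shorter genes would place most gene
pairs at 0 or 1 differences and the distribution would reflect the lattice,
not the event. The default gives the clock roughly three resolvable steps
below the youngest peak.

## Hi-C contacts, overlaps, and expression

Each haplotype chromosome is cut into `n_unitigs_per_hap` unitigs (default
10): gene-carrying unitigs hold consecutive blocks of genes; a configurable
fraction (default 0.2) carries no gene and enters the pipeline only through
rescue. Contact counts between unitig pairs are Poisson with base rates
`lambda_intra` (same haplotype, default 20), `lambda_allelic`
(cross-haplotype pairs sharing a reference gene, default 4) and `lambda_bg`
(otherwise, default 1), each scaled by the pair's length product over the
squared mean unitig length. The scaling mirrors real Hi-C, where link
counts grow with the sizes of the interacting regions; without it,
length-normalized link densities of large unitigs sink toward background
and no density-based clusterer can satisfy its contract once unitig lengths
vary realistically. Allelic unitig pairs are additionally emitted as PAF
overlaps spanning 70% of the shorter unitig at 97% identity — above the
phasing stage's "large overlap" threshold by construction.

Expression counts are negative binomial (dispersion parameter 10, mean 200
per allele copy) over 4 timepoints × 3 replicates, matching the 12-sample
flooding time-course design (0–3 days after flooding). Subgenome-B copies
receive a `dominance_log2` mean shift (default 1, i.e. 2-fold B dominance);
a fraction `ase_fraction` (default 0.2) of loci receive ±`ase_log2`
(default 2) on one randomly chosen allele, constant across timepoints.
Library sizes are equal across samples.

What the generator does **not** emulate: read-level noise and mapping
ambiguity, assembly errors and chimeric unitigs, chromatin distance decay
within chromosomes, gene loss/fractionation (every locus stays sextuple),
homoeologous exchange, variable gene lengths, and condition-dependent ASE.
Passing recovery tests therefore demonstrates the correctness of the
algorithms under the stated model, not robustness to the full error
structure of real data.

## Phasing stage

Operating on one homologous chromosome group at a time:

1. **Prune** — all Hi-C contacts among each reference gene's allelic unitig
   set are zeroed (idempotent, never increases a count).
2. **Partition** — gene-carrying unitigs are clustered into K = 6 groups.
   "Hi-C link density" of a unitig against a set is its summed link count
   divided by the unitig's length in bp. Clustering is greedy agglomerative
   with average-density linkage — links between two clusters divided by the
   summed length products of their cross pairs — followed by a
   deterministic local-move refinement maximizing the partition's global
   within-group density (total within-group links over total within-group
   length products). Because link counts scale with the interacting
   lengths, product normalization keeps the intra/background contrast
   independent of unitig size; normalizing by summed lengths instead lets
   background linkage between two large clusters outgrow true merges of
   small unitigs, and summing per-group ratios (rather than one global
   ratio) admits degenerate optima that isolate a single dense pair. The
   refinement makes the greedy result agree with the exhaustive-search
   optimum on small planted instances, which the tests check directly.
   Ties break on lexicographic unitig id.
3. **Dedup** — within each group, overlapping pairs (overlap ≥ 0.5 × the
   shorter unitig at ≥ 0.9 identity; both configurable) are processed in
   descending overlap length; the member with the lower link density to the
   rest of its group moves to the ungrouped pool, densities being
   recomputed after every removal.
4. **Rescue** — ungrouped unitigs (gene-less ones plus dedup casualties)
   are processed in descending order of their best group link density; each
   joins the strongest-contact group with which it has no large overlap, in
   a single ordered pass (no re-testing of earlier rejections); unitigs
   with zero contact signal stay ungrouped rather than joining an arbitrary
   group.
5. **Chromosome assignment** — unitigs without genes are assigned to the
   best-scoring chromosome from alignment hits (ties to the lowest
   chromosome id); **collapse QC** flags depth windows at ≥ 1.75 × the
   genome median as candidate collapsed regions.

Phasing accuracy against truth is the length-weighted fraction of correctly
grouped unitigs under the best group-to-haplotype matching (Hungarian
assignment); ungrouped unitigs are excluded from the denominator and
reported separately.

## Allelic pairing

Cross-haplotype similarity hits (in the synthetic benchmark: 1 − p-distance
between CDS, so no aligner dependency) pass three filters per haplotype
pair: a c-score filter (keep hit (i,j) iff score ≥ c × max(best score of i,
best score of j); c = 0.7 by default, c = 1 reduces to reciprocal best
hits), collinear chaining on gene-rank coordinates (consecutive kept hits
within `dist` = 20 ranks on both haplotypes; blocks under `min_size` = 4
dropped), and greedy one-to-one reduction by descending score. Pairs from
all 15 haplotype pairs form a graph whose connected components are allelic
loci; a component with two genes on one haplotype is repaired by dropping
its lowest-score edge until valid. Loci are classified by member count
(sextuple … double); genes in no retained pair are singletons.

## Ks estimation and dating

NG86 with Jukes–Cantor correction: synonymous/nonsynonymous site counts per
codon (changes to stop codons count as nonsynonymous, so S + N = 3 × codons
exactly), averaged over both sequences; differences in multi-substitution
codons averaged over all minimal mutational pathways, excluding pathways
through stop codons (codon pairs where every pathway hits a stop are
skipped and counted); pS = Sd/S; Ks = −(3/4)·ln(1 − (4/3)·pS). Pairs with
pS ≥ 3/4 are flagged saturated and excluded from distributions, not
clamped. Plain NG86 is used (no gamma correction): it is closed-form,
verifiable against naive enumeration to 10⁻¹², and matches the simulator's
mutation model.

Per-category distributions use a Gaussian KDE on a 512-point linear grid
over [0, 1.05 × max Ks]. The bandwidth default is Silverman's rule with a
floor of one quantization step (1/median S) when site counts are available:
below that floor the density reproduces the 1/S lattice of per-gene Ks
rather than the divergence signal. Peaks are interior local maxima of the
density, merged within `min_separation` (default 0.005) keeping the denser
peak, ordered by density. Dating is T = Ks/(2r); ages are reported in Myr
rounded to 2 decimals.

Peak-based dating of a young event is biased slightly low: at `t_wgdh` the
per-gene synonymous difference count is Poisson with mean ≈ 3.4, whose
smoothed mode sits below its mean, so recovered WGDh ages run ~10% under
truth (0.38–0.40 vs 0.44 Myr at n = 2000). This is a property of dating
from the distribution peak, shared with the field's standard practice, and
is well inside the recovery tolerances the tests assert.

Subgenome assignment searches all C(6,2) = 15 splits of the haplotypes into
a 2 + 4 partition, minimizing mean within-subgenome median Ks; a
between/within contrast below 1.5 triggers a "no clear subgenome structure"
warning.

## ASE and dominance

TPM is computed per sample from raw counts and effective lengths. For each
allele pair at a locus, per timepoint: log2FC = log2((mean TPM_a + ε)/(mean
TPM_b + ε)) with ε = 0.01 TPM (below biological resolution, avoids
infinities), and a two-sided exact binomial test on replicate-summed raw
counts with null proportion = the pair's length share (0.5 for equal
lengths). The binomial test was chosen because it is self-contained and
exactly computable; no external model fitting is involved. A pair is
significant at |log2FC| > 1 and p < 0.05. Raw p-values are the default
decision rule; `apply_bh_fdr` optionally re-thresholds on
Benjamini–Hochberg adjusted p-values for users who want family-wise error
control. A locus is an ASE locus if any pair is significant at any
timepoint; a pair whose dominant allele switches between significant
timepoints is an inconsistent ASE gene pair. Subgenome dominance contrasts
mean TPM over haplotype-1/2 copies against haplotype-3/6 copies per locus;
|log2(B/A)| > 1 marks bias.

Replicates are summed within timepoint for the binomial test and averaged
for the fold change; timepoints are tested separately and aggregated by
"any significant timepoint", which matches a per-treatment testing design.

## Problem sizes and determinism

The default benchmark (`hexorigin demo`) runs 500 loci of 1500 codons; the
acceptance script (`scripts/acceptance.py`) uses 2000 loci, the size at
which the law-of-large-numbers and peak-recovery checks are calibrated, and
completes in a few minutes on one core. All randomness flows from a single
integer seed through `numpy.random.SeedSequence`-derived per-stage streams;
identical configurations give byte-identical outputs, and every output
table embeds the seed and a configuration hash in `#` header lines.

## Known limitations

* The clustering contract is verified against exhaustive search only up to
  10 unitigs, and greedy + local refinement carries no global optimality
  guarantee on adversarial instances.
* Collinearity chaining uses simple rank-distance chaining without
  orientation handling; inverted blocks are chained like forward ones.
* The component-repair rule for same-haplotype conflicts (iterative
  weakest-edge removal) is one of several defensible choices; real data
  with tandem duplicates would exercise it far more than the generator
  does.
* Sequence simulation excludes indels, so all allelic CDS stay equal
  length and the NG86 stage never sees gaps in the benchmark (the gap path
  is unit-tested separately).
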