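"""Allele-specific expression and subgenome dominance.

Expression of the alleles at each multi-allelic locus is compared per
timepoint: the fold change is computed on replicate-averaged TPM and the
p-value from a two-sided exact binomial test on pooled raw counts, with the
null allele proportion given by the allele pair's length share (equal-length
alleles test against 0.5). A pair is significant at a timepoint when
|log2FC| > 1 and p < alpha; a locus is an ASE locus when any of its allele
pairs is significant at any timepoint. Subgenome dominance contrasts the
mean TPM of subgenome-A copies (haplotypes 1-2) against subgenome-B copies
(haplotypes 3-6) per locus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "TimepointResult",
    "PairResult",
    "compute_tpm",
    "test_allele_pair",
    "test_locus_pairs",
    "classify_asegs",
    "ase_percentage",
    "inconsistent_asegs",
    "dominance_summary",
]

EPSILON_TPM = 0.01


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: (count / length) scaled to 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total expression: {bad}")
    return rate.div(totals, axis=1) * 1e6


@dataclass
class TimepointResult:
    timepoint: str
    log2fc: float
    pvalue: float
    significant: bool
    dominant: str | None  # gene id of the higher-expressed allele


@dataclass
class PairResult:
    gene_a: str
    gene_b: str
    timepoints: list[TimepointResult] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return any(t.significant for t in self.timepoints)


def _timepoint_of(sample: str) -> str:
    return sample.rsplit("_", 1)[0]


def test_allele_pair(
    counts_a: pd.Series,
    counts_b: pd.Series,
    tpm_a: pd.Series,
    tpm_b: pd.Series,
    len_a: float = 1.0,
    len_b: float = 1.0,
    alpha: float = 0.05,
    lfc: float = 1.0,
    eps: float = EPSILON_TPM,
    gene_a: str = "a",
    gene_b: str = "b",
) -> PairResult | None:
    """Per-timepoint allele contrast for one pair.

    Samples are named ``{timepoint}_R{rep}``; replicates are averaged for
    the TPM fold change and summed for the binomial test. Returns None for
    an untestable pair (zero raw counts at every timepoint). Swapping the
    alleles negates every log2FC and leaves p-values unchanged.
    """
    null_p = len_a / (len_a + len_b)
    res = PairResult(gene_a=gene_a, gene_b=gene_b)
    tps = sorted({_timepoint_of(s) for s in counts_a.index})
    any_counts = False
    for tp in tps:
        cols = [s for s in counts_a.index if _timepoint_of(s) == tp]
        ka = int(counts_a[cols].sum())
        kb = int(counts_b[cols].sum())
        log2fc = float(np.log2((tpm_a[cols].mean() + eps) / (tpm_b[cols].mean() + eps)))
        n = ka + kb
        if n == 0:
            res.timepoints.append(TimepointResult(tp, log2fc, 1.0, False, None))
            continue
        any_counts = True
        p = binomtest(ka, n, null_p, alternative="two-sided").pvalue
        sig = abs(log2fc) > lfc and p < alpha
        dominant = None
        if sig:
            dominant = gene_a if log2fc > 0 else gene_b
        res.timepoints.append(TimepointResult(tp, log2fc, float(p), sig, dominant))
    return res if any_counts else None


def test_locus_pairs(
    locus_members: dict[int, str],
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    lengths: pd.Series | None = None,
    alpha: float = 0.05,
    lfc: float = 1.0,
) -> list[PairResult]:
    """All pairwise allele contrasts within one locus."""
    out = []
    genes = [locus_members[h] for h in sorted(locus_members)]
    for ga, gb in itertools.combinations(genes, 2):
        la = float(lengths[ga]) if lengths is not None else 1.0
        lb = float(lengths[gb]) if lengths is not None else 1.0
        r = test_allele_pair(
            counts.loc[ga], counts.loc[gb], tpm.loc[ga], tpm.loc[gb],
            la, lb, alpha=alpha, lfc=lfc, gene_a=ga, gene_b=gb,
        )
        if r is not None:
            out.append(r)
    return out


def apply_bh_fdr(results: list[PairResult], alpha: float = 0.05,
                 lfc: float = 1.0) -> list[PairResult]:
    """Re-threshold significance on Benjamini-Hochberg adjusted p-values.

    Raw p-values are the default criterion; this re-flags every timepoint
    result using BH-adjusted p-values pooled over all pair x timepoint
    tests. Returns the same result objects, updated in place.
    """
    from scipy.stats import false_discovery_control

    tests = [(r, t) for r in results for t in r.timepoints]
    if not tests:
        return results
    q = false_discovery_control([t.pvalue for _, t in tests], method="bh")
    for (r, t), qv in zip(tests, q):
        t.significant = abs(t.log2fc) > lfc and qv < alpha
        if t.significant:
            t.dominant = r.gene_a if t.log2fc > 0 else r.gene_b
        else:
            t.dominant = None
    return results


def classify_asegs(results_by_locus: dict[str, list[PairResult]]):
    """ASE census: a locus is ASE if any pair is significant at any timepoint.

    Returns (ase locus ids, percentage) with the percentage over all tested
    loci, rounded to 2 decimals.
    """
    ase = sorted(
        locus for locus, results in results_by_locus.items()
        if any(r.significant for r in results)
    )
    return ase, ase_percentage(len(ase), len(results_by_locus))


def ase_percentage(n_ase: int, n_total: int) -> float:
    if n_total == 0:
        return 0.0
    return round(100.0 * n_ase / n_total, 2)


def inconsistent_asegs(results: list[PairResult]) -> list[PairResult]:
    """Pairs whose dominant allele switches between significant timepoints."""
    out = []
    for r in results:
        doms = {t.dominant for t in r.timepoints if t.significant}
        if len(doms) > 1:
            out.append(r)
    return out


def dominance_summary(
    tpm: pd.DataFrame,
    loci,
    subgenome_a=(1, 2),
    subgenome_b=(3, 4, 5, 6),
    lfc: float = 1.0,
    eps: float = EPSILON_TPM,
) -> pd.DataFrame:
    """Per-locus subgenome expression contrast.

    For each locus the mean TPM over subgenome-A member genes and over
    subgenome-B member genes (across all samples) gives
    log2B_over_A = log2((B + eps) / (A + eps)); |log2| > ``lfc`` marks the
    locus biased toward the higher subgenome. Returns a DataFrame with
    columns locus_id, mean_a, mean_b, log2_b_over_a, bias in {A, B, none}.
    """
    rows = []
    for locus in loci:
        genes_a = [g for h, g in locus.members.items() if h in subgenome_a]
        genes_b = [g for h, g in locus.members.items() if h in subgenome_b]
        if not genes_a or not genes_b:
            continue
        mean_a = float(tpm.loc[genes_a].to_numpy().mean())
        mean_b = float(tpm.loc[genes_b].to_numpy().mean())
        l2 = float(np.log2((mean_b + eps) / (mean_a + eps)))
        bias = "B" if l2 > lfc else ("A" if l2 < -lfc else "none")
        rows.append((locus.locus_id, mean_a, mean_b, l2, bias))
    return pd.DataFrame(
        rows, columns=["locus_id", "mean_a", "mean_b", "log2_b_over_a", "bias"]
    )
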