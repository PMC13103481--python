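"""Synonymous-substitution (Ks) estimation and molecular-clock dating.

Implements the Nei–Gojobori (1986) counting method with Jukes–Cantor
multiple-hit correction for pairs of in-frame coding sequences, kernel
density estimation of Ks distributions per pair category, peak detection,
the molecular clock T = Ks / (2 r), and the exhaustive subgenome-partition
search used to separate the diploid-derived from the tetraploid-derived
haplotypes of a hexaploid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from ._codon import PAIR_ND, PAIR_OK, PAIR_SD, SYN_SITES, encode_codons

__all__ = [
    "KsRecord",
    "KsDistribution",
    "DatingResult",
    "ng86_ks",
    "ks_distribution",
    "find_peaks",
    "ks_to_time",
    "assign_subgenomes",
]

SATURATION_PS = 0.75


@dataclass
class KsRecord:
    """NG86 output for one gene pair."""

    gene_a: str
    gene_b: str
    S: float          # synonymous sites
    N: float          # nonsynonymous sites
    Sd: float         # synonymous differences (pathway-averaged)
    Nd: float         # nonsynonymous differences
    pS: float
    pN: float
    Ks: float         # NaN when saturated
    Ka: float
    saturated: bool
    codons_compared: int
    codons_skipped: int  # gap codons plus all-stop-pathway codon pairs


def _jc_correct(p: float) -> float:
    if p >= SATURATION_PS:
        return float("nan")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def ng86_ks(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b") -> KsRecord:
    """NG86 Ka/Ks for two equal-length, in-frame coding sequences.

    Gap codons (any codon containing ``-``) are skipped pairwise. Site counts
    are averaged over both sequences; differences within multi-substitution
    codons are averaged over all minimal mutational pathways, excluding
    pathways through stop codons. Codon pairs whose every pathway hits a stop
    are skipped and counted in ``codons_skipped``. Internal stop codons in
    either sequence raise ValueError.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError(
            f"sequence lengths differ: {len(cds_a)} vs {len(cds_b)}"
        )
    if len(cds_a) % 3:
        raise ValueError(f"length {len(cds_a)} is not a multiple of 3")
    a_up, b_up = cds_a.upper(), cds_b.upper()
    keep_a, keep_b = [], []
    skipped = 0
    for i in range(0, len(a_up), 3):
        ca, cb = a_up[i:i + 3], b_up[i:i + 3]
        if "-" in ca or "-" in cb:
            skipped += 1
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    if not keep_a:
        raise ValueError("no comparable codons (all gapped)")
    ia = encode_codons("".join(keep_a))
    ib = encode_codons("".join(keep_b))
    if np.any(np.isnan(SYN_SITES[ia])) or np.any(np.isnan(SYN_SITES[ib])):
        raise ValueError("internal stop codon in input sequence")

    ok = PAIR_OK[ia, ib]
    skipped += int((~ok).sum())
    ia, ib = ia[ok], ib[ok]
    n_codons = int(ia.size)
    if n_codons == 0:
        raise ValueError("no comparable codons after skipping")

    S = float((SYN_SITES[ia].sum() + SYN_SITES[ib].sum()) / 2.0)
    N = 3.0 * n_codons - S
    Sd = float(PAIR_SD[ia, ib].sum())
    Nd = float(PAIR_ND[ia, ib].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    saturated = pS >= SATURATION_PS
    return KsRecord(
        gene_a=gene_a, gene_b=gene_b, S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN,
        Ks=_jc_correct(pS), Ka=_jc_correct(pN) if pN < SATURATION_PS else float("nan"),
        saturated=saturated,
        codons_compared=n_codons, codons_skipped=skipped,
    )


@dataclass
class KsDistribution:
    """Ks values for one pair category with their Gaussian KDE."""

    label: str
    values: np.ndarray
    bandwidth: float
    grid: np.ndarray
    density: np.ndarray
    peaks: list[float] = field(default_factory=list)


def ks_distribution(
    records,
    labels=None,
    bandwidth: float | None = None,
    min_records: int = 30,
    grid_points: int = 512,
) -> dict[str, KsDistribution]:
    """Build per-category Ks distributions with Gaussian KDEs.

    ``records`` is an iterable of KsRecord (or bare Ks floats); ``labels``
    assigns each record a category. Saturated / undefined Ks values are
    excluded. A category with fewer than ``min_records`` usable values raises
    ValueError naming the category. ``bandwidth`` is an absolute kernel
    standard deviation in Ks units; default is Silverman's rule.
    """
    records = list(records)
    if labels is None:
        labels = ["all"] * len(records)
    by_cat: dict[str, list[float]] = {}
    syn_sites: dict[str, list[float]] = {}
    for rec, lab in zip(records, labels, strict=True):
        by_cat.setdefault(lab, [])
        syn_sites.setdefault(lab, [])
        if isinstance(rec, KsRecord):
            ks = rec.Ks
            syn_sites[lab].append(rec.S)
        else:
            ks = float(rec)
        if np.isfinite(ks):
            by_cat[lab].append(ks)

    out = {}
    for lab in by_cat:
        vals = np.asarray(sorted(by_cat[lab]))
        if vals.size < min_records:
            raise ValueError(
                f"category {lab!r} has only {vals.size} usable Ks values "
                f"(minimum {min_records})"
            )
        hi = 1.05 * vals.max() if vals.max() > 0 else 1.0
        grid = np.linspace(0.0, hi, grid_points)
        if np.ptp(vals) == 0:
            # degenerate point mass: unit spike at the common value
            bw = 0.0
            density = np.zeros_like(grid)
            density[np.argmin(np.abs(grid - vals[0]))] = 1.0
        else:
            sd = vals.std(ddof=1)
            iqr = np.subtract(*np.percentile(vals, [75, 25]))
            if bandwidth is None:
                spread = min(sd, iqr / 1.34) if iqr > 0 else sd
                bw = 0.9 * spread * vals.size ** (-1 / 5)
                # per-gene Ks is quantized in steps of ~1/S (one synonymous
                # difference); keep the kernel at least that wide so the
                # density reflects the divergence signal, not the lattice
                if syn_sites[lab]:
                    bw = max(bw, 1.0 / float(np.median(syn_sites[lab])))
            else:
                bw = float(bandwidth)
            kde = stats.gaussian_kde(vals, bw_method=bw / sd)
            density = kde(grid)
        out[lab] = KsDistribution(
            label=lab, values=vals, bandwidth=bw, grid=grid, density=density
        )
    return out


def find_peaks(dist: KsDistribution, min_separation: float = 0.005) -> list[float]:
    """Local KDE maxima, merged within ``min_separation``, densest first.

    Grid boundary points are not peak candidates; if the density has no
    interior local maximum the global argmax is returned as the single peak.
    Peaks are stored on the distribution and returned.
    """
    idx, _ = signal.find_peaks(dist.density)
    if idx.size == 0:
        idx = np.array([int(np.argmax(dist.density))])
    # densest first, then merge close peaks keeping the denser one
    order = idx[np.argsort(dist.density[idx])[::-1]]
    kept: list[int] = []
    for i in order:
        if all(abs(dist.grid[i] - dist.grid[j]) >= min_separation for j in kept):
            kept.append(i)
    dist.peaks = [float(dist.grid[i]) for i in kept]
    return dist.peaks


@dataclass
class DatingResult:
    """A dated divergence/duplication event."""

    label: str
    peak_ks: float
    rate: float
    T_years: float
    T_mya: float  # rounded to 2 decimals


def ks_to_time(ks: float, r: float, label: str = "") -> DatingResult:
    """Molecular clock: T = Ks / (2 r), with r per site per year."""
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    if ks < 0:
        raise ValueError(f"Ks must be non-negative, got {ks}")
    T = ks / (2.0 * r)
    return DatingResult(label=label, peak_ks=ks, rate=r, T_years=T,
                        T_mya=round(T / 1e6, 2))


def plot_distributions(dists: dict[str, "KsDistribution"], path) -> None:
    """Write a Ks density plot (one curve per category, peaks marked)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for lab, d in sorted(dists.items()):
        ax.plot(d.grid, d.density, label=lab)
        for p in d.peaks:
            ax.axvline(p, ls="--", lw=0.7, color="grey")
    ax.set_xlabel(r"$K_S$ (synonymous substitutions per synonymous site)")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def assign_subgenomes(
    median_ks: np.ndarray,
    haplotypes=None,
    a_size: int = 2,
    margin: float = 1.5,
):
    """Split haplotypes into subgenomes by exhaustive search.

    ``median_ks`` is a symmetric H x H matrix of median pairwise Ks between
    haplotypes. All C(H, a_size) splits are scored by the mean of
    within-subgenome entries; the minimizing split is returned as
    (subgenome_A, subgenome_B, contrast) where contrast is the ratio of mean
    between- to mean within-subgenome Ks. A contrast below ``margin`` emits a
    "no clear subgenome structure" warning.
    """
    m = np.asarray(median_ks, dtype=float)
    H = m.shape[0]
    if m.shape != (H, H) or not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("median_ks must be a symmetric square matrix")
    if haplotypes is None:
        haplotypes = list(range(1, H + 1))

    def pair_vals(members):
        return [m[i, j] for i, j in itertools.combinations(members, 2)]

    best = None
    for a in itertools.combinations(range(H), a_size):
        b = tuple(i for i in range(H) if i not in a)
        within = pair_vals(a) + pair_vals(b)
        score = float(np.mean(within))
        key = (score, a)  # deterministic tie-break on the index tuple
        if best is None or key < best[0]:
            best = (key, a, b)
    _, a, b = best
    within = float(np.mean(pair_vals(a) + pair_vals(b)))
    between = float(np.mean([m[i, j] for i in a for j in b]))
    contrast = between / within if within > 0 else float("inf")
    if contrast < margin:
        warnings.warn(
            f"no clear subgenome structure: between/within Ks contrast "
            f"{contrast:.3g} < {margin}",
            stacklevel=2,
        )
    return (
        [haplotypes[i] for i in a],
        [haplotypes[i] for i in b],
        contrast,
    )
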