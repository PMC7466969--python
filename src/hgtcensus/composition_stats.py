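"""Compositional evidence for foreign origin of genes.

GC content, intron statistics, 5-mer and codon-usage profiles, and the
statistical tests applied to them: one-way ANOVA with Tukey HSD, the
Kruskal-Wallis rank test (tie-corrected), and principal component analysis.
The test statistics are computed directly from their defining sums of
squares / rank formulas; SciPy supplies only the reference distributions
(F, chi-square, studentized range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _dist

from .io_formats import GeneModel

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PcaResult:
    """Scores (n x r), orthonormal loadings (p x r), variance fractions, column means."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_fraction: np.ndarray
    mean: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T + self.mean


@dataclass
class StatResult:
    """A test outcome: statistic, degrees of freedom, p, optional extras."""

    statistic: float
    df: int | tuple[int, int]
    p: float
    pairwise: dict[tuple[str, str], float] | None = None
    pca: PcaResult | None = None


@dataclass
class GeneComposition:
    """Per-gene compositional summary used by the group comparisons."""

    gene_id: str
    gc: float
    n_introns: int
    norm_intron_len: float
    kmer_vec: np.ndarray
    codon_vec: np.ndarray
    group: str  # hgt | neighbor_fungal | all_fungal


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T); N bases are excluded from both counts."""
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    return gc / (gc + at)


def intron_stats(gene: GeneModel) -> tuple[int, float]:
    """Number of introns and normalized intron length (intron nt / span nt)."""
    total = sum(e - s for s, e in gene.introns)
    return len(gene.introns), total / gene.span_length


def _encode(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and anything else (N, ambiguity codes) to -1."""
    codes = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def kmer_profile(cds: str, k: int = 5) -> np.ndarray:
    """Overlapping k-mer counts (step 1) divided by the full CDS length.

    Windows containing an ambiguous base are skipped; the denominator stays
    the full sequence length so profiles remain comparable across genes.
    """
    n = len(cds)
    if n < k:
        raise ValueError(f"CDS length {n} < k={k}")
    codes = _encode(cds)
    # polynomial rolling index over valid windows
    nwin = n - k + 1
    idx = np.zeros(nwin, dtype=np.int64)
    valid = np.ones(nwin, dtype=bool)
    for j in range(k):
        c = codes[j : j + nwin]
        idx = idx * 4 + np.where(c >= 0, c, 0)
        valid &= c >= 0
    counts = np.bincount(idx[valid], minlength=4**k).astype(float)
    return counts / n


def codon_usage(cds: str) -> np.ndarray:
    """In-frame codon counts divided by CDS length (64-vector summing to 1/3)."""
    n = len(cds)
    if n == 0 or n % 3 != 0:
        raise ValueError(f"CDS length {n} is not a positive multiple of 3")
    codes = _encode(cds)
    trip = codes.reshape(-1, 3)
    valid = (trip >= 0).all(axis=1)
    idx = trip[valid, 0] * 16 + trip[valid, 1] * 4 + trip[valid, 2]
    counts = np.bincount(idx, minlength=64).astype(float)
    return counts / n


CODONS = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def anova_oneway(groups) -> StatResult:
    """One-way fixed-effects ANOVA from the between/within SS decomposition."""
    gs = _as_groups(groups)
    for i, g in enumerate(gs):
        if len(g) < 2:
            raise ValueError(f"group {i} has n={len(g)} < 2")
    k = len(gs)
    n_total = sum(len(g) for g in gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df = (k - 1, n_total - k)
    if ssw == 0.0:
        if ssb == 0.0:
            return StatResult(statistic=0.0, df=df, p=1.0)
        return StatResult(statistic=float("inf"), df=df, p=0.0)
    f_stat = (ssb / df[0]) / (ssw / df[1])
    p = float(_dist.f.sf(f_stat, df[0], df[1]))
    return StatResult(statistic=float(f_stat), df=df, p=p)


def tukey_hsd(groups, names=None) -> dict[tuple[str, str], float]:
    """Tukey honestly-significant-difference adjusted p per group pair.

    Uses the studentized-range statistic with the pooled within-group mean
    square (Tukey-Kramer form for unequal n).
    """
    gs = _as_groups(groups)
    for i, g in enumerate(gs):
        if len(g) < 2:
            raise ValueError(f"group {i} has n={len(g)} < 2")
    k = len(gs)
    if names is None:
        names = [str(i) for i in range(k)]
    n_total = sum(len(g) for g in gs)
    df_w = n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    out: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            diff = abs(gs[i].mean() - gs[j].mean())
            if msw == 0.0:
                p = 1.0 if diff == 0.0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
                q = diff / se
                p = float(_dist.studentized_range.sf(q, k, df_w))
            out[(names[i], names[j])] = min(max(p, 0.0), 1.0)
    return out


def kruskal_wallis(groups) -> StatResult:
    """Kruskal-Wallis rank H with the standard tie correction.

    H = [12/(N(N+1)) * sum n_i Rbar_i^2 - 3(N+1)] / [1 - sum(t^3-t)/(N^3-N)]
    compared against chi-square on k-1 df.
    """
    gs = _as_groups(groups)
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need total n >= 3")
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical: H is undefined")
    ranks = _dist.rankdata(pooled)
    h = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + len(g)]
        h += len(g) * r.mean() ** 2
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    h /= tie
    df = len(gs) - 1
    return StatResult(statistic=float(h), df=df, p=float(_dist.chi2.sf(h, df)))


def pca(matrix: np.ndarray, scale: bool = False) -> PcaResult:
    """PCA by SVD of the column-centered (optionally standardized) matrix.

    Loadings are orthonormal; variance fractions are non-increasing and sum
    to 1.  Sign convention: within each component the largest-magnitude
    loading entry is positive.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 1:
        raise ValueError("need an n x p matrix with n >= 2, p >= 1")
    mean = x.mean(axis=0)
    xc = x - mean
    if not np.any(xc):
        raise ValueError("constant matrix: no variance to decompose")
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention
    for comp in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    var = s**2
    frac = var / var.sum()
    return PcaResult(
        scores=u * s,
        loadings=vt.T,
        variance_fraction=frac,
        mean=mean if not scale else mean,  # reconstruction valid for scale=False
    )


def permutation_group_separation(
    scores: np.ndarray,
    labels,
    n_components: int = 2,
    n_permutations: int = 999,
    seed: int = 0,
) -> StatResult:
    """Permutation test for centroid separation of two groups in PC space.

    Statistic: Euclidean distance between group centroids in the first
    ``n_components`` score columns; the null distribution comes from
    relabeling genes at random.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    x = np.asarray(scores)[:, :n_components]

    def stat(lab: np.ndarray) -> float:
        a = x[lab == uniq[0]].mean(axis=0)
        b = x[lab == uniq[1]].mean(axis=0)
        return float(np.linalg.norm(a - b))

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if stat(lab) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return StatResult(statistic=observed, df=n_components, p=p)


def gene_composition(
    gene: GeneModel, cds: str, group: str, k: int = 5
) -> GeneComposition:
    """Bundle every compositional feature of one gene."""
    n_introns, norm_len = intron_stats(gene)
    return GeneComposition(
        gene_id=gene.gene_id,
        gc=gc_content(cds),
        n_introns=n_introns,
        norm_intron_len=norm_len,
        kmer_vec=kmer_profile(cds, k=k),
        codon_vec=codon_usage(cds),
        group=group,
    )


def composition_groups(
    genes,
    calls: dict[str, str],
    final_hgt: set[str],
) -> dict[str, str]:
    """Assign each gene to hgt / neighbor_fungal / all_fungal for the contrasts.

    ``neighbor_fungal`` genes are fungal-call genes that share a scaffold with
    a retained HGT gene; they are a subset of ``all_fungal`` conceptually but
    the three groups here are disjoint (neighbors are reported as neighbors),
    mirroring a three-level factor.
    """
    hgt_scaffolds = {g.scaffold_id for g in genes if g.gene_id in final_hgt}
    out: dict[str, str] = {}
    for g in genes:
        if g.gene_id in final_hgt:
            out[g.gene_id] = "hgt"
        elif calls.get(g.gene_id) == "fungal":
            if g.scaffold_id in hgt_scaffolds:
                out[g.gene_id] = "neighbor_fungal"
            else:
                out[g.gene_id] = "all_fungal"
    return out
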