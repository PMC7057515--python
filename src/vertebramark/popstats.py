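"""Windowed diversity and differentiation statistics, distances and ordination.

Implements the genome-scan layer: windowed nucleotide diversity (pi),
Weir-Cockerham F_ST with ratio-of-sums window aggregation, the joint
top-quantile F_ST x log2 pi-ratio selective-sweep flagging, genotype-dosage
LD decay, (1-IBS) sample distances, Saitou-Nei neighbor joining and a
smartpca-style genotype PCA.

Conventions
-----------
* Window pi divides the summed per-site diversity by the full window
  length (per-bp diversity, the convention of windowed scans); a
  per-variant-site mean is available via ``per_site=True``.
* Window F_ST is the ratio of summed Weir-Cockerham variance components
  ``sum(a) / sum(a+b+c)`` -- the "weighted" estimator -- and negative
  values are reported as-is.
* The log2 pi ratio is oriented control/case, so positive values mean
  reduced diversity in the case group (candidate case-direction sweep).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    MISSING,
    ConfigurationError,
    GeneInterval,
    GenotypeMatrix,
    SampleManifest,
)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicWindow:
    chrom: str
    start: int  # 0-based half-open
    end: int


def tile_windows(
    chrom_lengths: dict[str, int], size: int = 50_000, step: int = 10_000
) -> list[GenomicWindow]:
    """Sliding windows of ``size`` advancing by ``step`` over each chromosome."""
    windows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        start = 0
        while start < length:
            windows.append(GenomicWindow(chrom, start, start + size))
            start += step
    return windows


def _window_site_index(
    matrix: GenotypeMatrix, windows: Sequence[GenomicWindow]
) -> list[np.ndarray]:
    """Indices of matrix loci falling in each window (0-based half-open)."""
    pos0 = matrix.loci["pos"].to_numpy() - 1
    chroms = matrix.loci["chrom"].to_numpy()
    out = []
    for w in windows:
        on_chrom = np.flatnonzero(chroms == w.chrom)
        p = pos0[on_chrom]
        out.append(on_chrom[(p >= w.start) & (p < w.end)])
    return out


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(matrix: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    """Per-site unbiased pi: 2 * c_ref * c_alt / (m * (m-1)) over m alleles.

    Sites with fewer than 2 non-missing alleles yield 0 (skipped).
    """
    alleles = matrix.alleles[:, sample_idx, :]
    nonmiss = alleles != MISSING
    m = nonmiss.sum(axis=(1, 2)).astype(float)
    c_alt = np.where(nonmiss, alleles, 0).sum(axis=(1, 2)).astype(float)
    c_ref = m - c_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c_ref * c_alt / (m * (m - 1.0))
    pi[m < 2] = 0.0
    return pi


def window_pi(
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    populations: Sequence[str],
    windows: Sequence[GenomicWindow],
    min_sites: int = 1,
    per_site: bool = False,
) -> pd.DataFrame:
    """Windowed nucleotide diversity per bp for a population group."""
    idx = matrix.sample_index(manifest.samples_of_group(populations))
    pi = site_pi(matrix, idx)
    rows = []
    for w, sites in zip(windows, _window_site_index(matrix, windows)):
        n = len(sites)
        total = float(pi[sites].sum())
        if per_site:
            value = total / n if n else np.nan
        else:
            value = total / (w.end - w.start)
        rows.append(
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "n_sites": n, "pi": value, "low_sites": n < min_sites,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def wc_site_components(
    matrix: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components for two diploid groups.

    Returns ``(a, a+b+c)`` arrays over loci; NaN where a group has fewer
    than one genotyped diploid or the denominator degenerates.  Uses the
    full diploid estimator with observed heterozygosity.
    """
    comps = []
    for idx in (idx_a, idx_b):
        al = matrix.alleles[:, idx, :]
        called = ~(al == MISSING).any(axis=2)  # (L, n) whole-call presence
        n_i = called.sum(axis=1).astype(float)
        alt = np.where(al == 1, 1, 0).sum(axis=2)  # alt dosage per call
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(called, alt, 0).sum(axis=1) / (2.0 * n_i)
            het = ((al[:, :, 0] != al[:, :, 1]) & called).sum(axis=1) / n_i
        comps.append((n_i, p_i, het))

    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        inner = p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    total = a + b + c
    bad = (n1 < 1) | (n2 < 1) | (n_bar <= 1) | ~np.isfinite(total)
    a = np.where(bad, np.nan, a)
    total = np.where(bad, np.nan, total)
    return a, total


def window_fst(
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    group_a: Sequence[str],
    group_b: Sequence[str],
    windows: Sequence[GenomicWindow],
) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST, ratio-of-sums over usable sites.

    Windows with no usable site get NaN (absent), never zero.
    """
    idx_a = matrix.sample_index(manifest.samples_of_group(group_a))
    idx_b = matrix.sample_index(manifest.samples_of_group(group_b))
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ConfigurationError("both groups need >=2 diploids for FST")
    a, total = wc_site_components(matrix, idx_a, idx_b)
    usable = np.isfinite(total) & (total != 0.0)
    rows = []
    for w, sites in zip(windows, _window_site_index(matrix, windows)):
        s = sites[usable[sites]]
        if len(s) == 0:
            fst = np.nan
        else:
            fst = float(a[s].sum() / total[s].sum())
        rows.append(
            {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "n_sites": len(s), "fst": fst,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sweep scan
# ---------------------------------------------------------------------------

def sweep_scan(
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    case_group: Sequence[str],
    control_group: Sequence[str],
    windows: Sequence[GenomicWindow],
    min_sites: int = 2,
) -> pd.DataFrame:
    """Per-window pi (both groups), F_ST and log2(pi_control / pi_case).

    The ratio is defined only where both window pi values are positive.
    """
    pi_case = window_pi(matrix, manifest, case_group, windows, min_sites=min_sites)
    pi_ctrl = window_pi(matrix, manifest, control_group, windows, min_sites=min_sites)
    fst = window_fst(matrix, manifest, case_group, control_group, windows)
    out = pi_case[["chrom", "start", "end", "n_sites"]].copy()
    out["pi_case"] = pi_case["pi"]
    out["pi_control"] = pi_ctrl["pi"]
    out["fst"] = fst["fst"]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.log2(out["pi_control"] / out["pi_case"])
    ratio[(out["pi_case"] <= 0) | (out["pi_control"] <= 0)] = np.nan
    out["log2_pi_ratio"] = ratio
    out["low_sites"] = pi_case["low_sites"]
    return out


def select_sweep_windows(
    sweep: pd.DataFrame, top_fraction: float = 0.05, min_windows: int = 20
) -> pd.DataFrame:
    """Flag windows in the joint top tail of F_ST and log2 pi ratio.

    Case-direction sweeps require both F_ST and the log2 ratio at or above
    their (1 - top_fraction) empirical quantiles (type-7, inclusive at the
    threshold); control-direction uses the negated ratio.  Windows below
    the min-sites filter, or with undefined statistics, are excluded before
    quantiles are taken but retained in the output with flag "none".
    """
    sweep = sweep.copy()
    eligible = (
        ~sweep["low_sites"]
        & np.isfinite(sweep["fst"])
        & np.isfinite(sweep["log2_pi_ratio"])
    )
    if eligible.sum() < min_windows:
        raise ConfigurationError(
            f"only {int(eligible.sum())} eligible windows; need >= {min_windows} "
            "for stable quantiles"
        )
    q = 1.0 - top_fraction
    fst = sweep.loc[eligible, "fst"]
    ratio = sweep.loc[eligible, "log2_pi_ratio"]
    fst_thr = float(np.quantile(fst, q))
    ratio_thr = float(np.quantile(ratio, q))
    neg_thr = float(np.quantile(-ratio, q))

    selected = np.full(len(sweep), "none", dtype=object)
    case_hit = eligible & (sweep["fst"] >= fst_thr) & (sweep["log2_pi_ratio"] >= ratio_thr)
    ctrl_hit = eligible & (sweep["fst"] >= fst_thr) & (-sweep["log2_pi_ratio"] >= neg_thr)
    selected[case_hit] = "case"
    # a window can only be reduced in one direction unless ratios degenerate;
    # on the degenerate tie, case takes precedence deterministically
    selected[ctrl_hit & ~case_hit] = "control"
    sweep["selected_for"] = selected
    sweep.attrs["thresholds"] = {
        "fst": fst_thr, "log2_pi_ratio": ratio_thr, "neg_log2_pi_ratio": neg_thr,
    }
    return sweep


def annotate_sweep_genes(
    sweep: pd.DataFrame, genes: Sequence[GeneInterval]
) -> pd.DataFrame:
    """Comma-joined ids of genes overlapping each window."""
    sweep = sweep.copy()
    labels = []
    for _, w in sweep.iterrows():
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == w["chrom"] and g.start < w["end"] and g.end > w["start"]
        ]
        labels.append(",".join(sorted(hits)) if hits else ".")
    sweep["genes"] = labels
    return sweep


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(
    matrix: GenotypeMatrix,
    manifest: SampleManifest,
    population: str,
    max_distance: int = 100_000,
    bin_width: int = 5_000,
) -> pd.DataFrame:
    """Mean squared dosage correlation (r^2) binned by pair distance.

    r^2 is the squared Pearson correlation of alt-allele dosage vectors
    over samples with both calls present; monomorphic (zero-variance)
    loci are skipped.  Pairs are restricted to the same chromosome and
    ``0 < |pos1 - pos2| <= max_distance``.
    """
    samples = manifest.samples_of(population)
    if len(samples) < 3:
        raise ConfigurationError("LD decay needs >=3 samples")
    idx = matrix.sample_index(samples)
    dosage = matrix.dosage()[:, idx]

    n_bins = int(np.ceil(max_distance / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    pos = matrix.loci["pos"].to_numpy()
    for chrom in matrix.loci["chrom"].unique():
        on = np.flatnonzero(matrix.loci["chrom"].to_numpy() == chrom)
        p = pos[on]
        d = dosage[on]
        for i in range(len(on)):
            # loci are position-sorted within chromosome
            jmax = np.searchsorted(p, p[i] + max_distance, side="right")
            for j in range(i + 1, jmax):
                dist = p[j] - p[i]
                if dist == 0:
                    continue
                both = ~np.isnan(d[i]) & ~np.isnan(d[j])
                if both.sum() < 3:
                    continue
                x, y = d[i, both], d[j, both]
                if x.std() == 0 or y.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                b = min(int((dist - 1) // bin_width), n_bins - 1)
                sums[b] += r * r
                counts[b] += 1

    rows = []
    for b in range(n_bins):
        rows.append(
            {
                "bin_start": b * bin_width,
                "bin_end": min((b + 1) * bin_width, max_distance),
                "mean_r2": sums[b] / counts[b] if counts[b] else np.nan,
                "n_pairs": int(counts[b]),
            }
        )
    return pd.DataFrame(rows)


def pair_r2(matrix: GenotypeMatrix, i: int, j: int,
            sample_idx: np.ndarray | None = None) -> float:
    """r^2 between two loci (by row index); NaN if undefined."""
    d = matrix.dosage()
    if sample_idx is not None:
        d = d[:, sample_idx]
    both = ~np.isnan(d[i]) & ~np.isnan(d[j])
    x, y = d[i, both], d[j, both]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------

def ibs_distance(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise (1 - IBS) distance matrix over samples.

    Per locus the shared-allele count under best pairing is 2 minus the
    total-variation distance of the two allele multisets -- equivalently
    ``2 - |dosage_i - dosage_j|`` for biallelic diploid calls.  IBS is the
    mean shared fraction over jointly non-missing loci.
    """
    if matrix.n_samples < 2:
        raise ConfigurationError("IBS needs >=2 samples")
    d = matrix.dosage()
    S = matrix.n_samples
    out = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            both = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            n = int(both.sum())
            if n == 0:
                raise ConfigurationError(
                    f"samples {matrix.samples[i]!r} and {matrix.samples[j]!r} "
                    "share no non-missing loci"
                )
            shared = (2.0 - np.abs(d[both, i] - d[both, j])).sum()
            dist = 1.0 - shared / (2.0 * n)
            out[i, j] = out[j, i] = dist
    return pd.DataFrame(out, index=matrix.samples, columns=matrix.samples)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: pd.DataFrame, outgroup: str | None = None) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Agglomerates by the Q criterion with deterministic tie-breaking on
    (row, column) index order.  Negative branch lengths are clamped to 0
    with the deficit transferred to the sibling branch.  With an outgroup,
    the tree is rooted on the outgroup's pendant edge (midpoint of it).
    """
    D = dist.to_numpy(dtype=float)
    if not np.allclose(D, D.T):
        raise ConfigurationError("distance matrix is not symmetric")
    if not np.isfinite(D).all():
        raise ConfigurationError("distance matrix has non-finite entries")
    names = list(dist.index)
    if len(names) < 3:
        raise ConfigurationError("neighbor joining needs >=3 taxa")

    nodes = [f"{n}" for n in names]  # newick fragments
    active = list(range(len(names)))
    D = D.copy()

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic argmin: first (i, j) in row-major order
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, transferring length to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)

        ai, aj = active[i], active[j]
        new = f"({nodes[ai]}:{li:.10g},{nodes[aj]}:{lj:.10g})"
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)-d(i,j))/2
        du = 0.5 * (D[ai] + D[aj] - dij)
        D = np.vstack([D, du])
        du2 = np.append(du, 0.0)
        D = np.column_stack([D, du2])
        nodes.append(new)
        u = len(nodes) - 1
        active = [a for a in active if a not in (ai, aj)] + [u]

    ai, aj = active
    final = max(D[ai, aj], 0.0)
    newick = f"({nodes[ai]}:{final:.10g},{nodes[aj]}:0);"
    if outgroup is not None:
        if outgroup not in names:
            raise ConfigurationError(f"outgroup {outgroup!r} not among taxa")
        newick = _root_at_outgroup(newick, outgroup)
    return newick


def _root_at_outgroup(newick: str, outgroup: str) -> str:
    """Re-root an unrooted NJ tree at the midpoint of the outgroup's edge."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    leaf = tree.find_node_with_taxon_label(outgroup)
    edge_len = leaf.edge.length or 0.0
    tree.reroot_at_edge(leaf.edge, length1=edge_len / 2.0,
                        length2=edge_len / 2.0, update_bipartitions=False)
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x PCs
    variance_fractions: np.ndarray = field(repr=False)


def pca_genotypes(matrix: GenotypeMatrix, n_components: int | None = None) -> PCAResult:
    """Genotype PCA with allele-frequency scaling.

    Dosage columns are mean-centered and scaled by sqrt(p(1-p)) where p is
    the sample alt-allele frequency (the smartpca normalisation); missing
    dosages are mean-imputed.  Monomorphic loci are dropped; components
    come ordered by eigenvalue, variance fractions sum to 1, and each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    if matrix.n_samples < 3:
        raise ConfigurationError("PCA needs >=3 samples")
    d = matrix.dosage()  # (L, S)
    mean = np.nanmean(d, axis=1)
    p = mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ConfigurationError("all loci are monomorphic")
    d = d[poly]
    mean = mean[poly]
    p = p[poly]
    filled = np.where(np.isnan(d), mean[:, None], d)
    z = (filled - mean[:, None]) / np.sqrt(p * (1.0 - p))[:, None]

    X = z.T  # samples x loci
    cov = X @ X.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[lead, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    frac = eigval / eigval.sum()
    k = n_components or matrix.n_samples
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0, None))
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=matrix.samples, columns=cols),
        variance_fractions=frac,
    )
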