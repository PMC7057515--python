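import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vertebramark.io_core import ConfigurationError
from vertebramark.popstats import (
    GenomicWindow,
    ibs_distance,
    ld_decay,
    neighbor_joining,
    pair_r2,
    pca_genotypes,
    select_sweep_windows,
    site_pi,
    sweep_scan,
    tile_windows,
    wc_site_components,
    window_fst,
    window_pi,
)
from vertebramark.simdata import CausalRegion, SimConfig, simulate_cohort

from conftest import make_manifest, make_matrix


def random_cohort(rng, n_loci=40, n_samples=8, chrom="chr1", missing=0.0):
    loci = [(chrom, int(p), "A", "C")
            for p in sorted(rng.choice(49_000, n_loci, replace=False) + 1)]
    calls = []
    for _ in range(n_loci):
        p = rng.uniform(0.1, 0.9)
        row = []
        for _ in range(n_samples):
            if rng.random() < missing:
                row.append("./.")
            else:
                row.append(f"{int(rng.random() < p)}/{int(rng.random() < p)}")
        calls.append(row)
    samples = [f"S{i}" for i in range(n_samples)]
    half = n_samples // 2
    rows = [(s, "A" if i < half else "B", 15, 5) for i, s in enumerate(samples)]
    return make_matrix(loci, samples, calls), make_manifest(rows)


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def brute_force_window_pi(matrix, sample_idx, window):
    """Mean pairwise allele differences per bp over all allele pairs."""
    pos0 = matrix.loci["pos"].to_numpy() - 1
    rows = np.flatnonzero(
        (matrix.loci["chrom"] == window.chrom).to_numpy()
        & (pos0 >= window.start) & (pos0 < window.end)
    )
    total = 0.0
    for i in rows:
        alleles = [
            a for j in sample_idx for a in matrix.alleles[i, j] if a >= 0
        ]
        pairs = list(itertools.combinations(alleles, 2))
        if not pairs:
            continue
        total += sum(a != b for a, b in pairs) / len(pairs)
    return total / (window.end - window.start)


class TestWindowPi:
    def test_monomorphic_window_is_zero(self):
        m = make_matrix([("chr1", 100, "A", "C")], ["a", "b"], [["0/0", "0/0"]])
        man = make_manifest([("a", "P", 15, 5), ("b", "P", 15, 5)])
        out = window_pi(m, man, ["P"], [GenomicWindow("chr1", 0, 50_000)])
        assert out["pi"].iloc[0] == 0.0

    def test_single_site_two_two_counts(self):
        """Allele counts 2 ref / 2 alt in a 50 kb window: (4/6)/50000."""
        m = make_matrix([("chr1", 100, "A", "C")], ["a", "b"], [["0/0", "1/1"]])
        man = make_manifest([("a", "P", 15, 5), ("b", "P", 15, 5)])
        out = window_pi(m, man, ["P"], [GenomicWindow("chr1", 0, 50_000)])
        assert out["pi"].iloc[0] == pytest.approx((4 / 6) / 50_000, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_pairwise_difference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, man = random_cohort(rng, n_loci=60, n_samples=10)
        w = GenomicWindow("chr1", 0, 50_000)
        out = window_pi(m, man, ["A", "B"], [w])
        oracle = brute_force_window_pi(m, np.arange(10), w)
        assert out["pi"].iloc[0] == pytest.approx(oracle, rel=1e-12)

    def test_oracle_equivalence_with_missing_sites(self):
        rng = np.random.default_rng(3)
        m, man = random_cohort(rng, n_loci=40, n_samples=8, missing=0.2)
        w = GenomicWindow("chr1", 0, 50_000)
        out = window_pi(m, man, ["A", "B"], [w])
        # oracle counts per-site over non-missing alleles only
        oracle = brute_force_window_pi(m, np.arange(8), w)
        assert out["pi"].iloc[0] == pytest.approx(oracle, rel=1e-10)


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def wc_oracle_site(calls_a, calls_b):
    """Independent scalar transcription of the two-population diploid
    Weir-Cockerham (1984) variance components; returns (a, a+b+c)."""
    def summarize(calls):
        calls = [c for c in calls if -1 not in c]
        n = len(calls)
        p = sum(a1 + a2 for a1, a2 in calls) / (2 * n)
        h = sum(a1 != a2 for a1, a2 in calls) / n
        return n, p, h

    n1, p1, h1 = summarize(calls_a)
    n2, p2, h2 = summarize(calls_b)
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, a + b + c


class TestWindowFst:
    def test_site_components_match_oracle_to_1e12(self):
        rng = np.random.default_rng(4)
        m, man = random_cohort(rng, n_loci=50, n_samples=10)
        idx_a, idx_b = np.arange(5), np.arange(5, 10)
        a, total = wc_site_components(m, idx_a, idx_b)
        for i in range(m.n_loci):
            calls_a = [tuple(m.alleles[i, j]) for j in idx_a]
            calls_b = [tuple(m.alleles[i, j]) for j in idx_b]
            oa, ot = wc_oracle_site(calls_a, calls_b)
            assert a[i] == pytest.approx(oa, abs=1e-12)
            assert total[i] == pytest.approx(ot, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        m = make_matrix(
            [("chr1", 100, "A", "C"), ("chr1", 200, "G", "T")],
            ["a1", "a2", "b1", "b2"],
            [["0/0", "0/0", "1/1", "1/1"]] * 2,
        )
        man = make_manifest(
            [("a1", "A", 15, 5), ("a2", "A", 15, 5),
             ("b1", "B", 14, 5), ("b2", "B", 14, 5)]
        )
        out = window_fst(m, man, ["A"], ["B"], [GenomicWindow("chr1", 0, 50_000)])
        assert out["fst"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_random_split_of_panmictic_pool_near_zero(self):
        """Mean window FST over random 5+5 splits of one pool: |mean| < 0.02."""
        cfg = SimConfig(
            seed=9, populations=(("P", 10),), case_population="P",
            chrom_lengths={"chr1": 2_000_000}, n_loci_per_chrom=2000,
            shared_pool=True, drift_f=0.0, switch_rate=1.0, missing_rate=0.0,
            pool_sizes={}, default_pool_size=40,
            causal=CausalRegion(chrom="chr1", start=0, end=100, n_loci=1),
        )
        cohort = simulate_cohort(cfg)
        samples = cohort.matrix.samples
        rng = np.random.default_rng(1)
        perm = rng.permutation(samples)
        rows = [(s, "A" if i < 5 else "B", 15, 5) for i, s in enumerate(perm)]
        man = make_manifest(rows)
        windows = tile_windows({"chr1": 2_000_000}, size=10_000, step=10_000)
        out = window_fst(cohort.matrix, man, ["A"], ["B"], windows)
        vals = out["fst"].dropna()
        assert len(vals) >= 190
        assert abs(vals.mean()) < 0.02

    def test_ratio_of_sums_invariant_to_site_splits(self):
        rng = np.random.default_rng(6)
        m, man = random_cohort(rng, n_loci=30, n_samples=10)
        idx_a, idx_b = np.arange(5), np.arange(5, 10)
        a, total = wc_site_components(m, idx_a, idx_b)
        whole = np.nansum(a) / np.nansum(total)
        split = (np.nansum(a[:13]) + np.nansum(a[13:])) / (
            np.nansum(total[:13]) + np.nansum(total[13:])
        )
        assert whole == pytest.approx(split, rel=1e-12)

    def test_empty_window_absent_not_zero(self):
        rng = np.random.default_rng(2)
        m, man = random_cohort(rng, n_loci=10, n_samples=8)
        out = window_fst(m, man, ["A"], ["B"], [GenomicWindow("chr9", 0, 1000)])
        assert np.isnan(out["fst"].iloc[0])


# ---------------------------------------------------------------------------
# sweep selection
# ---------------------------------------------------------------------------

def _sweep_frame(fst, ratio, low_sites=None):
    n = len(fst)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 10_000,
            "end": np.arange(n) * 10_000 + 50_000,
            "n_sites": 10,
            "pi_case": 1e-3,
            "pi_control": 1e-3,
            "fst": fst,
            "log2_pi_ratio": ratio,
            "low_sites": low_sites if low_sites is not None else [False] * n,
        }
    )


class TestSelectSweepWindows:
    def test_matches_brute_force_rank_intersection(self):
        rng = np.random.default_rng(8)
        fst = rng.random(100)
        ratio = rng.standard_normal(100)
        out = select_sweep_windows(_sweep_frame(fst, ratio), top_fraction=0.05)
        fst_thr = np.quantile(fst, 0.95)
        ratio_thr = np.quantile(ratio, 0.95)
        expected = (fst >= fst_thr) & (ratio >= ratio_thr)
        assert ((out["selected_for"] == "case").to_numpy() == expected).all()

    def test_all_tied_fst_all_flagged(self):
        """Every window at the threshold: inclusive rule flags them all."""
        fst = np.ones(30)
        ratio = np.ones(30)
        out = select_sweep_windows(_sweep_frame(fst, ratio))
        assert (out["selected_for"] == "case").all()

    def test_planted_low_diversity_region_flagged_for_case(self):
        cfg = SimConfig(seed=21, n_loci_per_chrom=1500, missing_rate=0.0,
                        sweep_halo=20_000)
        cohort = simulate_cohort(cfg)
        windows = tile_windows(cfg.chrom_lengths, size=50_000, step=50_000)
        table = sweep_scan(cohort.matrix, cohort.manifest, ["YC"], ["ZC", "GY"],
                           windows, min_sites=2)
        table = select_sweep_windows(table, top_fraction=0.05)
        causal = table[
            (table["chrom"] == cfg.causal.chrom)
            & (table["start"] <= cfg.causal.start)
            & (table["end"] >= cfg.causal.end)
        ]
        assert (causal["selected_for"] == "case").any()

    def test_refuses_too_few_windows(self):
        with pytest.raises(ConfigurationError):
            select_sweep_windows(_sweep_frame(np.ones(10), np.ones(10)))

    def test_low_sites_windows_excluded_from_quantiles(self):
        fst = np.concatenate([np.full(30, 0.1), [0.99]])
        ratio = np.concatenate([np.full(30, 0.1), [5.0]])
        low = [False] * 30 + [True]
        out = select_sweep_windows(_sweep_frame(fst, ratio, low))
        assert out["selected_for"].iloc[-1] == "none"


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

class TestLdDecay:
    def test_identical_locus_pair_r2_one(self):
        rng = np.random.default_rng(0)
        m, man = random_cohort(rng, n_loci=2, n_samples=8)
        m.alleles[1] = m.alleles[0]
        assert pair_r2(m, 0, 1) == pytest.approx(1.0)

    def test_perfect_repulsion_r2_one(self):
        """Anticorrelated dosages: r^2 is sign-invariant."""
        m = make_matrix(
            [("chr1", 100, "A", "C"), ("chr1", 200, "G", "T")],
            ["a", "b", "c"],
            [["0/0", "0/1", "1/1"], ["1/1", "0/1", "0/0"]],
        )
        assert pair_r2(m, 0, 1) == pytest.approx(1.0)

    def test_independent_loci_mean_r2_near_1_over_n_minus_1(self):
        rng = np.random.default_rng(12)
        m, man = random_cohort(rng, n_loci=45, n_samples=50)
        man = make_manifest([(s, "P", 15, 5) for s in m.samples])
        out = ld_decay(m, man, "P", max_distance=50_000, bin_width=50_000)
        mean_r2 = out["mean_r2"].iloc[0]
        assert out["n_pairs"].iloc[0] > 500
        assert mean_r2 == pytest.approx(1 / 49, abs=0.012)

    def test_decay_monotone_trend_on_copying_haplotypes(self):
        """Spearman correlation of mean r^2 vs distance bin is negative."""
        cfg = SimConfig(
            seed=13, populations=(("P", 25),), case_population="P",
            chrom_lengths={"chr1": 200_000}, n_loci_per_chrom=350,
            pool_sizes={"P": 4}, switch_rate=0.05, missing_rate=0.0,
            causal=CausalRegion(chrom="chr1", start=0, end=60, n_loci=1),
        )
        cohort = simulate_cohort(cfg)
        out = ld_decay(cohort.matrix, cohort.manifest, "P",
                       max_distance=50_000, bin_width=5_000)
        ok = out.dropna(subset=["mean_r2"])
        rho, p = stats.spearmanr(ok["bin_start"], ok["mean_r2"])
        assert rho < 0 and p < 0.01


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------

class TestIbsDistance:
    def test_identical_opposite_and_half_shared(self):
        m = make_matrix(
            [("chr1", 100, "A", "C")],
            ["s1", "s2", "s3", "s4"],
            [["0/0", "0/0", "1/1", "0/1"]],
        )
        d = ibs_distance(m)
        assert d.loc["s1", "s2"] == 0.0
        assert d.loc["s1", "s3"] == 1.0
        assert d.loc["s1", "s4"] == 0.5
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.diag(d.to_numpy()).sum() == 0.0

    def test_no_joint_loci_raises(self):
        m = make_matrix(
            [("chr1", 100, "A", "C"), ("chr1", 200, "G", "T")],
            ["s1", "s2"],
            [["0/0", "./."], ["./.", "1/1"]],
        )
        with pytest.raises(ConfigurationError, match="s1"):
            ibs_distance(m)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_taxa):
    """Random binary tree; returns (leaf names, exact pairwise distances)."""
    # adjacency: node -> list of (node, length); leaves are L0..L{n-1}
    adj = {}

    def connect(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    edges = []
    connect("L0", "L1", round(rng.uniform(0.1, 1.0), 3))
    edges.append(("L0", "L1"))
    next_internal = 0
    for k in range(2, n_taxa):
        u, v = edges[rng.integers(len(edges))]
        w = dict(adj[u])[v]
        mid = f"I{next_internal}"
        next_internal += 1
        adj[u] = [(x, l) for x, l in adj[u] if x != v]
        adj[v] = [(x, l) for x, l in adj[v] if x != u]
        split = round(rng.uniform(0.3, 0.7), 3)
        connect(u, mid, round(w * split, 6))
        connect(mid, v, round(w - w * split, 6))
        connect(mid, f"L{k}", round(rng.uniform(0.1, 1.0), 3))
        edges = [e for e in edges if e != (u, v)]
        edges += [(u, mid), (mid, v), (mid, f"L{k}")]

    leaves = [f"L{i}" for i in range(n_taxa)]
    dist = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for leaf in leaves:
        seen = {leaf: 0.0}
        stack = [leaf]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen[nxt] = seen[node] + w
                    stack.append(nxt)
        for other in leaves:
            dist.loc[leaf, other] = seen[other]
    sym = (dist.to_numpy() + dist.to_numpy().T) / 2.0  # remove float path-order jitter
    return leaves, pd.DataFrame(sym, index=leaves, columns=leaves)


def patristic_from_newick(newick, leaves):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    out = pd.DataFrame(0.0, index=leaves, columns=leaves)
    for i, a in enumerate(leaves):
        for b in leaves[i + 1:]:
            d = pdm.patristic_distance(taxa[a], taxa[b])
            out.loc[a, b] = out.loc[b, a] = d
    return out


class TestNeighborJoining:
    def test_three_taxon_worked_example(self):
        dist = pd.DataFrame(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        newick = neighbor_joining(dist)
        pat = patristic_from_newick(newick, list("ABC"))
        assert pat.loc["A", "B"] == pytest.approx(2.0)
        assert pat.loc["A", "C"] == pytest.approx(4.0)
        # pendant branch lengths A:1, B:1, C:3
        import dendropy
        tree = dendropy.Tree.get(data=newick, schema="newick")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_recovers_random_additive_trees_exactly(self, n_taxa):
        rng = np.random.default_rng(100 + n_taxa)
        leaves, dist = random_additive_tree(rng, n_taxa)
        newick = neighbor_joining(dist)
        pat = patristic_from_newick(newick, leaves)
        assert np.allclose(pat.to_numpy(), dist.to_numpy(), atol=1e-8)

    def test_agrees_with_skbio_on_additive_metric(self):
        """Independent cross-check: scikit-bio NJ on the same additive
        matrix yields the same patristic distances."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(42)
        leaves, dist = random_additive_tree(rng, 6)
        dm = skbio.DistanceMatrix(dist.to_numpy(), ids=leaves)
        sk_tree = skbio.tree.nj(dm)
        mine = patristic_from_newick(neighbor_joining(dist), leaves)
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                assert mine.loc[a, b] == pytest.approx(
                    sk_tree.find(a).distance(sk_tree.find(b)), abs=1e-8
                )

    def test_equidistant_taxa_deterministic(self):
        dist = pd.DataFrame(
            1.0 - np.eye(4), index=list("ABCD"), columns=list("ABCD")
        )
        assert neighbor_joining(dist) == neighbor_joining(dist)

    def test_outgroup_rooting(self):
        import dendropy
        dist = pd.DataFrame(
            [[0, 2, 4, 9], [2, 0, 4, 9], [4, 4, 0, 9], [9, 9, 9, 0]],
            index=list("ABCO"), columns=list("ABCO"), dtype=float,
        )
        newick = neighbor_joining(dist, outgroup="O")
        tree = dendropy.Tree.get(data=newick, schema="newick")
        children = tree.seed_node.child_nodes()
        labels = [
            c.taxon.label if c.taxon else None for c in children
        ]
        assert "O" in labels  # outgroup sits on the root's pendant edge

    def test_nonsymmetric_matrix_rejected(self):
        dist = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 2], [2, 2, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        with pytest.raises(ConfigurationError):
            neighbor_joining(dist)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPcaGenotypes:
    def test_pc1_separates_two_populations(self):
        cfg = SimConfig(seed=17, n_loci_per_chrom=300, drift_f=0.3,
                        missing_rate=0.0)
        cohort = simulate_cohort(cfg)
        result = pca_genotypes(cohort.matrix)
        coords = result.coordinates
        yc = coords.loc[[s for s in coords.index if s.startswith("YC")], "PC1"]
        gy = coords.loc[[s for s in coords.index if s.startswith("GY")], "PC1"]
        # one of the first two PCs fully separates case from GY controls
        sep = False
        for pc in ("PC1", "PC2"):
            a = coords.loc[yc.index, pc]
            b = coords.loc[gy.index, pc]
            if a.max() < b.min() or b.max() < a.min():
                sep = True
        assert sep

    def test_duplicate_samples_identical_coordinates(self):
        rng = np.random.default_rng(5)
        m, _ = random_cohort(rng, n_loci=30, n_samples=4)
        dup = m.subset_samples(m.samples + m.samples[:1])
        dup.samples[-1] = "dup"
        result = pca_genotypes(dup)
        c = result.coordinates
        np.testing.assert_allclose(
            c.loc[m.samples[0]].to_numpy(), c.loc["dup"].to_numpy(), atol=1e-6
        )

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        m, _ = random_cohort(rng, n_loci=30, n_samples=6)
        result = pca_genotypes(m)
        assert result.variance_fractions.sum() == pytest.approx(1.0)

    def test_all_monomorphic_rejected(self):
        m = make_matrix(
            [("chr1", 100, "A", "C")], ["a", "b", "c"], [["0/0"] * 3]
        )
        with pytest.raises(ConfigurationError):
            pca_genotypes(m)
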