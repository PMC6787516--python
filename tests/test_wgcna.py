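import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster

import coexnet as cx
from coexnet import wgcna as wg

from conftest import make_expr


# ---------------------------------------------------------------------------
# adjacency

def test_adjacency_identical_genes_and_identity_power():
    rng = np.random.default_rng(0)
    base = rng.standard_normal(10)
    x = np.vstack([base, base, rng.standard_normal(10)])
    m = make_expr(x)
    for beta in (1, 4, 7):
        a = cx.adjacency(m, beta).matrix
        assert a[0, 1] == pytest.approx(1.0)
    a1 = cx.adjacency(m, 1).matrix
    c = np.corrcoef(x)
    np.testing.assert_allclose(a1, np.abs(c), atol=1e-12)


def test_adjacency_matches_elementwise_bruteforce():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((20, 15))
    a = cx.adjacency(make_expr(x), 4).matrix
    for i in range(20):
        for j in range(20):
            expected = 1.0 if i == j else abs(np.corrcoef(x[i], x[j])[0, 1]) ** 4
            assert a[i, j] == pytest.approx(expected, abs=1e-12)


def test_raising_power_weakly_decreases_offdiagonal():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((15, 12))
    m = make_expr(x)
    a1 = cx.adjacency(m, 1).matrix
    a6 = cx.adjacency(m, 6).matrix
    off = ~np.eye(15, dtype=bool)
    assert (a6[off] <= a1[off] + 1e-15).all()


# ---------------------------------------------------------------------------
# TOM

def _tom_oracle(a):
    """O(n^3) triple-loop topological overlap."""
    n = a.shape[0]
    t = np.ones((n, n))
    k = np.array([a[i].sum() - a[i, i] for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            t[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return t


def random_adjacency(rng, n):
    c = rng.uniform(0, 1, size=(n, n))
    a = (c + c.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def test_tom_full_clique_and_empty_graph():
    n = 8
    a = np.ones((n, n))
    t = wg.tom_from_adjacency(a)
    off = ~np.eye(n, dtype=bool)
    np.testing.assert_allclose(t[off], 1.0, atol=1e-12)
    a0 = np.eye(n)
    t0 = wg.tom_from_adjacency(a0)
    np.testing.assert_allclose(t0[off], 0.0, atol=1e-12)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(3)
    a = random_adjacency(rng, 50)
    np.testing.assert_allclose(wg.tom_from_adjacency(a), _tom_oracle(a),
                               atol=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_tom_bounds_on_random_adjacency(seed):
    rng = np.random.default_rng(seed)
    a = random_adjacency(rng, 30)
    t = wg.tom_from_adjacency(a)
    assert (t >= -1e-12).all() and (t <= 1 + 1e-12).all()
    np.testing.assert_allclose(t, t.T, atol=1e-12)


# ---------------------------------------------------------------------------
# scale-free fit and power selection

def test_scale_free_fit_exact_power_law_is_one():
    # points evenly spaced within geometric bins: density is exactly
    # proportional to 1/k on the log-log scale
    ks = []
    m = 50
    for b in range(10):
        lo = 2.0 ** b
        ks.extend(np.linspace(lo, 2 * lo, m, endpoint=False))
    fit = wg.scale_free_fit(np.array(ks), n_bins=10)
    assert fit == pytest.approx(1.0, abs=1e-9)


def test_scan_mean_connectivity_decreases_with_power(small_dataset):
    expr, _ = small_dataset
    scan = cx.soft_connectivity_scan(expr, powers=(1, 2, 4, 6), seed=0)
    mk = scan.mean_connectivity
    assert all(mk[i + 1] < mk[i] for i in range(len(mk) - 1))


def test_scan_chooses_smallest_power_reaching_target(small_dataset):
    expr, _ = small_dataset
    scan = cx.soft_connectivity_scan(expr, powers=(1, 2, 3, 4, 5, 6, 8),
                                     target_fit=0.85, seed=0)
    # oracle: independent straight-line fit over the same binned densities
    chosen = None
    for p, f in zip(scan.powers, scan.fit_index):
        if f is not None and f >= 0.85:
            chosen = p
            break
    assert scan.chosen_power == chosen


# ---------------------------------------------------------------------------
# clustering and module detection

def _average_linkage_oracle(d):
    """Textbook O(n^3) average-linkage; returns sorted merge heights."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    nxt = n
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters.pop(i) + clusters.pop(j)
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for k, mem in clusters.items():
            pair_d = np.mean([d[a, b] for a in merged for b in mem])
            dist[(min(k, nxt), max(k, nxt))] = pair_d
        clusters[nxt] = merged
        nxt += 1
    return np.sort(heights)


def test_average_linkage_matches_textbook_oracle():
    rng = np.random.default_rng(4)
    pts = rng.standard_normal((30, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    z = cx.cluster_genes(d)
    np.testing.assert_allclose(np.sort(z[:, 2]), _average_linkage_oracle(d),
                               atol=1e-10)


def test_linkage_heights_nondecreasing_and_separated_blocks():
    rng = np.random.default_rng(5)
    d = rng.uniform(0.8, 0.9, size=(20, 20))
    d[:10, :10] = rng.uniform(0.0, 0.1, size=(10, 10))
    d[10:, 10:] = rng.uniform(0.0, 0.1, size=(10, 10))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    z = cx.cluster_genes(d)
    assert (np.diff(z[:, 2]) >= -1e-12).all()
    two = fcluster(z, t=2, criterion="maxclust")
    assert len(set(two[:10])) == 1 and len(set(two[10:])) == 1
    assert set(two[:10]) != set(two[10:])


def _block_dissimilarity(rng, sizes, n_extra=0, within=0.1, between=0.9):
    n = sum(sizes) + n_extra
    d = rng.uniform(between - 0.05, between + 0.05, size=(n, n))
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = rng.uniform(
            within - 0.05, within + 0.05, size=(s, s))
        start += s
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d


def test_cut_modules_recovers_planted_blocks_exactly():
    rng = np.random.default_rng(6)
    sizes = [60, 60, 60, 60]
    d = _block_dissimilarity(rng, sizes)
    z = cx.cluster_genes(d)
    ids = [f"g{i:03d}" for i in range(sum(sizes))]
    mods = cx.cut_modules(z, d, ids, min_size=30, cut_height=0.5)
    truth = pd.Series(np.repeat([f"M{i}" for i in range(4)], 60), index=ids)
    ari, jac = cx.recovery_scores(truth, mods)
    assert ari == pytest.approx(1.0)
    assert all(v == 1.0 for v in jac.values())


def test_cut_modules_all_grey_when_min_size_too_large():
    rng = np.random.default_rng(7)
    d = _block_dissimilarity(rng, [20, 20])
    z = cx.cluster_genes(d)
    ids = [f"g{i}" for i in range(40)]
    mods = cx.cut_modules(z, d, ids, min_size=30, cut_height=0.5)
    assert mods.modules() == []
    assert (mods.labels == "grey").all()


def test_outlier_gene_never_forms_singleton_module():
    rng = np.random.default_rng(8)
    d = _block_dissimilarity(rng, [30, 30], n_extra=1, between=0.9)
    # the extra gene sits between the blocks
    d[-1, :] = d[:, -1] = 0.6
    d[-1, -1] = 0
    z = cx.cluster_genes(d)
    ids = [f"g{i}" for i in range(61)]
    mods = cx.cut_modules(z, d, ids, min_size=10, cut_height=0.75)
    sizes = mods.sizes()
    assert all(s >= 10 for s in sizes.values())


# ---------------------------------------------------------------------------
# eigengenes

def test_eigengene_of_identical_genes_is_their_profile():
    rng = np.random.default_rng(9)
    base = rng.standard_normal(12)
    x = np.vstack([base] * 5 + [rng.standard_normal(12) for _ in range(5)])
    expr = make_expr(x)
    labels = pd.Series(["blue"] * 5 + ["grey"] * 5, index=expr.gene_ids)
    egs = cx.module_eigengene(expr, cx.ModuleAssignment(labels))
    me = egs.profile("blue")
    r = np.corrcoef(me, base)[0, 1]
    assert r == pytest.approx(1.0, abs=1e-10)
    assert np.linalg.norm(me) == pytest.approx(1.0, abs=1e-10)


def test_eigengene_matches_independent_svd_oracle():
    rng = np.random.default_rng(10)
    x = rng.standard_normal((30, 15))
    expr = make_expr(x)
    labels = pd.Series(["m1"] * 30, index=expr.gene_ids)
    egs = cx.module_eigengene(expr, cx.ModuleAssignment(labels))
    me = egs.profile("m1")
    xs = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
    # oracle: first PC from the full eigen-decomposition of the sample
    # covariance of the standardized matrix
    w, v = np.linalg.eigh(xs.T @ xs)
    pc1 = v[:, -1]
    assert abs(np.corrcoef(me, pc1)[0, 1]) >= 1 - 1e-10
    # Rayleigh optimality: no other unit vector explains more variance
    assert np.linalg.norm(xs @ me) ** 2 == pytest.approx(w[-1], rel=1e-9)


def test_eigengene_sign_orientation_flips_with_members():
    rng = np.random.default_rng(11)
    x = rng.standard_normal((6, 10)) + rng.standard_normal(10)[None, :]
    expr = make_expr(x)
    labels = pd.Series(["m"] * 6, index=expr.gene_ids)
    me1 = cx.module_eigengene(expr, cx.ModuleAssignment(labels)).profile("m")
    expr_neg = make_expr(-x)
    me2 = cx.module_eigengene(expr_neg, cx.ModuleAssignment(
        pd.Series(["m"] * 6, index=expr_neg.gene_ids))).profile("m")
    np.testing.assert_allclose(me1, -me2, atol=1e-10)


def test_merge_unions_same_factor_modules_keeps_orthogonal():
    rng = np.random.default_rng(12)
    n = 60
    z1, z2 = rng.standard_normal((2, n))
    x = np.empty((40, n))
    for i, z in enumerate([z1, z1, z2, z2]):  # two module pairs share factors
        rows = slice(i * 10, (i + 1) * 10)
        x[rows] = 0.95 * z + np.sqrt(1 - 0.95 ** 2) * rng.standard_normal((10, n))
    expr = make_expr(x)
    labels = pd.Series(np.repeat(["a", "b", "c", "d"], 10), index=expr.gene_ids)
    merged = cx.merge_similar_modules(expr, cx.ModuleAssignment(labels),
                                      merge_height=0.25, min_size=5)
    assert len(merged.modules()) == 2
    # members of each factor end up together
    m_of = merged.labels
    assert len(set(m_of.iloc[:20])) == 1
    assert len(set(m_of.iloc[20:])) == 1
    assert m_of.iloc[0] != m_of.iloc[-1]


# ---------------------------------------------------------------------------
# module statistics

def test_module_trait_pvalue_closed_form_examples():
    # printed (cor, P) pairs at n = 70
    assert round(float(cx.correlation_pvalue(0.28, 70)), 2) == 0.02
    assert round(float(cx.correlation_pvalue(0.31, 70)), 3) == 0.009
    assert round(float(cx.correlation_pvalue(0.34, 70)), 3) == 0.004
    assert float(cx.correlation_pvalue(0.0, 10)) == pytest.approx(1.0)


def test_module_trait_correlation_matches_t_transform(small_dataset):
    expr, traits = small_dataset
    labels = pd.Series(["blue"] * 40 + ["grey"] * 260, index=expr.gene_ids)
    egs = cx.module_eigengene(expr, cx.ModuleAssignment(labels))
    mt = cx.module_trait_correlation(egs, traits)
    row = mt[(mt["module"] == "blue") & (mt["trait"] == "t1")].iloc[0]
    from scipy import stats
    r = row["cor"]
    t = abs(r) * np.sqrt(row["n"] - 2) / np.sqrt(1 - r * r)
    assert row["p"] == pytest.approx(2 * stats.t.sf(t, row["n"] - 2), abs=1e-12)
    assert abs(r) > 0.5  # trait is the module's latent factor


def test_gene_significance_trait_equal_to_gene(small_dataset):
    expr, traits = small_dataset
    t = traits.traits.copy()
    t["self"] = expr.data.iloc[0]
    tt = cx.TraitTable(traits=t, group=traits.group)
    gs = cx.gene_significance(expr, tt)
    assert gs["gs"].iloc[0]["self"] == pytest.approx(1.0, abs=1e-12)


def test_gene_significance_null_pvalues_uniform():
    rng = np.random.default_rng(13)
    expr = make_expr(rng.standard_normal((1000, 30)))
    idx = expr.sample_ids
    tt = cx.TraitTable(
        traits=pd.DataFrame({"rand": rng.standard_normal(30)}, index=idx),
        group=pd.Series(["a"] * 15 + ["b"] * 15, index=idx))
    gs = cx.gene_significance(expr, tt)
    from scipy.stats import kstest
    assert kstest(gs["p"]["rand"], "uniform").pvalue > 0.01


def test_gene_significance_planted_module_beats_background(small_dataset):
    expr, traits = small_dataset
    gs = cx.gene_significance(expr, traits)["gs"]["t1"].abs()
    module, background = gs.iloc[:40].to_numpy(), gs.iloc[40:].to_numpy()
    frac = (module[:, None] > background[None, :]).mean()
    assert frac >= 0.95


def test_module_membership_planted_and_symmetries(small_dataset):
    expr, traits = small_dataset
    labels = pd.Series(["blue"] * 40 + ["grey"] * 260, index=expr.gene_ids)
    egs = cx.module_eigengene(expr, cx.ModuleAssignment(labels))
    kme = cx.module_membership(expr, egs)
    assert (kme.iloc[:40]["blue"] > 0.5).mean() >= 0.95
    # the eigengene itself as a pseudo-gene has kME 1 with its module
    pseudo = pd.DataFrame([egs.profile("blue"), -egs.profile("blue")],
                          index=["me", "negme"], columns=expr.sample_ids)
    kme2 = cx.module_membership(cx.ExpressionMatrix(pseudo), egs)
    assert kme2.loc["me", "blue"] == pytest.approx(1.0, abs=1e-10)
    assert kme2.loc["negme", "blue"] == pytest.approx(-1.0, abs=1e-10)


def test_hub_genes_star_topology_and_bruteforce():
    n = 12
    a = np.full((n, n), 0.1)
    a[0, :] = a[:, 0] = 0.9  # star center
    np.fill_diagonal(a, 1.0)
    ids = [f"g{i:02d}" for i in range(n)]
    adj = wg.AdjacencyMatrix(gene_ids=ids, matrix=a, power=1)
    labels = pd.Series(["m"] * n, index=ids)
    hubs = cx.hub_genes(adj, cx.ModuleAssignment(labels), top_n=5)
    assert hubs.iloc[0]["gene"] == "g00"
    # brute-force oracle on a random two-module adjacency
    rng = np.random.default_rng(14)
    a2 = rng.uniform(0, 1, (20, 20))
    a2 = (a2 + a2.T) / 2
    np.fill_diagonal(a2, 1.0)
    ids2 = [f"h{i:02d}" for i in range(20)]
    labels2 = pd.Series(["x"] * 10 + ["y"] * 10, index=ids2)
    adj2 = wg.AdjacencyMatrix(gene_ids=ids2, matrix=a2, power=1)
    hubs2 = cx.hub_genes(adj2, cx.ModuleAssignment(labels2), top_n=100)
    for mod, rows in hubs2.groupby("module"):
        members = [i for i, l in enumerate(labels2) if l == mod]
        kin = {ids2[i]: sum(a2[i, j] for j in members if j != i)
               for i in members}
        expected = sorted(kin, key=lambda g: (-kin[g], g))
        assert list(rows.sort_values("rank")["gene"]) == expected


def test_prune_low_kme_strips_noise_members(small_dataset):
    expr, _ = small_dataset
    # module contaminated with 10 noise genes
    labels = pd.Series(["blue"] * 50 + ["grey"] * 250, index=expr.gene_ids)
    pruned = cx.prune_low_kme(expr, cx.ModuleAssignment(labels),
                              min_kme=0.5, min_size=10)
    kept = set(pruned.genes_in(pruned.modules()[0]))
    assert kept <= set(expr.gene_ids[:40])
    assert len(kept) >= 35


# ---------------------------------------------------------------------------
# property tests

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=100, deadline=None)
@given(r=st.floats(-0.999, 0.999), n=st.integers(5, 500))
def test_correlation_pvalue_properties(r, n):
    p = float(cx.correlation_pvalue(r, n))
    assert 0 < p <= 1
    # strictly stronger correlation at the same n is at least as significant
    p2 = float(cx.correlation_pvalue(min(0.999, abs(r) + 0.05), n))
    assert p2 <= p + 1e-12
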