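"""Network construction: similarity/adjacency/TOM algebra, power
selection, module detection, eigengenes and hub selection."""

import numpy as np
import pandas as pd
import pytest

from gliohub import network
from gliohub.errors import DegenerateInputError, NoQualifyingPowerError
from gliohub.simulate import SynthConfig, generate_cohort

from conftest import toy_expression


def expr_with_correlation(r, n=400, seed=0):
    """Two genes with population correlation r (plus tiny jitter-free draw)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = r * a + np.sqrt(1 - r * r) * rng.standard_normal(n)
    return toy_expression(np.vstack([a, b]))


class TestSimilarity:
    def test_identical_genes_score_one_in_both_modes(self):
        expr = toy_expression([[1.0, 2.0, 3.0, 5.0], [1.0, 2.0, 3.0, 5.0]])
        for mode in ("unsigned", "signed"):
            s = network.similarity(expr, mode=mode)
            assert s.iloc[0, 1] == pytest.approx(1.0)

    def test_constant_gene_is_rejected_by_name(self):
        expr = toy_expression([[1, 1, 1], [1, 2, 3]])
        with pytest.raises(DegenerateInputError, match="g1"):
            network.similarity(expr)

    def test_negative_correlation_maps_per_formula(self):
        # empirically r ~ -0.8; unsigned = |r|, signed = r/2 + 0.5
        expr = expr_with_correlation(-0.8, n=5000)
        r = np.corrcoef(expr.to_numpy())[0, 1]
        s_u = network.similarity(expr, "unsigned").iloc[0, 1]
        s_s = network.similarity(expr, "signed").iloc[0, 1]
        assert s_u == pytest.approx(abs(r), abs=1e-12)
        assert s_s == pytest.approx(r / 2 + 0.5, abs=1e-12)


class TestAdjacency:
    def test_elementwise_power(self):
        s = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        assert network.adjacency(s, 2).iloc[0, 1] == pytest.approx(0.25)
        assert network.adjacency(s, 1).iloc[0, 1] == pytest.approx(0.5)

    def test_power_nine_reference_value(self):
        s = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"], columns=["a", "b"])
        assert network.adjacency(s, 9).iloc[0, 1] == pytest.approx(0.387420489)

    def test_power_below_one_rejected(self):
        s = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            network.adjacency(s, 0)


class TestScaleFreeFit:
    def test_perfect_power_law_scores_plus_one(self):
        # construct connectivities whose binned log-log frequencies are
        # exactly collinear by placing n_j = c * k_j^-g nodes at degree k_j
        ks = np.array([1.0, 2.0, 4.0, 8.0])
        counts = np.array([64, 16, 4, 1])
        k = np.repeat(ks, counts)
        # bypass adjacency: scale_free_fit only uses connectivity; make a
        # diagonal-free matrix with the required row sums (k_i / (n-1) each)
        n = k.size
        a = np.tile(k[:, None] / (n - 1), (1, n))
        np.fill_diagonal(a, 0)
        # row sums now k * (n-1)/(n-1) = k (minus negligible diagonal share)
        adj = pd.DataFrame(a * (n - 1) / (n - 1), index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        r2, slope = network.scale_free_fit(adj, n_bins=10)
        assert slope < 0
        assert r2 > 0.99

    def test_increasing_frequencies_score_minus(self):
        ks = np.array([1.0, 2.0, 4.0, 8.0])
        counts = np.array([1, 4, 16, 64])  # frequency rising with k
        k = np.repeat(ks, counts)
        n = k.size
        a = np.tile(k[:, None] / (n - 1), (1, n))
        np.fill_diagonal(a, 0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        r2, slope = network.scale_free_fit(adj, n_bins=10)
        assert slope > 0
        assert r2 < -0.9

    def test_random_networks_rarely_look_scale_free(self):
        hits = 0
        trials = 20
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((500, 40))
            expr = toy_expression(x)
            adj = network.adjacency(network.similarity(expr), 3)
            r2, _ = network.scale_free_fit(adj)
            hits += r2 >= 0.9
        assert hits <= 1  # >= 95% of seeds below the cutoff


class TestPickPower:
    def test_mean_connectivity_strictly_decreases(self, small_cohort):
        expr, _, _ = small_cohort
        scan = network.soft_threshold_scan(expr, range(1, 8))
        assert (np.diff(scan["mean_k"]) < 0).all()

    def test_r2_zero_returns_smallest_candidate(self, small_cohort):
        expr, _, _ = small_cohort
        power, _ = network.pick_power(expr, range(2, 9), r2_min=0.0)
        assert power == 2

    def test_planted_cohort_qualifies_within_default_grid(self):
        # co-expression structure at default module-grade correlations
        cfg = SynthConfig(deg_lfc_range=(0.0, 0.0), deg_gene_scale=1.0)
        expr, _, _ = generate_cohort(cfg, seed=0)
        power, scan = network.pick_power(expr)
        assert power in range(1, 21)
        row = scan[scan["power"] == power].iloc[0]
        assert row["r2"] >= 0.9

    def test_independent_noise_has_no_qualifying_power(self, rng):
        # restricted to small powers: raising noise correlations to a high
        # power makes extreme-value degrees mimic a power law, so only the
        # low-power regime separates real structure from noise
        expr = toy_expression(rng.standard_normal((300, 60)))
        with pytest.raises(NoQualifyingPowerError) as err:
            network.pick_power(expr, range(1, 7))
        assert err.value.scan.shape[0] == 6


class TestTOM:
    def test_fully_connected_triple(self):
        a = pd.DataFrame(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                         index=list("abc"), columns=list("abc"))
        np.fill_diagonal(a.values, 1.0)
        omega = network.tom(a)
        # l_12 = 1, a_12 = 1, min(k)=2: (1+1)/(2+1-1) = 1
        assert omega.loc["a", "b"] == pytest.approx(1.0)

    def test_empty_adjacency_gives_identity_pattern(self):
        a = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        omega = network.tom(a)
        off = omega.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(omega), 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        n = 12
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                           columns=[f"g{i}" for i in range(n)])
        omega = network.tom(adj).to_numpy()
        a0 = a.copy()
        np.fill_diagonal(a0, 0.0)
        k = a0.sum(1)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l_ij = sum(a0[i, u] * a0[u, j] for u in range(n) if u not in (i, j))
                expect = (l_ij + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
                assert omega[i, j] == pytest.approx(expect, abs=1e-12)


def block_tom(sizes, within=0.8, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    omega = np.zeros((n, n))
    start = 0
    for s in sizes:
        omega[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(omega, 1.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(omega, index=genes, columns=genes)


class TestDetectModules:
    def test_perfect_blocks_recovered_exactly(self):
        omega = block_tom([40, 35, 30])
        asg = network.detect_modules(omega, min_module_size=20)
        assert len(asg.modules()) == 3
        assert (asg.labels != "grey").all()
        sizes = sorted(asg.sizes().tolist(), reverse=True)
        assert sizes == [40, 35, 30]

    def test_degenerate_tom_collapses_to_single_module(self, caplog):
        omega = block_tom([60])  # all off-diagonals equal
        with caplog.at_level("WARNING"):
            asg = network.detect_modules(omega, min_module_size=10)
        assert len(asg.modules()) == 1

    def test_all_noise_cohort_is_mostly_grey(self, rng):
        expr = toy_expression(rng.standard_normal((300, 200)))
        adj = network.adjacency(network.similarity(expr), 6)
        omega = network.tom(adj)
        asg = network.detect_modules(omega, min_module_size=30, expr=expr)
        assert (asg.labels == "grey").mean() >= 0.9


class TestEigengenes:
    def test_identical_genes_give_perfect_membership(self):
        rng = np.random.default_rng(1)
        profile = rng.standard_normal(30)
        expr = toy_expression(np.vstack([profile * 2 + 5] * 4))
        asg = network.ModuleAssignment(pd.Series("turquoise", index=expr.index))
        me = network.module_eigengenes(expr, asg)
        assert np.linalg.norm(me["turquoise"]) == pytest.approx(1.0)
        r = np.corrcoef(expr.iloc[0], me["turquoise"])[0, 1]
        assert r == pytest.approx(1.0)

    def test_recovers_latent_factor(self):
        cfg = SynthConfig(n_normal=0, n_grade2=170, n_grade3=170, n_grade4=160,
                          n_modules=1, genes_per_module=50, n_background_genes=0,
                          module_grade_cor=(0.0,), n_nuisance_factors=0,
                          deg_lfc_range=(0.0, 0.0), deg_gene_scale=1.0)
        expr, _, truth = generate_cohort(cfg, seed=8)
        asg = network.ModuleAssignment(
            pd.Series("turquoise", index=expr.index))
        me = network.module_eigengenes(expr, asg)
        # eigengene should track the mean standardized profile (the factor)
        z = (expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True))
        z /= z.std(1, ddof=1, keepdims=True)
        proxy = z.mean(0)
        r = abs(np.corrcoef(me["turquoise"], proxy)[0, 1])
        assert r >= 0.95

    def test_negating_expression_negates_the_eigengene(self):
        rng = np.random.default_rng(3)
        expr = toy_expression(rng.standard_normal((6, 25)))
        asg = network.ModuleAssignment(pd.Series("blue", index=expr.index))
        me_pos = network.module_eigengenes(expr, asg)
        me_neg = network.module_eigengenes(-expr, asg)
        assert np.allclose(me_pos["blue"], -me_neg["blue"], atol=1e-10)

    def test_sign_convention_stable_under_sample_reordering(self):
        rng = np.random.default_rng(4)
        expr = toy_expression(rng.standard_normal((6, 25)))
        asg = network.ModuleAssignment(pd.Series("blue", index=expr.index))
        me = network.module_eigengenes(expr, asg)
        perm = rng.permutation(expr.columns)
        me_perm = network.module_eigengenes(expr[perm], asg)
        assert np.allclose(me_perm.loc[perm, "blue"].to_numpy(),
                           me.loc[perm, "blue"].to_numpy())


class TestTraitCorrelation:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(5)
        expr = toy_expression(rng.standard_normal((8, 40)))
        asg = network.ModuleAssignment(pd.Series("red", index=expr.index))
        me = network.module_eigengenes(expr, asg)
        traits = pd.DataFrame({"t": me["red"].to_numpy()}, index=me.index)
        out = network.module_trait_correlation(me, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-30

    def test_three_sample_p_matches_cauchy_closed_form(self):
        # with n = 3 and r = 0.5 the t transform has 1 df (Cauchy):
        # p = 2 * (1/2 - arctan(t)/pi), t = r / sqrt((1-r^2)/1)
        r = 0.5
        t = r * np.sqrt(1 / (1 - r ** 2))
        expected = 2 * (0.5 - np.arctan(t) / np.pi)
        from gliohub._stats import correlation_pvalues
        assert correlation_pvalues(np.array(r), 3) == pytest.approx(expected, rel=1e-12)

    def test_independent_trait_gives_uniform_pvalues(self):
        rng = np.random.default_rng(6)
        expr = toy_expression(rng.standard_normal((40, 300)))
        asg = network.ModuleAssignment(
            pd.Series(["turquoise"] * 20 + ["blue"] * 20, index=expr.index))
        me = network.module_eigengenes(expr, asg)
        ps = []
        for seed in range(60):
            t = np.random.default_rng(seed).standard_normal(300)
            traits = pd.DataFrame({"t": t}, index=me.index)
            ps.extend(network.module_trait_correlation(me, traits)["p"])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_trait_rejected(self):
        rng = np.random.default_rng(7)
        expr = toy_expression(rng.standard_normal((4, 20)))
        asg = network.ModuleAssignment(pd.Series("red", index=expr.index))
        me = network.module_eigengenes(expr, asg)
        traits = pd.DataFrame({"t": np.ones(20)}, index=me.index)
        with pytest.raises(DegenerateInputError):
            network.module_trait_correlation(me, traits)


class TestHubSelection:
    def make_scores(self, mm, gs, genes):
        idx = pd.Index(genes, name="gene")
        return {
            "mm": pd.DataFrame({"turquoise": mm}, index=idx),
            "mm_p": pd.DataFrame({"turquoise": np.zeros(len(genes))}, index=idx),
            "gs": pd.DataFrame({"gs": gs, "p": np.zeros(len(genes))}, index=idx),
        }

    def test_coincident_rankings_give_exact_fraction(self):
        genes = [f"g{i}" for i in range(10)]
        vals = np.linspace(0.1, 0.9, 10)
        scores = self.make_scores(vals, vals, genes)
        asg = network.ModuleAssignment(pd.Series("turquoise", index=scores["mm"].index))
        hubs = network.select_module_hubs(scores, asg, ["turquoise"], top_frac=0.2)
        assert hubs == {"g8", "g9"}

    def test_antialigned_rankings_give_empty_intersection(self):
        genes = [f"g{i}" for i in range(10)]
        vals = np.linspace(0.1, 0.9, 10)
        scores = self.make_scores(vals, vals[::-1], genes)
        asg = network.ModuleAssignment(pd.Series("turquoise", index=scores["mm"].index))
        hubs = network.select_module_hubs(scores, asg, ["turquoise"], top_frac=0.2)
        assert hubs == set()

    def test_missing_module_raises(self):
        genes = ["a", "b"]
        scores = self.make_scores([0.5, 0.6], [0.5, 0.6], genes)
        asg = network.ModuleAssignment(pd.Series("turquoise", index=scores["mm"].index))
        with pytest.raises(KeyError):
            network.select_module_hubs(scores, asg, ["magenta"])


class TestPickTraitModules:
    def test_trait_built_module_ranks_first_and_ties_break_stably(self):
        table = pd.DataFrame([
            {"module": "blue", "trait": "grade", "r": 0.9, "p": 1e-12},
            {"module": "red", "trait": "grade", "r": -0.5, "p": 1e-4},
            {"module": "tan", "trait": "grade", "r": 0.5, "p": 1e-5},
            {"module": "cyan", "trait": "grade", "r": 0.1, "p": 0.5},
            {"module": "grey", "trait": "grade", "r": 0.95, "p": 1e-20},
        ])
        out = network.pick_trait_modules(table, "grade", n_top=3)
        assert out == ["blue", "tan", "red"]  # |r| tie broken by smaller p

    def test_insignificant_modules_are_dropped(self):
        table = pd.DataFrame([
            {"module": "blue", "trait": "grade", "r": 0.2, "p": 0.3},
        ])
        assert network.pick_trait_modules(table, "grade", n_top=4) == []


class TestSubnetwork:
    def test_full_fractions_return_seed_neighbourhood(self):
        omega = block_tom([5], within=0.5)
        edges, conn = network.extract_subnetwork(omega, ["g0"], 1.0, 1.0)
        assert len(conn) == 5
        assert len(edges) == 10  # all pairs among 5 nodes

    def test_star_hub_has_maximal_connectivity(self):
        n = 6
        omega = np.full((n, n), 0.01)
        omega[0, 1:] = omega[1:, 0] = 0.9
        np.fill_diagonal(omega, 1.0)
        genes = [f"g{i}" for i in range(n)]
        tomdf = pd.DataFrame(omega, index=genes, columns=genes)
        edges, conn = network.extract_subnetwork(tomdf, ["g0"], 0.4, 1.0)
        assert conn.index[0] == "g0"

    def test_kept_edge_count_matches_threshold_rule(self, rng):
        n = 10
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        genes = [f"g{i}" for i in range(n)]
        tomdf = pd.DataFrame(w, index=genes, columns=genes)
        edges, _ = network.extract_subnetwork(tomdf, genes, 0.01, 1.0)
        assert len(edges) == int(np.ceil(0.01 * 45))


def test_planted_cohort_modules_recovered(default_cohort):
    expr, _, truth = default_cohort
    from sklearn.metrics import adjusted_rand_score
    scan = network.soft_threshold_scan(expr)
    power = int(scan.loc[scan["r2"].idxmax(), "power"])
    omega = network.tom(network.adjacency(network.similarity(expr), power))
    asg = network.detect_modules(omega, min_module_size=30, expr=expr)
    ari = adjusted_rand_score(truth.module_of.to_numpy(), asg.labels.to_numpy())
    assert len(asg.modules()) == 6
    assert ari >= 0.9


def test_planted_hubs_dominate_membership_in_their_module(default_cohort):
    expr, _, truth = default_cohort
    labels = truth.module_of.map(lambda m: m if m != "background" else "grey")
    asg = network.ModuleAssignment(labels)
    me = network.module_eigengenes(expr, asg)
    grade = pd.Series(
        np.repeat([0.0, 2, 3, 4], [20, 60, 60, 60]), index=expr.columns)
    scores = network.membership_and_significance(expr, me, grade)
    for m in truth.grade_linked_modules():
        members = asg.members(m)
        hub_members = [g for g in members if g in truth.hub_genes]
        mm = scores["mm"].loc[members, m].abs()
        own = scores["mm"].loc[hub_members].abs()
        # every hub's own-module membership beats its membership elsewhere
        others = [c for c in scores["mm"].columns if c != m]
        assert (own[m] >= own[others].max(axis=1)).all()
        # hubs occupy the top of the membership ranking
        top = set(mm.sort_values(ascending=False).index[:len(hub_members)])
        assert len(top & set(hub_members)) >= 0.8 * len(hub_members)
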