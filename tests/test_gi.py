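"""Interaction profiles, Theta, the singleton null, class summaries,
divergence bins, and partner clustering."""

import itertools

import numpy as np
import pytest

from duplofate import gi
from duplofate.catalog import DuplicatePair, PairCatalog

from conftest import make_edge_frame


class TestMatrixConstruction:
    def test_symmetrization_both_directions_significant(self):
        df = make_edge_frame([("a", "b", -0.2, 0.01),
                              ("b", "a", -0.4, 0.02)])
        m = gi.GIMatrix.from_edges(df)
        eps, p = m.edge("a", "b")
        assert eps == pytest.approx(-0.3)    # mean of the two directions
        assert p == pytest.approx(0.01)      # minimum p

    def test_symmetrization_one_direction_significant(self):
        df = make_edge_frame([("a", "b", -0.2, 0.01),
                              ("b", "a", 0.4, 0.60)])
        eps, p = gi.GIMatrix.from_edges(df).edge("a", "b")
        assert (eps, p) == (-0.2, 0.01)

    def test_replicates_collapse_to_min_p(self):
        df = make_edge_frame([("a", "b", -0.2, 0.04),
                              ("a", "b", -0.9, 0.30)])
        eps, p = gi.GIMatrix.from_edges(df).edge("a", "b")
        assert (eps, p) == (-0.2, 0.04)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gi.GIMatrix({("a", "b"): (0.1, 1.5)})


class TestSignificantProfile:
    def test_alpha_strict_and_signs(self, toy_matrix):
        prof = gi.significant_profile(toy_matrix, "a")
        assert prof.partners == {"b", "c", "d"}     # e at p=0.2 excluded
        assert gi.significant_profile(toy_matrix, "a", sign="pos").partners \
            == {"d"}
        assert gi.significant_profile(toy_matrix, "a", sign="neg").partners \
            == {"b", "c"}

    def test_p_exactly_alpha_excluded(self):
        m = gi.GIMatrix({("a", "b"): (-0.3, 0.05)}, universe={"a", "b"})
        assert gi.significant_profile(m, "a", alpha=0.05).partners == set()

    def test_unknown_gene_named_in_error(self, toy_matrix):
        with pytest.raises(KeyError, match="zzz"):
            gi.significant_profile(toy_matrix, "zzz")


class TestTheta:
    @pytest.mark.parametrize("set_a,set_b,expected", [
        ({"x", "y", "z"}, {"x", "y", "z"}, 1.0),
        ({"x", "y"}, {"z", "w"}, 0.0),
        ({"p1", "p2", "p3", "p4"}, {"p3", "p4", "p5", "p6", "p7", "p8"}, 0.4),
    ])
    def test_formula(self, set_a, set_b, expected):
        pa = gi.GIProfile("a", frozenset(set_a), {})
        pb = gi.GIProfile("b", frozenset(set_b), {})
        assert gi.theta_shared(pa, pb).theta == pytest.approx(expected)

    def test_empty_profiles_flagged_not_thrown(self):
        pa = gi.GIProfile("a", frozenset(), {})
        pb = gi.GIProfile("b", frozenset(), {})
        res = gi.theta_shared(pa, pb)
        assert res.theta is None and not res.defined

    def test_pair_edge_excluded_by_default(self, toy_matrix):
        pa = gi.significant_profile(toy_matrix, "a")
        pb = gi.significant_profile(toy_matrix, "b")
        res = gi.theta_shared(pa, pb)
        # a's partners {b,c,d} -> {c,d}; b's {a,c,d,f} -> {c,d,f}
        assert res.n_shared == 2
        assert res.theta == pytest.approx(4 / 5)
        kept = gi.theta_shared(pa, pb, exclude_pair_edge=False)
        assert kept.theta == pytest.approx(4 / 7)

    def test_symmetry_and_relabeling_invariance(self, rng):
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            sa = frozenset(rng.choice(universe, size=8, replace=False))
            sb = frozenset(rng.choice(universe, size=12, replace=False))
            pa = gi.GIProfile("a", sa, {})
            pb = gi.GIProfile("b", sb, {})
            t1 = gi.theta_shared(pa, pb).theta
            t2 = gi.theta_shared(pb, pa).theta
            assert t1 == t2
            # relabeling oracle: brute-force set intersection
            oracle = 2 * len(sa & sb) / (len(sa) + len(sb))
            assert t1 == pytest.approx(oracle)
            assert 2 * len(sa & sb) <= len(sa) + len(sb)

    def test_bound_attained_only_for_identical_sets(self):
        pa = gi.GIProfile("a", frozenset({"x"}), {})
        pb = gi.GIProfile("b", frozenset({"x", "y"}), {})
        assert gi.theta_shared(pa, pb).theta < 1.0


class TestRandomPairNull:
    def test_reproducibility(self, toy_matrix):
        singles = set("cdefgh")
        n1 = gi.random_pair_null(toy_matrix, singles, n_pairs=500, seed=3)
        n2 = gi.random_pair_null(toy_matrix, singles, n_pairs=500, seed=3)
        assert np.array_equal(n1.samples, n2.samples)
        n3 = gi.random_pair_null(toy_matrix, singles, n_pairs=500, seed=4)
        assert not np.array_equal(n1.samples, n3.samples)

    def test_empty_null(self, toy_matrix):
        null = gi.random_pair_null(toy_matrix, set("cdefgh"), n_pairs=0,
                                   seed=1)
        assert null.n_pairs == 0 and null.quantiles == {}

    def test_too_few_eligible_singletons(self, toy_matrix):
        with pytest.raises(ValueError, match="fewer than 2"):
            gi.random_pair_null(toy_matrix, {"g"}, n_pairs=10, seed=1)

    def test_samples_are_valid_thetas(self, toy_matrix):
        null = gi.random_pair_null(toy_matrix, set("cdefgh"), n_pairs=200,
                                   seed=7)
        assert ((null.samples >= 0) & (null.samples <= 1)).all()


class TestEmpiricalTest:
    def test_extremes(self):
        null = gi.NullDistribution(np.linspace(0, 0.5, 100), 100, 0)
        p_low, flag_low = gi.empirical_test(-1.0, null)
        assert p_low == pytest.approx(1.0) and not flag_low
        p_hi, flag_hi = gi.empirical_test(0.9, null)
        assert p_hi == pytest.approx(1 / 101) and flag_hi

    def test_exactly_at_95th_percentile_not_flagged(self):
        # hand-built 20-sample null: values 1..20, 95th pct by linear
        # interpolation = 19.05
        samples = np.arange(1.0, 21.0)
        null = gi.NullDistribution(samples, 20, 0)
        q95 = float(np.quantile(samples, 0.95))
        _, flag = gi.empirical_test(q95, null)
        assert not flag
        _, flag_above = gi.empirical_test(q95 + 1e-9, null)
        assert flag_above


class TestEpistasisSummary:
    def test_flat_recomputation_oracle(self, toy_matrix, toy_catalog):
        summaries = {s.gene_class: s
                     for s in gi.epistasis_summary(toy_matrix, toy_catalog)}
        # brute-force oracle: recompute from the raw edge dict
        alpha = 0.05
        classes = toy_catalog.gene_class()
        for cls in ("singleton", "SSD"):
            genes = [g for g, c in classes.items() if c == cls]
            eps_all, counts = [], []
            for g in genes:
                inc = [(eps, p) for (x, y), (eps, p)
                       in toy_matrix.edges.items()
                       if g in (x, y) and p < alpha]
                counts.append(len(inc))
                eps_all.extend(e for e, _ in inc)
            s = summaries[cls]
            assert s.mean_gi == pytest.approx(np.mean(counts))
            assert s.mean_eps == pytest.approx(np.mean(eps_all))
            pos = [e for e in eps_all if e > 0]
            neg = [e for e in eps_all if e < 0]
            assert s.n_pos == len(pos) and s.n_neg == len(neg)
            assert s.mean_eps_pos == pytest.approx(np.mean(pos))
            assert s.mean_eps_neg == pytest.approx(np.mean(neg))
            assert s.mean_eps_neg <= 0 <= s.mean_eps_pos

    def test_constructed_counts(self):
        # every SSD gene 4 significant edges, every WGD gene 2
        edges = {}
        for i, g in enumerate(("s1", "s2")):
            for k in range(4):
                edges[(g, f"x{i}{k}")] = (-0.1, 0.01)
        for i, g in enumerate(("w1", "w2")):
            for k in range(2):
                edges[(g, f"y{i}{k}")] = (-0.1, 0.01)
        universe = {g for e in edges for g in e}
        m = gi.GIMatrix(edges, universe=universe)
        catalog = PairCatalog(
            pairs=[DuplicatePair("s1", "s2", "SSD"),
                   DuplicatePair("w1", "w2", "WGD")],
            singletons=universe - {"s1", "s2", "w1", "w2"})
        by_cls = {s.gene_class: s for s in gi.epistasis_summary(m, catalog)}
        assert by_cls["SSD"].mean_gi == 4
        assert by_cls["WGD"].mean_gi == 2
        assert by_cls["SSD"].n_pos == 0
        assert by_cls["SSD"].mean_eps_neg == pytest.approx(-0.1)


class TestWithinPairEpistasis:
    def test_hand_computation(self):
        edges = {}
        pairs = []
        strengths = [-0.1, -0.2, -0.3]
        for i in range(10):
            a, b = f"w{i}a", f"w{i}b"
            pairs.append(DuplicatePair(a, b, "WGD"))
            if i < 3:
                edges[(a, b)] = (strengths[i], 0.001)
            edges[(a, f"z{i}")] = (-0.05, 0.01)   # keep genes in universe
            edges[(b, f"z{i}")] = (-0.05, 0.01)
        universe = {g for e in edges for g in e}
        m = gi.GIMatrix(edges, universe=universe)
        catalog = PairCatalog(pairs=pairs,
                              singletons=universe
                              - {g for p in pairs for g in p.genes})
        res = gi.within_pair_epistasis(m, catalog)["WGD"]
        assert res["fraction"] == pytest.approx(0.3)
        assert res["mean_epsilon"] == pytest.approx(-0.2)

    def test_unassayed_member_excluded(self, toy_matrix):
        catalog = PairCatalog(
            pairs=[DuplicatePair("a", "b", "SSD", 0.5),
                   DuplicatePair("q1", "q2", "SSD", 0.5)],
            singletons=set("cdefgh"))
        res = gi.within_pair_epistasis(toy_matrix, catalog)["SSD"]
        assert res["n_pairs"] == 1 and res["n_excluded"] == 1
        assert res["fraction"] == 1.0            # (a, b) edge at p=0.001


class TestDivergenceBins:
    @pytest.mark.parametrize("div,label", [
        (0.1, "<=0.4"), (0.4, "<=0.4"), (0.45, "(0.4,0.6]"),
        (0.6, "(0.4,0.6]"), (0.61, "(0.6,0.8]"), (1.7999, "(1.6,1.8]"),
        (1.8, ">=1.8"), (1.9, ">=1.8"), (0.0, "<=0.4"),
    ])
    def test_assignment(self, div, label):
        assert gi.BinSpec().assign(div) == label

    def test_every_pair_in_exactly_one_bin(self, rng):
        pairs = [DuplicatePair(f"p{i:03d}a", f"p{i:03d}b", "WGD",
                               float(d))
                 for i, d in enumerate(rng.gamma(2.0, 0.4, size=200))]
        bins = gi.bin_by_divergence(pairs)
        assert sum(len(v) for v in bins.values()) == len(pairs)
        # oracle: re-bin by explicit interval logic
        for label, members in bins.items():
            for p in members:
                assert gi.BinSpec().assign(p.divergence) == label

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            gi.BinSpec().assign(-0.1)


def brute_force_links(matrix, partners, alpha=0.05):
    """Independent oracle: count significant edges by pair enumeration."""
    return sum(1 for a, b in itertools.combinations(sorted(partners), 2)
               if matrix.edge(a, b) is not None
               and matrix.edge(a, b)[1] < alpha)


class TestClusteringKappa:
    def test_worked_example_five_partners_seven_links(self):
        partners = [f"p{i}" for i in range(5)]
        pairs = list(itertools.combinations(partners, 2))[:7]
        edges = {pair: (-0.1, 0.01) for pair in pairs}
        edges[("hub", "p0")] = (-0.2, 0.01)
        m = gi.GIMatrix(edges, universe=set(partners) | {"hub"})
        res = gi.clustering_kappa(m, set(partners))
        assert res.n_links == 7
        assert res.kappa == pytest.approx(0.7)

    def test_edgeless_and_complete(self):
        partners = {f"p{i}" for i in range(4)}
        empty = gi.GIMatrix({("a", "p0"): (-0.1, 0.01)},
                            universe=partners | {"a"})
        assert gi.clustering_kappa(empty, partners).kappa == 0.0
        full = gi.GIMatrix(
            {p: (-0.1, 0.01)
             for p in itertools.combinations(sorted(partners), 2)},
            universe=partners)
        assert gi.clustering_kappa(full, partners).kappa == 1.0

    def test_undefined_below_two_partners(self, toy_matrix):
        assert not gi.clustering_kappa(toy_matrix, {"c"}).defined
        with pytest.raises(ValueError):
            gi.kappa_value(1, 0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        genes = [f"g{i}" for i in range(12)]
        edges = {}
        for a, b in itertools.combinations(genes, 2):
            if rng.random() < 0.3:
                edges[(a, b)] = (-0.1, float(rng.uniform(0, 0.2)))
        m = gi.GIMatrix(edges, universe=set(genes))
        for _ in range(10):
            partners = set(rng.choice(genes, size=6, replace=False))
            res = gi.clustering_kappa(m, partners)
            links = brute_force_links(m, partners)
            assert res.n_links == links
            assert res.kappa == pytest.approx(2 * links / (6 * 5))

    def test_adding_internal_edge_never_decreases_kappa(self):
        partners = {f"p{i}" for i in range(5)}
        all_pairs = list(itertools.combinations(sorted(partners), 2))
        prev = -1.0
        for k in range(len(all_pairs) + 1):
            edges = {p: (-0.1, 0.01) for p in all_pairs[:k]}
            edges[("x", "p0")] = (-0.1, 0.01)
            m = gi.GIMatrix(edges, universe=partners | {"x"})
            kap = gi.clustering_kappa(m, partners).kappa
            assert kap >= prev
            prev = kap


class TestPairJointKappa:
    def test_identical_partner_sets_match_per_copy(self):
        partners = [f"p{i}" for i in range(4)]
        edges = {}
        for g in ("a", "b"):
            for p in partners:
                edges[(g, p)] = (-0.1, 0.01)
        edges[("p0", "p1")] = (-0.1, 0.01)
        edges[("p2", "p3")] = (-0.1, 0.01)
        m = gi.GIMatrix(edges, universe=set(partners) | {"a", "b"})
        pair = DuplicatePair("a", "b", "WGD")
        joint = gi.pair_joint_kappa(m, pair)
        per_a = gi.gene_kappa(m, "a")
        assert joint.kappa == pytest.approx(per_a.kappa)

    def test_disjoint_modules_dilute_joint_kappa(self):
        # two internally complete modules, no cross edges
        mod1 = [f"m1_{i}" for i in range(4)]
        mod2 = [f"m2_{i}" for i in range(4)]
        edges = {}
        for mod in (mod1, mod2):
            for x, y in itertools.combinations(mod, 2):
                edges[(x, y)] = (-0.1, 0.01)
        for p in mod1:
            edges[tuple(sorted(("a", p)))] = (-0.1, 0.01)
        for p in mod2:
            edges[tuple(sorted(("b", p)))] = (-0.1, 0.01)
        m = gi.GIMatrix(edges, universe=set(mod1 + mod2 + ["a", "b"]))
        pair = DuplicatePair("a", "b", "SSD")
        joint = gi.pair_joint_kappa(m, pair)
        per_a = gi.gene_kappa(m, "a")
        per_b = gi.gene_kappa(m, "b")
        # oracle edge count: 2 complete K4s = 12 links over 8 partners
        assert joint.n_links == 12
        assert joint.kappa < min(per_a.kappa, per_b.kappa)

    def test_union_of_one_flagged_undefined(self):
        edges = {("a", "x"): (-0.1, 0.01), ("b", "x"): (-0.1, 0.01)}
        m = gi.GIMatrix(edges, universe={"a", "b", "x"})
        res = gi.pair_joint_kappa(m, DuplicatePair("a", "b", "WGD"))
        assert not res.defined
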