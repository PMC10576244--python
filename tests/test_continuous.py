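import subprocess
import textwrap

import numpy as np
import pytest
import scipy.stats

from salparch.continuous import (
    ContinuousTipData,
    blomberg_k,
    bm_asr,
    bm_fit,
    classify_architecture_by_angle,
    signal_across_trees,
)
from salparch.synthetic_data import (
    scale_to_height,
    simulate_bm_angles,
    simulate_yule_tree,
)
from salparch.treeio import parse_newick, write_newick
from conftest import random_tree
from oracles import rerooted_gls_asr


def tipdata(pairs, se=0.0, n=3):
    return ContinuousTipData({k: (v, se, n) for k, v in pairs.items()})


class TestBmFit:
    def test_two_tip_equal_branches_midpoint_root(self):
        tree = parse_newick("(A:2,B:2);")
        fit = bm_fit(tree, tipdata({"A": 10.0, "B": 30.0}))
        assert fit.root_state == pytest.approx(20.0)

    def test_two_tip_unequal_branches_weighted_root(self):
        t1, t2 = 1.0, 3.0
        x1, x2 = 12.0, 40.0
        tree = parse_newick(f"(A:{t1},B:{t2});")
        fit = bm_fit(tree, tipdata({"A": x1, "B": x2}))
        expected = (x1 / t1 + x2 / t2) / (1 / t1 + 1 / t2)
        assert fit.root_state == pytest.approx(expected, abs=1e-10)

    def test_constant_data_gives_zero_rate(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        fit = bm_fit(tree, tipdata({t: 45.0 for t in "ABCD"}))
        assert fit.sigma2 == 0.0
        assert fit.root_state == pytest.approx(45.0)

    def test_rate_recovery_under_pure_bm(self):
        errs = []
        for i in range(30):
            tree = scale_to_height(simulate_yule_tree(150, 1.0, seed=200 + i))
            bm = simulate_bm_angles(tree, 400.0, 90.0, (3, 3), within_sd=0.0,
                                    seed=300 + i)
            errs.append(bm_fit(tree, bm.data).sigma2)
        assert np.median(errs) == pytest.approx(400.0, rel=0.15)

    def test_se_variant_discounts_measurement_noise(self):
        # white noise on short terminal branches inflates the naive BM rate
        # (the quadratic form picks up noise_var * tr(C^-1)/n); the SE model
        # attributes it to the tips instead, landing nearer the truth
        naive, with_se = [], []
        for i in range(15):
            tree = scale_to_height(simulate_yule_tree(100, 1.0, seed=400 + i))
            bm = simulate_bm_angles(tree, 50.0, 90.0, (4, 4), within_sd=10.0,
                                    seed=450 + i)
            naive.append(bm_fit(tree, bm.data).sigma2)
            with_se.append(bm_fit(tree, bm.data, use_se=True).sigma2)
        assert np.median(with_se) < np.median(naive)
        assert abs(np.median(with_se) - 50.0) < abs(np.median(naive) - 50.0)


class TestBmAsr:
    def test_two_tip_midpoint_with_symmetric_ci(self):
        tree = parse_newick("(A:2,B:2);")
        x = tipdata({"A": 10.0, "B": 30.0})
        asr = bm_asr(tree, x)
        r = tree.root
        assert asr.estimates[r] == pytest.approx(20.0)
        assert asr.ci_high[r] - asr.estimates[r] == pytest.approx(
            asr.estimates[r] - asr.ci_low[r], abs=1e-12
        )

    def test_constant_data_degenerate_cis(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        asr = bm_asr(tree, tipdata({t: 33.0 for t in "ABCD"}))
        for v in asr.estimates:
            assert asr.estimates[v] == pytest.approx(33.0)
            assert asr.ci_high[v] - asr.ci_low[v] == pytest.approx(0.0)

    def test_matches_rerooted_gls_oracle(self):
        """Gaussian conditioning equals rerooted GLS on random trees."""
        rng = np.random.default_rng(54)
        for case in range(300):
            tree = random_tree(rng, int(rng.integers(3, 9)))
            vals = {lab: float(rng.uniform(0, 90)) for lab in tree.tip_labels}
            x = tipdata(vals)
            fit = bm_fit(tree, x)
            if fit.sigma2 == 0:
                continue
            asr = bm_asr(tree, x, fit)
            oracle = rerooted_gls_asr(tree, vals, fit.sigma2)
            for v, (est, var) in oracle.items():
                assert asr.estimates[v] == pytest.approx(est, abs=1e-8)
                half = asr.ci_high[v] - asr.estimates[v]
                assert half == pytest.approx(1.96 * np.sqrt(var), abs=1e-8)

    def test_ci_width_shrinks_toward_short_terminal_branches(self):
        tree = parse_newick("((A:0.05,B:0.05):0.95,(C:0.5,D:0.5):0.5);")
        rng = np.random.default_rng(55)
        vals = {lab: float(rng.uniform(0, 90)) for lab in tree.tip_labels}
        asr = bm_asr(tree, tipdata(vals))
        shallow = tree.tip_by_label("A").parent
        deep = tree.tip_by_label("C").parent
        w_shallow = asr.ci_high[shallow] - asr.ci_low[shallow]
        w_deep = asr.ci_high[deep] - asr.ci_low[deep]
        assert w_shallow < w_deep


class TestBlombergK:
    def test_star_tree_K_exactly_one(self):
        tree = parse_newick("(A:2,B:2,C:2,D:2,E:2);")
        x = tipdata({"A": 5.0, "B": 60.0, "C": 22.0, "D": 80.0, "E": 41.0})
        sig = blomberg_k(tree, x, n_perm=9, seed=0)
        assert sig.K == pytest.approx(1.0, abs=1e-12)

    def test_mean_K_near_one_under_bm(self):
        ks = []
        for i in range(60):
            tree = simulate_yule_tree(60, 1.0, seed=500 + i)
            bm = simulate_bm_angles(tree, 100.0, 90.0, (3, 3), within_sd=0.0,
                                    seed=600 + i)
            ks.append(blomberg_k(tree, bm.data, n_perm=1, seed=i).K)
        assert 0.9 <= np.mean(ks) <= 1.1

    def test_destroyed_signal_lowers_K(self):
        rng = np.random.default_rng(56)
        low_k, high_p = 0, 0
        n_rep = 40
        for i in range(n_rep):
            tree = scale_to_height(simulate_yule_tree(50, 1.0, seed=700 + i))
            bm = simulate_bm_angles(tree, 200.0, 45.0, (3, 3), within_sd=0.0,
                                    seed=800 + i)
            labels = list(bm.data.data)
            vals = [bm.data.data[lab] for lab in labels]
            perm = rng.permutation(len(labels))
            shuffled = ContinuousTipData(
                {labels[i]: vals[perm[i]] for i in range(len(labels))}
            )
            sig = blomberg_k(tree, shuffled, n_perm=49, seed=i)
            low_k += sig.K < 1
            high_p += sig.p_value > 0.05
        assert low_k >= 0.9 * n_rep
        assert high_p >= 0.9 * n_rep

    def test_affine_invariance(self):
        rng = np.random.default_rng(57)
        tree = scale_to_height(simulate_yule_tree(20, 1.0, seed=58))
        vals = {lab: float(rng.uniform(10, 80)) for lab in tree.tip_labels}
        ses = {lab: float(rng.uniform(0.5, 3.0)) for lab in tree.tip_labels}
        x = ContinuousTipData({k: (vals[k], ses[k], 3) for k in vals})
        scaled = ContinuousTipData(
            {k: (1.8 * vals[k] + 7.0, 1.8 * ses[k], 3) for k in vals}
        )
        for use_se in (False, True):
            k1 = blomberg_k(tree, x, use_se=use_se, n_perm=1, seed=0).K
            k2 = blomberg_k(tree, scaled, use_se=use_se, n_perm=1, seed=0).K
            assert k2 == pytest.approx(k1, rel=1e-6)

    def test_permutation_p_uniform_under_null(self):
        """Over label-permuted BM data, p-values are uniform (KS, alpha=0.01)."""
        tree = scale_to_height(simulate_yule_tree(10, 1.0, seed=60))
        rng = np.random.default_rng(61)
        pvals = []
        for i in range(500):
            vals = rng.uniform(0, 90, size=10)
            x = ContinuousTipData(
                {lab: (float(v), 0.0, 3) for lab, v in zip(tree.tip_labels, vals)}
            )
            pvals.append(blomberg_k(tree, x, n_perm=99, seed=i).p_value)
        stat, p = scipy.stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_constant_trait_rejected(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(ZeroDivisionError):
            blomberg_k(tree, tipdata({t: 5.0 for t in "ABCD"}), n_perm=9)

    def test_too_few_tips_rejected(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            blomberg_k(tree, tipdata({"A": 1.0, "B": 2.0, "C": 3.0}), n_perm=9)


class TestSignalAcrossTrees:
    def test_single_tree_summary_collapses(self):
        tree = scale_to_height(simulate_yule_tree(12, 1.0, seed=62))
        bm = simulate_bm_angles(tree, 100.0, 45.0, seed=63)
        results, summary = signal_across_trees([tree], bm.data, n_perm=9, seed=0)
        assert len(results) == 1
        assert summary["min"] == summary["max"] == results[0].K

    def test_duplicate_trees_zero_spread(self):
        tree = scale_to_height(simulate_yule_tree(12, 1.0, seed=64))
        bm = simulate_bm_angles(tree, 100.0, 45.0, seed=65)
        _, summary = signal_across_trees([tree] * 10, bm.data, n_perm=9, seed=0)
        assert summary["max"] - summary["min"] == pytest.approx(0.0)

    def test_alternative_topologies_spread_but_positive(self):
        # same tip set, different trees: K varies yet stays positive
        bm_tree = scale_to_height(simulate_yule_tree(12, 1.0, seed=66))
        bm = simulate_bm_angles(bm_tree, 100.0, 45.0, seed=67)
        trees = [
            scale_to_height(simulate_yule_tree(12, 1.0, seed=900 + i))
            for i in range(20)
        ]
        results, summary = signal_across_trees(trees, bm.data, n_perm=1, seed=0)
        ks = [r.K for r in results]
        assert summary["max"] > summary["min"]
        assert all(k > 0 for k in ks)

    def test_order_invariance(self):
        trees = [
            scale_to_height(simulate_yule_tree(10, 1.0, seed=950 + i))
            for i in range(5)
        ]
        bm = simulate_bm_angles(trees[0], 100.0, 45.0, seed=68)
        _, s1 = signal_across_trees(trees, bm.data, n_perm=1, seed=0)
        _, s2 = signal_across_trees(trees[::-1], bm.data, n_perm=1, seed=0)
        for key in s1:
            assert s1[key] == pytest.approx(s2[key], abs=1e-12)

    def test_missing_tip_names_tree_index(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
        x = tipdata({t: float(i) for i, t in enumerate("ABCD")})
        with pytest.raises(ValueError, match="tree 1"):
            signal_across_trees([t1, t2], x, n_perm=9, seed=0)


class TestAngleClassifier:
    @pytest.mark.parametrize(
        "angle,label",
        [
            (90.0, "transversal-like"),
            (40.49, "oblique"),
            (0.0, "linear-like"),
            (39.99, "linear-like"),
            (80.0, "transversal-like"),
            (79.99, "oblique"),
        ],
    )
    def test_threshold_semantics(self, angle, label):
        assert classify_architecture_by_angle(angle) == label

    def test_configurable_thresholds(self):
        assert (
            classify_architecture_by_angle(50.0, linear_threshold=60.0)
            == "linear-like"
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_architecture_by_angle(180.0)
        with pytest.raises(ValueError):
            classify_architecture_by_angle(-1.0)


@pytest.fixture(scope="module")
def r_reference(tmp_path_factory):
    d = tmp_path_factory.mktemp("rref")
    tree = scale_to_height(simulate_yule_tree(8, 1.0, seed=70))
    rng = np.random.default_rng(71)
    vals = {lab: float(rng.uniform(5, 85)) for lab in tree.tip_labels}
    (d / "tree.nwk").write_text(write_newick(tree) + "\n")
    (d / "x.csv").write_text(
        "\n".join(f"{k},{v}" for k, v in sorted(vals.items())) + "\n"
    )
    script = textwrap.dedent("""
        suppressMessages({library(ape); library(phytools)})
        args <- commandArgs(trailingOnly=TRUE)
        tree <- read.tree(args[1])
        tab <- read.csv(args[2], header=FALSE)
        x <- setNames(tab$V2, tab$V1)[tree$tip.label]
        k <- phylosig(tree, x, method="K", test=FALSE)
        a <- ace(x, tree, method="ML", model="BM")
        cat(sprintf("%.12f %.12f %.12f\\n", as.numeric(k),
            a$ace[1], a$sigma2[1]))
    """)
    (d / "ref.R").write_text(script)
    out = subprocess.run(
        ["Rscript", str(d / "ref.R"), str(d / "tree.nwk"), str(d / "x.csv")],
        capture_output=True, text=True, check=True,
    )
    k_ref, root_ref, sigma2_ref = map(float, out.stdout.split())
    return tree, vals, k_ref, root_ref, sigma2_ref

class TestAgainstRImplementations:
    """Cross-checks against ape/phytools via Rscript on a small fixture."""

    def test_K_matches_phytools(self, r_reference):
        tree, vals, k_ref, _, _ = r_reference
        x = tipdata(vals)
        sig = blomberg_k(tree, x, n_perm=1, seed=0)
        assert sig.K == pytest.approx(k_ref, abs=1e-8)

    def test_root_estimate_and_rate_match_ape_ace(self, r_reference):
        tree, vals, _, root_ref, sigma2_ref = r_reference
        x = tipdata(vals)
        fit = bm_fit(tree, x)
        asr = bm_asr(tree, x, fit)
        # ape::ace fits by numerical optimization; match to its tolerance
        assert asr.estimates[tree.root] == pytest.approx(root_ref, abs=1e-3)
        # ace maximizes the joint likelihood over ancestral states and rate,
        # which scales the rate by n/(2n-2) relative to the marginal ML fit
        n = len(vals)
        assert fit.sigma2 * n / (2 * n - 2) == pytest.approx(sigma2_ref, rel=1e-3)
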