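"""Codon-model likelihood machinery: GY94, pruning, fits, per-branch dN."""

import itertools

import numpy as np
import pytest

import ifacevol as iv
from ifacevol._codes import get_code
from ifacevol.codonml import (
    CodonModelSpec,
    TreeLikelihood,
    branch_dn,
    f3x4_frequencies,
    fit_fixed_sites,
    fit_m0,
    fit_site_models_lrt,
    gy94_rate_matrix,
    transition_matrix,
    tree_loglik,
)
from ifacevol.codonsort import CodonAlignment


def _aln(rows, code=2):
    return CodonAlignment(
        taxa=[t for t, _ in rows],
        codons=np.array([[s[i : i + 3] for i in range(0, len(s), 3)] for _, s in rows]),
        code_table=code,
    )


class TestF3x4:
    def test_degenerate_single_codon(self):
        aln = _aln([("a", "AAAAAA"), ("b", "AAAAAA")], code=1)
        pi = f3x4_frequencies(aln)
        code = get_code(1)
        assert pi[code.sense_codons.index("AAA")] == pytest.approx(1.0)
        assert pi.sum() == pytest.approx(1.0)

    def test_uniform_nucleotides_universal(self):
        # all four nucleotides equally used at every position -> uniform 1/61
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
        seq = "".join(codons)
        aln = _aln([("a", seq), ("b", seq)], code=1)
        pi = f3x4_frequencies(aln)
        np.testing.assert_allclose(pi, np.full(61, 1 / 61), atol=1e-12)

    def test_matches_hand_count(self):
        aln = _aln([("a", "ATGGCA"), ("b", "ATGGCC")], code=1)
        pi = f3x4_frequencies(aln)
        code = get_code(1)
        # position freqs: p1 = {A: 1/2, G: 1/2}; p2 = {T: 1/2, C: 1/2};
        # p3 = {G: 1/2, A: 1/4, C: 1/4}
        raw_atg = 0.5 * 0.5 * 0.5
        raw_gcc = 0.5 * 0.5 * 0.25
        ratio = pi[code.sense_codons.index("ATG")] / pi[code.sense_codons.index("GCC")]
        assert ratio == pytest.approx(raw_atg / raw_gcc)

    def test_unobserved_position_is_error(self):
        aln = _aln([("a", "---")], code=1)
        with pytest.raises(ValueError, match="no observed"):
            f3x4_frequencies(aln)


class TestRateMatrix:
    @pytest.mark.parametrize("omega", [0.0, 0.3, 1.0, 4.0])
    def test_rows_sum_to_zero_and_unit_scale(self, omega):
        spec = CodonModelSpec(code_table=2, kappa=3.0)
        Q = gy94_rate_matrix(spec, omega)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -(spec.pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(60))
        spec = CodonModelSpec(code_table=2, pi=pi, kappa=2.5)
        Q = gy94_rate_matrix(spec, 0.4)
        flux = spec.pi[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        from ifacevol._codes import single_change_pairs

        spec = CodonModelSpec(code_table=2, kappa=2.0)
        Q = gy94_rate_matrix(spec, 0.0)
        ii, jj, ts, ns = single_change_pairs(2)
        assert np.all(Q[ii[ns], jj[ns]] == 0.0)
        assert np.all(Q[ii[~ns], jj[~ns]] > 0.0)

    def test_multi_nucleotide_changes_forbidden(self):
        code = get_code(2)
        spec = CodonModelSpec(code_table=2)
        Q = gy94_rate_matrix(spec, 0.5)
        for i, c1 in enumerate(code.sense_codons[:10]):
            for j, c2 in enumerate(code.sense_codons):
                ndiff = sum(a != b for a, b in zip(c1, c2))
                if ndiff > 1:
                    assert Q[i, j] == 0.0

    def test_invalid_parameters_rejected(self):
        spec = CodonModelSpec(code_table=2)
        with pytest.raises(ValueError):
            gy94_rate_matrix(spec, -0.1)
        bad = CodonModelSpec(code_table=2)
        bad.kappa = 0.0
        with pytest.raises(ValueError):
            gy94_rate_matrix(bad, 0.5)

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_transition_probabilities_conserved(self, t):
        spec = CodonModelSpec(code_table=2, kappa=2.0)
        P = transition_matrix(spec, 0.5, t)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (P >= 0).all()


class TestPruning:
    def _enumerate_lnl(self, tree, aln, tl, kappa, omega):
        """Brute-force sum over all ancestral state combinations."""
        S = tl.code.n_states
        mats = tl._branch_matrices(tree.branch_lengths(), kappa, omega)
        states = aln.sense_states()
        order = tree.tip_index()
        st = np.zeros((tree.n_tips, aln.n_columns), dtype=int)
        for t, name in enumerate(aln.taxa):
            st[order[name]] = states[t]
        internals = [
            n for n in range(tree.n_tips, tree.n_nodes) if n != tree.root
        ]
        total = 0.0
        for col in range(aln.n_columns):
            lik = 0.0
            for rs in range(S):
                for assign in itertools.product(range(S), repeat=len(internals)):
                    ns = {tree.root: rs}
                    ns.update(dict(zip(internals, assign)))
                    ns.update({t: st[t, col] for t in range(tree.n_tips)})
                    p = tl.pi[rs]
                    for b in tree.branch_ids():
                        p *= mats[b][ns[tree.parent[b]], ns[b]]
                    lik += p
            total += np.log(lik)
        return total

    @pytest.mark.parametrize("n_tips,kappa,omega", [(3, 2.0, 0.2), (4, 3.0, 0.8)])
    def test_matches_exhaustive_enumeration(self, n_tips, kappa, omega):
        code = get_code(2)
        tree = iv.simulate_tree(n_tips, 0.3, seed=n_tips)
        aln, _ = iv.simulate_codon_alignment(
            tree, {"a": omega}, kappa=kappa, columns_per_partition={"a": 2},
            seed=n_tips + 10,
        )
        pi = np.full(code.n_states, 1 / code.n_states)
        tl = TreeLikelihood(tree, aln, 2, pi=pi)
        lnl = tl.loglik(tree.branch_lengths(), kappa, omega)
        assert lnl == pytest.approx(self._enumerate_lnl(tree, aln, tl, kappa, omega), abs=1e-8)

    def test_zero_branch_limit_is_log_pi(self):
        code = get_code(2)
        aln = _aln([("t1", "ATG"), ("t2", "ATG"), ("t3", "ATG")])
        tree = iv.simulate_tree(3, 0.1, seed=1).with_lengths([1e-12] * 3)
        pi = np.full(code.n_states, 1 / code.n_states)
        tl = TreeLikelihood(tree, aln, 2, pi=pi)
        lnl = tl.loglik(tree.branch_lengths(), 2.0, 0.5)
        assert lnl == pytest.approx(np.log(pi[code.sense_index["ATG"]]), abs=1e-5)

    def test_invariant_to_rerooting(self):
        import dendropy

        tree = iv.simulate_tree(5, 0.25, seed=8)
        aln, _ = iv.simulate_codon_alignment(
            tree, {"a": 0.5}, kappa=2.0, columns_per_partition={"a": 20}, seed=9
        )
        spec = CodonModelSpec(code_table=2, kappa=2.0, omega=0.5)
        base = tree_loglik(tree, aln, spec)
        newick = tree.to_newick()
        for rot in range(3):
            dt = dendropy.Tree.get(data=newick, schema="newick")
            node = dt.internal_nodes()[rot % len(dt.internal_nodes())]
            if node is dt.seed_node:
                continue
            dt.reroot_at_node(node, update_bipartitions=False)
            rerooted = iv.PhyloTree.from_dendropy(dt)
            assert tree_loglik(rerooted, aln, spec) == pytest.approx(base, abs=1e-6)

    def test_stop_codon_in_data_is_error(self):
        aln = _aln([("t1", "AGA"), ("t2", "ATG"), ("t3", "ATG")])  # AGA: mito stop
        tree = iv.simulate_tree(3, 0.1, seed=1)
        with pytest.raises(ValueError, match="stop codon"):
            TreeLikelihood(tree, aln, 2)

    def test_taxon_mismatch_is_error(self):
        aln = _aln([("x1", "ATG"), ("x2", "ATG"), ("x3", "ATG")])
        tree = iv.simulate_tree(3, 0.1, seed=1)  # taxa t1..t3
        with pytest.raises(ValueError, match="mismatch"):
            TreeLikelihood(tree, aln, 2)

    def test_gapped_codons_treated_as_ambiguous(self):
        rows = [("t1", "ATG---"), ("t2", "ATGGCA"), ("t3", "ATGGCC")]
        tree = iv.simulate_tree(3, 0.2, seed=2)
        tl = TreeLikelihood(tree, _aln(rows), 2)
        lnl = tl.loglik(tree.branch_lengths(), 2.0, 0.5)
        assert np.isfinite(lnl)
        # ambiguous column contributes at most the fully-unknown likelihood 1
        tl1 = TreeLikelihood(tree, _aln([(t, s[:3]) for t, s in rows]), 2)
        assert lnl <= tl1.loglik(tree.branch_lengths(), 2.0, 0.5) + 1e-9


class TestFits:
    def test_m0_recovers_simulation_parameters(self):
        # ω = 0.2, κ = 4 truth; mean over a few replicates inside [0.15, 0.25]
        omegas, kappas = [], []
        for rep in range(5):
            tree = iv.simulate_tree(4, 0.2, seed=30 + rep)
            aln, _ = iv.simulate_codon_alignment(
                tree, {"a": 0.2}, kappa=4.0, columns_per_partition={"a": 500},
                seed=60 + rep,
            )
            fit = fit_m0(tree, aln)
            omegas.append(fit.params["omega"])
            kappas.append(fit.params["kappa"])
        assert 0.15 < np.mean(omegas) < 0.25
        assert 2.5 < np.mean(kappas) < 6.0

    def test_m0_identical_sequences_collapse_branches(self):
        aln = _aln([(f"t{i+1}", "ATGGCAACAGTT" * 5) for i in range(4)])
        tree = iv.simulate_tree(4, 0.2, seed=3)
        fit = fit_m0(tree, aln)
        assert np.all(fit.params["branch_lengths"] < 1e-4)

    def test_m0_refit_from_perturbed_start_consistent(self):
        tree = iv.simulate_tree(4, 0.2, seed=40)
        aln, _ = iv.simulate_codon_alignment(
            tree, {"a": 0.3}, kappa=2.0, columns_per_partition={"a": 200}, seed=41
        )
        a = fit_m0(tree, aln, init_kappa=2.0, init_omega=0.4)
        b = fit_m0(tree, aln, init_kappa=8.0, init_omega=0.05)
        assert a.lnl == pytest.approx(b.lnl, abs=1e-3)

    def test_fixed_sites_identical_partitions_equal_omega(self):
        tree = iv.simulate_tree(5, 0.2, seed=50)
        aln, _ = iv.simulate_codon_alignment(
            tree, {"a": 0.3}, kappa=2.0, columns_per_partition={"a": 150}, seed=51
        )
        cols = list(range(150))
        fit = fit_fixed_sites(tree, aln, {"p": cols, "q": cols}, with_se=False)
        om = fit.params["omega"]
        assert om["p"] == pytest.approx(om["q"], abs=1e-3)

    def test_fixed_sites_empty_partition_skipped(self):
        tree = iv.simulate_tree(5, 0.2, seed=50)
        aln, _ = iv.simulate_codon_alignment(
            tree, {"a": 0.3}, kappa=2.0, columns_per_partition={"a": 60}, seed=52
        )
        fit = fit_fixed_sites(
            tree, aln, {"p": list(range(60)), "empty": []}, with_se=False
        )
        assert fit.params["skipped_partitions"] == ["empty"]
        with pytest.raises(ValueError, match="empty"):
            fit_fixed_sites(tree, aln, {"p": [], "q": []})

    def test_lrt_detects_planted_positive_selection(self):
        # 10% of sites at ω = 5 on a deep 12-taxon tree
        rejections = 0
        for rep in range(6):
            tree = iv.simulate_tree(12, 0.5, seed=540 + rep)
            aln, _ = iv.simulate_codon_alignment(
                tree,
                {"cons": 0.2, "neut": 1.0, "pos": 5.0},
                kappa=2.0,
                columns_per_partition={"cons": 240, "neut": 120, "pos": 40},
                seed=640 + rep,
            )
            res = fit_site_models_lrt(tree, aln)
            assert res["lnL_M2a"] >= res["lnL_M1a"] - 1e-6
            rejections += res["p"] < 0.05
        assert rejections >= 5

    def test_lrt_statistic_invariant_to_taxon_order(self):
        tree = iv.simulate_tree(5, 0.3, seed=70)
        aln, _ = iv.simulate_codon_alignment(
            tree, {"a": 0.4}, kappa=2.0, columns_per_partition={"a": 80}, seed=71
        )
        res1 = fit_site_models_lrt(tree, aln)
        perm = [3, 1, 4, 0, 2]
        shuffled = CodonAlignment(
            taxa=[aln.taxa[i] for i in perm],
            codons=aln.codons[perm],
            code_table=aln.code_table,
        )
        res2 = fit_site_models_lrt(tree, shuffled)
        assert res1["stat"] == pytest.approx(res2["stat"], abs=1e-3)


class TestBranchDN:
    def test_identical_partitions_zero_difference(self):
        tree = iv.simulate_tree(5, 0.2, seed=80)
        aln, _ = iv.simulate_codon_alignment(
            tree, {"a": 0.3}, kappa=2.0, columns_per_partition={"a": 100}, seed=81
        )
        cols = list(range(100))
        bd = branch_dn(
            tree, aln, {"x": cols, "y": cols}, {"x": 0.3, "y": 0.3}, 2.0,
            diff=("x", "y"),
        )
        np.testing.assert_allclose(bd.difference, 0.0, atol=1e-12)

    def test_contrasting_partitions_bias_positive(self):
        tree = iv.simulate_tree(8, 0.2, seed=82)
        aln, truth = iv.simulate_codon_alignment(
            tree, {"fast": 0.5, "slow": 0.05}, kappa=3.0,
            columns_per_partition={"fast": 250, "slow": 250}, seed=83,
        )
        fit = fit_fixed_sites(tree, aln, truth.partition_columns, with_se=False)
        bd = branch_dn(
            tree, aln, truth.partition_columns, fit.params["omega"],
            fit.params["kappa"], diff=("fast", "slow"),
        )
        assert bd.difference.mean() > 0
        assert (bd.difference > 0).mean() >= 0.8

    def test_branch_count_matches_unrooted_formula(self):
        tree = iv.simulate_tree(371, 0.1, seed=84)
        aln, _ = iv.simulate_codon_alignment(
            iv.simulate_tree(5, 0.2, seed=85), {"a": 0.3}, kappa=2.0,
            columns_per_partition={"a": 10}, seed=86,
        )
        assert tree.n_branches == 739
        small = iv.simulate_tree(5, 0.2, seed=85)
        bd = branch_dn(small, aln, {"a": list(range(10))}, {"a": 0.3}, 2.0)
        assert len(bd.branch_ids) == 2 * 5 - 3
        assert np.all(bd.dn["a"] >= 0)

    def test_expected_counts_scale_with_branch_length(self):
        # doubling every branch roughly doubles expected substitutions
        tree = iv.simulate_tree(5, 0.1, seed=87)
        aln, _ = iv.simulate_codon_alignment(
            tree, {"a": 0.5}, kappa=2.0, columns_per_partition={"a": 200}, seed=88
        )
        tl = TreeLikelihood(tree, aln, 2)
        c1 = tl.expected_nonsyn_counts(tree.branch_lengths(), 2.0, 0.5)
        total1 = sum(c1.values())
        assert total1 > 0
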