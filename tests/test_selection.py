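import itertools

import numpy as np
import pytest

from slocus_kit.codons import N_SENSE, SENSE_CODONS, translate
from slocus_kit.selection import (
    CodonAlignment,
    CodonModelSpec,
    LabeledTree,
    branchsite_class_proportions,
    codon_rate_matrix,
    fit_model,
    lrt,
    simulate_codon_alignment,
    tree_loglikelihood,
)
from slocus_kit.selection import _site_class_omegas, _TransitionCache

EQUAL_PI = np.full(N_SENSE, 1.0 / N_SENSE)


def brute_force_loglik(aln, tree, spec, params, pi):
    """Exhaustive enumeration of all internal-node codon states."""
    codes = aln.codon_codes()
    classes = _site_class_omegas(spec, params)
    taxr = {t: i for i, t in enumerate(aln.taxa)}
    internals = [n for n in tree.nodes if n.taxon is None]
    ll = 0.0
    for site in range(codes.shape[1]):
        site_l = 0.0
        for prop, wbg, wfg in classes:
            Ps = {}
            for n in tree.nodes[:-1]:
                w = wfg if n.foreground else wbg
                Ps[n.index] = _TransitionCache(params["kappa"], w, pi).P(n.length)
            tot = 0.0
            for assign in itertools.product(range(N_SENSE), repeat=len(internals)):
                st = {n.index: s for n, s in zip(internals, assign)}
                for n in tree.nodes:
                    if n.taxon is not None:
                        st[n.index] = codes[taxr[n.taxon], site]
                p = pi[st[tree.nodes[-1].index]]
                for n in tree.nodes[:-1]:
                    p *= Ps[n.index][st[n.parent], st[n.index]]
                tot += p
            site_l += prop * tot
        ll += np.log(site_l)
    return ll


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        Q = codon_rate_matrix(2.0, 0.5, EQUAL_PI)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_neutral_equal_rates(self):
        Q = codon_rate_matrix(1.0, 1.0, EQUAL_PI)
        off = Q[~np.eye(N_SENSE, dtype=bool)]
        nonzero = off[off > 0]
        assert np.allclose(nonzero, nonzero[0])

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pi = rng.dirichlet(np.ones(N_SENSE))
            Q = codon_rate_matrix(rng.uniform(0.5, 5), rng.uniform(0.05, 3), pi)
            flux = pi[:, None] * Q
            assert np.allclose(flux, flux.T, atol=1e-12)

    def test_unit_expected_rate(self):
        pi = np.random.default_rng(1).dirichlet(np.ones(N_SENSE))
        Q = codon_rate_matrix(3.0, 0.2, pi)
        assert np.isclose(-np.dot(pi, np.diag(Q)), 1.0)

    def test_bad_freqs_error(self):
        with pytest.raises(ValueError):
            codon_rate_matrix(2.0, 0.5, np.ones(N_SENSE))


class TestBranchSiteMixture:
    @pytest.mark.parametrize("p0,p1", [(0.5, 0.3), (0.7, 0.1), (0.05, 0.9)])
    def test_proportions_sum_to_one(self, p0, p1):
        props = branchsite_class_proportions(p0, p1)
        assert props.shape == (4,) and np.isclose(props.sum(), 1.0)
        assert (props >= 0).all()

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            branchsite_class_proportions(0.8, 0.4)


class TestLikelihood:
    def test_zero_branch_identical_codon(self):
        tree = LabeledTree.from_newick("(A:0,B:0);")
        aln = CodonAlignment(["A", "B"], ["ATG", "ATG"])
        ll = tree_loglikelihood(
            aln, tree, CodonModelSpec("M0", "equal"), {"kappa": 2, "omega": 1}, EQUAL_PI
        )
        assert ll == pytest.approx(np.log(1 / 61), abs=1e-9)

    def test_zero_branch_differing_codons_error(self):
        tree = LabeledTree.from_newick("(A:0,B:0);")
        aln = CodonAlignment(["A", "B"], ["ATG", "TTG"])
        with pytest.raises(FloatingPointError):
            tree_loglikelihood(
                aln, tree, CodonModelSpec("M0", "equal"), {"kappa": 2, "omega": 1}, EQUAL_PI
            )

    @pytest.mark.parametrize("model", ["M0", "branch_2ratio", "branchsite_A_alt"])
    def test_matches_enumeration_oracle(self, model):
        rng = np.random.default_rng(42)
        tree = LabeledTree.from_newick("((A:0.2,B:0.3):0.1,C:0.25,D#1:0.4);")
        spec = CodonModelSpec(model, "equal")
        for trial in range(3):
            params = {"kappa": float(rng.uniform(1, 4))}
            if model == "M0":
                params["omega"] = float(rng.uniform(0.1, 2))
            elif model == "branch_2ratio":
                params["omega_bg"] = float(rng.uniform(0.05, 1))
                params["omega_fg"] = float(rng.uniform(0.5, 3))
            else:
                params.update(omega0=0.2, omega2=3.0, p0=0.5, p1=0.3)
            aln = simulate_codon_alignment(tree, spec, params, 2, seed=trial)
            ll = tree_loglikelihood(aln, tree, spec, params, EQUAL_PI)
            oracle = brute_force_loglik(aln, tree, spec, params, EQUAL_PI)
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_root_placement_invariance(self):
        """Pulley principle: reversible M0 likelihood ignores rooting."""
        params = {"kappa": 2.0, "omega": 0.4}
        spec = CodonModelSpec("M0", "equal")
        t1 = LabeledTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        t2 = LabeledTree.from_newick("(A:0.1,B:0.2,C:0.35);")
        aln = simulate_codon_alignment(t1, spec, params, 30, seed=3)
        l1 = tree_loglikelihood(aln, t1, spec, params, EQUAL_PI)
        l2 = tree_loglikelihood(aln, t2, spec, params, EQUAL_PI)
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_m0_special_case_of_branch_model(self):
        tree = LabeledTree.from_newick("((A:0.1,B:0.2):0.05,C#1:0.3);")
        spec0 = CodonModelSpec("M0", "equal")
        aln = simulate_codon_alignment(tree, spec0, {"kappa": 2, "omega": 0.4}, 20, seed=4)
        l0 = tree_loglikelihood(aln, tree, spec0, {"kappa": 2, "omega": 0.4}, EQUAL_PI)
        lb = tree_loglikelihood(
            aln,
            tree,
            CodonModelSpec("branch_2ratio", "equal"),
            {"kappa": 2, "omega_bg": 0.4, "omega_fg": 0.4},
            EQUAL_PI,
        )
        assert l0 == pytest.approx(lb, abs=1e-10)

    def test_foreground_required(self):
        tree = LabeledTree.from_newick("(A:0.1,B:0.2);")
        aln = CodonAlignment(["A", "B"], ["ATG", "ATG"])
        with pytest.raises(ValueError, match="foreground"):
            tree_loglikelihood(
                aln,
                tree,
                CodonModelSpec("branch_2ratio"),
                {"kappa": 2, "omega_bg": 0.2, "omega_fg": 1.0},
            )


class TestSimulation:
    def test_zero_branches_identical_taxa(self):
        tree = LabeledTree.from_newick("((A:0,B:0):0,C:0);")
        aln = simulate_codon_alignment(
            tree, CodonModelSpec("M0", "equal"), {"kappa": 2, "omega": 1}, 50, seed=0
        )
        assert len(set(aln.seqs)) == 1

    def test_omega_zero_only_synonymous_changes(self):
        tree = LabeledTree.from_newick("(A:3.0,B:3.0);")
        aln = simulate_codon_alignment(
            tree, CodonModelSpec("M0", "equal"), {"kappa": 2, "omega": 1e-9}, 120, seed=1
        )
        assert aln.seqs[0] != aln.seqs[1]  # long branches: some change
        assert translate(aln.seqs[0]) == translate(aln.seqs[1])

    def test_no_stop_codons(self):
        tree = LabeledTree.from_newick("((A:0.5,B:0.5):0.2,(C:0.4,D#1:0.6):0.2);")
        aln = simulate_codon_alignment(
            tree,
            CodonModelSpec("branchsite_A_alt", "equal"),
            {"kappa": 2, "omega0": 0.1, "omega2": 4.0, "p0": 0.4, "p1": 0.4},
            200,
            seed=2,
        )
        for s in aln.seqs:
            for i in range(0, len(s), 3):
                assert s[i : i + 3] not in ("TAA", "TAG", "TGA")

    def test_determinism_and_seed_sensitivity(self):
        tree = LabeledTree.from_newick("(A:0.3,B:0.3);")
        spec = CodonModelSpec("M0", "equal")
        p = {"kappa": 2, "omega": 0.5}
        a1 = simulate_codon_alignment(tree, spec, p, 50, seed=7)
        a2 = simulate_codon_alignment(tree, spec, p, 50, seed=7)
        a3 = simulate_codon_alignment(tree, spec, p, 50, seed=8)
        assert a1.seqs == a2.seqs and a1.seqs != a3.seqs


class TestFitAndLrt:
    def test_alt_loglik_at_least_null(self):
        tree = LabeledTree.from_newick("((A:0.2,B:0.2):0.1,(C:0.2,D#1:0.3):0.1);")
        aln = simulate_codon_alignment(
            tree, CodonModelSpec("M0", "equal"), {"kappa": 2, "omega": 0.3}, 100, seed=5
        )
        f0 = fit_model(aln, tree, CodonModelSpec("M0", "equal"), n_starts=1)
        f1 = fit_model(aln, tree, CodonModelSpec("branch_2ratio", "equal"), n_starts=1)
        assert f1.loglik >= f0.loglik - 1e-6

    def test_lrt_boundary(self):
        res = lrt(-100.0, -100.0 + 3.841 / 2, df=1)
        assert res.p_value == pytest.approx(0.05, abs=0.001)

    def test_lrt_equal_logliks(self):
        res = lrt(-50.0, -50.0, df=1)
        assert res.two_delta_l == 0 and res.p_value == 1.0 and not res.reject_at_5pct

    def test_lrt_negative_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = lrt(-50.0, -50.1, df=1)
        assert res.two_delta_l == 0.0

    def test_lrt_df_error(self):
        with pytest.raises(ValueError):
            lrt(-1.0, 0.0, df=0)


class TestAlignmentContainer:
    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="codon"):
            CodonAlignment(["A", "B"], ["TAAATG", "ATGATG"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            CodonAlignment(["A", "B"], ["ATG", "ATGATG"])

    def test_f3x4(self):
        aln = CodonAlignment(["A", "B"], ["ATGAAA", "ATGAAG"])
        pi = aln.f3x4_frequencies()
        assert pi.shape == (N_SENSE,) and np.isclose(pi.sum(), 1.0)
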