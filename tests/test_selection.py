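import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, spearmanr

from famevol.genetic_code import CODONS
from famevol.reconcile import Subgroup
from famevol.selection import (BranchModel, OneRatioModel, SiteMixtureModel,
                               SwitchingModel, compare_subgroup_means,
                               label_branches_by_partition, lrt, ml_pairwise,
                               ng86_pairwise, partition_positive_sites,
                               subgroup_pairwise_omega)
from famevol.selection.codon_matrix import (build_rate_matrix, f3x4_frequencies,
                                            stationary_check)
from famevol.selection.models import CodonModelResults
from famevol.simulate import (SimulationConfig, simulate_codon_alignment,
                              switching_generator)
from famevol.species import PARTITION
from famevol.tree import parse_newick

from _oracles import ng86_oracle

RNG = np.random.default_rng


def _random_pair(rng, n_codons, diverge=0.3):
    tree = parse_newick(f"(X:{diverge / 2},Y:{diverge / 2});")
    cfg = SimulationConfig(n_codons=n_codons, omega=0.4, seed=0)
    truth = simulate_codon_alignment(tree, cfg, rng=rng)
    return truth.sequences["X"], truth.sequences["Y"]


class TestNG86:
    def test_identical_sequences_flagged_undefined(self):
        seq = "ATGAAAGTT" * 5
        pw = ng86_pairwise(seq, seq)
        assert pw.dn == 0.0 and pw.ds == 0.0
        assert pw.undefined and np.isnan(pw.omega)

    def test_synonymous_only_change_has_zero_dn(self):
        pw = ng86_pairwise("TTT", "TTC")  # Phe -> Phe
        assert pw.dn == 0.0

    def test_matches_path_enumeration_oracle(self):
        rng = RNG(20)
        for _ in range(10):
            a, b = _random_pair(rng, 20, diverge=0.6)
            pw = ng86_pairwise(a, b)
            dn_o, ds_o = ng86_oracle(a, b)
            if np.isinf(ds_o) or np.isinf(pw.ds):
                assert pw.saturated
                continue
            assert pw.dn == pytest.approx(dn_o, abs=1e-10)
            assert pw.ds == pytest.approx(ds_o, abs=1e-10)

    def test_gap_codons_pairwise_deleted(self):
        pw_full = ng86_pairwise("TTTATG", "TTCATG")
        pw_gap = ng86_pairwise("TTT---ATG", "TTCAAAATG")
        assert pw_full.ds == pytest.approx(pw_gap.ds)


class TestMLPairwise:
    def test_parameter_recovery(self):
        rng = RNG(21)
        tree = parse_newick("(X:0.25,Y:0.25);")
        cfg = SimulationConfig(omega=0.2, kappa=2.0, n_codons=20_000, seed=0)
        truth = simulate_codon_alignment(tree, cfg, rng=rng)
        pw = ml_pairwise(truth.sequences["X"], truth.sequences["Y"])
        assert abs(pw.omega - 0.2) < 0.03
        assert abs(pw.t - 0.5) < 0.05

    def test_identical_sequences_multinomial_limit(self):
        seq = "ATGAAAGTTCCC" * 10
        pw = ml_pairwise(seq, seq, codon_freq="uniform")
        assert pw.t == 0.0
        assert pw.lnl == pytest.approx(40 * np.log(1 / 61), rel=1e-12)

    def test_concordance_with_ng86_at_low_divergence(self):
        rng = RNG(22)
        for _ in range(5):
            a, b = _random_pair(rng, 3000, diverge=0.25)
            ml = ml_pairwise(a, b)
            ng = ng86_pairwise(a, b)
            assert abs(ml.omega - ng.omega) / ng.omega < 0.25

    def test_rank_agreement_across_omega_range(self):
        rng = RNG(23)
        ml_vals, ng_vals = [], []
        for _ in range(40):
            omega = float(rng.uniform(0.05, 1.5))
            t = float(rng.uniform(0.1, 1.0))
            tree = parse_newick(f"(X:{t / 2},Y:{t / 2});")
            cfg = SimulationConfig(omega=omega, kappa=2.0, n_codons=800, seed=0)
            truth = simulate_codon_alignment(tree, cfg, rng=rng)
            ml = ml_pairwise(truth.sequences["X"], truth.sequences["Y"])
            ng = ng86_pairwise(truth.sequences["X"], truth.sequences["Y"])
            if not (ml.undefined or ng.undefined):
                ml_vals.append(ml.omega)
                ng_vals.append(ng.omega)
        rho, _ = spearmanr(ml_vals, ng_vals)
        assert rho >= 0.9


class TestSubgroupOmega:
    def _alignment(self, rng, members, diverge=0.3, n_codons=300):
        tree_parts = []
        half = diverge / 2
        nwk = "(" + ",".join(f"{m}:{half}" for m in members[:2]) + ")"
        for m in members[2:]:
            nwk = f"({nwk}:{half},{m}:{half})"
        cfg = SimulationConfig(n_codons=n_codons, omega=0.3, seed=0)
        truth = simulate_codon_alignment(parse_newick(nwk + ";"), cfg, rng=rng)
        return truth.sequences

    def test_pair_combinatorics(self):
        rng = RNG(24)
        members = [f"Ath_f_{i}" for i in range(1, 5)]
        aln = self._alignment(rng, members)
        sg = Subgroup(id="sg1", partition="dicot", members=members,
                      species={"Ath"})
        out = subgroup_pairwise_omega(aln, [sg])
        assert len(out[0].pairs) + out[0].n_discarded_saturated == 6

    def test_identical_pair_reported_missing(self):
        seq = "ATGAAAGTTCCC" * 20
        sg = Subgroup(id="sg1", partition="dicot",
                      members=["Ath_f_1", "Ath_f_2"], species={"Ath"})
        out = subgroup_pairwise_omega({"Ath_f_1": seq, "Ath_f_2": seq}, [sg])
        assert np.isnan(out[0].mean_omega)

    def test_saturated_pair_excluded(self):
        rng = RNG(25)
        members = ["Osa_f_1", "Osa_f_2"]
        aln = self._alignment(rng, members, diverge=12.0, n_codons=400)
        sg = Subgroup(id="sg1", partition="grass", members=members,
                      species={"Osa"})
        out = subgroup_pairwise_omega(aln, [sg], ds_max=2.0)
        assert out[0].n_discarded_saturated == 1
        assert not out[0].pairs


class TestCompareMeans:
    def test_identical_sets_not_significant(self):
        res = compare_subgroup_means([0.2, 0.2, 0.2], [0.2, 0.2, 0.2])
        assert res["pvalue"] == 1.0 and res["label"] == "n.s."

    def test_exact_small_sample_matches_permutation(self):
        d, g = [0.1, 0.11, 0.12], [0.9, 0.91, 0.92]
        res = compare_subgroup_means(d, g)
        # permutation oracle over all C(6,3) labelings of the pooled values
        pooled = d + g
        observed = sum(1 for x in d for y in g if x > y)
        count = 0
        total = 0
        for combo in itertools.combinations(range(6), 3):
            dd = [pooled[i] for i in combo]
            gg = [pooled[i] for i in range(6) if i not in combo]
            u = sum(1 for x in dd for y in gg if x > y)
            total += 1
            count += (min(u, 9 - u) <= min(observed, 9 - observed))
        assert res["pvalue"] == pytest.approx(count / total)
        assert res["label"] == "n.s."  # n = 3 each cannot beat p = 0.1

    def test_power_on_separated_distributions(self):
        # omega sets with estimator-like noise around 0.1 vs 0.3
        rng = RNG(26)
        reject = 0
        n_rep = 200
        for _ in range(n_rep):
            d = rng.gamma(9.0, 0.1 / 9.0, size=10)
            g = rng.gamma(9.0, 0.3 / 9.0, size=10)
            reject += compare_subgroup_means(d, g)["pvalue"] < 0.05
        assert reject / n_rep > 0.8


class TestLRT:
    def _dummy(self, loglik, k):
        return CodonModelResults(model=None, name=f"m{k}", loglik=loglik,
                                 params={}, branch_lengths={}, n_free_params=k,
                                 converged=True)

    def test_equal_fits_give_zero(self):
        res = lrt(self._dummy(-100.0, 3), self._dummy(-100.0, 4))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_hand_fed_chi_square_tail(self):
        res = lrt(self._dummy(-100.0, 3), self._dummy(-95.0, 4))
        assert res.statistic == pytest.approx(10.0)
        assert res.pvalue == pytest.approx(float(chi2.sf(10.0, 1)))

    def test_df_override(self):
        res = lrt(self._dummy(-100.0, 3), self._dummy(-95.0, 4), df=2)
        assert res.df == 2
        assert res.pvalue == pytest.approx(float(chi2.sf(10.0, 2)))

    def test_large_negative_statistic_raises(self):
        with pytest.raises(RuntimeError, match="converge"):
            lrt(self._dummy(-95.0, 3), self._dummy(-100.0, 4))


@pytest.fixture(scope="module")
def small_tree_alignment():
    nwk = ("(((Ath_f_1:0.2,Bra_f_1:0.2):0.2,Gma_f_1:0.2):0.1,"
           "((Osa_f_1:0.2,Bdi_f_1:0.2):0.2,Zma_f_1:0.2):0.1);")
    tree = parse_newick(nwk)
    cfg = SimulationConfig(omega=0.3, kappa=2.0, n_codons=200, seed=31)
    truth = simulate_codon_alignment(tree, cfg)
    return tree, truth.sequences


class TestCodonModels:
    def test_rate_matrix_stationarity(self):
        pi = f3x4_frequencies()
        q = build_rate_matrix(2.0, 0.5, pi)
        assert stationary_check(q, pi) < 1e-8
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_likelihood_invariant_to_sequence_order(self, small_tree_alignment):
        tree, seqs = small_tree_alignment
        theta = None
        lnls = []
        for ordering in (list(seqs), list(reversed(list(seqs)))):
            model = OneRatioModel({k: seqs[k] for k in ordering}, tree)
            if theta is None:
                theta = np.concatenate([model._blen_param_init(),
                                        [np.log(2.0), np.log(0.3)]])
            dec_key = theta  # same parameter point for both orderings

            def neg_ll(m, th):
                from famevol.selection.codon_matrix import (CodonMatrixExp,
                                                            build_rate_matrix)
                blens = m._blens_from(th[:len(m.edges)])
                kappa, omega = np.exp(th[-2]), np.exp(th[-1])
                dec = CodonMatrixExp(build_rate_matrix(kappa, omega, m.pi), m.pi)
                p = {e._uid: dec.probability_matrix(t)
                     for e, t in zip(m.edges, blens)}
                return m.engine.loglik(p, m.pi)

            lnls.append(neg_ll(model, theta))
        assert abs(lnls[0] - lnls[1]) < 1e-6

    def test_one_ratio_recovery(self, small_tree_alignment):
        tree, _ = small_tree_alignment
        cfg = SimulationConfig(omega=0.15, kappa=2.0, n_codons=400, seed=32)
        truth = simulate_codon_alignment(tree, cfg)
        res = OneRatioModel(truth.sequences, tree).fit()
        assert res.converged
        assert 0.08 < res.params["omega"] < 0.25

    def test_branch_class_with_no_branches_rejected(self, small_tree_alignment):
        tree, seqs = small_tree_alignment
        labels = {e._uid: "all" for e in tree.postorder() if e.parent}
        BranchModel(seqs, tree, labels)  # one universal class is fine
        with pytest.raises(ValueError, match="no branches"):
            BranchModel(seqs, tree, {**labels, -1: "ghost"})

    def test_m3_posteriors_normalized(self, small_tree_alignment):
        tree, seqs = small_tree_alignment
        res = SiteMixtureModel(seqs, tree, 3).fit(n_restarts=1)
        post = res.site_posteriors.to_numpy()
        assert np.abs(post.sum(axis=1) - 1.0).max() < 1e-9
        assert sum(res.params["proportions"]) == pytest.approx(1.0)
        assert res.params["omegas"] == sorted(res.params["omegas"])

    def test_switching_generator_is_proper(self):
        pi = f3x4_frequencies()
        big, stat = switching_generator(2.0, np.array([0.1, 0.8, 3.0]),
                                        np.array([0.5, 0.3, 0.2]), 0.7, pi)
        assert np.abs(big.sum(axis=1)).max() < 1e-9
        assert stationary_check(big, stat) < 1e-8
        assert stat.sum() == pytest.approx(1.0)

    def test_switching_collapses_to_m3_at_zero_delta(self, small_tree_alignment):
        tree, seqs = small_tree_alignment
        m3 = SiteMixtureModel(seqs, tree, 3)
        s1 = SwitchingModel(seqs, tree, 3)
        theta = m3._default_x0(2.0, None, None)
        lnl_m3 = -m3._neg_ll(theta)
        lnl_s1 = -s1._neg_ll_switch(np.concatenate([theta, [np.log(1e-8)]]))
        assert abs(lnl_m3 - lnl_s1) < 1e-6


@pytest.fixture(scope="module")
def switch_fit(small_tree_alignment):
    tree, seqs = small_tree_alignment
    m3 = SiteMixtureModel(seqs, tree, 3).fit(n_restarts=1)
    return SwitchingModel(seqs, tree, 3).fit(init_from=m3)


class TestPositiveSites:
    def test_no_lists_when_top_omega_below_one(self, switch_fit):
        import copy
        fit = copy.copy(switch_fit)
        fit.params = dict(fit.params, omegas=[0.1, 0.3, 0.9])
        out = partition_positive_sites(fit, PARTITION,
                                       kept_column_map=np.arange(200))
        assert all(df.empty for df in out.values())

    def test_threshold_monotonicity(self, switch_fit):
        import copy
        fit = copy.copy(switch_fit)
        # force the top class to count as positive so thresholding runs
        # on the fitted posteriors regardless of the neutral-data fit
        omegas = list(fit.params["omegas"])
        omegas[-1] = max(omegas[-1], 1.5)
        fit.params = dict(fit.params, omegas=omegas)
        loose = partition_positive_sites(fit, PARTITION, threshold=0.5,
                                        kept_column_map=np.arange(200))
        strict = partition_positive_sites(fit, PARTITION, threshold=0.95,
                                         kept_column_map=np.arange(200))
        for side in ("dicot", "grass"):
            assert set(strict[side]["site"]) <= \
                set(loose[side]["site"]) | set(loose["shared"]["site"])


class TestBranchLabeledNewick:
    def test_round_trip_codeml_labels(self):
        from famevol.selection import (read_branch_labeled_newick,
                                       write_branch_labeled_newick)
        text = "((Ath_f_1:0.1,Bra_f_1:0.1) #1:0.2,(Osa_f_1:0.1,Zma_f_1 #2:0.1):0.2);"
        tree, labels = read_branch_labeled_newick(text)
        assert sorted(labels.values()) == ["1", "2"]
        named = {(tuple(sorted(l.name for l in n.leaves()))): lab
                 for n, lab in ((n, labels.get(n._uid)) for n in tree.postorder())
                 if lab}
        assert named[("Ath_f_1", "Bra_f_1")] == "1"
        assert named[("Zma_f_1",)] == "2"
        again, labels2 = read_branch_labeled_newick(
            write_branch_labeled_newick(tree, labels))
        assert sorted(labels2.values()) == ["1", "2"]


class TestNG86Convergence:
    def test_counting_estimator_converges_without_transition_bias(self):
        # at kappa = 1 the NG86 equal-weight site counting is unbiased;
        # the empirical dN/dS converges to the simulated omega
        tree = parse_newick("(X:0.25,Y:0.25);")
        cfg = SimulationConfig(omega=0.5, kappa=1.0, n_codons=50_000, seed=70)
        truth = simulate_codon_alignment(tree, cfg)
        pw = ng86_pairwise(truth.sequences["X"], truth.sequences["Y"])
        assert abs(pw.omega - 0.5) / 0.5 < 0.10
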