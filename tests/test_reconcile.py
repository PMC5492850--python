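import itertools

import numpy as np
import pandas as pd
import pytest

from famevol.reconcile import (detect_subgroups, infer_events,
                               reconstruct_copy_numbers, reconcile,
                               root_gene_tree, summarize_events)
from famevol.simulate import SimulationConfig, simulate_family
from famevol.species import PARTITION
from famevol.tree import parse_newick, reroot_above, same_unrooted_topology

from _oracles import min_duplications_oracle
from conftest import random_gene_tree


class TestRooting:
    def test_congruent_tree_rooted_between_partitions(self, species_tree,
                                                      congruent_gene_tree):
        misrooted = reroot_above(
            congruent_gene_tree.copy().find("Ath_fam1_1"))
        rooted = root_gene_tree(misrooted, species_tree)
        rec = reconcile(rooted, species_tree)
        assert rec.n_duplications == 0 and rec.n_losses == 0
        sides = [{PARTITION[l.name.split("_")[0]] for l in c.leaves()}
                 for c in rooted.children]
        assert sorted(map(sorted, sides)) == [["dicot"], ["grass"]]

    def test_midpoint_two_leaves(self):
        tree = parse_newick("(A_f_1:1.0,B_f_1:3.0);")
        rooted = root_gene_tree(tree, _two_species_tree(), method="midpoint")
        lengths = sorted(l.length for l in rooted.leaves())
        assert lengths == pytest.approx([2.0, 2.0])

    def test_outgroup_rooting(self, species_tree, congruent_gene_tree):
        rooted = root_gene_tree(congruent_gene_tree.copy(), species_tree,
                                method="outgroup", outgroup="Zma_fam1_1")
        assert rooted.children[0].name == "Zma_fam1_1" or \
            rooted.children[1].name == "Zma_fam1_1"
        with pytest.raises(ValueError, match="not found"):
            root_gene_tree(congruent_gene_tree.copy(), species_tree,
                           method="outgroup", outgroup="nope")

    def test_minimize_duplication_equals_exhaustive_search(self,
                                                           small_species_tree):
        rng = np.random.default_rng(10)
        st = small_species_tree
        species = st.leaf_names()
        for _ in range(15):
            n = int(rng.integers(4, 9))
            tree = random_gene_tree(rng, species, n)
            rooted = root_gene_tree(tree.copy(), st)
            best = reconcile(rooted, st)
            best_cost = best.n_duplications + best.n_losses
            # exhaustive re-rooting
            candidates = [x for x in tree.postorder() if x.parent is not None]
            costs = []
            for i in range(len(candidates)):
                work = tree.copy()
                target = [x for x in work.postorder()
                          if x.parent is not None][i]
                rr = reroot_above(target)
                r = reconcile(rr, st)
                costs.append(r.n_duplications + r.n_losses)
            assert best_cost == min(costs)


def _two_species_tree():
    from famevol.species import SpeciesTree
    return SpeciesTree(parse_newick("(A:1,B:1);"),
                       partition={"A": "dicot", "B": "grass"})


class TestSubgroups:
    def test_congruent_tree_two_subgroups(self, species_tree,
                                          congruent_gene_tree):
        sgs = detect_subgroups(congruent_gene_tree, species_tree)
        assert sorted(s.partition for s in sgs) == ["dicot", "grass"]
        assert {s.n_members for s in sgs} == {5, 6}

    def test_split_dicot_clades(self, species_tree):
        nwk = ("(((Ath_f_1,Bra_f_1),(Osa_f_1,Zma_f_1)),(Gma_f_1,Mtr_f_1));")
        sgs = detect_subgroups(parse_newick(nwk), species_tree)
        assert sum(s.partition == "dicot" for s in sgs) == 2
        assert sum(s.partition == "grass" for s in sgs) == 1

    def test_matches_exhaustive_clade_scan(self, species_tree):
        rng = np.random.default_rng(11)
        species = species_tree.leaf_names()
        for _ in range(20):
            tree = random_gene_tree(rng, species, int(rng.integers(3, 11)))
            sgs = detect_subgroups(tree, species_tree)
            # oracle: all maximal pure clades by direct enumeration
            clades = []
            for node in tree.postorder():
                parts = {PARTITION[l.name.split("_")[0]] for l in node.leaves()}
                if len(parts) != 1:
                    continue
                parent_pure = False
                if node.parent is not None:
                    pp = {PARTITION[l.name.split("_")[0]]
                          for l in node.parent.leaves()}
                    parent_pure = len(pp) == 1
                if not parent_pure:
                    clades.append(frozenset(l.name for l in node.leaves()))
            assert sorted((frozenset(s.members) for s in sgs), key=sorted) == \
                sorted(clades, key=sorted)
            # no two subgroups share a member
            all_members = [m for s in sgs for m in s.members]
            assert len(all_members) == len(set(all_members))


class TestInferEvents:
    def test_congruent_tree_no_events(self, species_tree, congruent_gene_tree):
        sgs = detect_subgroups(congruent_gene_tree, species_tree)
        table, rec = infer_events(congruent_gene_tree, species_tree, sgs)
        assert table.empty
        assert rec.n_duplications == 0 and rec.n_losses == 0

    def test_recent_duplication_and_loss(self, species_tree):
        # Ath present twice, Mtr missing from the dicot subgroup
        nwk = ("((((Ath_f_1,Ath_f_2),Bra_f_1),((Gma_f_1,Gma_f_2x),"
               "(Ptr_f_1,Rco_f_1))),((Bdi_f_1,Osa_f_1),(Sit_f_1,"
               "(Sbi_f_1,Zma_f_1))));").replace("Gma_f_2x", "Gma_f_2")
        tree = parse_newick(nwk)
        sgs = detect_subgroups(tree, species_tree)
        table, rec = infer_events(tree, species_tree, sgs)
        dups = table[table["event"] == "duplication"]
        losses = table[table["event"] == "loss"]
        assert (dups["class"] == "recent-dicot").sum() >= 1
        assert len(losses) == 1
        assert losses.iloc[0]["species"] == "Mtr"
        assert losses.iloc[0]["class"] == "dicot"

    def test_duplication_count_matches_brute_force(self, small_species_tree):
        rng = np.random.default_rng(12)
        st = small_species_tree
        for _ in range(25):
            tree = random_gene_tree(rng, st.leaf_names(),
                                    int(rng.integers(3, 8)))
            rec = reconcile(tree, st)
            assert rec.n_duplications == min_duplications_oracle(tree, st)

    def test_unknown_species_rejected(self, species_tree):
        tree = parse_newick("(Ath_f_1,Xxx_f_1);")
        with pytest.raises(ValueError, match="Xxx"):
            reconcile(tree, species_tree)


class TestCopyNumbers:
    def test_single_congruent_cog(self, species_tree, congruent_gene_tree):
        rec = reconcile(congruent_gene_tree, species_tree)
        prof = reconstruct_copy_numbers([rec], species_tree)
        frame = prof.to_frame()
        assert (frame["count"] == 1).all()
        assert (frame["gains"] == 0).all() and (frame["losses"] == 0).all()

    def test_ancient_dicot_duplication_profile(self, species_tree):
        nwk = ("((((Ath_f_1,Bra_f_1),((Gma_f_1,Mtr_f_1),(Ptr_f_1,Rco_f_1))),"
               "((Ath_f_2,Bra_f_2),((Gma_f_2,Mtr_f_2),(Ptr_f_2,Rco_f_2)))),"
               "((Bdi_f_1,Osa_f_1),(Sit_f_1,(Sbi_f_1,Zma_f_1))));")
        rec = reconcile(parse_newick(nwk), species_tree)
        prof = reconstruct_copy_numbers([rec], species_tree)
        st = species_tree
        assert prof.counts[st.mrca_all] == 1
        assert prof.counts[st.mrca_dicot] == 2
        assert prof.gains[st.mrca_dicot] == 1

    def test_balance_on_simulated_families(self, species_tree):
        rng = np.random.default_rng(13)
        for _ in range(40):
            cfg = SimulationConfig(birth_rate=0.12, death_rate=0.06, seed=0)
            h = simulate_family(species_tree, cfg, rng=rng)
            recs = [reconcile(t, species_tree) for t in h.gene_trees]
            if recs:
                # check_balance raises on any violated branch
                reconstruct_copy_numbers(recs, species_tree)

    def test_counts_match_truth_when_fully_observable(self, species_tree):
        rng = np.random.default_rng(14)
        checked = 0
        for _ in range(60):
            cfg = SimulationConfig(birth_rate=0.1, death_rate=0.05, seed=0)
            h = simulate_family(species_tree, cfg, rng=rng)
            if not h.gene_trees or not (h.events.empty
                                        or h.events["observable"].all()):
                continue
            recs = [reconcile(t, species_tree) for t in h.gene_trees]
            # a family observed in only one partition reveals nothing
            # about copies above its surviving clade
            if any(r.origination != species_tree.mrca_all for r in recs):
                continue
            prof = reconstruct_copy_numbers(recs, species_tree)
            for idx in (species_tree.mrca_all, species_tree.mrca_dicot,
                        species_tree.mrca_grass):
                assert prof.counts.get(idx, 0) == h.counts[idx]
            checked += 1
        assert checked >= 10


class TestSummaries:
    def test_empty_summary_is_zero(self):
        out = summarize_events([])
        assert out.iloc[-1]["cog_id"] == "total"
        assert (out.iloc[-1][1:] == 0).all()

    def test_totals_row_sums_columns(self, species_tree):
        tables = []
        rng = np.random.default_rng(15)
        for i in range(5):
            cfg = SimulationConfig(birth_rate=0.15, death_rate=0.05, seed=0)
            h = simulate_family(species_tree, cfg, rng=rng)
            for j, t in enumerate(h.gene_trees):
                sgs = detect_subgroups(t, species_tree)
                table, _ = infer_events(t, species_tree, sgs,
                                        cog_id=f"cog{i}_{j}")
                tables.append(table)
        out = summarize_events(tables)
        body, total = out.iloc[:-1], out.iloc[-1]
        for col in out.columns[1:]:
            assert total[col] == body[col].sum()


class TestAnnotatedOutputs:
    def test_annotated_newick_carries_event_labels(self, species_tree):
        from famevol.reconcile import annotated_newick
        nwk = ("(((Ath_f_1,Ath_f_2),Bra_f_1),(Osa_f_1,Zma_f_1));")
        rec = reconcile(parse_newick(nwk), species_tree)
        out = annotated_newick(rec)
        assert "D_Ath" in out       # the Ath duplication
        assert "S_MRCA_all" in out  # the root speciation

    def test_confirmed_absent_whitelist_flags_losses(self, species_tree):
        nwk = ("(((Ath_f_1,Bra_f_1),((Gma_f_1,Ptr_f_1),Rco_f_1)),"
               "((Bdi_f_1,Osa_f_1),(Sit_f_1,(Sbi_f_1,Zma_f_1))));")
        tree = parse_newick(nwk)  # Mtr missing
        sgs = detect_subgroups(tree, species_tree)
        table, _ = infer_events(tree, species_tree, sgs,
                                confirmed_absent={"Mtr"})
        losses = table[table["event"] == "loss"]
        assert losses.set_index("species")["validated"].to_dict() == {"Mtr": True}
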