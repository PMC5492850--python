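import itertools

import numpy as np
import pytest

from famevol.genetic_code import translate_cds
from famevol.homology import (BeTGraph, SequenceRecord, build_cogs, cog_report,
                              compute_bets, filter_sequences, load_hit_table,
                              score_all_pairs)
from famevol.species import PARTITION
from famevol.simulate import SimulationConfig, generate_dataset

from _oracles import cog_components_oracle


def _rec(rid, species, cds):
    return SequenceRecord(id=rid, species=species, cds=cds,
                          protein=translate_cds(cds))


def _random_cds(rng, n_codons):
    safe = [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
            if c not in ("TAA", "TAG", "TGA")]
    return "".join(rng.choice(safe) for _ in range(n_codons))


class TestFilters:
    def test_short_sequences_removed_with_reason(self):
        rng = np.random.default_rng(0)
        keep = _rec("Ath_f_1", "Ath", _random_cds(rng, 150))
        short = _rec("Ath_f_2", "Ath", _random_cds(rng, 100))  # 300 nt
        kept, report = filter_sequences([keep, short])
        assert [r.id for r in kept] == ["Ath_f_1"]
        row = report[report["id"] == "Ath_f_2"].iloc[0]
        assert row["reason"] == "short"

    def test_allele_removed_source_retained(self):
        rng = np.random.default_rng(1)
        cds = _random_cds(rng, 150)
        allele = list(cds)
        positions = rng.choice(len(cds), size=round(0.03 * len(cds)),
                               replace=False)
        for pos in positions:
            for alt in "ACGT":
                allele[pos] = alt
                codon = "".join(allele[(pos // 3) * 3:(pos // 3) * 3 + 3])
                if alt != cds[pos] and codon not in ("TAA", "TAG", "TGA"):
                    break
        source = _rec("Bra_f_1", "Bra", cds)
        copy = _rec("Bra_f_2", "Bra", "".join(allele))
        kept, report = filter_sequences([source, copy])
        assert [r.id for r in kept] == ["Bra_f_1"]
        assert report.iloc[0]["reason"] == "allele"

    def test_indel_pair_both_retained(self):
        # same length and high alignment similarity, but the optimal
        # global alignment needs gaps (a deleted codon + appended codon)
        rng = np.random.default_rng(2)
        cds = _random_cds(rng, 30)
        shifted = cds[:45] + cds[48:] + "GCT"
        a = _rec("Gma_f_1", "Gma", cds)
        b = _rec("Gma_f_2", "Gma", shifted)
        kept, report = filter_sequences([a, b], min_len_nt=60)
        assert {r.id for r in kept} == {"Gma_f_1", "Gma_f_2"}

    def test_translation_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        cds = _random_cds(rng, 140)
        bad = SequenceRecord(id="Mtr_f_1", species="Mtr", cds=cds,
                             protein="M" * (len(cds) // 3))
        kept, report = filter_sequences([bad])
        assert not kept
        assert report.iloc[0]["reason"] == "translation_mismatch"

    def test_filter_idempotent(self):
        cfg = SimulationConfig(birth_rate=0.05, death_rate=0, n_codons=160,
                               seed=4)
        ds = generate_dataset(cfg, n_families=1, n_alleles=2, n_fragments=1)
        records = [_rec(r.id, r.species, r.cds) for r in ds.records]
        once, _ = filter_sequences(records)
        twice, report2 = filter_sequences(once)
        assert [r.id for r in once] == [r.id for r in twice]
        assert report2.empty


class TestScoring:
    def test_symmetry_and_self_similarity(self):
        rng = np.random.default_rng(5)
        recs = [_rec(f"{sp}_f_1", sp, _random_cds(rng, 140))
                for sp in ("Ath", "Osa", "Zma")]
        hits = score_all_pairs(recs)
        for a, b in itertools.combinations([r.id for r in recs], 2):
            sab = hits[(hits["query"] == a) & (hits["subject"] == b)]["score"]
            sba = hits[(hits["query"] == b) & (hits["subject"] == a)]["score"]
            assert float(sab.iloc[0]) == float(sba.iloc[0])
        assert (hits["query"] != hits["subject"]).all()

    def test_smith_waterman_matches_dp_oracle(self):
        # exhaustive affine-gap DP on a tiny pair
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        a, b = "MKTWQEVLHS", "MKTWEVLHAS"

        def sw_oracle(x, y, gap_open=11, gap_extend=1):
            n, m = len(x), len(y)
            neg = -1e9
            M = np.full((n + 1, m + 1), neg)
            Ix = np.full((n + 1, m + 1), neg)
            Iy = np.full((n + 1, m + 1), neg)
            best = 0.0
            M[:, 0] = M[0, :] = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    s = blosum[x[i - 1], y[j - 1]]
                    M[i, j] = max(0.0, s + max(M[i - 1, j - 1],
                                               Ix[i - 1, j - 1],
                                               Iy[i - 1, j - 1]))
                    Ix[i, j] = max(M[i - 1, j] - gap_open - gap_extend,
                                   Ix[i - 1, j] - gap_extend)
                    Iy[i, j] = max(M[i, j - 1] - gap_open - gap_extend,
                                   Iy[i, j - 1] - gap_extend)
                    best = max(best, M[i, j])
            return best

        from famevol.homology import _protein_aligner
        assert _protein_aligner().score(a, b) == pytest.approx(sw_oracle(a, b))

    def test_hit_table_validation(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("g1\tg2\t98.5\t100\t2\t0\t1\t100\t1\t100\t1e-50\t200\n")
        table = load_hit_table(path, {"g1", "g2"})
        assert len(table) == 1 and table.iloc[0]["score"] == 200.0
        with pytest.raises(ValueError, match="unknown ids"):
            load_hit_table(path, {"g1"})


class TestBeTs:
    def _hits(self, rows):
        import pandas as pd
        return pd.DataFrame(rows, columns=["query", "subject", "score",
                                           "pident", "length"])

    def test_three_species_mutual_best(self):
        rows = []
        genes = {"a1": "Ath", "b1": "Bra", "o1": "Osa"}
        for g, h in itertools.permutations(genes, 2):
            rows.append((g, h, 100.0, 99.0, 100))
        bets = compute_bets(self._hits(rows), genes)
        assert all(lab == "reciprocal" for _, _, lab in bets.edges())
        assert len(bets.reciprocal_pairs()) == 3

    def test_asymmetric_edge(self):
        species = {"a1": "Ath", "a2": "Ath", "b1": "Bra"}
        rows = [("a1", "b1", 90.0, 95.0, 100),
                ("b1", "a2", 95.0, 96.0, 100),  # b1's best in Ath is a2
                ("b1", "a1", 90.0, 95.0, 100),
                ("a2", "b1", 99.0, 97.0, 100)]
        bets = compute_bets(self._hits(rows), species)
        labels = {(a, b): lab for a, b, lab in bets.edges()}
        assert labels[("a1", "b1")] == "asymmetric"
        assert labels[("a2", "b1")] == "reciprocal"

    def test_orthologs_all_reciprocal_on_clean_families(self, species_tree):
        cfg = SimulationConfig(birth_rate=0, death_rate=0, n_codons=150, seed=6)
        ds = generate_dataset(cfg, n_families=1)
        recs = [_rec(r.id, r.species, r.cds) for r in ds.records]
        bets = compute_bets(score_all_pairs(recs),
                            {r.id: r.species for r in recs})
        assert all(lab == "reciprocal" for _, _, lab in bets.edges())


class TestCogs:
    def _graph(self, pairs, species):
        bets = {}
        for p in pairs:
            a, b = sorted(p)
            bets[(a, species[b])] = b
            bets[(b, species[a])] = a
        return BeTGraph(bets=bets, species_of=species)

    def test_complete_graph_single_cog(self):
        species = {f"g{i}": sp for i, sp in enumerate(["Ath", "Bra", "Osa", "Zma"])}
        pairs = {frozenset(p) for p in itertools.combinations(species, 2)}
        cogs = build_cogs(self._graph(pairs, species))
        assert len(cogs) == 1
        assert set(cogs[0].core) == set(species)

    def test_disjoint_triangles_two_cogs(self):
        species = {"a1": "Ath", "b1": "Bra", "o1": "Osa",
                   "a2": "Ath", "b2": "Bra", "z2": "Zma"}
        pairs = {frozenset(("a1", "b1")), frozenset(("b1", "o1")),
                 frozenset(("a1", "o1")),
                 frozenset(("a2", "b2")), frozenset(("b2", "z2")),
                 frozenset(("a2", "z2"))}
        cogs = build_cogs(self._graph(pairs, species))
        assert len(cogs) == 2
        assert {frozenset(c.core) for c in cogs} == {
            frozenset({"a1", "b1", "o1"}), frozenset({"a2", "b2", "z2"})}

    def test_matches_triangle_component_oracle(self):
        rng = np.random.default_rng(7)
        all_species = ["Ath", "Bra", "Gma", "Osa", "Zma", "Sit"]
        for trial in range(25):
            genes = {f"g{i}": all_species[rng.integers(len(all_species))]
                     for i in range(12)}
            candidates = [frozenset(p) for p in itertools.combinations(genes, 2)
                          if genes[tuple(p)[0]] != genes[tuple(p)[1]]]
            raw = [candidates[i] for i in
                   rng.choice(len(candidates), size=18, replace=False)]
            # respect the BeT constraint: one partner per (gene, species)
            used, chosen = set(), set()
            for p in sorted(raw, key=sorted):
                a, b = sorted(p)
                if (a, genes[b]) in used or (b, genes[a]) in used:
                    continue
                used |= {(a, genes[b]), (b, genes[a])}
                chosen.add(p)
            cogs = build_cogs(self._graph(chosen, genes),
                              include_satellites=False)
            expected = cog_components_oracle(chosen, genes)
            assert sorted((frozenset(c.core) for c in cogs), key=sorted) == \
                sorted((frozenset(s) for s in expected), key=sorted)

    def test_core_sets_partition_genes(self):
        rng = np.random.default_rng(8)
        species = {f"g{i}": ["Ath", "Bra", "Osa", "Zma", "Sit"][i % 5]
                   for i in range(15)}
        candidates = [frozenset(p) for p in itertools.combinations(species, 2)
                      if species[tuple(p)[0]] != species[tuple(p)[1]]]
        chosen = {candidates[i] for i in
                  rng.choice(len(candidates), size=30, replace=False)}
        cogs = build_cogs(self._graph(chosen, species))
        seen = set()
        for c in cogs:
            assert not (set(c.core) & seen)
            seen |= set(c.core)

    def test_report_flags(self):
        from famevol.homology import COG
        species_of = {f"{sp}_f_1": sp for sp in PARTITION}
        full = COG(id="cog1", core=sorted(species_of))
        missing = COG(id="cog2", core=sorted(g for g in species_of
                                             if not g.startswith("Mtr")))
        report = cog_report([full, missing], species_of, PARTITION)
        assert report.iloc[0]["flag"] == "complete"
        row = report.iloc[1]
        assert row["flag"] == "incomplete" and row["dicot_species"] == 5

    def test_empty_cog_list(self):
        report = cog_report([], {}, PARTITION)
        assert report.empty
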