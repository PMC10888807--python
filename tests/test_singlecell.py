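"""Single-cell genotyping tests: extraction, chimera filter, UMI collapse
(with a brute-force oracle), matrix, clonotypes, assignment, congruence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from shuffleseq.config import Config
from shuffleseq.simulate import DEFAULT_DESIGN, sc_read2_sequence
from shuffleseq.singlecell import (
    BcCellMatrix, Clonotype, T7_RECORD_COLUMNS, assign_cells, build_matrix,
    call_sc_rearrangements, collapse_umis, extract_t7_record,
    filter_chimeric_umis, hamming, jaccard, merge_with_bulk,
    pr_threshold_analysis, qc_cells, reconstruct_clonotypes,
)


def _records(rows):
    return pd.DataFrame(rows, columns=T7_RECORD_COLUMNS)


# ------------------------------------------------------------ extraction

class TestExtractT7:
    BC1, BC2 = "ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG"

    def _read1(self, cell="C" * 16, umi="A" * 12):
        return cell + umi

    def test_cs2_layout(self):
        read2 = sc_read2_sequence(DEFAULT_DESIGN, self.BC1, self.BC2, "CS2")
        rec = extract_t7_record(self._read1(), read2)
        assert rec is not None
        assert (rec["bc1"], rec["bc2"], rec["capture_side"]) == (
            self.BC1, self.BC2, "CS2")
        assert read2.find("TGAGC") == 14  # anchor at position 15, 1-based

    def test_cs1_layout_extraction_order(self):
        read2 = sc_read2_sequence(DEFAULT_DESIGN, self.BC1, self.BC2, "CS1")
        rec = extract_t7_record(self._read1(), read2)
        assert rec is not None
        assert (rec["bc1"], rec["bc2"], rec["capture_side"]) == (
            self.BC1, self.BC2, "CS1")
        assert read2.find("AAAGC") == 14

    def test_anchor_outside_window_rejected(self):
        read2 = "G" * 40 + sc_read2_sequence(DEFAULT_DESIGN, self.BC1,
                                             self.BC2, "CS2")
        assert extract_t7_record(self._read1(), read2) is None

    def test_whitelist_mismatch_rejected(self):
        read2 = sc_read2_sequence(DEFAULT_DESIGN, self.BC1, self.BC2, "CS2")
        assert extract_t7_record(self._read1(), read2,
                                 whitelist={"T" * 16}) is None
        assert extract_t7_record(self._read1(), read2,
                                 whitelist={"C" * 16}) is not None


# ------------------------------------------------------------ chimera filter

class TestChimeraFilter:
    def test_minor_share_dropped(self):
        rows = [("c1", "u1", "b1", "b2", "CS2", 9),
                ("c1", "u1", "b3", "b4", "CS2", 1)]
        out = filter_chimeric_umis(_records(rows), 0.2)
        assert len(out) == 1 and out["bc1"].iloc[0] == "b1"

    def test_even_split_both_kept(self):
        rows = [("c1", "u1", "b1", "b2", "CS2", 5),
                ("c1", "u1", "b3", "b4", "CS2", 5)]
        assert len(filter_chimeric_umis(_records(rows), 0.2)) == 2

    def test_single_combination_kept(self):
        rows = [("c1", "u1", "b1", "b2", "CS2", 1)]
        assert len(filter_chimeric_umis(_records(rows), 0.2)) == 1

    def test_share_computed_within_cell_and_umi(self):
        rows = [("c1", "u1", "b1", "b2", "CS2", 9),
                ("c2", "u1", "b3", "b4", "CS2", 1)]  # different cell: kept
        assert len(filter_chimeric_umis(_records(rows), 0.2)) == 2


# ------------------------------------------------------------ UMI collapse

def brute_force_umi_components(umis, max_dist=1):
    """Oracle: explicit graph + networkx connected components."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(umis)
    for a, b in itertools.combinations(umis, 2):
        if hamming(a, b) <= max_dist:
            g.add_edge(a, b)
    return nx.number_connected_components(g)


class TestCollapseUmis:
    def _count(self, umis):
        rows = [("c1", u, "b1", "b2", "CS2", 1) for u in umis]
        out = collapse_umis(_records(rows))
        return int(out["umi_count"].iloc[0])

    def test_distance_one_collapses(self):
        assert self._count(["AAAAAAAAAAAA", "AAAAAAAAAAAT"]) == 1

    def test_distant_umis_stay_separate(self):
        umis = ["AAAAAAAAAAAA", "CCCCAAAAAAAA", "GGGGAAAAAAAA",
                "TTTTAAAAAAAA", "AACCGGAAAAAA"]
        assert self._count(umis) == 5

    def test_chain_is_one_component(self):
        chain = ["AAAAAAAAAAAA", "AAAAAAAAAAAT", "AAAAAAAAAATT"]
        assert self._count(chain) == brute_force_umi_components(chain) == 1

    def test_matches_brute_force_on_random_instances(self):
        """200 randomized UMI sets vs the explicit-graph oracle."""
        rng = np.random.default_rng(7)
        bases = list("ACGT")
        for trial in range(200):
            n = int(rng.integers(2, 20))
            seeds = ["".join(rng.choice(bases, 12))
                     for _ in range(max(1, n // 4))]
            umis = set()
            for _ in range(n):
                u = list(seeds[int(rng.integers(len(seeds)))])
                for _ in range(int(rng.integers(0, 3))):
                    u[int(rng.integers(12))] = bases[int(rng.integers(4))]
                umis.add("".join(u))
            umis = sorted(umis)
            assert self._count(umis) == brute_force_umi_components(umis), trial


# ------------------------------------------------------------ matrix & QC

class TestMatrix:
    def test_capture_sides_summed(self):
        rows = [("c1", "AAAAAAAAAAAA", "b1", "b2", "CS2", 1),
                ("c1", "CCCCCCCCCCCC", "b1", "b2", "CS2", 1),
                ("c1", "GGGGGGGGGGGG", "b1", "b2", "CS1", 1)]
        counts = collapse_umis(_records(rows))
        mat = build_matrix(counts)
        assert mat.matrix.toarray().tolist() == [[3]]

    def test_empty(self):
        mat = build_matrix(collapse_umis(_records([])))
        assert mat.matrix.shape == (0, 0)

    def test_marginals_consistent(self, sc_experiment):
        mat = sc_experiment["matrix"]
        assert mat.pair_totals.sum() == mat.cell_totals.sum()
        assert mat.pair_totals.sum() == mat.matrix.sum()


class TestQcCells:
    TABLE = pd.DataFrame({
        "cell_bc": ["a", "b", "c", "d"],
        "transcriptome_umi": [1500, 900, 1500, 1500],
        "mito_pct": [5.0, 5.0, 13.0, 5.0],
        "doublet_score": [0.1, 0.1, 0.1, 0.5],
    })

    def test_thresholds(self):
        assert qc_cells(self.TABLE, 1000, (1, 12), 0.4) == {"a"}


# ------------------------------------------------------------ clonotypes

class TestClonotypes:
    def test_rank_cut_rejects_small_candidate(self, cfg):
        """A community whose inflection leaves only 3 pairs is rejected
        (needs > 6)."""
        from shuffleseq.singlecell import _rank_inflection_cut
        frac = np.array([0.9, 0.88, 0.85, 0.2, 0.15, 0.1] + [0.0] * 10)
        n = _rank_inflection_cut(frac, 1.5)
        assert n == 3  # 0.85 / 0.2 = 4.25 > 1.5
        assert n < cfg.min_clonotype_pairs

    def test_recovery_at_stated_conditions(self, sc_experiment):
        """20 clones x 30 pairs, capture 0.7, ambient 2%: every clone is
        recovered with a perfect barcode-pair set."""
        best = sc_experiment["best_match"]
        perfect = {name for j, name in best.values() if j == 1.0}
        assert perfect == set(sc_experiment["clone_pairs"])

    def test_near_duplicates_merge(self, cfg):
        a = frozenset((f"b{i}", f"c{i}") for i in range(30))
        b = frozenset(list(a)[:29])  # Jaccard 29/30 = 0.97
        from shuffleseq.singlecell import _merge_by_jaccard
        merged = _merge_by_jaccard([a, b], cfg.jaccard_connect)
        assert len(merged) == 1 and merged[0] == b  # intersection

    def test_merge_with_bulk(self):
        de_novo = [Clonotype("d0", frozenset({("a", "x"), ("b", "y")}),
                             "de_novo_round1")]
        bulk = {"k1": [("a", "x"), ("b", "y")],          # same clone
                "k2": [("q", "r"), ("s", "t")]}           # new clone
        out = merge_with_bulk(de_novo, bulk, 0.05)
        assert {c.id for c in out} == {"d0", "bulk.k2"}

    def test_rare_clone_found_in_round_two(self, cfg):
        """A 2%-abundance clone masked in round 1 appears after assignable
        cells are removed."""
        rng = np.random.default_rng(11)
        pairs = [(f"A{i:03d}" + "G" * 16, f"T{i:03d}" + "C" * 16)
                 for i in range(40)]
        common, rare = pairs[:20], pairs[20:]
        cells, rows = [], []
        for i in range(280):
            cell = f"cell{i:04d}" + "A" * 8
            cells.append(cell)
            mine = common if i >= 6 else rare
            for p in mine:
                if rng.random() < 0.8:
                    rows.append((cell, *p, rng.poisson(6) + 3))
        counts = pd.DataFrame(rows, columns=["cell_bc", "bc1", "bc2",
                                             "umi_count"])
        counts["capture_side"] = "CS2"
        mat = build_matrix(counts)
        small_cfg = Config(seed=0, knn_neighbors=10)
        from shuffleseq.singlecell import iterate_rounds
        clons, _ = iterate_rounds(mat, small_cfg)
        best_rare = max(jaccard(c.barcode_pairs, frozenset(rare))
                        for c in clons)
        best_common = max(jaccard(c.barcode_pairs, frozenset(common))
                          for c in clons)
        assert best_common > 0.85 and best_rare > 0.85
        round1 = reconstruct_clonotypes(mat, small_cfg)
        assert all(jaccard(c.barcode_pairs, frozenset(rare)) < 0.1
                   for c in round1)


# ------------------------------------------------------------ assignment

def _mat_from_cells(cell_pairs: dict[str, dict[tuple, int]]) -> BcCellMatrix:
    rows = [(c, b1, b2, "CS2", n) for c, pairs in cell_pairs.items()
            for (b1, b2), n in pairs.items()]
    df = pd.DataFrame(rows, columns=["cell_bc", "bc1", "bc2",
                                     "capture_side", "umi_count"])
    return build_matrix(df)


class TestAssignCells:
    CLON = [Clonotype("k0", frozenset((f"a{i:02d}", f"x{i:02d}")
                                      for i in range(30)), "bulk"),
            Clonotype("k1", frozenset((f"b{i:02d}", f"y{i:02d}")
                                      for i in range(30)), "bulk")]

    def test_good_cell_assigned(self):
        pairs = {(f"a{i:02d}", f"x{i:02d}"): 3 for i in range(9)}
        pairs[("zz", "zz")] = 3
        mat = _mat_from_cells({"c1" + "A" * 14: pairs})
        out = assign_cells(mat, self.CLON)
        row = out.iloc[0]
        assert row["status"] == "assigned" and row["clonotype_id"] == "k0"
        assert row["top_precision"] == pytest.approx(0.9)
        assert row["top_recall"] == pytest.approx(0.3)

    def test_low_precision_unassigned(self):
        pairs = {(f"a{i:02d}", f"x{i:02d}"): 3 for i in range(6)}
        pairs.update({(f"zz{i}", f"qq{i}"): 3 for i in range(4)})
        mat = _mat_from_cells({"c1" + "A" * 14: pairs})
        out = assign_cells(mat, self.CLON)
        assert out.iloc[0]["status"] != "assigned"

    def test_second_recall_doublet_removed(self):
        pairs = {(f"a{i:02d}", f"x{i:02d}"): 3 for i in range(25)}
        pairs.update({(f"b{i:02d}", f"y{i:02d}"): 3 for i in range(5)})
        mat = _mat_from_cells({"c1" + "A" * 14: pairs})
        out = assign_cells(mat, self.CLON)
        row = out.iloc[0]
        assert row["second_recall"] > 0.1
        assert row["status"] == "ambiguous/doublet"

    def test_min_umi_threshold_applies(self):
        pairs = {(f"a{i:02d}", f"x{i:02d}"): 1 for i in range(30)}
        mat = _mat_from_cells({"c1" + "A" * 14: pairs})
        out = assign_cells(mat, self.CLON, min_umi=2)
        assert out.iloc[0]["status"] == "low_capture"

    def test_permutation_invariance(self, sc_experiment):
        mat = sc_experiment["matrix"]
        rng = np.random.default_rng(3)
        pperm = rng.permutation(len(mat.pairs))
        cperm = rng.permutation(len(mat.cells))
        shuffled = BcCellMatrix(
            mat.matrix[pperm][:, cperm].tocsr(),
            [mat.pairs[i] for i in pperm], [mat.cells[i] for i in cperm])
        clons = sc_experiment["clonotypes"]
        a = assign_cells(mat, clons).sort_values("cell_bc").reset_index(drop=True)
        b = assign_cells(shuffled, clons).sort_values("cell_bc").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_accuracy_against_truth(self, sc_experiment):
        """>= 99% of assigned cells carry their true clone identity."""
        asg = sc_experiment["assignments"]
        truth = sc_experiment["cell_truth"].set_index("cell_bc")
        name_of = {cid: name for cid, (j, name)
                   in sc_experiment["best_match"].items()}
        assigned = asg[asg["status"] == "assigned"]
        assert len(assigned) > 1000
        ok = [name_of[r.clonotype_id]
              in truth.loc[r.cell_bc, "clone_ids"].split(",")
              for r in assigned.itertuples(index=False)]
        assert np.mean(ok) >= 0.99


# ------------------------------------------------------------ PR analysis

class TestPrAnalysis:
    def test_noise_free_perfect_precision(self):
        clon = [Clonotype("k0", frozenset((f"a{i:02d}", f"x{i:02d}")
                                          for i in range(10)), "bulk")]
        pairs = {(f"a{i:02d}", f"x{i:02d}"): 5 for i in range(10)}
        mat = _mat_from_cells({"c1" + "A" * 14: pairs})
        asg = assign_cells(mat, clon)
        pr = pr_threshold_analysis(mat, asg, clon, thresholds=range(1, 6))
        assert (pr["mean_precision"] == 1.0).all()

    def test_threshold_beyond_max_umi_zero_recall(self):
        clon = [Clonotype("k0", frozenset((f"a{i:02d}", f"x{i:02d}")
                                          for i in range(10)), "bulk")]
        pairs = {(f"a{i:02d}", f"x{i:02d}"): 3 for i in range(10)}
        mat = _mat_from_cells({"c1" + "A" * 14: pairs})
        asg = assign_cells(mat, clon)
        pr = pr_threshold_analysis(mat, asg, clon, thresholds=[20])
        assert pr["mean_recall"].iloc[0] == 0.0

    def test_monotonicity_on_ambient_spiked_data(self, small_state, cfg):
        """Ambient molecules live at ~1 UMI: mean precision is
        non-decreasing and mean recall non-increasing in the UMI threshold
        on a doublet-free, ambient-spiked simulation."""
        from shuffleseq.simulate import emit_t7_single_cell_reads
        from shuffleseq.singlecell import matrix_from_records
        records, _, _, _ = emit_t7_single_cell_reads(
            small_state, n_cells=400, capture_rate=0.8, umi_depth=6.0,
            ambient_rate=0.05, doublet_rate=0.0, seed=29,
            cells_per_event=0)
        mat = matrix_from_records(records, cfg)
        clons = reconstruct_clonotypes(mat, cfg)
        asg = assign_cells(mat, clons)
        pr = pr_threshold_analysis(mat, asg, clons)
        prec = pr["mean_precision"].to_numpy()
        rec = pr["mean_recall"].to_numpy()
        assert (np.diff(prec) >= -1e-12).all()
        assert (np.diff(rec) <= 1e-12).all()
        assert prec[1] > prec[0]  # the jump from 1 to 2 UMIs

    def test_recall_non_increasing_on_full_experiment(self, sc_experiment):
        pr = pr_threshold_analysis(sc_experiment["matrix"],
                                   sc_experiment["assignments"],
                                   sc_experiment["clonotypes"])
        rec = pr["mean_recall"].to_numpy()
        assert (np.diff(rec) <= 1e-12).all()
        assert pr["mean_precision"].iloc[1] > pr["mean_precision"].iloc[0]


# ------------------------------------------------------------ FASTQ route

class TestFastqRoute:
    def test_round_trip_preserves_umi_counts(self, small_state, cfg,
                                             tmp_path):
        from shuffleseq.simulate import emit_t7_single_cell_reads
        from shuffleseq.singlecell import records_from_fastq, write_sc_fastq
        records, _, _, wl = emit_t7_single_cell_reads(
            small_state, n_cells=20, capture_rate=0.8, umi_depth=4.0,
            ambient_rate=0.0, doublet_rate=0.0, seed=19)
        p1, p2 = write_sc_fastq(records, tmp_path / "t7")
        parsed = records_from_fastq(p1, p2, whitelist=set(wl))
        orig = (records.groupby(["cell_bc", "umi", "bc1", "bc2",
                                 "capture_side"], sort=True)["read_count"]
                .sum().reset_index())
        pd.testing.assert_frame_equal(parsed, orig)


# ------------------------------------------------------------ congruence

class TestScCalls:
    def test_congruent_call_from_own_clone(self, sc_experiment):
        state = sc_experiment["state"]
        calls = call_sc_rearrangements(
            sc_experiment["matrix"], state.insertions,
            sc_experiment["clonotypes"], sc_experiment["assignments"], 2)
        assert len(calls) > 0
        truth_pairs = set(zip(state.detectable_derivatives()["bc1"],
                              state.detectable_derivatives()["bc2"]))
        congruent = calls[calls["congruent"]]
        assert set(zip(congruent["bc1"], congruent["bc2"])) <= truth_pairs

    def test_zero_ambient_all_congruent(self, small_state, cfg):
        from shuffleseq.simulate import emit_t7_single_cell_reads
        from shuffleseq.singlecell import matrix_from_records
        records, truth, qc, _ = emit_t7_single_cell_reads(
            small_state, n_cells=400, capture_rate=0.9, umi_depth=8.0,
            ambient_rate=0.0, doublet_rate=0.0, seed=17)
        mat = matrix_from_records(records, cfg)
        clons = reconstruct_clonotypes(mat, cfg)
        asg = assign_cells(mat, clons)
        calls = call_sc_rearrangements(mat, small_state.insertions,
                                       clons, asg, 2)
        if len(calls):
            assert calls["congruent"].all()

    def test_incongruent_flagged_as_ambient(self, sc_experiment):
        """Rearranged pairs detected in a cell of a different clone are
        flagged; every truth-ambient novel-pair call is incongruent."""
        state = sc_experiment["state"]
        calls = call_sc_rearrangements(
            sc_experiment["matrix"], state.insertions,
            sc_experiment["clonotypes"], sc_experiment["assignments"], 2)
        truth = sc_experiment["cell_truth"].set_index("cell_bc")
        ev_by_clone = state.events.set_index("event_id")["clone_id"]
        dv = state.detectable_derivatives().set_index(["bc1", "bc2"])
        for row in calls.itertuples(index=False):
            host_clones = truth.loc[row.cell_bc, "clone_ids"].split(",")
            host_events = truth.loc[row.cell_bc, "event_ids"]
            ev = dv.loc[(row.bc1, row.bc2), "event_id"]
            ev = ev if isinstance(ev, str) else ev.iloc[0]
            if row.congruent:
                assert ev_by_clone[ev] in host_clones
            else:
                assert ev not in host_events.split(",")
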