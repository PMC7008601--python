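import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csfscreen import build_presence_matrix, group_peptide_stats, merge_replicates
from csfscreen.presence import round_half_up

from conftest import make_design, make_table


def random_rows(rng, samples, n_proteins=8, n_peptides=5, replicates=("r1", "r2"), p=0.4):
    """Random evidence rows: each (sample, protein, peptide, replicate) kept with prob p."""
    rows = []
    for sid in samples:
        for i in range(n_proteins):
            for j in range(n_peptides):
                for rep in replicates:
                    if rng.random() < p:
                        rows.append((sid, rep, f"P{i}", f"Protein {i}", f"G{i}", "A" * (j + 1) + "K"))
    return rows


class TestMergeReplicates:
    def test_union_keeps_single_replicate_evidence(self, two_group_design):
        table = make_table([("control01", "r1", "P1", "Protein 1", "G1", "PEPTIDEK")])
        merged = merge_replicates(table, "union", two_group_design)
        assert len(merged) == 1

    def test_intersection_drops_single_replicate_evidence(self, two_group_design):
        table = make_table([("control01", "r1", "P1", "Protein 1", "G1", "PEPTIDEK")])
        merged = merge_replicates(table, "intersection", two_group_design)
        assert len(merged) == 0

    def test_intersection_keeps_concordant_evidence(self, two_group_design):
        table = make_table([
            ("control01", "r1", "P1", "Protein 1", "G1", "PEPTIDEK"),
            ("control01", "r2", "P1", "Protein 1", "G1", "PEPTIDEK"),
        ])
        merged = merge_replicates(table, "intersection", two_group_design)
        assert len(merged) == 1

    def test_union_matches_brute_force_set_union(self):
        rng = np.random.default_rng(7)
        design = make_design({"control": 2, "case": 2})
        rows = random_rows(rng, design.sample_ids)
        table = make_table(rows)
        merged = merge_replicates(table, "union", design)
        # brute force: per sample, the set union over replicates
        expect = {
            sid: {(r[2], r[5]) for r in rows if r[0] == sid} for sid in design.sample_ids
        }
        got = {
            sid: set(
                zip(
                    merged.records[merged.records.sample_id == sid].protein_accession,
                    merged.records[merged.records.sample_id == sid].peptide_sequence,
                )
            )
            for sid in design.sample_ids
        }
        assert got == expect

    def test_union_presence_superset_of_intersection(self):
        rng = np.random.default_rng(11)
        design = make_design({"control": 3, "case": 3})
        table = make_table(random_rows(rng, design.sample_ids))
        mu = build_presence_matrix(merge_replicates(table, "union", design), design)
        mi = build_presence_matrix(merge_replicates(table, "intersection", design), design)
        common = mi.detected.index
        assert bool((mu.detected.loc[common] | ~mi.detected.loc[common]).all().all())


class TestPresenceMatrix:
    def test_hand_built_boolean_matrix(self):
        design = make_design({"g": 2}, control="g", replicates=("r1",))
        table = make_table([
            ("g01", "r1", "P1", "Protein 1", "G1", "AAK"),
            ("g01", "r1", "P2", "Protein 2", "G2", "CCK"),
            ("g02", "r1", "P2", "Protein 2", "G2", "DDK"),
            ("g02", "r1", "P3", "Protein 3", "G3", "EEK"),
        ])
        m = build_presence_matrix(table, design)
        assert m.detected.loc["P1"].tolist() == [True, False]
        assert m.detected.loc["P2"].tolist() == [True, True]
        assert m.detected.loc["P3"].tolist() == [False, True]

    def test_q_max_drops_high_q_records(self):
        design = make_design({"g": 1}, control="g", replicates=("r1",))
        table = make_table([("g01", "r1", "P1", "Protein 1", "G1", "AAK", 0.02)])
        m = build_presence_matrix(table, design, q_max=0.01)
        assert "P1" not in m.detected.index or not m.detected.loc["P1"].any()

    def test_lowering_q_max_never_adds_detections(self):
        rng = np.random.default_rng(5)
        design = make_design({"g": 3}, control="g", replicates=("r1",))
        rows = [
            (sid, "r1", f"P{i}", f"Protein {i}", f"G{i}", "A" * (j + 1) + "K",
             round(float(rng.uniform(0, 0.05)), 4))
            for sid in design.sample_ids for i in range(6) for j in range(3)
            if rng.random() < 0.5
        ]
        table = make_table(rows)
        loose = build_presence_matrix(table, design, q_max=0.04)
        tight = build_presence_matrix(table, design, q_max=0.01)
        shared = tight.detected.index.intersection(loose.detected.index)
        assert bool((loose.detected.loc[shared] | ~tight.detected.loc[shared]).all().all())
        assert set(tight.detected.index) <= set(loose.detected.index)

    def test_unknown_sample_is_hard_error(self, two_group_design):
        table = make_table([("ghost", "r1", "P1", "Protein 1", "G1", "AAK")])
        with pytest.raises(ValueError, match="ghost"):
            build_presence_matrix(table, two_group_design)

    def test_detected_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        design = make_design({"control": 2, "case": 2}, replicates=("r1",))
        rows = random_rows(rng, design.sample_ids, replicates=("r1",))
        table = make_table(rows)
        m = build_presence_matrix(table, design)
        for sid in design.sample_ids:
            expect = len({r[2] for r in rows if r[0] == sid})
            assert int(m.n_detected_per_sample()[sid]) == expect


class TestGroupPeptideStats:
    def test_five_patients_same_single_peptide(self):
        design = make_design({"pat": 5}, control="pat", replicates=("r1",))
        rows = [(sid, "r1", "P1", "Protein 1", "G1", "SAMEPEPK") for sid in design.sample_ids]
        m = build_presence_matrix(make_table(rows), design)
        s = group_peptide_stats(m, design, "P1", "pat")
        assert (s.n_detected, s.total_unique, s.mean_unique) == (5, 1, 1.0)

    def test_undetected_group_is_empty(self, two_group_design):
        rows = [("control01", "r1", "P1", "Protein 1", "G1", "AAK")]
        m = build_presence_matrix(make_table(rows), two_group_design)
        s = group_peptide_stats(m, two_group_design, "P1", "case")
        assert (s.n_detected, s.total_unique, s.mean_unique) == (0, 0, None)

    def test_unknown_group_is_hard_error(self, two_group_design):
        rows = [("control01", "r1", "P1", "Protein 1", "G1", "AAK")]
        m = build_presence_matrix(make_table(rows), two_group_design)
        with pytest.raises(ValueError, match="unknown group"):
            group_peptide_stats(m, two_group_design, "P1", "nope")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_union_and_mean_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        design = make_design({"g": 4}, control="g", replicates=("r1",))
        rows = random_rows(rng, design.sample_ids, n_proteins=3, replicates=("r1",), p=0.5)
        if not rows:
            return
        m = build_presence_matrix(make_table(rows), design)
        for acc in m.accessions:
            sets = {
                sid: {r[5] for r in rows if r[0] == sid and r[2] == acc}
                for sid in design.sample_ids
            }
            nonempty = [s for s in sets.values() if s]
            s = group_peptide_stats(m, design, acc, "g")
            assert s.n_detected == len(nonempty)
            assert s.total_unique == len(set().union(*nonempty)) if nonempty else s.total_unique == 0
            if nonempty:
                assert s.mean_unique == pytest.approx(np.mean([len(x) for x in nonempty]))
            assert s.n_detected <= design.group_size("g")
            assert s.total_unique <= sum(len(x) for x in nonempty)


@pytest.mark.parametrize(
    "value,expected",
    [(2.25, 2.3), (2.24, 2.2), (1.05, 1.1), (0.0, 0.0), (2.35, 2.4)],
)
def test_round_half_up_ties_go_up(value, expected):
    assert round_half_up(value, 1) == expected
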