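import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from csfscreen import (
    SelectionCriteria,
    apply_blocklist,
    check_positive_control,
    compute_overlap,
    default_blocklist,
    select_candidates,
)
from csfscreen.io import BlocklistRule
from csfscreen.presence import PresenceMatrix
from csfscreen.reference import build_candidate_fixture, build_overlap_fixture

from conftest import make_design


def matrix_from_bool(mat, design, prefix="P", names=None, genes=None):
    """Wrap a boolean numpy array (proteins x samples) as a PresenceMatrix
    with one placeholder peptide per detection."""
    accs = [f"{prefix}{i}" for i in range(mat.shape[0])]
    proteins = pd.DataFrame({
        "accession": accs,
        "name": names if names is not None else [f"Protein {a}" for a in accs],
        "gene_symbol": genes if genes is not None else accs,
    })
    detected = pd.DataFrame(mat, index=pd.Index(accs, name="accession"), columns=design.sample_ids)
    peptides = {
        (a, s): frozenset({f"PEP{a}"})
        for i, a in enumerate(accs)
        for j, s in enumerate(design.sample_ids)
        if mat[i, j]
    }
    return PresenceMatrix(proteins=proteins, samples=design.sample_ids, detected=detected, peptides=peptides)


class TestBlocklist:
    def test_albumin_name_substring_removed(self, two_group_design):
        m = matrix_from_bool(
            np.ones((2, 6), dtype=bool), two_group_design,
            names=["Serum albumin", "Glia-derived nexin"], genes=["XALBX", "SERPINE2"],
        )
        kept, removed = apply_blocklist(m, [BlocklistRule("name_substring", "albumin")])
        assert removed == ["P0"]
        assert kept.accessions == ["P1"]

    def test_empty_rule_list_is_identity(self, two_group_design):
        m = matrix_from_bool(np.ones((3, 6), dtype=bool), two_group_design)
        kept, removed = apply_blocklist(m, [])
        assert removed == [] and kept.accessions == m.accessions

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_partition_matches_brute_force_rule_scan(self, seed):
        rng = np.random.default_rng(seed)
        design = make_design({"control": 2, "case": 2}, replicates=("r1",))
        n = 12
        tokens = ["albumin", "keratin", "nexin", "oxidase"]
        names = [f"Protein with {tokens[rng.integers(4)]}" for _ in range(n)]
        genes = [["KRT1", "ALB", "SERPINE2", "NQO1"][rng.integers(4)] for _ in range(n)]
        m = matrix_from_bool(rng.random((n, 4)) < 0.5, design, names=names, genes=genes)
        rules = [BlocklistRule("name_substring", "Albumin"), BlocklistRule("gene_prefix", "KRT")]
        kept, removed = apply_blocklist(m, rules)
        assert sorted(kept.accessions + removed) == sorted(m.accessions)
        for acc, name, gene in zip(m.accessions, names, genes):
            expect = ("albumin" in name.lower()) or gene.startswith("KRT")
            assert (acc in removed) == expect


class TestSelectCandidates:
    def test_reference_table_pd_group_yields_no_candidates(self):
        matrix, design = build_candidate_fixture()
        assert select_candidates(matrix, design, SelectionCriteria(), "PD") == []

    def test_reference_table_serpine2_selected_for_ad(self):
        matrix, design = build_candidate_fixture()
        entries = select_candidates(matrix, design, SelectionCriteria(), "AD")
        top = entries[0]
        assert top.gene_symbol == "SERPINE2"
        assert top.stats["control"].n_detected == 0
        assert top.stats["AD"].n_detected == 8

    def test_patient_group_equal_to_control_is_error(self):
        matrix, design = build_candidate_fixture()
        with pytest.raises(ValueError, match="control"):
            select_candidates(matrix, design, SelectionCriteria(), "control")
        with pytest.raises(ValueError, match="unknown group"):
            select_candidates(matrix, design, SelectionCriteria(), "HD")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_selection_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        design = make_design({"control": 4, "case": 5}, replicates=("r1",))
        mat = rng.random((50, 9)) < rng.uniform(0.1, 0.7)
        m = matrix_from_bool(mat, design)
        crit = SelectionCriteria(max_control_detections=int(rng.integers(0, 3)),
                                 min_patient_fraction=float(rng.uniform(0.2, 1.0)))
        got = {e.accession for e in select_candidates(m, design, crit, "case")}
        min_count = max(1, math.ceil(crit.min_patient_fraction * 5))
        expect = set()
        for i, acc in enumerate(m.accessions):
            n_ctrl = mat[i, :4].sum()
            n_case = mat[i, 4:].sum()
            if n_ctrl <= crit.max_control_detections and n_case >= min_count:
                expect.add(acc)
        assert got == expect

    def test_threshold_relaxation_is_monotone(self):
        rng = np.random.default_rng(42)
        design = make_design({"control": 10, "case": 10}, replicates=("r1",))
        m = matrix_from_bool(rng.random((200, 20)) < 0.3, design)
        base = {e.accession for e in select_candidates(m, design, SelectionCriteria(1, 0.5), "case")}
        looser_ctrl = {e.accession for e in select_candidates(m, design, SelectionCriteria(2, 0.5), "case")}
        looser_pat = {e.accession for e in select_candidates(m, design, SelectionCriteria(1, 0.3), "case")}
        assert base <= looser_ctrl and base <= looser_pat

    def test_fully_relaxed_criteria_select_any_patient_detection(self):
        rng = np.random.default_rng(8)
        design = make_design({"control": 4, "case": 6}, replicates=("r1",))
        mat = rng.random((80, 10)) < 0.25
        m = matrix_from_bool(mat, design)
        crit = SelectionCriteria(max_control_detections=4, min_patient_fraction=1e-9)
        got = {e.accession for e in select_candidates(m, design, crit, "case")}
        expect = {m.accessions[i] for i in range(80) if mat[i, 4:].any()}
        assert got == expect


class TestOverlap:
    def test_identical_groups_are_fully_common(self):
        design = make_design({"a": 1, "b": 1, "c": 1}, control="a", replicates=("r1",))
        m = matrix_from_bool(np.ones((5, 3), dtype=bool), design)
        ov = compute_overlap(m, design)
        assert ov.region_counts["a&b&c"] == 5
        assert ov.percent_common == 100

    def test_reference_marginals_give_56_percent_common(self):
        matrix, design = build_overlap_fixture()
        ov = compute_overlap(matrix, design)
        assert ov.grand_total == 1854
        assert ov.region_counts["control&AD&PD"] == 1042
        assert ov.percent_common == 56
        assert ov.group_totals == {"control": 1342, "AD": 1562, "PD": 1281}

    def test_single_group_is_error(self):
        design = make_design({"a": 2}, control="a", replicates=("r1",))
        m = matrix_from_bool(np.ones((2, 2), dtype=bool), design)
        with pytest.raises(ValueError, match="2 groups"):
            compute_overlap(m, design)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_regions_match_brute_force_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        design = make_design({"a": 2, "b": 2, "c": 2}, control="a", replicates=("r1",))
        mat = rng.random((40, 6)) < 0.4
        m = matrix_from_bool(mat, design)
        ov = compute_overlap(m, design)
        sets = {
            g: {m.accessions[i] for i in range(40) if mat[i][[design.sample_ids.index(s) for s in design.samples_in(g)]].any()}
            for g in ("a", "b", "c")
        }
        for region, count in ov.region_counts.items():
            inside = set(region.split("&"))
            members = [
                acc for acc in m.accessions
                if {g for g in sets if acc in sets[g]} == inside
            ]
            assert count == len(members), region
        assert sum(ov.region_counts.values()) == ov.grand_total
        for g in ("a", "b", "c"):
            assert ov.group_totals[g] == sum(
                c for r, c in ov.region_counts.items() if g in r.split("&")
            )


class TestPositiveControl:
    def _matrix_with_spike(self, design, counts):
        accs = ["KLK6SYN"]
        proteins = pd.DataFrame({"accession": accs, "name": ["Kallikrein-6"], "gene_symbol": ["KLK6"]})
        detected = pd.DataFrame(
            [[c > 0 for c in counts]], index=pd.Index(accs, name="accession"), columns=design.sample_ids
        )
        peptides = {
            ("KLK6SYN", s): frozenset(f"PEP{i}" for i in range(c))
            for s, c in zip(design.sample_ids, counts) if c > 0
        }
        return PresenceMatrix(proteins=proteins, samples=design.sample_ids, detected=detected, peptides=peptides)

    def test_spiked_in_all_samples_passes(self, two_group_design):
        counts = [9, 13, 10, 11, 12, 9]
        m = self._matrix_with_spike(two_group_design, counts)
        qc = check_positive_control(m, "KLK6", min_peptides=9)
        assert qc.passed
        assert all(v["detected"] for v in qc.per_sample.values())

    def test_one_missing_sample_fails_and_is_flagged(self, two_group_design):
        m = self._matrix_with_spike(two_group_design, [9, 0, 10, 11, 12, 9])
        qc = check_positive_control(m, "KLK6", min_peptides=1)
        assert not qc.passed
        assert not qc.per_sample["control02"]["detected"]

    def test_min_peptides_above_all_counts_fails(self, two_group_design):
        m = self._matrix_with_spike(two_group_design, [9, 13, 10, 11, 12, 9])
        assert not check_positive_control(m, "KLK6", min_peptides=14).passed

    def test_absent_protein_fails_with_all_flags_false(self, two_group_design):
        m = self._matrix_with_spike(two_group_design, [9, 9, 9, 9, 9, 9])
        qc = check_positive_control(m, "NOPE", min_peptides=1)
        assert not qc.passed and not any(v["detected"] for v in qc.per_sample.values())
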