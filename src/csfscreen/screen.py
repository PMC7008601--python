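"""Blocklist filtering, the two-part candidate selection rule, group overlap
and the spiked positive-control QC.

The selection rule is frequency-based, not quantitative: a protein is a
candidate self-antigen for a patient group when it is (1) near-absent in the
control group — detected in at most ``max_control_detections`` control
individuals — and (2) recurrent in the patient group — detected in at least
``ceil(min_patient_fraction * group size)`` patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

from csfscreen.io import BlocklistRule, StudyDesign
from csfscreen.presence import (
    GroupPeptideStats,
    PresenceMatrix,
    group_peptide_stats,
    round_half_up,
)

__all__ = [
    "SelectionCriteria",
    "CandidateEntry",
    "CandidateReport",
    "OverlapSummary",
    "QCReport",
    "apply_blocklist",
    "select_candidates",
    "compute_overlap",
    "check_positive_control",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the two-part group-frequency rule.

    Defaults implement "detected in at most 1 control individual and in at
    least half of the patient group" (ceil for odd group sizes).
    """

    max_control_detections: int = 1
    min_patient_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.max_control_detections < 0:
            raise ValueError("max_control_detections must be non-negative")
        if not (0 < self.min_patient_fraction <= 1):
            raise ValueError("min_patient_fraction must be in (0, 1]")

    def min_patient_count(self, patient_group_size: int) -> int:
        return max(1, math.ceil(self.min_patient_fraction * patient_group_size))

    def validate_against(self, design: StudyDesign) -> None:
        n_ctrl = design.group_size(design.control_group)
        if self.max_control_detections > n_ctrl:
            raise ValueError(
                f"max_control_detections={self.max_control_detections} exceeds "
                f"control group size {n_ctrl}"
            )


@dataclass
class CandidateEntry:
    """One selected protein with per-group detection statistics."""

    accession: str
    name: str
    gene_symbol: str | None
    stats: dict[str, GroupPeptideStats]  # keyed by group label


@dataclass
class CandidateReport:
    """Candidate lists per patient group plus the criteria and blocklist audit.

    Candidate lists are sorted by descending patient-group detection count,
    ties broken by protein name.
    """

    per_group: dict[str, list[CandidateEntry]]
    criteria: SelectionCriteria
    group_order: list[str]
    n_removed_by_blocklist: int = 0
    removed_accessions: list[str] = field(default_factory=list)

    def n_candidates(self, group: str) -> int:
        return len(self.per_group[group])


@dataclass
class OverlapSummary:
    """Venn-style decomposition of group-level protein sets.

    ``region_counts`` holds all 2^k - 1 exclusive regions keyed by
    ``&``-joined group labels (design order); ``percent_common`` is
    100 x all-groups-common / grand total, rounded to the nearest integer.
    """

    group_totals: dict[str, int]
    region_counts: dict[str, int]
    grand_total: int
    percent_common: int

    def to_dict(self) -> dict:
        return {
            "group_totals": self.group_totals,
            "region_counts": self.region_counts,
            "grand_total": self.grand_total,
            "percent_common": self.percent_common,
        }


@dataclass
class QCReport:
    """Per-sample detection of the spiked positive-control protein."""

    control_protein: str
    min_peptides: int
    per_sample: dict[str, dict]  # sample_id -> {detected: bool, n_peptides: int}
    passed: bool

    def to_dict(self) -> dict:
        return {
            "control_protein": self.control_protein,
            "min_peptides": self.min_peptides,
            "per_sample": self.per_sample,
            "pass": self.passed,
        }


def apply_blocklist(
    matrix: PresenceMatrix, rules: list[BlocklistRule]
) -> tuple[PresenceMatrix, list[str]]:
    """Remove proteins matching any blocklist rule.

    Returns the filtered matrix and the removed accessions; together they
    partition the input protein set.  An empty rule list is the identity.
    """
    removed: list[str] = []
    kept: list[str] = []
    for _, row in matrix.proteins.iterrows():
        acc, name, gene = row["accession"], row["name"], row["gene_symbol"]
        gene = None if gene is None or (isinstance(gene, float)) else gene
        if any(r.matches(str(acc), str(name), gene) for r in rules):
            removed.append(acc)
        else:
            kept.append(acc)
    return matrix.subset(kept), removed


def select_candidates(
    matrix: PresenceMatrix,
    design: StudyDesign,
    criteria: SelectionCriteria,
    patient_group: str,
) -> list[CandidateEntry]:
    """Apply the two-part rule for one patient group against the control group.

    Returns exactly the proteins with control detections <=
    ``max_control_detections`` and patient-group detections >= the resolved
    minimum count, each annotated with stats for every study group.
    """
    if patient_group == design.control_group:
        raise ValueError("patient_group must differ from the control group")
    if patient_group not in design.group_labels:
        raise ValueError(f"unknown group label {patient_group!r}")
    criteria.validate_against(design)

    ctrl_samples = design.samples_in(design.control_group)
    pat_samples = design.samples_in(patient_group)
    min_count = criteria.min_patient_count(len(pat_samples))

    n_ctrl = matrix.detected[ctrl_samples].sum(axis=1)
    n_pat = matrix.detected[pat_samples].sum(axis=1)
    hits = matrix.detected.index[
        (n_ctrl <= criteria.max_control_detections) & (n_pat >= min_count)
    ]

    meta = matrix.proteins.set_index("accession")
    entries = []
    for acc in hits:
        stats = {
            g: group_peptide_stats(matrix, design, acc, g) for g in design.group_labels
        }
        gene = meta.loc[acc, "gene_symbol"]
        entries.append(
            CandidateEntry(
                accession=acc,
                name=str(meta.loc[acc, "name"]),
                gene_symbol=None if gene is None or isinstance(gene, float) else str(gene),
                stats=stats,
            )
        )
    entries.sort(key=lambda e: (-e.stats[patient_group].n_detected, e.name))
    return entries


def compute_overlap(matrix: PresenceMatrix, design: StudyDesign) -> OverlapSummary:
    """Count every exclusive Venn region of the group-level protein sets.

    A protein belongs to a group when it is detected in at least one of the
    group's samples (independently of candidate thresholds).
    """
    groups = list(design.group_labels)
    if len(groups) < 2:
        raise ValueError("overlap requires at least 2 groups")

    group_sets: dict[str, set] = {}
    for g in groups:
        members = design.samples_in(g)
        det = matrix.detected[members].any(axis=1)
        group_sets[g] = set(matrix.detected.index[det])

    region_counts: dict[str, int] = {}
    for k in range(1, len(groups) + 1):
        for combo in combinations(groups, k):
            inside = set.intersection(*(group_sets[g] for g in combo))
            outside = set.union(
                *(group_sets[g] for g in groups if g not in combo), set()
            ) if len(combo) < len(groups) else set()
            region_counts["&".join(combo)] = len(inside - outside)

    grand_total = len(set.union(*group_sets.values())) if group_sets else 0
    all_common = region_counts["&".join(groups)]
    percent_common = int(round_half_up(100.0 * all_common / grand_total, 0)) if grand_total else 0
    return OverlapSummary(
        group_totals={g: len(group_sets[g]) for g in groups},
        region_counts=region_counts,
        grand_total=grand_total,
        percent_common=percent_common,
    )


def check_positive_control(
    matrix: PresenceMatrix, control: str, min_peptides: int = 1
) -> QCReport:
    """Verify the spiked positive-control protein is seen in every sample.

    ``control`` may be the accession or the gene symbol.  Passes iff the
    protein is detected in all samples with at least ``min_peptides``
    distinct peptides; an absent protein fails with all flags false.
    """
    acc = None
    if control in set(matrix.accessions):
        acc = control
    else:
        genes = matrix.proteins.set_index("accession")["gene_symbol"]
        match = genes[genes == control]
        if len(match):
            acc = match.index[0]

    per_sample: dict[str, dict] = {}
    if acc is None:
        for sid in matrix.samples:
            per_sample[sid] = {"detected": False, "n_peptides": 0}
        return QCReport(control, min_peptides, per_sample, passed=False)

    ok = True
    for sid in matrix.samples:
        detected = bool(matrix.detected.loc[acc, sid])
        n_pep = len(matrix.peptide_set(acc, sid))
        per_sample[sid] = {"detected": detected, "n_peptides": n_pep}
        if not detected or n_pep < min_peptides:
            ok = False
    return QCReport(control, min_peptides, per_sample, passed=ok)
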