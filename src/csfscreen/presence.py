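"""Replicate merging and the protein x sample presence matrix.

Detection is presence/absence: a protein counts as detected in a sample when
at least ``min_peptides`` distinct peptide sequences survive replicate
merging and the optional q-value filter.  Peptide identity is the
modification-stripped uppercase sequence; protein identity is the accession
exactly as delivered by the upstream search (protein inference is not
re-done here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from csfscreen.io import IdentificationTable, StudyDesign, RECORD_COLUMNS

__all__ = [
    "PresenceMatrix",
    "GroupPeptideStats",
    "merge_replicates",
    "build_presence_matrix",
    "group_peptide_stats",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (2.25 -> 2.3), as printed reports do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GroupPeptideStats:
    """Per-protein detection summary within one study group.

    ``total_unique`` is the size of the union of peptide sets over the
    group's samples; ``mean_unique`` averages per-sample distinct-peptide
    counts over *detected* samples only (None when nothing is detected).
    ``peptide_detail`` is False when the source was presence-marks only, in
    which case peptide counts are placeholders and must not be reported.
    """

    n_detected: int
    total_unique: int
    mean_unique: float | None
    peptide_detail: bool = True


@dataclass
class PresenceMatrix:
    """Boolean protein x sample detection matrix with peptide sets.

    ``detected`` is indexed by accession with one column per sample id;
    ``peptides[(accession, sample_id)]`` holds the frozen set of distinct
    peptide sequences behind each detection.
    """

    proteins: pd.DataFrame  # columns: accession, name, gene_symbol
    samples: list[str]
    detected: pd.DataFrame  # bool, index accession, columns sample ids
    peptides: dict[tuple[str, str], frozenset]
    peptide_detail: bool = True

    @property
    def accessions(self) -> list[str]:
        return self.proteins["accession"].tolist()

    def peptide_set(self, accession: str, sample_id: str) -> frozenset:
        return self.peptides.get((accession, sample_id), frozenset())

    def n_detected_per_sample(self) -> pd.Series:
        return self.detected.sum(axis=0)

    def subset(self, keep: list[str]) -> "PresenceMatrix":
        keep_set = set(keep)
        proteins = self.proteins[self.proteins["accession"].isin(keep_set)].reset_index(drop=True)
        detected = self.detected.loc[proteins["accession"]]
        peptides = {k: v for k, v in self.peptides.items() if k[0] in keep_set}
        return PresenceMatrix(
            proteins=proteins,
            samples=list(self.samples),
            detected=detected,
            peptides=peptides,
            peptide_detail=self.peptide_detail,
        )

    def to_wide_tsv(self, path) -> None:
        """Export as an inspectable wide TSV of I/blank marks."""
        marks = self.detected.map(lambda b: "I" if b else "")
        out = self.proteins.set_index("accession").join(marks)
        out.to_csv(path, sep="\t", encoding="utf-8")


def merge_replicates(
    table: IdentificationTable,
    policy: str = "union",
    design: StudyDesign | None = None,
) -> IdentificationTable:
    """Collapse technical replicates to one evidence stream per sample.

    ``union`` keeps a (protein, peptide) pair seen in any replicate of a
    sample; ``intersection`` keeps it only when it appears in every replicate
    of that sample (the replicate set is taken from the study design when
    given, else from the replicates observed in the table).  The smallest
    q-value over the merged replicates is retained.
    """
    if policy not in ("union", "intersection"):
        raise ValueError(f"unknown replicate merge policy {policy!r}")
    df = table.records
    keys = ["sample_id", "protein_accession", "peptide_sequence"]

    if policy == "intersection":
        if design is not None:
            n_reps = {s.sample_id: len(s.replicate_ids) for s in design.samples}
            zero = [sid for sid, n in n_reps.items() if n == 0]
            if zero:
                raise ValueError(f"intersection merge impossible: samples with zero replicates: {zero}")
        else:
            n_reps = df.groupby("sample_id")["replicate_id"].nunique().to_dict()
        seen = df.groupby(keys)["replicate_id"].nunique().reset_index(name="n_seen")
        seen["n_need"] = seen["sample_id"].map(lambda s: n_reps.get(s, 1))
        concordant = seen.loc[seen["n_seen"] >= seen["n_need"], keys]
        df = df.merge(concordant, on=keys, how="inner")

    merged = (
        df.sort_values("q_value", na_position="last")
        .drop_duplicates(keys, keep="first")
        .assign(replicate_id="merged")
        .sort_values(keys)
        .reset_index(drop=True)
    )
    return IdentificationTable(
        records=merged[RECORD_COLUMNS], dialect=table.dialect, peptide_detail=table.peptide_detail
    )


def build_presence_matrix(
    table: IdentificationTable,
    design: StudyDesign,
    q_max: float | None = None,
    min_peptides: int = 1,
) -> PresenceMatrix:
    """Build the protein x sample presence matrix from merged evidence.

    Records with ``q_value`` above ``q_max`` are dropped first (records with
    no q-value pass).  A protein is detected in a sample iff at least
    ``min_peptides`` distinct peptide sequences remain.  The matrix covers
    every sample in the design and the union of proteins over all samples.
    """
    df = table.records
    unknown = set(df["sample_id"].unique()) - set(design.sample_ids)
    if unknown:
        raise ValueError(f"identification table references samples absent from design: {sorted(unknown)}")
    if q_max is not None:
        df = df[df["q_value"].isna() | (df["q_value"] <= q_max)]

    proteins = (
        df.drop_duplicates("protein_accession")[["protein_accession", "protein_name", "gene_symbol"]]
        .rename(columns={"protein_accession": "accession", "protein_name": "name"})
        .reset_index(drop=True)
    )
    accessions = proteins["accession"].tolist()
    samples = design.sample_ids

    grouped = df.groupby(["protein_accession", "sample_id"])["peptide_sequence"].agg(
        lambda s: frozenset(s)
    )
    row_of = {a: i for i, a in enumerate(accessions)}
    col_of = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((len(accessions), len(samples)), dtype=bool)
    peptides: dict[tuple[str, str], frozenset] = {}
    for (acc, sid), peps in grouped.items():
        if len(peps) >= min_peptides:
            peptides[(acc, sid)] = peps
            mat[row_of[acc], col_of[sid]] = True
    detected = pd.DataFrame(mat, index=pd.Index(accessions, name="accession"), columns=samples)
    return PresenceMatrix(
        proteins=proteins,
        samples=list(samples),
        detected=detected,
        peptides=peptides,
        peptide_detail=table.peptide_detail,
    )


def group_peptide_stats(
    matrix: PresenceMatrix, design: StudyDesign, protein: str, group: str
) -> GroupPeptideStats:
    """Detection count, union peptide count and mean per-sample unique
    peptides for one protein within one group (mean over detected samples)."""
    if protein not in set(matrix.accessions):
        raise ValueError(f"protein {protein!r} not in presence matrix")
    members = design.samples_in(group)  # raises on unknown group
    detected_sets = [
        matrix.peptide_set(protein, sid)
        for sid in members
        if bool(matrix.detected.loc[protein, sid])
    ]
    n_detected = len(detected_sets)
    if n_detected == 0:
        return GroupPeptideStats(0, 0, None, matrix.peptide_detail)
    union: set = set()
    for s in detected_sets:
        union |= s
    mean = float(np.mean([len(s) for s in detected_sets]))
    return GroupPeptideStats(
        n_detected=n_detected,
        total_unique=len(union),
        mean_unique=mean,
        peptide_detail=matrix.peptide_detail,
    )
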