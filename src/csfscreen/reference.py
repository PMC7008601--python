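"""Published reference values for the three-arm CSF autoantibody screen, and
builders that turn them into in-memory study fixtures.

The reference study compared 10 headache controls, 10 Alzheimer's (AD) and
10 Parkinson's (PD) patients.  ``CANDIDATE_TABLE`` carries the reported
per-group detection counts and unique-peptide statistics for the 16 AD
candidate antigens; ``VENN_MARGINALS`` the reported group-level antigen
totals after abundant-serum-protein removal; ``SEX_COUNTS`` the cohort's
female/male split.  The builders reconstruct presence matrices consistent
with these printed group-level numbers — per-sample detail below the group
level is synthetic (which samples carry a detection is arbitrary, peptide
sets reproduce group totals exactly and means only approximately).
"""

from __future__ import annotations

import pandas as pd

from csfscreen.io import SampleRecord, StudyDesign
from csfscreen.presence import PresenceMatrix

__all__ = [
    "CANDIDATE_TABLE",
    "VENN_MARGINALS",
    "SEX_COUNTS",
    "reference_design",
    "build_candidate_fixture",
    "venn_regions_from_marginals",
    "build_overlap_fixture",
]

_GROUPS = ("control", "AD", "PD")

# protein name, gene; then per group: n detected, total unique peptides,
# mean unique peptides (means as printed, 1 decimal)
_CANDIDATE_ROWS = [
    ("Glia-derived nexin", "SERPINE2", (0, 0, 0.0), (8, 7, 2.3), (3, 2, 1.0)),
    ("Fibromodulin", "FMOD", (0, 0, 0.0), (6, 4, 1.5), (0, 0, 0.0)),
    ("Quinone oxidoreductase", "NQO1", (0, 0, 0.0), (5, 1, 1.0), (3, 1, 1.0)),
    ("Cathepsin F", "CTSF", (1, 1, 1.0), (6, 5, 2.3), (1, 1, 1.0)),
    ("Cadherin-13", "CDH13", (1, 1, 1.0), (6, 5, 2.0), (1, 1, 1.0)),
    ("Phospholipase D4", "PLD4", (1, 1, 1.0), (6, 1, 1.0), (3, 1, 1.0)),
    ("Inositol 1,4,5-trisphosphate receptor type 1", "ITPR1", (1, 1, 1.0), (5, 6, 1.4), (0, 0, 0.0)),
    ("Sushi repeat-containing protein", "SRPX", (1, 1, 1.0), (5, 5, 1.8), (3, 1, 1.0)),
    ("Sarco/endoplasmic reticulum calcium ATPase 2", "ATP2A2", (1, 1, 1.0), (5, 5, 1.2), (2, 1, 1.0)),
    ("Oligodendrocyte-myelin glycoprotein", "OMG", (1, 1, 1.0), (5, 4, 1.4), (3, 1, 1.0)),
    ("4F2 cell-surface antigen heavy chain", "SLC3A2", (1, 1, 1.0), (5, 4, 1.2), (2, 1, 1.0)),
    ("WD repeat-containing protein 1", "WDR1", (1, 1, 1.0), (5, 3, 1.4), (2, 2, 1.5)),
    ("Isoaspartyl peptidase", "ASRGL1", (1, 1, 1.0), (5, 2, 1.4), (2, 1, 1.0)),
    ("Heterogeneous nuclear ribonucleoprotein H", "HNRNPH1", (1, 1, 1.0), (5, 2, 1.2), (1, 1, 1.0)),
    ("Metalloproteinase inhibitor 2", "TIMP2", (1, 1, 1.0), (5, 2, 1.2), (1, 1, 1.0)),
    ("Cerebellin-3", "CBLN3", (1, 1, 1.0), (5, 2, 1.0), (0, 0, 0.0)),
]

CANDIDATE_TABLE = pd.DataFrame(
    [
        {
            "protein_name": name,
            "gene_symbol": gene,
            **{
                f"{g}_{k}": v
                for g, triple in zip(_GROUPS, triples)
                for k, v in zip(("n_detected", "total_unique", "mean_unique"), triple)
            },
        }
        for (name, gene, *triples) in _CANDIDATE_ROWS
    ]
)

#: reported group-level antigen counts after blocklist removal
VENN_MARGINALS = {
    "group_totals": {"control": 1342, "AD": 1562, "PD": 1281},
    "group_unique": {"control": 137, "AD": 299, "PD": 129},
    "all_common": 1042,
    "grand_total": 1854,
}

#: females then males per group (n = 10 each)
SEX_COUNTS = {"control": (6, 4), "AD": (6, 4), "PD": (4, 6)}


def reference_design(n_per_group: int = 10) -> StudyDesign:
    """The three-arm layout of the reference cohort (no demographics)."""
    samples = tuple(
        SampleRecord(sample_id=f"{g}{i + 1:02d}", group=g, replicate_ids=("r1",))
        for g in _GROUPS
        for i in range(n_per_group)
    )
    return StudyDesign(samples=samples, group_labels=_GROUPS, control_group="control")


def _assign_peptides(n_detected: int, total_unique: int) -> list[frozenset]:
    """Per-sample peptide sets whose union has exactly ``total_unique``
    members, every detected sample holding at least one."""
    # distinct valid residue strings; identity only matters within a protein
    pool = ["A" * (j + 1) + "K" for j in range(total_unique)]
    sets = [set() for _ in range(n_detected)]
    for i in range(n_detected):
        sets[i].add(pool[i % total_unique])
    for j in range(n_detected, total_unique):
        sets[j % n_detected].add(pool[j])
    return [frozenset(s) for s in sets]


def build_candidate_fixture(n_per_group: int = 10) -> tuple[PresenceMatrix, StudyDesign]:
    """A presence matrix reproducing the reference candidate table's
    per-group detection counts and total unique peptides.

    Detections fill the first samples of each group; each protein's group
    peptide union has exactly the reported size (the same single peptide in
    all five detected AD samples for NQO1, as reported).
    """
    design = reference_design(n_per_group)
    accessions, names, genes = [], [], []
    detected = {}
    peptides: dict[tuple[str, str], frozenset] = {}
    for name, gene, *triples in _CANDIDATE_ROWS:
        acc = gene  # accession stands in for the gene symbol in this fixture
        accessions.append(acc)
        names.append(name)
        genes.append(gene)
        row = {}
        for g, (n_det, total, _mean) in zip(_GROUPS, triples):
            members = [f"{g}{i + 1:02d}" for i in range(n_per_group)]
            sets = _assign_peptides(n_det, total) if n_det else []
            for i, sid in enumerate(members):
                hit = i < n_det
                row[sid] = hit
                if hit:
                    peptides[(acc, sid)] = sets[i]
        detected[acc] = row
    proteins = pd.DataFrame({"accession": accessions, "name": names, "gene_symbol": genes})
    det = pd.DataFrame.from_dict(detected, orient="index")[design.sample_ids]
    det.index.name = "accession"
    matrix = PresenceMatrix(
        proteins=proteins,
        samples=design.sample_ids,
        detected=det,
        peptides=peptides,
        peptide_detail=True,
    )
    return matrix, design


def venn_regions_from_marginals(marginals: dict | None = None) -> dict[str, int]:
    """Solve the 7 exclusive three-set Venn regions from printed marginals.

    The reported group totals, group-unique counts, all-common count and
    grand total over-determine the three pairwise-only regions; the solution
    must be non-negative integers and reproduce the grand total, otherwise
    the marginals are inconsistent and a ValueError is raised.
    """
    m = marginals or VENN_MARGINALS
    (g1, t1), (g2, t2), (g3, t3) = m["group_totals"].items()
    u = m["group_unique"]
    core = m["all_common"]
    s1 = t1 - u[g1] - core  # (g1&g2 only) + (g1&g3 only)
    s2 = t2 - u[g2] - core
    s3 = t3 - u[g3] - core
    ab = (s1 + s2 - s3) // 2  # g1&g2 only
    ac = s1 - ab  # g1&g3 only
    bc = s2 - ab  # g2&g3 only
    regions = {
        g1: u[g1], g2: u[g2], g3: u[g3],
        f"{g1}&{g2}": ab, f"{g1}&{g3}": ac, f"{g2}&{g3}": bc,
        f"{g1}&{g2}&{g3}": core,
    }
    if min(regions.values()) < 0 or sum(regions.values()) != m["grand_total"]:
        raise ValueError("inconsistent Venn marginals")
    return regions


def build_overlap_fixture(marginals: dict | None = None) -> tuple[PresenceMatrix, StudyDesign]:
    """A presence matrix (one synthetic sample per group, presence-marks
    only) whose group-level protein sets realise the printed Venn marginals."""
    m = marginals or VENN_MARGINALS
    groups = list(m["group_totals"])
    regions = venn_regions_from_marginals(m)
    samples = tuple(
        SampleRecord(sample_id=f"{g}_pooled", group=g, replicate_ids=("r1",)) for g in groups
    )
    design = StudyDesign(samples=samples, group_labels=tuple(groups), control_group=groups[0])

    accessions, membership = [], []
    i = 0
    for region, count in regions.items():
        member_groups = set(region.split("&"))
        for _ in range(count):
            i += 1
            accessions.append(f"AG{i:05d}")
            membership.append(member_groups)
    proteins = pd.DataFrame(
        {"accession": accessions, "name": accessions, "gene_symbol": accessions}
    )
    det = pd.DataFrame(
        [[g in mem for g in groups] for mem in membership],
        index=pd.Index(accessions, name="accession"),
        columns=[s.sample_id for s in samples],
    )
    peptides = {
        (acc, f"{g}_pooled"): frozenset({f"PRESENCE:{acc}"})
        for acc, mem in zip(accessions, membership)
        for g in mem
    }
    matrix = PresenceMatrix(
        proteins=proteins,
        samples=[s.sample_id for s in samples],
        detected=det,
        peptides=peptides,
        peptide_detail=False,
    )
    return matrix, design
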