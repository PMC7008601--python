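"""End-to-end orchestration: read -> merge -> matrix -> blocklist -> select
-> overlap -> QC -> cohort stats -> reports."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from csfscreen.cohort import chi_square_counts, dunn_pairwise, kruskal_wallis
from csfscreen.io import (
    StudyDesign,
    default_blocklist,
    read_blocklist,
    read_identifications,
    read_manifest,
    write_reports,
)
from csfscreen.presence import build_presence_matrix, merge_replicates
from csfscreen.screen import (
    CandidateReport,
    SelectionCriteria,
    apply_blocklist,
    check_positive_control,
    compute_overlap,
    select_candidates,
)

__all__ = ["RunConfig", "run_screen", "run_cohort_stats"]

log = logging.getLogger("csfscreen")


@dataclass
class RunConfig:
    """Everything one reproducible screening run needs."""

    manifest: str
    identifications: str
    outdir: str
    blocklist: str | None = None  # None -> shipped default
    dialect: str = "long_tsv"
    merge_policy: str = "union"
    q_max: float | None = None
    min_peptides: int = 1
    max_control_detections: int = 1
    min_patient_fraction: float = 0.5
    control_protein: str = "KLK6"
    qc_min_peptides: int = 1
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")


def run_screen(config: RunConfig) -> dict:
    """Execute the full candidate screen and write all report files.

    Returns a summary dict with per-stage protein counts (total, after
    blocklist, candidates per patient group), the resolved criteria and the
    written file paths.  Outputs are deterministic for a fixed config.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    design = read_manifest(config.manifest)
    log.info("stage=manifest samples=%d groups=%s", len(design.samples), list(design.group_labels))

    table = read_identifications(config.identifications, dialect=config.dialect)
    log.info("stage=read records=%d dialect=%s", len(table), table.dialect)

    merged = merge_replicates(table, policy=config.merge_policy, design=design)
    matrix = build_presence_matrix(
        merged, design, q_max=config.q_max, min_peptides=config.min_peptides
    )
    n_total = len(matrix.accessions)
    log.info("stage=matrix proteins=%d samples=%d", n_total, len(matrix.samples))

    rules = read_blocklist(config.blocklist) if config.blocklist else default_blocklist()
    filtered, removed = apply_blocklist(matrix, rules)
    n_after = len(filtered.accessions)
    log.info("stage=blocklist kept=%d removed=%d", n_after, len(removed))

    criteria = SelectionCriteria(
        max_control_detections=config.max_control_detections,
        min_patient_fraction=config.min_patient_fraction,
    )
    per_group = {}
    counts = {}
    for group in design.patient_groups:
        entries = select_candidates(filtered, design, criteria, group)
        per_group[group] = entries
        counts[group] = len(entries)
        log.info(
            "stage=select group=%s candidates=%d (min_patient_count=%d, max_control=%d)",
            group, len(entries),
            criteria.min_patient_count(design.group_size(group)),
            criteria.max_control_detections,
        )
    report = CandidateReport(
        per_group=per_group,
        criteria=criteria,
        group_order=list(design.group_labels),
        n_removed_by_blocklist=len(removed),
        removed_accessions=removed,
    )

    overlap = compute_overlap(filtered, design)
    qc = check_positive_control(matrix, config.control_protein, config.qc_min_peptides)
    log.info("stage=overlap grand_total=%d percent_common=%d", overlap.grand_total, overlap.percent_common)
    log.info("stage=qc control=%s pass=%s", config.control_protein, qc.passed)

    paths = write_reports(report, overlap, qc, config.outdir)
    outdir = Path(config.outdir)
    removed_path = outdir / "removed_accessions.txt"
    removed_path.write_text("\n".join(removed) + ("\n" if removed else ""), encoding="utf-8")
    summary = {
        "n_proteins_total": n_total,
        "n_after_blocklist": n_after,
        "n_removed_by_blocklist": len(removed),
        "per_group_totals": overlap.group_totals,
        "candidates": counts,
        "criteria": {
            "max_control_detections": criteria.max_control_detections,
            "min_patient_fraction": criteria.min_patient_fraction,
            "min_patient_count": {
                g: criteria.min_patient_count(design.group_size(g))
                for g in design.patient_groups
            },
        },
        "qc_pass": qc.passed,
        "percent_common": overlap.percent_common,
        "paths": {k: str(v) for k, v in paths.items()} | {"removed": str(removed_path)},
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    return {"report": report, "overlap": overlap, "qc": qc, "summary": summary}


_CONTINUOUS_VARS = ["age", "mmse", "hy", "frssd"]


def run_cohort_stats(design: StudyDesign | RunConfig, outpath: str | Path | None = None) -> dict:
    """Demographic comparisons across study groups.

    Chi-square for sex; Kruskal-Wallis plus Dunn pairwise for each
    continuous variable present in at least two groups (missing values
    excluded).  Returns (and optionally writes) a JSON-able dict keyed by
    variable; empty with a warning when no demographics are present.
    """
    if isinstance(design, RunConfig):
        config = design
        design = read_manifest(config.manifest)
        if outpath is None:
            outpath = Path(config.outdir) / "cohort_stats.json"

    results: dict[str, dict] = {}
    groups = list(design.group_labels)

    if len(groups) >= 2:
        sexes = sorted({s.sex for s in design.samples if s.sex is not None})
        if len(sexes) >= 2:
            table = [
                [sum(1 for s in design.samples if s.group == g and s.sex == x) for x in sexes]
                for g in groups
            ]
            try:
                results["sex"] = chi_square_counts(table, variable="sex").to_dict()
            except ValueError as e:
                warnings.warn(f"sex comparison skipped: {e}", stacklevel=2)

        for var in _CONTINUOUS_VARS:
            values = {
                g: [getattr(s, var) for s in design.samples if s.group == g and getattr(s, var) is not None]
                for g in groups
            }
            values = {g: v for g, v in values.items() if v}
            if len(values) < 2:
                continue
            kw = kruskal_wallis(values, variable=var)
            dunn = dunn_pairwise(values, adjust="none", variable=var)
            results[var] = kw.to_dict() | {"pairwise": dunn.to_dict()["pairwise"]}
    else:
        warnings.warn("cohort stats need at least 2 groups; returning empty result", stacklevel=2)

    if not results:
        warnings.warn("no demographic variables available for comparison", stacklevel=2)
    if outpath is not None:
        Path(outpath).parent.mkdir(parents=True, exist_ok=True)
        Path(outpath).write_text(json.dumps(results, indent=2) + "\n", encoding="utf-8")
    return results
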