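"""Readers and writers for manifests, identification tables, blocklists and reports.

Two identification-table dialects are supported and normalised to one record
layout:

* ``long_tsv`` — one row per (sample, replicate, protein, peptide) with an
  optional ``q_value`` column carrying the upstream FDR.
* ``wide_presence`` — protein (and optionally peptide) rows with one column
  per sample whose cells are ``"I"`` (identified) or blank (absent), the
  dialect of deposited presence-mark spreadsheets.

A wide table without peptide rows records presence only; peptide-level
statistics downstream are reported as unavailable rather than fabricated.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleRecord",
    "StudyDesign",
    "IdentificationTable",
    "BlocklistRule",
    "read_manifest",
    "write_manifest",
    "read_identifications",
    "write_identifications",
    "read_blocklist",
    "write_blocklist",
    "default_blocklist",
    "write_reports",
]

#: canonical record columns, shared by both dialects after normalisation
RECORD_COLUMNS = [
    "sample_id",
    "replicate_id",
    "protein_accession",
    "protein_name",
    "gene_symbol",
    "peptide_sequence",
    "q_value",
]

_MANIFEST_DEMOGRAPHICS = ["sex", "age", "mmse", "hy", "frssd"]
_MANIFEST_REQUIRED = ["sample_id", "group", "replicates"]

# 20 standard residues; bracketed modification annotations allowed inline
_PEPTIDE_RE = re.compile(r"^(?:[ACDEFGHIKLMNPQRSTVWY]|\[[^\]]+\])+$")

_MATCH_TYPES = ("gene_prefix", "name_substring", "accession_exact")


@dataclass(frozen=True)
class SampleRecord:
    """One study participant and the technical replicates of their sample."""

    sample_id: str
    group: str
    replicate_ids: tuple[str, ...]
    sex: str | None = None
    age: float | None = None
    mmse: int | None = None
    hy: float | None = None
    frssd: int | None = None

    def __post_init__(self) -> None:
        if len(self.replicate_ids) == 0:
            raise ValueError(f"sample {self.sample_id!r} declares no replicates")
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise ValueError(f"sample {self.sample_id!r} has duplicate replicate ids")


@dataclass(frozen=True)
class StudyDesign:
    """Samples, their group labels and the designated control group."""

    samples: tuple[SampleRecord, ...]
    group_labels: tuple[str, ...]
    control_group: str

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_id in study design: {sorted(dupes)}")
        if self.control_group not in self.group_labels:
            raise ValueError(f"control group {self.control_group!r} not among group labels")
        for s in self.samples:
            if s.group not in self.group_labels:
                raise ValueError(f"sample {s.sample_id!r} has undeclared group {s.group!r}")
        for g in self.group_labels:
            if not any(s.group == g for s in self.samples):
                raise ValueError(f"declared group {g!r} has no samples")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def group_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.group
        raise KeyError(sample_id)

    def samples_in(self, group: str) -> list[str]:
        if group not in self.group_labels:
            raise ValueError(f"unknown group label {group!r}")
        return [s.sample_id for s in self.samples if s.group == group]

    def group_size(self, group: str) -> int:
        return len(self.samples_in(group))

    @property
    def patient_groups(self) -> list[str]:
        return [g for g in self.group_labels if g != self.control_group]


@dataclass
class IdentificationTable:
    """Peptide->protein evidence records, one row per observation.

    ``peptide_detail`` is False when the source carried presence marks only;
    ``peptide_sequence`` then holds a synthetic per-protein placeholder and
    peptide-level statistics must be suppressed downstream.
    """

    records: pd.DataFrame
    dialect: str = "long_tsv"
    peptide_detail: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"identification table missing columns: {missing}")
        self.records = self.records[RECORD_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class BlocklistRule:
    """One abundant-protein removal rule.

    ``gene_prefix`` matches the start of the gene symbol, ``name_substring``
    a case-insensitive substring of the protein name, ``accession_exact`` the
    accession verbatim.
    """

    match_type: str
    pattern: str

    def __post_init__(self) -> None:
        if self.match_type not in _MATCH_TYPES:
            raise ValueError(f"unknown blocklist match_type {self.match_type!r}")
        if not self.pattern:
            raise ValueError("blocklist rule pattern is empty")

    def matches(self, accession: str, name: str, gene: str | None) -> bool:
        if self.match_type == "gene_prefix":
            return bool(gene) and str(gene).startswith(self.pattern)
        if self.match_type == "name_substring":
            return self.pattern.lower() in str(name).lower()
        return accession == self.pattern


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: str | Path) -> StudyDesign:
    """Read a sample manifest TSV into a :class:`StudyDesign`.

    Required columns: ``sample_id``, ``group``, ``replicates`` (semicolon
    separated replicate ids).  Optional demographics: ``sex``, ``age``,
    ``mmse``, ``hy``, ``frssd``; blank cells become missing values.  The
    control group is the first group encountered named ``control`` if present,
    otherwise the first group in file order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"manifest {path} is empty") from None
    if df.empty:
        raise ValueError(f"manifest {path} has a header but no samples")

    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in _MANIFEST_REQUIRED + _MANIFEST_DEMOGRAPHICS]
    if unknown:
        warnings.warn(f"manifest {path}: ignoring unknown columns {unknown}", stacklevel=2)

    dupes = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample_id in manifest: {dupes}")

    def _opt(row: pd.Series, col: str, cast) -> object | None:
        if col not in df.columns:
            return None
        v = row[col]
        if pd.isna(v) or str(v).strip() == "":
            return None
        return cast(v)

    samples = []
    for _, row in df.iterrows():
        samples.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                replicate_ids=tuple(str(row["replicates"]).split(";")),
                sex=_opt(row, "sex", str),
                age=_opt(row, "age", float),
                mmse=_opt(row, "mmse", lambda v: int(float(v))),
                hy=_opt(row, "hy", float),
                frssd=_opt(row, "frssd", lambda v: int(float(v))),
            )
        )
    groups = list(dict.fromkeys(s.group for s in samples))
    control = "control" if "control" in groups else groups[0]
    return StudyDesign(samples=tuple(samples), group_labels=tuple(groups), control_group=control)


def write_manifest(design: StudyDesign, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in design.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "replicates": ";".join(s.replicate_ids),
                "sex": s.sex if s.sex is not None else "",
                "age": s.age if s.age is not None else "",
                "mmse": s.mmse if s.mmse is not None else "",
                "hy": s.hy if s.hy is not None else "",
                "frssd": s.frssd if s.frssd is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# identifications

_WIDE_ID_COLUMNS = ["protein_accession", "protein_name", "gene_symbol", "peptide_sequence"]


def _validate_peptides(seqs: pd.Series, where: str) -> None:
    bad = seqs.dropna()[~seqs.dropna().astype(str).str.match(_PEPTIDE_RE)]
    if len(bad):
        raise ValueError(
            f"{where}: invalid peptide sequence(s), e.g. {bad.iloc[0]!r} "
            "(expected uppercase standard residues with optional [mod] annotations)"
        )


def read_identifications(path: str | Path, dialect: str = "long_tsv") -> IdentificationTable:
    """Read an identification table in either dialect.

    ``long_tsv`` requires columns ``sample_id``, ``replicate_id``,
    ``protein_accession``, ``protein_name``, ``peptide_sequence``; optional
    ``gene_symbol`` and ``q_value``.  ``wide_presence`` takes protein
    identifier columns followed by one column per sample (optionally
    ``sample:replicate``) with cells ``"I"`` or blank; any other token is a
    hard error naming the offending row and column.
    """
    path = Path(path)
    if dialect == "long_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["sample_id", "replicate_id", "protein_accession", "protein_name", "peptide_sequence"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"long_tsv {path} missing required columns: {missing}")
        if "gene_symbol" not in df.columns:
            df["gene_symbol"] = pd.NA
        if "q_value" not in df.columns:
            df["q_value"] = np.nan
        df["q_value"] = pd.to_numeric(df["q_value"], errors="coerce")
        qv = df["q_value"].dropna()
        if ((qv < 0) | (qv > 1)).any():
            raise ValueError(f"long_tsv {path}: q_value outside [0, 1]")
        _validate_peptides(df["peptide_sequence"], f"long_tsv {path}")
        return IdentificationTable(records=df[RECORD_COLUMNS], dialect="long_tsv", peptide_detail=True)

    if dialect == "wide_presence":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        id_cols = [c for c in _WIDE_ID_COLUMNS if c in df.columns]
        if "protein_accession" not in id_cols:
            raise ValueError(f"wide_presence {path} missing protein_accession column")
        sample_cols = [c for c in df.columns if c not in id_cols]
        if not sample_cols:
            raise ValueError(f"wide_presence {path} has no sample columns")
        peptide_detail = "peptide_sequence" in id_cols

        marks = df[sample_cols].apply(lambda s: s.str.strip())
        invalid = (marks != "") & (marks != "I")
        if invalid.to_numpy().any():
            r, c = np.argwhere(invalid.to_numpy())[0]
            raise ValueError(
                f"wide_presence {path}: unexpected cell {marks.iloc[r, c]!r} "
                f"at row {r + 2}, column {sample_cols[c]!r} (expected 'I' or blank)"
            )

        long = df.melt(id_vars=id_cols, value_vars=sample_cols, var_name="column", value_name="mark")
        long = long[long["mark"].str.strip() == "I"].drop(columns="mark")
        split = long["column"].str.split(":", n=1, expand=True)
        long["sample_id"] = split[0]
        if split.shape[1] > 1:
            long["replicate_id"] = split[1].fillna("r1")
        else:
            long["replicate_id"] = "r1"
        long = long.drop(columns="column")
        if "protein_name" not in long.columns:
            long["protein_name"] = long["protein_accession"]
        if "gene_symbol" not in long.columns:
            long["gene_symbol"] = pd.NA
        if peptide_detail:
            _validate_peptides(long["peptide_sequence"], f"wide_presence {path}")
        else:
            # placeholder flagged by peptide_detail=False; never counted as a real peptide
            long["peptide_sequence"] = "PRESENCE:" + long["protein_accession"].astype(str)
        long["q_value"] = np.nan
        return IdentificationTable(
            records=long[RECORD_COLUMNS], dialect="wide_presence", peptide_detail=peptide_detail
        )

    raise ValueError(f"unknown identification dialect {dialect!r}")


def write_identifications(
    table: IdentificationTable, path: str | Path, dialect: str | None = None
) -> Path:
    """Write an identification table in the requested dialect (default: its own)."""
    path = Path(path)
    dialect = dialect or table.dialect
    df = table.records
    if dialect == "long_tsv":
        df.to_csv(path, sep="\t", index=False, encoding="utf-8")
        return path
    if dialect == "wide_presence":
        key_cols = ["protein_accession"]
        if table.peptide_detail:
            key_cols.append("peptide_sequence")
        col = df["sample_id"].astype(str)
        reps = df["replicate_id"].astype(str)
        if reps.nunique() > 1 or (reps != "r1").any():
            col = col + ":" + reps
        marks = (
            df.assign(column=col, mark="I")
            .pivot_table(index=key_cols, columns="column", values="mark", aggfunc="first")
            .fillna("")
        )
        marks.columns.name = None
        meta = (
            df.drop_duplicates("protein_accession")
            .set_index("protein_accession")[["protein_name", "gene_symbol"]]
        )
        wide = marks.reset_index().join(meta, on="protein_accession")
        ordered = ["protein_accession", "protein_name", "gene_symbol"] + (
            ["peptide_sequence"] if table.peptide_detail else []
        )
        wide = wide[ordered + [c for c in wide.columns if c not in ordered]]
        wide.to_csv(path, sep="\t", index=False, encoding="utf-8")
        return path
    raise ValueError(f"unknown identification dialect {dialect!r}")


# ---------------------------------------------------------------------------
# blocklist


def read_blocklist(path: str | Path) -> list[BlocklistRule]:
    """Read a blocklist file: one ``match_type<TAB>pattern`` rule per line.

    Lines starting with ``#`` and blank lines are ignored; rules are returned
    in file order.
    """
    rules: list[BlocklistRule] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"blocklist {path} line {lineno}: expected 'match_type<TAB>pattern'")
        match_type, pattern = parts
        if match_type not in _MATCH_TYPES:
            raise ValueError(f"blocklist {path} line {lineno}: unknown match_type {match_type!r}")
        rules.append(BlocklistRule(match_type=match_type, pattern=pattern))
    return rules


def write_blocklist(rules: Iterable[BlocklistRule], path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{r.match_type}\t{r.pattern}" for r in rules]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def default_blocklist() -> list[BlocklistRule]:
    """The shipped abundant-serum-protein blocklist.

    Encodes the eight families prone to non-specific bead binding in
    protein-G immunoprecipitation: hemoglobin, haptoglobin, hemopexin,
    immunoglobulins, keratins, apolipoproteins, serum albumin and complement.
    """
    with resources.as_file(
        resources.files("csfscreen.data") / "abundant_serum_blocklist.tsv"
    ) as p:
        return read_blocklist(p)


# ---------------------------------------------------------------------------
# reports


def _fmt_mean(value: float | None) -> str:
    from csfscreen.presence import round_half_up  # local import to avoid cycle

    if value is None:
        return "0.0"  # undetected group, printed as zero in the report table
    return f"{round_half_up(value, 1):.1f}"


def write_reports(candidates, overlap, qc, outdir: str | Path) -> dict[str, Path]:
    """Write the candidate TSV and the overlap / QC JSON files.

    The candidate table has one row per (patient group, candidate protein)
    with, for every study group, the number of individuals identified, the
    total unique peptides and the mean unique peptides (1 decimal, half-up;
    ``NA`` when the source carried presence marks only).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise ValueError(f"cannot create output directory {outdir}: {e}") from e

    rows = []
    groups = candidates.group_order
    for patient_group, entries in candidates.per_group.items():
        for cand in entries:
            row: dict[str, object] = {
                "patient_group": patient_group,
                "protein_accession": cand.accession,
                "protein_name": cand.name,
                "gene_symbol": cand.gene_symbol if cand.gene_symbol else "",
            }
            for g in groups:
                st = cand.stats[g]
                row[f"{g}_n_identified"] = st.n_detected
                row[f"{g}_total_unique"] = st.total_unique if st.peptide_detail else "NA"
                row[f"{g}_mean_unique"] = _fmt_mean(st.mean_unique) if st.peptide_detail else "NA"
            rows.append(row)
    columns = ["patient_group", "protein_accession", "protein_name", "gene_symbol"]
    for g in groups:
        columns += [f"{g}_n_identified", f"{g}_total_unique", f"{g}_mean_unique"]
    cand_path = outdir / "candidates.tsv"
    pd.DataFrame(rows, columns=columns).to_csv(cand_path, sep="\t", index=False, encoding="utf-8")

    overlap_path = outdir / "overlap.json"
    overlap_path.write_text(json.dumps(overlap.to_dict(), indent=2) + "\n", encoding="utf-8")
    qc_path = outdir / "qc.json"
    qc_path.write_text(json.dumps(qc.to_dict(), indent=2) + "\n", encoding="utf-8")
    return {"candidates": cand_path, "overlap": overlap_path, "qc": qc_path}
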