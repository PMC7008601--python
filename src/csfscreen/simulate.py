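"""Seeded generator of synthetic antibody-capture MS studies.

Each protein class has a per-sample Bernoulli detection probability:

* background proteins — common probability ``p_bg`` in every sample,
* enriched proteins (per patient group) — ``p_enriched`` in their target
  group, ``p_ctrl_low`` everywhere else,
* contaminants — ``p_contam`` everywhere, named so the default
  abundant-serum blocklist removes them by construction,
* the spiked positive control — present in every sample with a uniform
  peptide count in ``spike_peptide_range``.

Per detection, the distinct-peptide count is 1 + Poisson(peptide_mean - 1),
drawn without replacement from a fixed per-protein peptide pool so that
group-level peptide unions are meaningful.  Each peptide observation lands
in all technical replicates with probability ``replicate_concordance`` and
in one random replicate otherwise, so both merge policies are exercised.

Default sizes emulate a three-arm CSF cohort (10 control, 10 + 10 patients)
whose per-sample detected-protein counts fall in the high hundreds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from csfscreen.io import IdentificationTable, RECORD_COLUMNS, SampleRecord, StudyDesign

__all__ = ["SimulationConfig", "generate_study", "score_recovery"]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# one synthetic name per abundant-serum family; every name contains a
# substring matched by the shipped blocklist
_CONTAMINANT_FAMILIES = [
    ("Hemoglobin subunit synthetic {i}", "HBS{i}"),
    ("Haptoglobin-related synthetic {i}", "HPS{i}"),
    ("Hemopexin-like synthetic {i}", "HPXS{i}"),
    ("Immunoglobulin heavy synthetic {i}", "IGHS{i}"),
    ("Keratin, type synthetic K{i}", "KRTS{i}"),
    ("Apolipoprotein synthetic {i}", "APOS{i}"),
    ("Serum albumin synthetic {i}", "ALBS{i}"),
    ("Complement component synthetic {i}", "C9S{i}"),
]


@dataclass
class SimulationConfig:
    """Study layout and detection-probability parameters (all seeded)."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 10, "AD": 10, "PD": 10}
    )
    control_group: str = "control"
    n_background: int = 2500
    p_bg: float = 0.35
    n_enriched: int = 50  # per patient group
    p_ctrl_low: float = 0.02
    p_enriched: float = 0.8
    n_contaminant: int = 60
    p_contam: float = 0.9
    replicates_per_sample: int = 2
    replicate_concordance: float = 0.8
    peptide_mean: float = 2.0  # mean of the 1 + Poisson(mean - 1) peptide-count law
    peptide_pool_size: int = 6
    spike_control: bool = True
    spike_peptide_range: tuple[int, int] = (9, 13)
    demographics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_bg, self.p_ctrl_low, self.p_enriched, self.p_contam,
                  self.replicate_concordance):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_background, self.n_enriched, self.n_contaminant) < 0:
            raise ValueError("protein counts must be non-negative")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.peptide_mean < 1:
            raise ValueError("peptide_mean must be >= 1")
        if self.control_group not in self.group_sizes:
            raise ValueError("control_group missing from group_sizes")
        if self.n_enriched > 0 and len(self.group_sizes) < 2:
            raise ValueError("enriched proteins require at least one patient group")

    @property
    def patient_groups(self) -> list[str]:
        return [g for g in self.group_sizes if g != self.control_group]


def _random_peptides(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    return ["".join(rng.choice(_AA, size=length)) for _ in range(n)]


def _make_design(config: SimulationConfig, rng: np.random.Generator) -> StudyDesign:
    samples = []
    rep_ids = tuple(f"r{i + 1}" for i in range(config.replicates_per_sample))
    for group, size in config.group_sizes.items():
        is_ctrl = group == config.control_group
        for i in range(size):
            sid = f"{group}{i + 1:02d}"
            demo: dict = {}
            if config.demographics:
                demo["sex"] = "F" if rng.random() < 0.5 else "M"
                demo["age"] = round(float(rng.normal(44 if is_ctrl else 75, 5)), 1)
                demo["mmse"] = int(np.clip(rng.normal(28 if is_ctrl else 19, 1 if is_ctrl else 4), 0, 30))
                if not is_ctrl:
                    demo["frssd"] = int(np.clip(rng.normal(11, 4), 0, 27))
                if group.upper().startswith("PD"):
                    demo["hy"] = float(rng.integers(2, 7)) / 2.0
            samples.append(SampleRecord(sample_id=sid, group=group, replicate_ids=rep_ids, **demo))
    return StudyDesign(
        samples=tuple(samples),
        group_labels=tuple(config.group_sizes),
        control_group=config.control_group,
    )


def generate_study(
    config: SimulationConfig,
) -> tuple[StudyDesign, IdentificationTable, dict[str, str]]:
    """Generate a complete synthetic study, deterministically from the seed.

    Returns the design, a long-format identification table (one row per
    sample/replicate/protein/peptide) and per-protein truth labels:
    ``background``, ``enriched:<group>``, ``contaminant`` or ``control``.
    """
    rng = np.random.default_rng(config.seed)
    design = _make_design(config, rng)
    sample_groups = {s.sample_id: s.group for s in design.samples}
    sample_ids = design.sample_ids
    n_samples = len(sample_ids)

    proteins: list[tuple[str, str, str | None, str]] = []  # acc, name, gene, truth
    probs: list[np.ndarray] = []  # per-sample detection probability

    group_vec = np.array([sample_groups[s] for s in sample_ids])
    for i in range(config.n_background):
        proteins.append((f"BG{i + 1:05d}", f"Background protein {i + 1}", f"BGP{i + 1}", "background"))
        probs.append(np.full(n_samples, config.p_bg))
    for g in config.patient_groups:
        for i in range(config.n_enriched):
            proteins.append(
                (f"EN{g}{i + 1:04d}", f"Enriched protein {g} {i + 1}", f"EN{g}{i + 1}", f"enriched:{g}")
            )
            p = np.where(group_vec == g, config.p_enriched, config.p_ctrl_low)
            probs.append(p)
    for i in range(config.n_contaminant):
        name_tpl, gene_tpl = _CONTAMINANT_FAMILIES[i % len(_CONTAMINANT_FAMILIES)]
        proteins.append(
            (f"CT{i + 1:04d}", name_tpl.format(i=i + 1), gene_tpl.format(i=i + 1), "contaminant")
        )
        probs.append(np.full(n_samples, config.p_contam))
    if config.spike_control:
        proteins.append(("KLK6SYN", "Kallikrein-6 synthetic spike", "KLK6", "control"))
        probs.append(np.full(n_samples, 1.0))

    detected = rng.random((len(proteins), n_samples)) < np.asarray(probs)

    lo, hi = config.spike_peptide_range
    rows: list[tuple] = []
    rep_ids = [f"r{i + 1}" for i in range(config.replicates_per_sample)]
    for pi, (acc, name, gene, truth_label) in enumerate(proteins):
        hit_samples = np.flatnonzero(detected[pi])
        if hit_samples.size == 0:
            continue
        is_spike = truth_label == "control"
        pool_size = hi if is_spike else config.peptide_pool_size
        pool = _random_peptides(rng, pool_size)
        for si in hit_samples:
            sid = sample_ids[si]
            if is_spike:
                n_pep = int(rng.integers(lo, hi + 1))
            else:
                n_pep = 1 + int(rng.poisson(config.peptide_mean - 1.0))
                n_pep = min(n_pep, pool_size)
            peps = rng.choice(pool, size=n_pep, replace=False)
            q = round(float(rng.uniform(0.0, 0.01)), 5)
            for pep in peps:
                if rng.random() < config.replicate_concordance:
                    reps = rep_ids
                else:
                    reps = [rep_ids[int(rng.integers(len(rep_ids)))]]
                for rep in reps:
                    rows.append((sid, rep, acc, name, gene, pep, q))

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    table = IdentificationTable(records=records, dialect="long_tsv", peptide_detail=True)
    truth = {acc: label for acc, _, _, label in proteins}
    return design, table, truth


def score_recovery(report, truth: dict[str, str]) -> dict[str, dict[str, float | None]]:
    """Sensitivity and false-candidate rate of a candidate report vs truth.

    Per patient group: sensitivity = selected enriched-for-that-group /
    total enriched-for-that-group; false-candidate rate = selected
    background / total background.  ``None`` when a class is absent.
    """
    n_background = sum(1 for v in truth.values() if v == "background")
    scores: dict[str, dict[str, float | None]] = {}
    for group, entries in report.per_group.items():
        selected = {e.accession for e in entries}
        missing = selected - set(truth)
        if missing:
            raise ValueError(f"candidates not in truth labels: {sorted(missing)[:5]}")
        enriched = {a for a, v in truth.items() if v == f"enriched:{group}"}
        scores[group] = {
            "sensitivity": (len(selected & enriched) / len(enriched)) if enriched else None,
            "false_candidate_rate": (
                len({a for a in selected if truth[a] == "background"}) / n_background
            ) if n_background else None,
        }
    return scores
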