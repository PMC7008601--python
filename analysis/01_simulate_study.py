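#!/usr/bin/env python
"""Generate the default synthetic three-arm CSF study and write it to disk.

Emulates a cohort of 10 controls, 10 AD and 10 PD samples with ~2,600
proteins (background, group-enriched, abundant-serum contaminants, and a
spiked kallikrein-6 positive control), technical duplicates, and seeded
determinism.  Outputs: manifest, long-format identification TSV and truth
labels under results/synthetic_study/.
"""

from pathlib import Path

from csfscreen import SimulationConfig, generate_study, write_identifications, write_manifest

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"


def main(seed: int = 1) -> None:
    config = SimulationConfig(seed=seed)
    design, table, truth = generate_study(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_manifest(design, OUT / "manifest.tsv")
    write_identifications(table, OUT / "identifications.tsv", dialect="long_tsv")
    with open(OUT / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("protein_accession\tlabel\n")
        for acc, label in truth.items():
            fh.write(f"{acc}\t{label}\n")
    print(f"samples: {len(design.samples)} in groups {list(design.group_labels)}")
    print(f"evidence records: {len(table)}")
    print(f"proteins: {len(truth)} "
          f"(background {sum(v == 'background' for v in truth.values())}, "
          f"contaminant {sum(v == 'contaminant' for v in truth.values())})")
    print(f"wrote {OUT}/manifest.tsv, identifications.tsv, truth.tsv")


if __name__ == "__main__":
    main()
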