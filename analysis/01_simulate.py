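"""Generate the synthetic study inputs.

Produces, under results/simulation/: a new checklist (~5,000 names) as a
Darwin Core Archive, an old backbone missing 10% of its species-group
names, a 5,000-record occurrence stream with the default corruption mix,
the per-occurrence ground truth, and the deletion manifest that later
steps use as their oracle.
"""

import sys
from pathlib import Path

from backbonekit import SimConfig, degrade_backbone, generate_checklist, generate_occurrences, write_dwca

SEED = 20210601 % (2**31)
OUT = Path(__file__).resolve().parent.parent / "results" / "simulation"


def main() -> None:
    config = SimConfig(seed=SEED)
    checklist = generate_checklist(config)
    old, manifest = degrade_backbone(checklist, config)
    occurrences, truth = generate_occurrences(checklist, 5000, config, old)

    OUT.mkdir(parents=True, exist_ok=True)
    write_dwca(checklist, OUT / "new_checklist")
    write_dwca(old, OUT / "old_backbone")
    with open(OUT / "occurrences.tsv", "w", encoding="utf-8") as fh:
        fh.write("occurrenceID\tscientificName\n")
        for o in occurrences:
            fh.write(f"{o.occurrence_id}\t{o.verbatim_name}\n")
    with open(OUT / "ground_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write(
            "occurrenceID\ttrueTaxonID\tcorruptionClass\texpectedNewRank\texpectedOldRank\texpectedInterpretedID\n"
        )
        for t in truth:
            fh.write(
                f"{t.occurrence_id}\t{t.true_taxon_id}\t{t.corruption_class}\t"
                f"{t.expected_new_rank}\t{t.expected_old_rank}\t{t.expected_interpreted_id}\n"
            )
    (OUT / "deletion_manifest.txt").write_text("\n".join(manifest) + "\n", encoding="utf-8")

    print(f"checklist: {len(checklist)} names ({OUT / 'new_checklist'})")
    print(f"old backbone: {len(old)} names ({len(manifest)} deleted)")
    print(f"occurrences: {len(occurrences)} rows, ground truth alongside")


if __name__ == "__main__":
    sys.exit(main())
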