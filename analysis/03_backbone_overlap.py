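"""Comparison 2: name overlap between the old backbone and the new checklist.

Counts names (canonical + authorship) present in both, newly added by
the checklist, and present only in the old backbone; verifies the added
count against the deletion manifest; and lists the genera contributing
the most new names.  Writes results/tables/overlap.json and
per_genus_new_names.tsv.
"""

import json
import sys
from pathlib import Path

from backbonekit import build_backbone, name_overlap, per_genus_new_names, read_dwca

SIM = Path(__file__).resolve().parent.parent / "results" / "simulation"
OUT = Path(__file__).resolve().parent.parent / "results" / "tables"
THRESHOLD = 10  # per-genus new-name filter for the table


def main() -> None:
    old = build_backbone(read_dwca(SIM / "old_backbone"))
    new = read_dwca(SIM / "new_checklist")
    manifest = (SIM / "deletion_manifest.txt").read_text(encoding="utf-8").split()
    report = name_overlap(old, new)
    top = per_genus_new_names(report, THRESHOLD)

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "overlap.json").write_text(
        json.dumps(
            {
                "in_both": report.in_both,
                "added_from_checklist": report.added_from_checklist,
                "other_sources_only": report.other_sources_only,
                "added_equals_deletion_manifest": report.added_from_checklist == len(manifest),
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    (OUT / "per_genus_new_names.tsv").write_text(
        "genus\tnew_names\n" + "".join(f"{g}\t{n}\n" for g, n in top.items()),
        encoding="utf-8",
    )

    print(f"names in both: {report.in_both}")
    print(f"added by the checklist: {report.added_from_checklist} "
          f"(matches deletion manifest: {report.added_from_checklist == len(manifest)})")
    print(f"old-backbone only: {report.other_sources_only}")
    print(f"genera with > {THRESHOLD} new names: {len(top)}")


if __name__ == "__main__":
    sys.exit(main())
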