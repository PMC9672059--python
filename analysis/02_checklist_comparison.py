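"""Comparison 1: two checklist versions, category by category.

Summarises the old and new checklists (accepted genera / species /
subspecies / varieties / forms, pooled synonyms, unplaced apart) and
tabulates the per-category absolute differences and their total — the
headline "number of differences recorded" between versions.
Writes results/tables/checklist_summary.tsv and checklist_diff.tsv.
"""

import sys
from pathlib import Path

from backbonekit import diff_summaries, read_dwca, summarize
from backbonekit.metrics import CATEGORIES

SIM = Path(__file__).resolve().parent.parent / "results" / "simulation"
OUT = Path(__file__).resolve().parent.parent / "results" / "tables"


def main() -> None:
    old = read_dwca(SIM / "old_backbone")
    new = read_dwca(SIM / "new_checklist")
    s_old, s_new = summarize(old), summarize(new)
    diff = diff_summaries(s_old, s_new)

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "checklist_summary.tsv", "w", encoding="utf-8") as fh:
        fh.write("category\told\tnew\tdifference\n")
        co, cn = s_old.category_counts(), s_new.category_counts()
        for cat in CATEGORIES:
            fh.write(f"{cat}\t{co[cat]}\t{cn[cat]}\t{diff.per_category_difference[cat]}\n")
        fh.write(f"total\t\t\t{diff.total_difference}\n")
    (OUT / "checklist_diff.tsv").write_text(
        "category\tabsolute\tsigned\n"
        + "".join(
            f"{c}\t{diff.per_category_difference[c]}\t{diff.signed_difference[c]}\n"
            for c in CATEGORIES
        ),
        encoding="utf-8",
    )

    print(f"old version: {s_old.total_records} records, new version: {s_new.total_records}")
    for cat in CATEGORIES:
        print(f"  {cat:<12} {co[cat]:>6} -> {cn[cat]:>6}  (|diff| {diff.per_category_difference[cat]})")
    print(f"total differences across categories: {diff.total_difference}")


if __name__ == "__main__":
    sys.exit(main())
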