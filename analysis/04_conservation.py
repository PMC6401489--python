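#!/usr/bin/env python
"""How robust are the inhibitions across growth media?

Partitions the union edges into their Venn cells over the three media,
reports the conserved-in->=2 and conserved-in-all-3 counts, classifies the
reciprocal pairs by single- vs multi-medium support, and measures the
nonhierarchical (mutual-inhibition) fraction. Writes results/venn.tsv and
results/conservation.json.
"""

import json
from pathlib import Path

import pandas as pd

import inhibnet as ih
from inhibnet.conservation import conservation_report

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data" / "fixture"


def main() -> None:
    paths = {p.stem: p for p in sorted(DATA.glob("*.tsv"))}
    tensor = ih.read_tensor(paths)
    block = conservation_report(tensor)

    (ROOT / "results" / "conservation.json").write_text(
        json.dumps(block, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    pd.DataFrame(list(block["venn_counts"].items()),
                 columns=["conditions", "count"]).to_csv(
        ROOT / "results" / "venn.tsv", sep="\t", index=False)

    total = block["n_union_edges"]
    c2 = block["conserved_at_least"]["2"]
    c3 = block["conserved_at_least"]["3"]
    nh = block["nonhierarchical"]
    print(f"{total} union inhibitions across "
          f"{len(block['conditions'])} media")
    print(f"conserved on >=2 media: {c2['count']} ({c2['percent']}%); "
          f"on all 3: {c3['count']}")
    print(f"nonhierarchical (reciprocal) edges: {nh['edge_count']} "
          f"({nh['percent']}%)")
    for entry in block["reciprocal_classes"]:
        print(f"  reciprocal pair {entry['pair'][0]}<->{entry['pair'][1]}: "
              f"{entry['class']}")


if __name__ == "__main__":
    main()
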