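#!/usr/bin/env python
"""Global network statistics of the study-scale screen.

Reads the fixture matrices written by 01_simulate_screen.py, builds the
union network, and reports connectance, sender-receiver asymmetry Q,
degree/partner summaries, and reciprocal pairs. Findings land in
results/network_stats.json.
"""

import json
from pathlib import Path

import inhibnet as ih

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data" / "fixture"


def main() -> None:
    paths = {p.stem: p for p in sorted(DATA.glob("*.tsv"))}
    tensor = ih.read_tensor(paths)
    network = ih.union_network(tensor)
    stats = ih.network_stats(network)

    out = ROOT / "results" / "network_stats.json"
    out.write_text(json.dumps(stats.to_dict(), indent=2, sort_keys=True)
                   + "\n", encoding="utf-8")

    d = stats.to_dict()
    print(f"{stats.n_species} strains, {stats.n_edges} directed inhibitions")
    print(f"connectance C = {d['connectance_reported']} "
          f"({stats.n_edges}/{stats.n_species ** 2})")
    print(f"sender-receiver asymmetry Q = {stats.asymmetry_q:+.2f} "
          f"({'producer' if stats.asymmetry_q < 0 else 'receiver'}-"
          f"determined)")
    print(f"mean distinct partners per strain = "
          f"{d['mean_partner_count_reported']}")
    print(f"reciprocal pairs: {len(stats.reciprocal_pairs)} -> {out}")


if __name__ == "__main__":
    main()
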