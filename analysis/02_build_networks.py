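"""Build the three association networks from a survey CSV.

For each network kind (identity-by-identity, behaviour-by-identity,
identity-by-behaviour): derive the binary occurrence matrix, apply the
node-frequency filter (keep nodes observed more than 3 times), and compute
Simple-Ratio-Index edge weights. Writes, per network, the filtered edge
list and the occurrence matrix, plus a node-count table (unfiltered vs
filtered, the package's analogue of a network-size summary).
"""

import argparse
from pathlib import Path

import pandas as pd

from cooccurnet.association import build_network
from cooccurnet.occurrence import KINDS, build_occurrence
from cooccurnet.survey_io import filter_items, read_survey


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/data/survey_structured.csv"))
    ap.add_argument("--threshold", type=int, default=3)
    ap.add_argument("--out", type=Path, default=Path("results/networks"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    dataset = read_survey(args.input)
    rows = []
    for kind in KINDS:
        occ_full = build_occurrence(dataset, kind)
        retained = filter_items(occ_full.col_total_map(), args.threshold)
        if not retained:
            print(f"{kind}: no nodes survive the filter at threshold {args.threshold}")
            rows.append({"network": kind, "unfiltered": len(occ_full.cols), "filtered": 0})
            continue
        occ = occ_full.restrict(retained)
        net = build_network(occ, provenance={"threshold": args.threshold})
        net.to_edge_csv(args.out / f"{kind}_edges.csv")
        occ.to_dense_csv(args.out / f"{kind}_occurrence.csv")
        rows.append(
            {"network": kind, "unfiltered": len(occ_full.cols), "filtered": len(occ.cols)}
        )
        print(
            f"{kind}: {len(occ_full.cols)} nodes unfiltered, {len(occ.cols)} filtered, "
            f"{len(net.edge_list())} edges"
        )
    pd.DataFrame(rows).to_csv(args.out / "node_counts.csv", index=False)


if __name__ == "__main__":
    main()
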