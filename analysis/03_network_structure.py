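"""Structural metrics for each filtered association network.

Reports density (2E/(n(n-1))), the coefficient of variation of dyad
weights, walktrap communities with weighted modularity, and the ten nodes
with the highest weighted betweenness (edge weights treated as path costs,
the convention of the graph libraries usually applied to association
matrices). Full betweenness tables and a metrics JSON are written per
network.
"""

import argparse
from pathlib import Path

import pandas as pd

from cooccurnet.association import build_network
from cooccurnet.metrics import metrics_report
from cooccurnet.occurrence import KINDS, build_occurrence
from cooccurnet.survey_io import filter_items, read_survey


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input", type=Path, default=Path("results/data/survey_structured.csv"))
    ap.add_argument("--threshold", type=int, default=3)
    ap.add_argument("--weight-mode", choices=["cost", "similarity_reciprocal"], default="cost")
    ap.add_argument("--out", type=Path, default=Path("results/structure"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    dataset = read_survey(args.input)
    for kind in KINDS:
        occ_full = build_occurrence(dataset, kind)
        retained = filter_items(occ_full.col_total_map(), args.threshold)
        if not retained:
            print(f"{kind}: nothing to analyse")
            continue
        net = build_network(occ_full.restrict(retained))
        report = metrics_report(net, weight_mode=args.weight_mode)
        report.to_json(args.out / f"{kind}_metrics.json")
        report.betweenness_csv(args.out / f"{kind}_betweenness.csv")
        top = pd.read_csv(args.out / f"{kind}_betweenness.csv").head(10)
        print(
            f"\n{kind}: density {report.density:.2f}, CV {report.cv_edge_weights:.2f}, "
            f"modularity {report.partition.modularity:.2f} "
            f"({report.partition.n_modules} modules)"
        )
        print(top.to_string(index=False))


if __name__ == "__main__":
    main()
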