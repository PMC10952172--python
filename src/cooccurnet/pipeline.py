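"""One-command orchestration of the full analysis.

For each requested network kind: build the occurrence matrix, apply the
node-frequency filter (keep labels observed more than ``threshold`` times),
compute the SRI association network, structural metrics (density, CV,
betweenness, walktrap modularity), and the datastream permutation tests
(global CV test plus preferred/avoided dyads). Finally a Mantel test
correlates the identity-by-identity and identity-by-behaviour networks on
their shared nodes.

Every number written to the human-readable summary also lives in a
machine-readable CSV/JSON, and ``manifest.json`` records the seeds and
options needed to reproduce a run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .association import AssociationNetwork, build_network
from .matrix_tests import MantelResult, mantel
from .metrics import MetricsReport, metrics_report
from .nullmodels import PermutationConfig, PermutationReport, dyad_tests
from .occurrence import KINDS, build_occurrence
from .survey_io import SurveyDataset, filter_items, read_survey, summarize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str | None = None
    networks: tuple[str, ...] = KINDS
    threshold: int = 3
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    weight_mode: str = "cost"
    cv_include_zero_dyads: bool = True
    walktrap_steps: int = 4
    mantel_permutations: int = 10_000
    mantel_pair: tuple[str, str] = ("identity_by_identity", "identity_by_behaviour")
    out_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("at least one network kind must be requested")
        for k in self.networks:
            if k not in KINDS:
                raise ValueError(f"unknown network kind: {k!r}")


@dataclass
class NetworkResult:
    kind: str
    n_nodes_unfiltered: int
    n_nodes_filtered: int
    network: AssociationNetwork | None = None
    metrics: MetricsReport | None = None
    permutation: PermutationReport | None = None
    note: str | None = None


@dataclass
class RunResult:
    networks: dict[str, NetworkResult]
    mantel: MantelResult | None
    manifest: dict


def _derived_seed(master: int | None, index: int) -> int | None:
    """Stable per-stage 31-bit seed derived from the master seed."""
    if master is None:
        return None
    child = np.random.SeedSequence(entropy=master, spawn_key=(index,))
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def run(config: RunConfig, dataset: SurveyDataset | None = None) -> RunResult:
    """Execute the full pipeline; returns all results in memory.

    ``dataset`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is read from ``config.input_path``. When ``config.out_dir``
    is set, the report bundle is written there.
    """
    if dataset is None:
        if config.input_path is None:
            raise ValueError("either a dataset or config.input_path is required")
        dataset = read_survey(config.input_path)

    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "threshold": config.threshold,
        "weight_mode": config.weight_mode,
        "cv_include_zero_dyads": config.cv_include_zero_dyads,
        "walktrap_steps": config.walktrap_steps,
        "permutation": {
            "n_permutations": config.permutation.n_permutations,
            "swaps_per_permutation": config.permutation.swaps_per_permutation,
            "burn_in_swaps": config.permutation.burn_in_swaps,
            "alpha": config.permutation.alpha,
            "p_convention": config.permutation.p_convention,
            "scheme": config.permutation.scheme,
        },
        "mantel_permutations": config.mantel_permutations,
        "input": config.input_path,
        "n_participants": len(dataset),
        "networks": {},
    }

    results: dict[str, NetworkResult] = {}
    nets: dict[str, AssociationNetwork] = {}
    for i, kind in enumerate(config.networks):
        logger.info("building %s network", kind)
        occ_full = build_occurrence(dataset, kind)
        counts = occ_full.col_total_map()
        retained = filter_items(counts, config.threshold)
        n_unf = len([c for c, v in counts.items() if v > 0])
        if not retained:
            logger.warning("%s: no nodes survive filter (threshold %d)", kind, config.threshold)
            results[kind] = NetworkResult(
                kind, n_unf, 0, note=f"no nodes survive filter at threshold {config.threshold}"
            )
            manifest["networks"][kind] = {
                "n_nodes_unfiltered": n_unf,
                "n_nodes_filtered": 0,
                "note": results[kind].note,
            }
            continue
        occ = occ_full.restrict(retained)
        net = build_network(
            occ, provenance={"threshold": config.threshold, "kind": kind}
        )
        nets[kind] = net
        metrics = metrics_report(
            net,
            weight_mode=config.weight_mode,
            include_zero_dyads=config.cv_include_zero_dyads,
            walktrap_steps=config.walktrap_steps,
        )
        perm_cfg = replace(config.permutation, seed=_derived_seed(config.seed, i))
        perm = dyad_tests(occ, perm_cfg)
        results[kind] = NetworkResult(
            kind, n_unf, len(occ.cols), network=net, metrics=metrics, permutation=perm
        )
        manifest["networks"][kind] = {
            "n_nodes_unfiltered": n_unf,
            "n_nodes_filtered": len(occ.cols),
            "permutation_seed": perm_cfg.seed,
        }
        if out:
            net.to_edge_csv(out / f"{kind}_edges.csv")
            metrics.to_json(out / f"{kind}_metrics.json")
            metrics.betweenness_csv(out / f"{kind}_betweenness.csv")
            perm.to_json(out / f"{kind}_permutation.json")
            perm.null_cv_csv(out / f"{kind}_null_cv.csv")
            perm.dyads_csv(out / f"{kind}_dyads.csv")

    mantel_result = None
    k1, k2 = config.mantel_pair
    if k1 in nets and k2 in nets:
        mantel_seed = _derived_seed(config.seed, 100)
        mantel_result = mantel(
            nets[k1], nets[k2], n_permutations=config.mantel_permutations, seed=mantel_seed
        )
        manifest["mantel_seed"] = mantel_seed
        if out:
            mantel_result.to_json(out / "mantel.json")
            mantel_result.shared_nodes_csv(out / "mantel_shared_nodes.csv")

    if out:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        summarize(dataset).to_json(out / "dataset_summary.json")
        _write_summary(out, results, mantel_result)

    return RunResult(networks=results, mantel=mantel_result, manifest=manifest)


def _write_summary(out: Path, results: dict[str, NetworkResult], mr: MantelResult | None) -> None:
    summary: dict = {"networks": {}}
    for kind, res in results.items():
        entry: dict = {
            "n_nodes_unfiltered": res.n_nodes_unfiltered,
            "n_nodes_filtered": res.n_nodes_filtered,
        }
        if res.note:
            entry["note"] = res.note
        if res.metrics:
            entry.update(
                density=res.metrics.density,
                cv_edge_weights=res.metrics.cv_edge_weights,
                modularity=res.metrics.partition.modularity,
                n_modules=res.metrics.partition.n_modules,
            )
        if res.permutation:
            entry.update(
                global_p=res.permutation.global_p,
                n_preferred=res.permutation.n_preferred,
                n_avoided=res.permutation.n_avoided,
            )
        summary["networks"][kind] = entry
    if mr:
        summary["mantel"] = {"r": mr.r, "p": mr.p, "n_shared_nodes": mr.n_shared_nodes}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
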