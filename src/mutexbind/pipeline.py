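"""End-to-end orchestration: map -> sub-networks -> motifs -> report.

Each sub-network is processed independently and failures are isolated: a
malformed structure aborts only its own sub-network, which is recorded in
the run report, and the pipeline moves on.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from . import network, validation
from .motifmatch import MatchParams, cluster_matches, clusters_table, pairwise_match
from .ranking import rank_clusters
from .structures import (
    DEFAULT_EXPOSURE_CUTOFF,
    accessibility_table,
    read_structure,
    surface_residues,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, serialisable configuration of one pipeline run.

    The matcher thresholds default to the method's operating point:
    2.1 A RMSD ceiling, mean PAM250 >= 1.2, >= 3 residues and >= 3 chains
    per cluster, 50% relative-accessibility surface cutoff, 30% redundancy
    threshold.
    """

    edges: str = ""
    structure_map: str = ""
    dialect: str = "tsv-pair"
    labels: str = ""  # optional ground-truth TSV (node, group_id)
    outdir: str = "mutexbind_out"
    rmsd_max: float = 2.1
    pam_min: float = 1.2
    min_residues: int = 3
    min_chains: int = 3
    neighbor_cutoff: float = 10.0
    distance_tolerance: float = 2.5
    exposure_cutoff: float = DEFAULT_EXPOSURE_CUTOFF
    redundancy_threshold: float = 30.0
    min_nodes: int = 3
    averaging: str = "pooled"
    ranking_key: str = "score"
    filter_redundancy: bool = True
    seed: int = 0
    verbosity: int = 1

    def match_params(self) -> MatchParams:
        return MatchParams(
            rmsd_max=self.rmsd_max,
            pam_min=self.pam_min,
            min_residues=self.min_residues,
            neighbor_cutoff=self.neighbor_cutoff,
            distance_tolerance=self.distance_tolerance,
        )

    def save(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        values: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                values[key] = value.strip() in ("True", "true", "1")
            elif isinstance(current, int):
                values[key] = int(value.strip())
            elif isinstance(current, float):
                values[key] = float(value.strip())
            else:
                values[key] = value.strip()
        return cls(**values)


def analyse_subnetwork(chains: dict[str, object], params: MatchParams,
                       exposure_cutoff: float = DEFAULT_EXPOSURE_CUTOFF,
                       min_chains: int = 3):
    """Surface -> all-against-all matching -> clustering for one sub-network.

    ``chains`` maps node ids to ChainStructure objects (chain_id must equal
    the node id so cluster membership is reported per node).
    """
    surfaces = {node: surface_residues(ch, cutoff=exposure_cutoff)
                for node, ch in chains.items()}
    matches = []
    for a, b in combinations(sorted(chains), 2):
        matches.extend(pairwise_match(surfaces[a], surfaces[b], params))
    return cluster_matches(matches, min_chains=min_chains,
                           overlap_min=params.min_residues)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; returns a machine-readable run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(config.edges) as fh:
        imap = network.parse_interactions(fh, dialect=config.dialect)
    with open(config.structure_map) as fh:
        index = network.read_structure_index(fh)
    subnets = network.extract_subnetworks(imap, index, min_nodes=config.min_nodes)
    (outdir / "subnetworks.tsv").write_text(network.subnetwork_manifest(subnets))

    groups = None
    if config.labels:
        with open(config.labels) as fh:
            groups = validation.read_group_labels(fh)

    params = config.match_params()
    report: dict = {
        "n_subnetworks": len(subnets),
        "n_analysed": 0,
        "n_with_clusters": 0,
        "failed": [],
        "subnetworks": {},
    }
    confusions: list[validation.ConfusionCounts] = []
    for sn in subnets:
        try:
            chains = {}
            for node in sn.nodes:
                ref = sn.structures[node]
                ch = read_structure(ref.path, ref.chain)
                ch.chain_id = node
                chains[node] = ch
            if config.filter_redundancy:
                seqs = {n: chains[n].sequence for n in sn.nodes}
                sn = network.filter_redundant(sn, seqs,
                                              threshold=config.redundancy_threshold,
                                              min_nodes=config.min_nodes)
                chains = {n: chains[n] for n in sn.nodes}
                if not sn.analysable:
                    logger.info("sub-network %s not analysable after "
                                "redundancy filtering", sn.hub)
                    report["subnetworks"][sn.hub] = {"n_clusters": 0,
                                                     "analysable": False}
                    continue
            report["n_analysed"] += 1
            clusters = analyse_subnetwork(chains, params,
                                          exposure_cutoff=config.exposure_cutoff,
                                          min_chains=config.min_chains)
            entry: dict = {"n_clusters": len(clusters), "analysable": True}
            if clusters:
                report["n_with_clusters"] += 1
                (outdir / f"clusters_{sn.hub}.tsv").write_text(
                    clusters_table(clusters))
                ranked = rank_clusters(clusters, key=config.ranking_key)
                lines = ["rank\tcluster_id\tscore\tconservation\tgdt_ts"]
                for r in ranked:
                    lines.append(f"{r.rank}\t{r.cluster.cluster_id}\t{r.score}"
                                 f"\t{r.conservation:.2f}\t{r.gdt_ts:.1f}")
                (outdir / f"ranking_{sn.hub}.tsv").write_text(
                    "\n".join(lines) + "\n")
                for node, ch in sorted(chains.items()):
                    (outdir / f"surface_{sn.hub}_{node}.tsv").write_text(
                        accessibility_table(ch, cutoff=config.exposure_cutoff))
                if groups is not None:
                    sub_conf = [
                        validation.confusion_counts(
                            frozenset(c.chains) & groups.universe, groups)
                        for c in clusters
                        if frozenset(c.chains) & groups.universe
                    ]
                    confusions.extend(sub_conf)
                    entry["confusion"] = [
                        {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                        for c in sub_conf
                    ]
            report["subnetworks"][sn.hub] = entry
        except Exception as exc:  # noqa: BLE001 - per-sub-network isolation
            logger.error("sub-network %s failed: %s", sn.hub, exc)
            report["failed"].append({"hub": sn.hub, "error": str(exc)})
    if groups is not None and confusions:
        report["validation"] = {
            "pooled": validation.summary_statistics(confusions, "pooled").as_dict(),
            "macro": validation.summary_statistics(confusions, "macro").as_dict(),
        }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
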