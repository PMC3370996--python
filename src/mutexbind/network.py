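"""PPI map parsing, hub sub-network extraction, redundancy filtering.

A sub-network is a hub protein together with its interactors that have a
mapped structure; only hubs with at least three such interactors are
analysable, since a shared surface motif needs three or more chains to be
meaningful evidence of mutually exclusive binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

logger = logging.getLogger(__name__)

DEFAULT_MIN_NODES = 3
DEFAULT_REDUNDANCY_THRESHOLD = 30.0  # percent sequence identity


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class StructureRef:
    """Where to find a protein's coordinates: file path + chain id."""

    path: str
    chain: str


@dataclass
class InteractionMap:
    """An undirected PPI edge set without self-edges."""

    edges: set[frozenset[str]] = field(default_factory=set)
    proteins: set[str] = field(default_factory=set)

    def add_edge(self, a: str, b: str) -> bool:
        """Add an undirected edge; self-edges are rejected (returns False)."""
        if a == b:
            return False
        self.edges.add(frozenset((a, b)))
        self.proteins.update((a, b))
        return True

    def neighbors(self, protein: str) -> set[str]:
        return {next(iter(e - {protein})) for e in self.edges if protein in e}

    def serialize(self) -> str:
        lines = sorted("\t".join(sorted(e)) for e in self.edges)
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class SubNetwork:
    """A hub plus its structure-mapped interactors."""

    hub: str
    nodes: list[str]
    structures: dict[str, StructureRef]
    analysable: bool = True

    def __post_init__(self):
        if self.hub in self.nodes:
            raise ValueError("hub cannot be one of its own nodes")


def _mitab_identifier(token: str) -> str:
    # PSI-MI TAB columns look like "uniprotkb:P12345"; keep the accession
    return token.split(":", 1)[1] if ":" in token else token


def parse_interactions(stream: Iterable[str] | TextIO,
                       dialect: str = "tsv-pair") -> InteractionMap:
    """Parse a two-column edge list or PSI-MI TAB 2.5 into an InteractionMap.

    Comment lines start with '#'; self-interactions are dropped (counted in
    the log); duplicate and reversed edges collapse. Malformed lines raise
    ParseError naming the line number.
    """
    if dialect not in ("tsv-pair", "psi-mitab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    imap = InteractionMap()
    n_self = 0
    n_lines = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise ParseError(f"line {lineno}: expected two identifiers, got {line!r}")
        a, b = fields[0].strip(), fields[1].strip()
        if dialect == "psi-mitab":
            a, b = _mitab_identifier(a), _mitab_identifier(b)
        if not a or not b:
            raise ParseError(f"line {lineno}: empty identifier in {line!r}")
        n_lines += 1
        if not imap.add_edge(a, b):
            n_self += 1
    if n_self:
        logger.info("dropped %d self-interaction(s)", n_self)
    if n_lines == 0:
        logger.warning("no interactions parsed: empty input")
    return imap


def extract_subnetworks(imap: InteractionMap,
                        structure_index: dict[str, StructureRef],
                        min_nodes: int = DEFAULT_MIN_NODES) -> list[SubNetwork]:
    """Cut hub-centred sub-networks of structure-mapped interactors.

    A protein becomes a hub when at least ``min_nodes`` of its neighbours
    have an entry in ``structure_index``; unmapped neighbours are excluded
    entirely. Output is sorted by hub id.
    """
    if min_nodes < 1:
        raise ValueError("min_nodes must be >= 1")
    out = []
    for hub in sorted(imap.proteins):
        mapped = sorted(n for n in imap.neighbors(hub) if n in structure_index)
        if len(mapped) >= min_nodes:
            out.append(SubNetwork(hub, mapped,
                                  {n: structure_index[n] for n in mapped}))
    return out


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment, over the shorter sequence.

    Alignment scoring: match +1, mismatch 0, gap open -10, gap extend -0.5.
    'X' positions never count as identical.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    identical = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for x, y in zip(seq_a[a0:a1].upper(), seq_b[b0:b1].upper()):
            if x == y and x != "X":
                identical += 1
    return 100.0 * identical / min(len(seq_a), len(seq_b))


def filter_redundant(subnet: SubNetwork, sequences: dict[str, str],
                     threshold: float = DEFAULT_REDUNDANCY_THRESHOLD,
                     min_nodes: int = DEFAULT_MIN_NODES) -> SubNetwork:
    """Greedy non-redundant node selection.

    Nodes are visited by descending sequence length (ties: id); a node is
    kept iff its identity to every kept node is <= threshold percent. If
    fewer than ``min_nodes`` survive, the sub-network is flagged
    non-analysable but still returned.
    """
    for node in subnet.nodes:
        if node not in sequences:
            raise KeyError(f"no sequence for node {node!r}")
    order = sorted(subnet.nodes, key=lambda n: (-len(sequences[n]), n))
    kept: list[str] = []
    for node in order:
        if all(sequence_identity(sequences[node], sequences[k]) <= threshold
               for k in kept):
            kept.append(node)
        else:
            logger.info("sub-network %s: dropped redundant node %s",
                        subnet.hub, node)
    kept_sorted = sorted(kept)
    return SubNetwork(subnet.hub, kept_sorted,
                      {n: subnet.structures[n] for n in kept_sorted},
                      analysable=len(kept_sorted) >= min_nodes)


def subnetwork_manifest(subnets: list[SubNetwork]) -> str:
    """Sub-network manifest as TSV: hub, node, pdb_file, chain."""
    lines = ["hub\tnode\tpdb_file\tchain"]
    for sn in subnets:
        for node in sn.nodes:
            ref = sn.structures[node]
            lines.append(f"{sn.hub}\t{node}\t{ref.path}\t{ref.chain}")
    return "\n".join(lines) + "\n"


def read_structure_index(stream: Iterable[str] | TextIO) -> dict[str, StructureRef]:
    """Read a structure map TSV: protein_id, file_path, chain_id."""
    index = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"line {lineno}: expected 3 columns, got {line!r}")
        index[fields[0].strip()] = StructureRef(fields[1].strip(), fields[2].strip())
    return index
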