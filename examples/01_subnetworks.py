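"""Extract hub sub-networks from a PPI edge list.

Builds a small interaction map in memory, maps four proteins to generated
structure files, and cuts out every hub with at least three
structure-mapped interactors.
"""

import io
import tempfile
from pathlib import Path

from mutexbind import extract_subnetworks, parse_interactions
from mutexbind.network import StructureRef, subnetwork_manifest
from mutexbind.structures import write_pdb
from mutexbind.synthetic import FixtureSpec, make_toy_chain

EDGES = """\
HUB1\tP1
HUB1\tP2
HUB1\tP3
HUB1\tP9
HUB2\tP1
HUB2\tP4
P2\tP3
"""

workdir = Path(tempfile.mkdtemp(prefix="mutexbind_example_"))
index = {}
for i, protein in enumerate(["P1", "P2", "P3", "P4"]):
    chain = make_toy_chain(FixtureSpec(seed=i, n_residues=10), chain_id="A")
    path = workdir / f"{protein}.pdb"
    write_pdb(chain, path)
    index[protein] = StructureRef(str(path), "A")
# P9 has no structure and therefore cannot join any sub-network

imap = parse_interactions(io.StringIO(EDGES))
subnets = extract_subnetworks(imap, index, min_nodes=3)

print(subnetwork_manifest(subnets))
print(f"{len(imap.edges)} interactions -> {len(subnets)} analysable sub-network(s)")
# HUB1 qualifies (3 of its 4 interactors have structures); HUB2 has only
# two mapped interactors and is dropped.
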