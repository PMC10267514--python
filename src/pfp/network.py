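"""Assembly of candidate-interactor tables into an annotated PPI network.

One bait node per bait proteoform (gene symbol + proteoform tag, e.g.
``MAVS_FL``); prey nodes collapse to gene symbols and are unioned across
methods.  Each (bait, prey, method) triple becomes one edge keyed by its
source method (virotrap / apms); support by a public PPI database is an edge
ATTRIBUTE, not an extra edge source, so experimental edge counts and
database-support counts are reported separately.  Preys get a sharing class
(FL-only / PR-only / shared) from their membership across the FL and PR
candidate lists of the same gene.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .io import partners_of


def build_network(
    candidate_tables: dict[tuple[str, str], set[str]],
    known_interactions: pd.DataFrame | None = None,
    bait_genes: dict[str, str] | None = None,
) -> nx.MultiGraph:
    """Merge per-(bait, method) candidate sets into one annotated network.

    ``candidate_tables`` maps (bait label, method) -> prey gene symbols;
    ``bait_genes`` maps bait label -> its gene symbol (for database lookup
    and FL/PR sharing; defaults to the label minus a ``_FL``/``_PR`` suffix).
    A prey equal to its bait's symbol yields a flagged, retained self-edge.
    """
    if not candidate_tables:
        return nx.MultiGraph()
    bait_genes = bait_genes or {}

    def gene_of(bait: str) -> str:
        if bait in bait_genes:
            return bait_genes[bait]
        for suffix in ("_FL", "_PR1", "_PR2", "_PR"):
            if bait.endswith(suffix):
                return bait[: -len(suffix)]
        return bait

    g = nx.MultiGraph()
    baits = sorted({bait for bait, _ in candidate_tables})
    for bait in baits:
        g.add_node(bait, role="bait", gene=gene_of(bait))

    # prey sharing class per gene: which proteoform classes saw the prey
    prey_sides: dict[str, set[str]] = {}
    for (bait, _method), preys in candidate_tables.items():
        side = "FL" if "_FL" in bait or bait.endswith("FL") else "PR"
        for prey in preys:
            prey_sides.setdefault(prey, set()).add(side)

    for (bait, method), preys in candidate_tables.items():
        for prey in preys:
            if prey not in g or g.nodes[prey].get("role") != "bait":
                sides = prey_sides[prey]
                sharing = "shared" if len(sides) > 1 else f"{next(iter(sides))}-only"
                if prey in g:
                    g.nodes[prey]["sharing"] = sharing
                else:
                    g.add_node(prey, role="prey", sharing=sharing)
            db = False
            if known_interactions is not None:
                db = prey in partners_of(known_interactions, gene_of(bait))
            self_edge = prey == gene_of(bait)
            if g.has_edge(bait, prey, key=method):
                continue  # dedup (bait, prey, method)
            g.add_edge(bait, prey, key=method, db_support=db, self_edge=self_edge)

    for node in g.nodes:
        if g.nodes[node].get("role") == "bait" and node in prey_sides:
            g.nodes[node]["role"] = "both"
    return g


def network_summary(network: nx.MultiGraph) -> dict:
    """Integer summary: node/edge counts, per-source edges, per-class nodes,
    database-support count and the per-node degree."""
    per_source: dict[str, int] = {}
    n_db = 0
    for _u, _v, key, data in network.edges(keys=True, data=True):
        per_source[key] = per_source.get(key, 0) + 1
        n_db += bool(data.get("db_support"))
    per_class: dict[str, int] = {}
    for _n, data in network.nodes(data=True):
        label = data.get("sharing", data.get("role", "bait"))
        per_class[label] = per_class.get(label, 0) + 1
    return {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "edges_per_source": per_source,
        "nodes_per_class": per_class,
        "n_db_supported_edges": n_db,
        "degree": dict(network.degree()),
    }
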