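"""Post-enumeration analytics: association graphs and taxonomy summaries."""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

from .model import NetworkCollection
from .selection import Enumeration, KeySpeciesResult


def association_graph(
    enum: Enumeration, ks: KeySpeciesResult | None = None
) -> nx.Graph:
    """Co-occurrence graph over the key species of an enumeration.

    Nodes are the organisms appearing in at least one enumerated
    minimal community; an edge joins two organisms iff they co-occur in
    at least one community.  Node attribute ``role`` marks essential vs
    alternative symbionts.  The graph is typically dense — the many
    equivalent optima usually combine a small pool of organisms — and
    is meant for export to standard viewers (see :func:`write_graph`).

    A truncated enumeration is accepted but stamped into
    ``G.graph["complete"]`` with a warning: co-occurrence is then only
    a lower bound.
    """
    if not enum.communities:
        raise ValueError("empty enumeration")
    if ks is None:
        from .selection import key_species_from_enumeration

        ks = key_species_from_enumeration(enum)
    g = nx.Graph(complete=enum.complete)
    if not enum.complete:
        warnings.warn(
            "association graph built from a truncated enumeration", stacklevel=2
        )
    for org in sorted(ks.key_species):
        role = "essential" if org in ks.essential_symbionts else "alternative"
        g.add_node(org, role=role)
    for community in enum.communities:
        for i, u in enumerate(community):
            for v in community[i + 1 :]:
                if u != v:
                    g.add_edge(u, v)
    return g


def write_graph(g: nx.Graph, gml_path: str | Path, tsv_path: str | Path) -> None:
    """Serialize an association graph as GML plus a TSV edge list."""
    nx.write_gml(g, str(gml_path))
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


def read_taxonomy(path: str | Path, rank: str | None = None) -> dict[str, str]:
    """Read a TSV taxonomy table (org_id in the first column).

    ``rank`` selects which column to use as the taxon label; default is
    the second column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unclassified")
    if df.shape[1] < 2:
        raise ValueError("taxonomy table needs an org_id column plus >=1 rank")
    col = rank if rank is not None else df.columns[1]
    return dict(zip(df.iloc[:, 0], df[col]))


def taxonomy_summary(
    ks: KeySpeciesResult,
    coll: NetworkCollection,
    taxonomy: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Count organisms per taxon and role.

    One row per taxon, columns ``initial`` (whole collection), ``KS``
    (key species), ``ES`` (essential symbionts) and ``AS`` (alternative
    symbionts); KS = ES + AS in every row.  Organisms missing from the
    taxonomy mapping fall under "unclassified"; an empty mapping yields
    a single unclassified row.
    """
    taxonomy = taxonomy or {}

    def taxon(org: str) -> str:
        return taxonomy.get(org, "unclassified")

    rows: dict[str, dict[str, int]] = {}

    def bump(org: str, col: str) -> None:
        row = rows.setdefault(
            taxon(org), {"initial": 0, "KS": 0, "ES": 0, "AS": 0}
        )
        row[col] += 1

    for net in coll:
        bump(net.org_id, "initial")
    for org in ks.key_species:
        bump(org, "KS")
    for org in ks.essential_symbionts:
        bump(org, "ES")
    for org in ks.alternative_symbionts:
        bump(org, "AS")
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "taxon"
    return df
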