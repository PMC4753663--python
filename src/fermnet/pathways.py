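"""Pathway library, over-representation analysis and topology impact.

A pathway is a named compound set plus a directed reaction-adjacency
graph on those compounds. Libraries serialize to GMT (membership) and a
single SIF file whose relation column carries the pathway id, so shared
compounds stay attributable.

Enrichment of a metabolite set against a background universe uses the
one-sided (upper tail) Fisher exact / hypergeometric test; topology
impact is the out-degree-centrality mass of the hit compounds relative
to the whole pathway. Pathways are kept when -log10(p) > 1 (p < 0.1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "Pathway",
    "PathwayLibrary",
    "PathwayResult",
    "map_compounds",
    "ora_fisher",
    "pathway_impact",
    "enrich_type",
]


@dataclass
class Pathway:
    id: str
    name: str
    compounds: frozenset[str]
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        self.compounds = frozenset(self.compounds)
        extra = set(self.graph.nodes) - set(self.compounds)
        if extra:
            raise ValueError(f"pathway {self.id}: graph nodes {sorted(extra)} outside compound set")


@dataclass
class PathwayLibrary:
    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate pathway ids in library")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def get(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def all_compounds(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.compounds
        return out

    # -- serialization ----------------------------------------------------

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.pathways:
                members = "\t".join(sorted(p.compounds))
                fh.write(f"{p.id}\t{p.name}\t{members}\n")

    def write_sif(self, path) -> None:
        """Edges as ``source <pathway id> target``; isolated nodes omitted
        (membership lives in the GMT)."""
        with open(path, "w") as fh:
            for p in self.pathways:
                for u, v in sorted(p.graph.edges):
                    fh.write(f"{u}\t{p.id}\t{v}\n")

    @classmethod
    def read(cls, gmt_path, sif_path) -> "PathwayLibrary":
        memberships: list[tuple[str, str, set[str]]] = []
        with open(gmt_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed GMT line: {line!r}")
                memberships.append((parts[0], parts[1], set(parts[2:]) - {""}))
        edges: dict[str, list[tuple[str, str]]] = {}
        with open(sif_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"malformed SIF line: {line!r}")
                src, rel, tgt = parts
                edges.setdefault(rel, []).append((src, tgt))
        pathways = []
        for pid, name, compounds in memberships:
            g = nx.DiGraph()
            g.add_nodes_from(sorted(compounds))
            g.add_edges_from(edges.get(pid, []))
            pathways.append(Pathway(id=pid, name=name, compounds=frozenset(compounds), graph=g))
        return cls(pathways)


@dataclass
class PathwayResult:
    pathway_id: str
    name: str
    hits: frozenset[str]
    x: int  # hits
    n: int  # query size
    K: int  # pathway size within background
    N: int  # background size
    p: float
    neg_log_p: float
    impact: float
    passes_filter: bool


def map_compounds(query, library: PathwayLibrary | set[str]):
    """Case-insensitive match of query ids against library compound ids.

    Returns ``(mapped, unmapped)`` where ``mapped`` is a set of canonical
    (library-cased) ids and ``unmapped`` lists query entries with no
    library counterpart, preserving first-seen order.
    """
    compounds = library if isinstance(library, set) else library.all_compounds
    if not compounds:
        raise ValueError("empty pathway library: nothing to map against")
    canon = {c.lower(): c for c in compounds}
    mapped: set[str] = set()
    unmapped: list[str] = []
    seen: set[str] = set()
    for q in query:
        key = str(q).lower()
        if key in seen:
            continue
        seen.add(key)
        if key in canon:
            mapped.add(canon[key])
        else:
            unmapped.append(str(q))
    return mapped, unmapped


def ora_fisher(x: int, n: int, K: int, N: int) -> float:
    """One-sided upper-tail hypergeometric (Fisher exact) enrichment p.

    p = P[X >= x] with X ~ Hypergeom(N, K, n): the chance of drawing at
    least ``x`` pathway members in a size-``n`` query from a background of
    ``N`` compounds of which ``K`` are in the pathway.
    """
    for name, v in (("x", x), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    x, n, K, N = int(x), int(n), int(K), int(N)
    if n > N or K > N:
        raise ValueError(f"inconsistent counts: n={n}, K={K} must not exceed N={N}")
    if x > min(n, K):
        raise ValueError(f"x={x} exceeds min(n, K)={min(n, K)}")
    if x < max(0, n + K - N):
        raise ValueError(f"x={x} below minimum attainable overlap {max(0, n + K - N)}")
    # survival function is evaluated in log space internally by scipy
    p = float(hypergeom.sf(x - 1, N, K, n))
    return min(max(p, math.ulp(0.0)), 1.0)


def pathway_impact(graph: nx.DiGraph, hits, compounds=None, centrality: str = "out_degree") -> float:
    """Centrality mass of the hit compounds relative to the pathway total.

    impact = sum(c_i for i in hits) / sum(c_i for i in pathway), with c_i
    the out-degree (or normalized betweenness) of compound i. Pathways
    with zero total centrality get impact 0.
    """
    nodes = set(graph.nodes) | (set(compounds) if compounds is not None else set())
    hits = set(hits)
    stray = hits - nodes
    if stray:
        raise ValueError(f"hits {sorted(stray)} not in pathway")
    if centrality == "out_degree":
        cent = {u: float(graph.out_degree(u)) if u in graph else 0.0 for u in nodes}
    elif centrality == "betweenness":
        bc = nx.betweenness_centrality(graph, normalized=True)
        cent = {u: bc.get(u, 0.0) for u in nodes}
    else:
        raise ValueError(f"unknown centrality {centrality!r}")
    total = sum(cent.values())
    if total <= 0:
        return 0.0
    return sum(cent[u] for u in hits) / total


def enrich_type(
    members,
    library: PathwayLibrary,
    background,
    neg_log_p_cutoff: float = 1.0,
    log_base: float = 10.0,
    centrality: str = "out_degree",
) -> list[PathwayResult]:
    """Over-representation + impact for one metabolite type's member set.

    The query and every pathway are intersected with the ``background``
    universe before counting. Results (one per pathway with at least one
    hit) are sorted by p ascending, ties broken by impact descending then
    pathway id. ``passes_filter`` is ``-log(p) > neg_log_p_cutoff`` in the
    configured log base (default base 10, i.e. p < 0.1).
    """
    background = set(background)
    query = set(members) & background
    outside = set(members) - background
    if outside:
        raise ValueError(
            f"type members {sorted(outside)} are outside the background universe"
        )
    N = len(background)
    n = len(query)
    results: list[PathwayResult] = []
    if n == 0:
        import warnings

        warnings.warn("empty mapped query; no enrichment computed", stacklevel=2)
        return results
    for p in library:
        in_bg = p.compounds & background
        hits = p.compounds & query
        if not hits:
            continue
        pval = ora_fisher(len(hits), n, len(in_bg), N)
        nlp = -math.log(pval) / math.log(log_base)
        impact = pathway_impact(p.graph, hits, compounds=p.compounds, centrality=centrality)
        results.append(
            PathwayResult(
                pathway_id=p.id,
                name=p.name,
                hits=frozenset(hits),
                x=len(hits),
                n=n,
                K=len(in_bg),
                N=N,
                p=pval,
                neg_log_p=nlp,
                impact=impact,
                passes_filter=nlp > neg_log_p_cutoff,
            )
        )
    results.sort(key=lambda r: (r.p, -r.impact, r.pathway_id))
    return results


def results_frame(results: list[PathwayResult]) -> pd.DataFrame:
    """Tabular view mirroring the per-pathway statistics columns."""
    from scipy.stats import false_discovery_control

    df = pd.DataFrame(
        {
            "pathway": [r.pathway_id for r in results],
            "name": [r.name for r in results],
            "x": [r.x for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "neg_log_p": [r.neg_log_p for r in results],
            "impact": [r.impact for r in results],
            "passes_filter": [r.passes_filter for r in results],
        }
    )
    # informational only; never used by the filter
    df["fdr"] = false_discovery_control(df["p"], method="bh") if len(df) else []
    return df
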