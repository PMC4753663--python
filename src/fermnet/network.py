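"""Bipartite metabolite-pathway network assembly and ratio trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .classify import TypedMetabolite
from .pathways import PathwayResult
from .tables import TIME_COL

__all__ = ["build_network", "ratio_trajectories", "RatioSeries", "format_ratio"]


def build_network(
    enrichment: dict[str, list[PathwayResult]] | list[PathwayResult],
    typed: list[TypedMetabolite],
    kegg_to_metabolite: dict[str, str] | None = None,
    only_passing: bool = True,
) -> nx.Graph:
    """Assemble the bipartite metabolite-pathway graph.

    Metabolite nodes carry their type code; pathway nodes carry p and
    impact; edges are the surviving pathway-metabolite incidences. When
    ``enrichment`` is a per-type dict, results are merged and nodes are
    deduplicated across types. Pathway hits are compound ids; a
    ``kegg_to_metabolite`` map translates them back to metabolite names.

    Raises if an incidence references a metabolite that was never typed.
    """
    if isinstance(enrichment, dict):
        results = [r for rs in enrichment.values() for r in rs]
    else:
        results = list(enrichment)
    by_name = {t.metabolite: t for t in typed}
    by_kegg = {t.kegg_id: t for t in typed if t.kegg_id}
    kegg_to_metabolite = kegg_to_metabolite or {}

    g = nx.Graph()
    for r in results:
        if only_passing and not r.passes_filter:
            continue
        pnode = f"pathway:{r.pathway_id}"
        if pnode not in g:
            g.add_node(
                pnode,
                kind="pathway",
                label=r.name,
                p=float(r.p),
                neg_log_p=float(r.neg_log_p),
                impact=float(r.impact),
            )
        for hit in sorted(r.hits):
            name = kegg_to_metabolite.get(hit, hit)
            t = by_name.get(name) or by_kegg.get(hit)
            if t is None:
                raise ValueError(f"incidence references unknown metabolite {hit!r}")
            mnode = f"metabolite:{t.metabolite}"
            if mnode not in g:
                g.add_node(
                    mnode,
                    kind="metabolite",
                    label=t.metabolite,
                    type_label=t.type_label,
                    type_code=t.type_code,
                )
            g.add_edge(mnode, pnode)
    return g


def network_edge_frame(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v in sorted(g.edges):
        m, p = (u, v) if g.nodes[u]["kind"] == "metabolite" else (v, u)
        rows.append(
            {
                "metabolite": g.nodes[m]["label"],
                "type_code": g.nodes[m]["type_code"],
                "pathway": g.nodes[p]["label"],
                "pathway_id": p.split(":", 1)[1],
                "neg_log_p": g.nodes[p]["neg_log_p"],
                "impact": g.nodes[p]["impact"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["metabolite", "type_code", "pathway", "pathway_id", "neg_log_p", "impact"],
    )


class RatioSeries:
    """Per-sampling-time ratio of replicate-mean abundances of two metabolites."""

    def __init__(self, numerator: str, denominator: str, time_h: np.ndarray, ratio: np.ndarray):
        self.numerator = numerator
        self.denominator = denominator
        self.time_h = np.asarray(time_h, dtype=float)
        self.ratio = np.asarray(ratio, dtype=float)  # NaN where denominator mean is 0

    def formatted(self) -> list[str]:
        return [format_ratio(r) for r in self.ratio]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time_h,
                "numerator": self.numerator,
                "denominator": self.denominator,
                "ratio": self.ratio,
                "ratio_display": self.formatted(),
            }
        )


def format_ratio(r: float) -> str:
    """Display rounding: whole numbers at >= 10, three decimals below."""
    if not np.isfinite(r):
        return "NA"
    return str(int(round(r))) if abs(r) >= 10 else f"{r:.3f}"


def ratio_trajectories(
    a_r: pd.DataFrame, samples: pd.DataFrame, pairs: list[tuple[str, str]]
) -> list[RatioSeries]:
    """Ratios of replicate-mean relative abundances over sampling times.

    ``samples`` must align row-wise with ``a_r`` and provide the
    ``time_h`` annotation. A zero denominator mean at a time point yields
    NaN with a warning rather than an error.
    """
    if len(samples) != len(a_r):
        raise ValueError("sample annotations and abundance matrix row counts differ")
    series: list[RatioSeries] = []
    grouped = a_r.groupby(samples[TIME_COL].to_numpy()).mean()
    times = grouped.index.to_numpy(dtype=float)
    for num, den in pairs:
        for col in (num, den):
            if col not in a_r.columns:
                raise ValueError(f"metabolite {col!r} not in abundance matrix")
        num_mean = grouped[num].to_numpy()
        den_mean = grouped[den].to_numpy()
        ratio = np.full(len(times), np.nan)
        ok = den_mean > 0
        ratio[ok] = num_mean[ok] / den_mean[ok]
        if not ok.all():
            import warnings

            t_bad = times[~ok].tolist()
            warnings.warn(
                f"{num}/{den}: zero denominator mean at times {t_bad}; emitting NA",
                stacklevel=2,
            )
        series.append(RatioSeries(num, den, times, ratio))
    return series
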