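"""End-to-end pipeline: rates -> PLS(x2) -> typing -> enrichment -> network.

``run_pipeline`` consumes a YAML/JSON config naming the input tables and
thresholds, executes every stage, and writes all intermediate tables, a
JSON run manifest (inputs, seeds, versions, thresholds, output hashes)
and a human-readable summary into the output directory. Reruns with the
same config and seed are byte-identical. ``simulate_bundle`` materializes
a complete synthetic input set from a design config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify, members_by_type, typed_frame
from .network import build_network, network_edge_frame, ratio_trajectories
from .pathways import PathwayLibrary, enrich_type, map_compounds, results_frame
from .pls import cross_validate, fit_pls, vip
from .rates import phenotype_at, relative_abundance
from .simulate import (
    FermentationParams,
    SimulationDesign,
    make_pathway_library,
    simulate_fermentation,
    simulate_metabolome,
)
from .tables import TIME_COL, MetaboliteTable, TimeCourse

__all__ = ["ConfigError", "StageError", "run_pipeline", "simulate_bundle"]


class ConfigError(Exception):
    """Malformed or incomplete run configuration."""


class StageError(Exception):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    path = Path(config)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigError("config must be a mapping")
    return loaded


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require_input(cfg: dict, key: str) -> Path:
    inputs = cfg.get("inputs")
    if not isinstance(inputs, dict) or key not in inputs:
        raise ConfigError(f"config missing inputs.{key}")
    path = Path(inputs[key])
    if not path.exists():
        raise ConfigError(f"inputs.{key}: file not found: {path}")
    return path


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config, out_dir) -> Path:
    """Execute the full analysis described by ``config`` into ``out_dir``."""
    cfg = _load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tc_path = _require_input(cfg, "time_course")
    mt_path = _require_input(cfg, "metabolite_table")
    gmt_path = _require_input(cfg, "pathway_gmt")
    sif_path = _require_input(cfg, "pathway_sif")
    is_col = cfg.get("inputs", {}).get("internal_standard", "IS_succinate_d4")
    kegg_path = cfg.get("inputs", {}).get("kegg_map")
    if kegg_path is not None and not Path(kegg_path).exists():
        raise ConfigError(f"inputs.kegg_map: file not found: {kegg_path}")

    seed = int(cfg.get("seed", 0))
    vip_threshold = float(cfg.get("vip_threshold", 1.0))
    neg_log_p_cutoff = float(cfg.get("neg_log_p_cutoff", 1.0))
    log_base = float(cfg.get("log_base", 10.0))
    centrality = str(cfg.get("centrality", "out_degree"))
    rate_method = str(cfg.get("rate_method", "central"))
    pls_cfg = cfg.get("pls", {}) or {}
    folds = int(pls_cfg.get("folds", 7))
    max_components = pls_cfg.get("max_components")
    ratio_pairs = [tuple(p) for p in cfg.get("ratio_pairs", [])]

    # ---- load -----------------------------------------------------------
    try:
        tc = TimeCourse.from_tsv(tc_path)
        table = MetaboliteTable.from_tsv(mt_path, internal_standard=is_col, kegg_map=kegg_path)
        library = PathwayLibrary.read(gmt_path, sif_path)
    except (ValueError, KeyError, OSError) as exc:
        raise StageError("load", str(exc)) from exc

    # ---- rates ----------------------------------------------------------
    try:
        sample_times = np.sort(table.data[TIME_COL].unique())
        phen = phenotype_at(tc, sample_times, method=rate_method)
        dcw_by_time = dict(zip(phen.time_h, phen.dcw_g_l))
        dcw_rows = table.data[TIME_COL].map(dcw_by_time).to_numpy(dtype=float)
        a_r = relative_abundance(table, dcw_rows)
    except ValueError as exc:
        raise StageError("rates", str(exc)) from exc

    phen.to_tsv(out / "phenotype.tsv")
    ar_out = pd.concat(
        [table.data[[TIME_COL, "replicate"]].reset_index(drop=True), a_r.reset_index(drop=True)],
        axis=1,
    )
    ar_out.to_csv(out / "relative_abundance.tsv", sep="\t", index=False)

    # ---- PLS per response ----------------------------------------------
    try:
        mu_by_time = dict(zip(phen.time_h, phen.mu))
        q_by_time = dict(zip(phen.time_h, phen.q))
        y_mu = table.data[TIME_COL].map(mu_by_time).to_numpy(dtype=float)
        y_q = table.data[TIME_COL].map(q_by_time).to_numpy(dtype=float)
        keep = a_r.std(axis=0, ddof=1) > 0
        dropped = [c for c, k in zip(a_r.columns, keep) if not k]
        if dropped:
            warnings.warn(f"dropping constant metabolite columns: {dropped}")
        X = a_r.loc[:, keep].to_numpy()
        cols = list(a_r.columns[keep])

        models = {}
        summaries = {}
        for resp, y in (("growth", y_mu), ("butanol", y_q)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                q2_list, chosen = cross_validate(
                    X, y, max_components=max_components, folds=folds, seed=seed
                )
                model = fit_pls(X, y, n_components=chosen, columns=cols)
            model.q2 = q2_list[model.n_components - 1]
            models[resp] = model
            summaries[resp] = dict(model.summary(), q2_per_component=[float(v) for v in q2_list])
    except ValueError as exc:
        raise StageError("pls", str(exc)) from exc

    _write_json(out / "model_summary.json", summaries)

    vip_g, vip_b = vip(models["growth"]), vip(models["butanol"])
    coef_g, coef_b = models["growth"].coef_, models["butanol"].coef_
    scores = pd.DataFrame(
        {
            "metabolite": cols,
            "kegg_id": [table.kegg_ids.get(c, "NA") for c in cols],
            "vip_b": vip_b,
            "coeff_b": coef_b,
            "vip_g": vip_g,
            "coeff_g": coef_g,
        }
    )
    scores.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.10g")

    # ---- typing ---------------------------------------------------------
    try:
        typed = classify(scores, vip_threshold=vip_threshold)
    except ValueError as exc:
        raise StageError("typing", str(exc)) from exc
    typed_frame(typed).to_csv(out / "typed_metabolites.tsv", sep="\t", index=False, float_format="%.10g")
    with open(out / "type_members.gmt", "w") as fh:
        for label, members in members_by_type(typed).items():
            fh.write("\t".join([f"type_{label}", f"metabolite type {label}", *sorted(members)]) + "\n")

    # ---- enrichment -----------------------------------------------------
    try:
        measured_ids = [table.kegg_ids.get(c, c) for c in cols]
        background, unmapped = map_compounds(measured_ids, library)
        kegg_to_met = {table.kegg_ids.get(c, c): c for c in cols}
        enrichment = {}
        frames = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for label, members in members_by_type(typed).items():
                ids = [table.kegg_ids.get(m, m) for m in members]
                mapped, _ = map_compounds(ids, library)
                res = enrich_type(
                    mapped,
                    library,
                    background,
                    neg_log_p_cutoff=neg_log_p_cutoff,
                    log_base=log_base,
                    centrality=centrality,
                )
                enrichment[label] = res
                df = results_frame(res)
                df.insert(0, "type_label", label)
                frames.append(df)
    except ValueError as exc:
        raise StageError("enrichment", str(exc)) from exc
    enrich_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")

    # ---- network --------------------------------------------------------
    try:
        graph = build_network(enrichment, typed, kegg_to_metabolite=kegg_to_met)
    except ValueError as exc:
        raise StageError("network", str(exc)) from exc
    nx.write_graphml(graph, out / "network.graphml")
    network_edge_frame(graph).to_csv(out / "network_edges.tsv", sep="\t", index=False, float_format="%.10g")

    # ---- ratios ---------------------------------------------------------
    if ratio_pairs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                series = ratio_trajectories(a_r, table.data, ratio_pairs)
        except ValueError as exc:
            raise StageError("ratios", str(exc)) from exc
        pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
            out / "ratios.tsv", sep="\t", index=False, float_format="%.10g"
        )

    # ---- manifest & summary --------------------------------------------
    inputs_hashed = {
        "time_course": _sha256(tc_path),
        "metabolite_table": _sha256(mt_path),
        "pathway_gmt": _sha256(gmt_path),
        "pathway_sif": _sha256(sif_path),
    }
    if kegg_path is not None:
        inputs_hashed["kegg_map"] = _sha256(Path(kegg_path))
    outputs = sorted(p.name for p in out.glob("*") if p.name not in ("manifest.json", "summary.txt"))
    manifest = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
        "config": cfg,
        "seed": seed,
        "thresholds": {
            "vip": vip_threshold,
            "neg_log_p": neg_log_p_cutoff,
            "log_base": log_base,
        },
        "input_sha256": inputs_hashed,
        "output_sha256": {name: _sha256(out / name) for name in outputs},
        "unmapped_metabolites": sorted(unmapped),
    }
    _write_json(out / "manifest.json", manifest)

    n_pass = int(enrich_df["passes_filter"].sum()) if len(enrich_df) else 0
    type_counts = typed_frame(typed)["type_label"].value_counts().sort_index()
    lines = [
        f"fermnet {__version__} pipeline summary",
        f"samples: {len(table.data)}  metabolites: {len(cols)}  pathways: {len(library)}",
        "",
        "model fit:",
    ]
    for resp, s in summaries.items():
        lines.append(
            f"  {resp}: A={s['n_components']}  R2X={s['r2x']:.3f}  R2Y={s['r2y']:.3f}  Q2={s['q2']:.3f}"
        )
    lines.append("")
    lines.append("metabolite types: " + "  ".join(f"{k}={v}" for k, v in type_counts.items()))
    lines.append(f"pathway results passing -log(p) filter: {n_pass}")
    lines.append(
        f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges"
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out


# ---------------------------------------------------------------------------
# synthetic input bundle


def _effect_class(bg: float, bb: float) -> str | None:
    if bg == 0 and bb == 0:
        return None
    parts = []
    if bg > 0:
        parts.append("g+")
    elif bg < 0:
        parts.append("g-")
    if bb > 0:
        parts.append("b+")
    elif bb < 0:
        parts.append("b-")
    return "".join(parts)


def default_design(seed: int = 0, effect: float | None = None, noise_sd: float = 0.15) -> SimulationDesign:
    """A 4x5x97 design with planted effects at 3x the noise SD."""
    if effect is None:
        effect = 3.0 * noise_sd
    planted = (
        [(j, effect, 0.0) for j in range(0, 10)]
        + [(j, -effect, 0.0) for j in range(10, 18)]
        + [(j, 0.0, effect) for j in range(18, 28)]
        + [(j, 0.0, -effect) for j in range(28, 36)]
        + [(j, effect, -effect) for j in range(36, 44)]
    )
    return SimulationDesign(planted_effects=planted, noise_sd=noise_sd, seed=seed)


def simulate_bundle(design_cfg, out_dir) -> Path:
    """Generate a complete synthetic input set plus a ready-to-run config.

    ``design_cfg`` is a mapping (or YAML path) with optional sections
    ``fermentation`` (parameter overrides), ``metabolome`` (design fields)
    and ``library`` (n_pathways, size_range, planted: {index: class},
    seed). Writes the time course, peak-area table, KEGG map, pathway
    GMT/SIF, ground truth, the echoed design, and ``run_config.yaml``.
    """
    cfg = _load_config(design_cfg) if design_cfg is not None else {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        ferm = FermentationParams(**(cfg.get("fermentation") or {}))
    except TypeError as exc:
        raise ConfigError(f"fermentation section: {exc}") from exc
    met_cfg = cfg.get("metabolome")
    try:
        design = SimulationDesign.from_dict(met_cfg) if met_cfg else default_design()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"metabolome section: {exc}") from exc
    lib_cfg = cfg.get("library") or {}

    try:
        tc = simulate_fermentation(ferm, seed=design.seed)
        phen = phenotype_at(tc, design.sample_times_h)
        table, truth = simulate_metabolome(phen, design)
    except ValueError as exc:
        raise StageError("simulate", str(exc)) from exc

    kegg = design.kegg_ids()
    pools: dict[str, list[str]] = {}
    for row in truth.effects.itertuples(index=False):
        cls = _effect_class(row.beta_g, row.beta_b)
        if cls is not None:
            pools.setdefault(cls, []).append(row.kegg_id)
    background = [kegg[m] for m in design.metabolite_names()]

    planted_assignment = lib_cfg.get("planted")
    if planted_assignment is None:
        planted_assignment = {i: cls for i, cls in enumerate(sorted(pools))}
    planted_assignment = {int(k): str(v) for k, v in planted_assignment.items()}
    try:
        library, planted = make_pathway_library(
            pools,
            background,
            n_pathways=int(lib_cfg.get("n_pathways", 12)),
            size_range=tuple(lib_cfg.get("size_range", (4, 10))),
            planted_type_assignment=planted_assignment,
            planted_fraction=float(lib_cfg.get("planted_fraction", 0.6)),
            graph_kind=str(lib_cfg.get("graph_kind", "dag")),
            seed=int(lib_cfg.get("seed", design.seed)),
        )
    except ValueError as exc:
        raise StageError("simulate", str(exc)) from exc
    truth.planted_pathways = planted

    tc.to_tsv(out / "time_course.tsv")
    table.to_tsv(out / "metabolite_table.tsv")
    table.kegg_map_frame().to_csv(out / "kegg_map.tsv", sep="\t", index=False)
    library.write_gmt(out / "pathways.gmt")
    library.write_sif(out / "pathways.sif")
    truth.effects.to_csv(out / "ground_truth_metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "pathway": list(planted),
            "planted_class": [planted[k] if planted[k] else "NA" for k in planted],
        }
    ).to_csv(out / "ground_truth_pathways.tsv", sep="\t", index=False)
    _write_json(out / "design.json", design.to_dict())

    run_cfg = {
        "inputs": {
            "time_course": str(out / "time_course.tsv"),
            "metabolite_table": str(out / "metabolite_table.tsv"),
            "kegg_map": str(out / "kegg_map.tsv"),
            "internal_standard": table.internal_standard,
            "pathway_gmt": str(out / "pathways.gmt"),
            "pathway_sif": str(out / "pathways.sif"),
        },
        "seed": design.seed,
        "ratio_pairs": [["met_000", "met_001"]],
    }
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return out
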