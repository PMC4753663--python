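"""Synthetic data generation with planted structure.

Provides the three generators the rest of the pipeline is tested
against:

* a four-phase batch fermentation time course (lag / exponential /
  stationary / decline) with solvent onset tied to the organic-acid peak;
* a metabolome peak-area table whose log relative abundances carry
  planted linear effects of the growth rate and the product-formation
  rate, plus a deuterated internal-standard channel;
* a pathway library (compound sets + directed compound graphs) in which
  chosen pathways are enriched for one planted effect class.

Every generator is deterministic given its seed. Randomness is split
into per-component substreams (one per metabolite, one for the internal
standard) so that enlarging the design never reshuffles existing
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.interpolate import PchipInterpolator

from .pathways import Pathway, PathwayLibrary
from .tables import REPLICATE_COL, TIME_COL, MetaboliteTable, PhenotypeVector, TimeCourse

__all__ = [
    "FermentationParams",
    "SimulationDesign",
    "GroundTruth",
    "simulate_fermentation",
    "simulate_metabolome",
    "make_pathway_library",
]

_IS_COLUMN = "IS_succinate_d4"
_IS_STREAM_KEY = 1_000_003  # substream id reserved for the internal standard


@dataclass
class FermentationParams:
    """Four-phase batch fermentation parameters.

    ``phase_bounds_h`` are the (start, lag end, log end, stationary end,
    decline end) times; ``mu_phases`` the specific growth rate held in
    each of the four phases. Butanol follows a sigmoid centered at
    ``butanol_mid_h`` with time constant ``butanol_tau_h``; acids peak at
    ``acid_peak_h`` and then decay toward a residual level.
    """

    phase_bounds_h: tuple[float, ...] = (0.0, 12.0, 45.0, 63.0, 84.0)
    mu_phases: tuple[float, ...] = (0.010, 0.090, 0.0048, -0.005)
    od0: float = 0.2
    dcw_per_od: float = 0.3
    dt_h: float = 1.0
    acid_peak_h: float = 32.0
    acetate_peak_g_l: float = 2.5
    butyrate_peak_g_l: float = 3.0
    acid_residual_g_l: float = 0.3
    butanol_max_g_l: float = 12.0
    butanol_mid_h: float = 50.0
    butanol_tau_h: float = 3.0
    glucose0_g_l: float = 60.0
    glucose_per_od: float = 3.0
    glucose_per_butanol: float = 3.0
    ph_knots: tuple[tuple[float, float], ...] = ((0.0, 6.8), (12.0, 4.3), (20.0, 4.4), (84.0, 4.0))
    noise_sd: float = 0.0

    def validate(self) -> None:
        b = np.asarray(self.phase_bounds_h, dtype=float)
        if len(b) != 5 or np.any(np.diff(b) <= 0):
            raise ValueError("phase boundaries must be 5 strictly increasing times")
        if len(self.mu_phases) != 4 or not np.all(np.isfinite(self.mu_phases)):
            raise ValueError("need 4 finite phase growth rates")
        if self.od0 <= 0 or self.dcw_per_od <= 0 or self.dt_h <= 0:
            raise ValueError("od0, dcw_per_od and dt_h must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _acid_profile(t: np.ndarray, peak: float, residual: float, t_peak: float) -> np.ndarray:
    # gamma-shaped pulse: 0 at t=0, max = peak at t_peak, decays toward residual
    u = np.clip(t / t_peak, 0.0, None)
    pulse = (u * np.exp(1.0 - u)) ** 2
    return residual * (1.0 - np.exp(-u)) + (peak - residual) * pulse


def simulate_fermentation(params: FermentationParams | None = None, seed: int = 0) -> TimeCourse:
    """Generate a four-phase fermentation time course.

    OD integrates the piecewise-constant growth rate exactly; DCW is a
    fixed multiple of OD. Butanol stays near zero before the acid peak
    and then rises sigmoidally; acetate and butyrate rise to a peak and
    fall; pH falls, bumps, then drifts down. With ``noise_sd > 0`` each
    concentration trace gets multiplicative log-normal measurement noise.
    """
    params = params or FermentationParams()
    params.validate()
    b = np.asarray(params.phase_bounds_h, dtype=float)
    t = np.arange(b[0], b[-1] + 0.5 * params.dt_h, params.dt_h)

    mu = np.asarray(params.mu_phases, dtype=float)
    # cumulative growth integral of the piecewise-constant mu(t)
    growth = np.zeros_like(t)
    for i in range(4):
        lo, hi = b[i], b[i + 1]
        growth += mu[i] * (np.clip(t, lo, hi) - lo)
    od = params.od0 * np.exp(growth)

    butanol = params.butanol_max_g_l / (
        1.0 + np.exp(-(t - params.butanol_mid_h) / params.butanol_tau_h)
    )
    acetate = _acid_profile(t, params.acetate_peak_g_l, params.acid_residual_g_l, params.acid_peak_h)
    butyrate = _acid_profile(t, params.butyrate_peak_g_l, params.acid_residual_g_l, params.acid_peak_h)
    glucose = (
        params.glucose0_g_l
        - params.glucose_per_od * (od - params.od0)
        - params.glucose_per_butanol * butanol
    )
    knots = np.asarray(params.ph_knots, dtype=float)
    ph = PchipInterpolator(knots[:, 0], knots[:, 1])(np.clip(t, knots[0, 0], knots[-1, 0]))

    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        for arr in (od, butanol, acetate, butyrate, glucose):
            arr *= np.exp(params.noise_sd * rng.standard_normal(len(t)))

    data = pd.DataFrame(
        {
            "time_h": t,
            "od600": od,
            "dcw_g_l": params.dcw_per_od * od,
            "butanol_g_l": np.clip(butanol, 0.0, None),
            "acetate_g_l": np.clip(acetate, 0.0, None),
            "butyrate_g_l": np.clip(butyrate, 0.0, None),
            "glucose_g_l": np.clip(glucose, 0.0, None),
            "ph": ph,
        }
    )
    return TimeCourse(data)


@dataclass
class SimulationDesign:
    """Metabolome sampling design with planted phenotype effects.

    ``planted_effects`` lists ``(metabolite_index, beta_g, beta_b)``:
    log-abundance slopes on the standardized growth rate and standardized
    product-formation rate respectively.
    """

    sample_times_h: tuple[float, ...] = (24.0, 48.0, 60.0, 80.0)
    n_replicates: int = 5
    n_metabolites: int = 97
    planted_effects: list[tuple[int, float, float]] = field(default_factory=list)
    noise_sd: float = 0.15
    seed: int = 0
    intercept_mean: float = -4.6  # ln scale; exp(-4.6) ~ 0.01 relative abundance
    intercept_sd: float = 1.0
    is_area: float = 1.0e6
    is_noise_sd: float = 0.02

    @property
    def n_times(self) -> int:
        return len(self.sample_times_h)

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per sampling time")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_metabolites < 1:
            raise ValueError("need at least one metabolite")
        for j, _, _ in self.planted_effects:
            if not (0 <= j < self.n_metabolites):
                raise ValueError(f"planted metabolite index {j} out of range")

    def metabolite_names(self) -> list[str]:
        width = max(3, len(str(self.n_metabolites - 1)))
        return [f"met_{j:0{width}d}" for j in range(self.n_metabolites)]

    def kegg_ids(self) -> dict[str, str]:
        return {name: f"C9{j:04d}" for j, name in enumerate(self.metabolite_names())}

    def to_dict(self) -> dict:
        return {
            "sample_times_h": list(self.sample_times_h),
            "n_replicates": self.n_replicates,
            "n_metabolites": self.n_metabolites,
            "planted_effects": [list(e) for e in self.planted_effects],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        known = {
            "sample_times_h",
            "n_replicates",
            "n_metabolites",
            "planted_effects",
            "noise_sd",
            "seed",
            "intercept_mean",
            "intercept_sd",
            "is_area",
            "is_noise_sd",
        }
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown design keys: {sorted(extra)}")
        d = dict(d)
        if "sample_times_h" in d:
            d["sample_times_h"] = tuple(float(x) for x in d["sample_times_h"])
        if "planted_effects" in d:
            d["planted_effects"] = [
                (int(j), float(bg), float(bb)) for j, bg, bb in d["planted_effects"]
            ]
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted: per-metabolite effects and per-pathway flags."""

    effects: pd.DataFrame  # metabolite, beta_g, beta_b, sign_g, sign_b
    planted_pathways: dict[str, str | None] = field(default_factory=dict)

    def planted_for(self, response: str) -> pd.DataFrame:
        col = {"growth": "beta_g", "butanol": "beta_b"}[response]
        return self.effects[self.effects[col] != 0.0]


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("phenotype has no variance across sampling times")
    return (v - v.mean()) / sd


def simulate_metabolome(
    phenotype: PhenotypeVector, design: SimulationDesign
) -> tuple[MetaboliteTable, GroundTruth]:
    """Generate a peak-area table with planted mu/q effects.

    The planted linear model lives on the *relative abundance* scale:
    ``ln A_r[s, j] = intercept_j + beta_g * z(mu_s) + beta_b * z(q_s) + eps``
    with ``z`` the standardization of the phenotype across sampling times
    and ``eps ~ Normal(0, noise_sd)``. Emitted peak areas are
    ``A_i = A_r * DCW_s * A_s`` so that downstream internal-standard
    normalization recovers the planted matrix exactly.
    """
    design.validate()
    times = np.asarray(design.sample_times_h, dtype=float)
    if len(np.unique(times)) < 2:
        raise ValueError("need at least 2 distinct sampling times to plant phenotype effects")
    ph_times = np.asarray(phenotype.time_h, dtype=float)
    idx = []
    for ti in times:
        hits = np.where(np.isclose(ph_times, ti))[0]
        if not hits.size:
            raise ValueError(f"phenotype has no entry for sampling time {ti} h")
        idx.append(hits[0])
    idx = np.asarray(idx)
    z_mu = _standardize(phenotype.mu[idx])
    z_q = _standardize(phenotype.q[idx])
    dcw_t = (
        phenotype.dcw_g_l[idx]
        if phenotype.dcw_g_l is not None
        else np.ones(len(times))
    )

    n_rep = design.n_replicates
    n_samples = len(times) * n_rep
    rep_of = np.tile(np.arange(1, n_rep + 1), len(times))
    time_of = np.repeat(times, n_rep)
    z_mu_s = np.repeat(z_mu, n_rep)
    z_q_s = np.repeat(z_q, n_rep)
    dcw_s = np.repeat(dcw_t, n_rep)

    betas = np.zeros((design.n_metabolites, 2))
    for j, bg, bb in design.planted_effects:
        betas[j, 0] += bg
        betas[j, 1] += bb

    names = design.metabolite_names()
    cols = {}
    for j, name in enumerate(names):
        rng = np.random.default_rng([design.seed, j])
        intercept = design.intercept_mean + design.intercept_sd * rng.standard_normal()
        eps = design.noise_sd * rng.standard_normal(n_samples)
        log_ar = intercept + betas[j, 0] * z_mu_s + betas[j, 1] * z_q_s + eps
        cols[name] = np.exp(log_ar)

    rng_is = np.random.default_rng([design.seed, _IS_STREAM_KEY])
    a_s = design.is_area * np.exp(design.is_noise_sd * rng_is.standard_normal(n_samples))

    data = pd.DataFrame({TIME_COL: time_of, REPLICATE_COL: rep_of})
    for name in names:
        data[name] = cols[name] * dcw_s * a_s
    data[_IS_COLUMN] = a_s

    table = MetaboliteTable(data, internal_standard=_IS_COLUMN, kegg_ids=design.kegg_ids())
    effects = pd.DataFrame(
        {
            "metabolite": names,
            "kegg_id": [design.kegg_ids()[n] for n in names],
            "beta_g": betas[:, 0],
            "beta_b": betas[:, 1],
            "sign_g": np.sign(betas[:, 0]).astype(int),
            "sign_b": np.sign(betas[:, 1]).astype(int),
        }
    )
    return table, GroundTruth(effects=effects)


def make_pathway_library(
    compound_pools: dict[str, list[str]],
    background: list[str],
    n_pathways: int,
    size_range: tuple[int, int] = (4, 10),
    planted_type_assignment: dict[int, str] | None = None,
    planted_fraction: float = 0.6,
    graph_kind: str = "dag",
    edge_p: float = 0.4,
    neutral_pool: list[str] | None = None,
    seed: int = 0,
) -> tuple[PathwayLibrary, dict[str, str | None]]:
    """Build a fixture pathway library with optionally planted pathways.

    Planted pathways (indices in ``planted_type_assignment``) draw at
    least ``planted_fraction`` of their members from the named compound
    pool; the remainder draws uniformly from the background. Neutral
    pathways draw from ``neutral_pool`` when given (e.g. effect-free
    compounds only, so they carry no planted signal), else from the full
    background. Each pathway carries a directed acyclic graph
    (``graph_kind='dag'``) or a simple chain on its members.

    Returns the library plus a ``{pathway_id: pool name or None}`` map of
    what was planted where.
    """
    lo, hi = size_range
    if lo < 2:
        raise ValueError("pathway sizes must be at least 2")
    if hi < lo:
        raise ValueError("size_range must be (lo, hi) with hi >= lo")
    background = list(dict.fromkeys(background))
    planted_type_assignment = planted_type_assignment or {}
    for i, pool in planted_type_assignment.items():
        if pool not in compound_pools:
            raise ValueError(f"unknown compound pool {pool!r} for pathway index {i}")

    rng = np.random.default_rng(seed)
    pathways: list[Pathway] = []
    planted: dict[str, str | None] = {}
    for i in range(n_pathways):
        pid = f"path_{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        pool_name = planted_type_assignment.get(i)
        if pool_name is not None:
            pool = list(dict.fromkeys(compound_pools[pool_name]))
            n_planted = int(np.ceil(planted_fraction * size))
            if n_planted > len(pool):
                raise ValueError(
                    f"pathway {pid}: needs {n_planted} members from pool {pool_name!r} "
                    f"but only {len(pool)} available"
                )
            members = list(rng.choice(pool, size=n_planted, replace=False))
            rest = [c for c in background if c not in members]
            n_rest = min(size - n_planted, len(rest))
            members += list(rng.choice(rest, size=n_rest, replace=False))
        else:
            pool = background if neutral_pool is None else list(dict.fromkeys(neutral_pool))
            if size > len(pool):
                raise ValueError(f"pathway {pid}: size {size} exceeds available compounds")
            members = list(rng.choice(pool, size=size, replace=False))
        order = [members[k] for k in rng.permutation(len(members))]
        g = nx.DiGraph()
        g.add_nodes_from(sorted(members))
        if graph_kind == "chain":
            g.add_edges_from(zip(order[:-1], order[1:]))
        elif graph_kind == "dag":
            for a in range(len(order)):
                for b in range(a + 1, len(order)):
                    if rng.random() < edge_p:
                        g.add_edge(order[a], order[b])
            # keep it connected enough: guarantee the chain backbone
            g.add_edges_from(zip(order[:-1], order[1:]))
        else:
            raise ValueError(f"unknown graph_kind {graph_kind!r}")
        pathways.append(Pathway(id=pid, name=f"synthetic pathway {i}", compounds=frozenset(members), graph=g))
        planted[pid] = pool_name
    return PathwayLibrary(pathways), planted
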