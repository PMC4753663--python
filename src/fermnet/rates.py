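"""Specific-rate and relative-abundance calculations.

Implements the three quantitative primitives of the pipeline:

* relative abundance  ``A_r = A_i / (DCW * A_s)``
* specific butanol production rate  ``q = dc / (DCW * dt)``
* specific growth rate  ``mu = d ln(OD) / dt``  (natural log)

Derivatives default to central finite differences on the sampled grid
(one-sided at the ends); a cubic smoothing-spline mode is available for
noisy data. Negative rates are retained, never clipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline

from .tables import MetaboliteTable, TimeCourse

__all__ = [
    "relative_abundance",
    "compute_mu",
    "compute_q",
    "display_transform",
]


def _gradient(y: np.ndarray, t: np.ndarray, method: str = "central", smoothing: float | None = None) -> np.ndarray:
    """Derivative dy/dt on a (possibly non-uniform) strictly increasing grid.

    ``central``: second-order central differences, one-sided at the ends
    (numpy.gradient). ``spline``: derivative of a cubic smoothing spline;
    ``smoothing`` is the spline's residual target (None = scipy default).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 time points to differentiate")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if method == "central":
        return np.gradient(y, t)
    if method == "spline":
        k = min(3, len(t) - 1)
        spl = UnivariateSpline(t, y, k=k, s=smoothing)
        return spl.derivative()(t)
    raise ValueError(f"unknown derivative method {method!r}")


def compute_mu(tc: TimeCourse, method: str = "central", smoothing: float | None = None) -> pd.Series:
    """Specific growth rate series mu(t) = d ln(OD600)/dt, per hour."""
    od = tc.column("od600")
    if np.any(~np.isfinite(od)) or np.any(od <= 0):
        raise ValueError("OD600 must be finite and > 0 to compute mu")
    mu = _gradient(np.log(od), tc.t, method=method, smoothing=smoothing)
    return pd.Series(mu, index=pd.Index(tc.t, name="time_h"), name="mu_per_h")


def compute_q(tc: TimeCourse, method: str = "central", smoothing: float | None = None) -> pd.Series:
    """Specific butanol production rate q(t) = (dc/dt) / DCW, per hour."""
    c = tc.column("butanol_g_l")
    dcw = tc.column("dcw_g_l")
    if np.any(~np.isfinite(c)):
        raise ValueError("butanol concentrations must be finite")
    if np.any(~np.isfinite(dcw)) or np.any(dcw <= 0):
        raise ValueError("DCW must be finite and > 0 to compute q")
    dc_dt = _gradient(c, tc.t, method=method, smoothing=smoothing)
    return pd.Series(dc_dt / dcw, index=pd.Index(tc.t, name="time_h"), name="q_per_h")


def relative_abundance(table: MetaboliteTable, dcw_per_sample) -> pd.DataFrame:
    """Internal-standard + biomass normalized abundance matrix.

    ``A_r[s, j] = A_i[s, j] / (DCW_s * A_s[s])``. The internal-standard
    column is removed from the output. Rows with non-positive DCW are
    rejected with an explicit diagnostic (non-positive internal-standard
    areas are already rejected at table construction).

    Parameters
    ----------
    table:
        Peak-area table with internal-standard column designated.
    dcw_per_sample:
        Dry cell weight (g/L) per row of the table, in row order, or a
        scalar applied to all rows.

    Returns
    -------
    DataFrame indexed like ``table.data`` with one column per metabolite.
    """
    dcw = np.broadcast_to(np.asarray(dcw_per_sample, dtype=float), (len(table.data),)).copy()
    bad = np.where(~np.isfinite(dcw) | (dcw <= 0))[0]
    if bad.size:
        keys = table.data.iloc[bad][["time_h", "replicate"]].to_records(index=False).tolist()
        raise ValueError(f"non-positive DCW for samples {keys}; cannot normalize")
    a_s = table.internal_standard_areas()
    areas = table.areas().to_numpy(dtype=float)
    a_r = areas / (dcw * a_s)[:, None]
    return pd.DataFrame(a_r, index=table.data.index, columns=table.metabolites)


def display_transform(a_r) -> np.ndarray | pd.DataFrame:
    """log10(10000 * A_r) display scaling for abundance heatmaps."""
    values = a_r.to_numpy(dtype=float) if isinstance(a_r, pd.DataFrame) else np.asarray(a_r, dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("display transform requires strictly positive abundances")
    out = np.log10(1e4 * values)
    if isinstance(a_r, pd.DataFrame):
        return pd.DataFrame(out, index=a_r.index, columns=a_r.columns)
    return out


def phenotype_at(tc: TimeCourse, sample_times, method: str = "central", smoothing: float | None = None):
    """Evaluate (mu, q, DCW) at the metabolome sampling times.

    Rates are computed on the full time course and then read off at the
    requested times, which must be on the sampled grid.
    """
    from .tables import PhenotypeVector

    mu = compute_mu(tc, method=method, smoothing=smoothing)
    q = compute_q(tc, method=method, smoothing=smoothing)
    t = np.asarray(sample_times, dtype=float)
    grid = tc.t
    idx = []
    for ti in t:
        hits = np.where(np.isclose(grid, ti))[0]
        if not hits.size:
            raise ValueError(f"sampling time {ti} h is not on the time-course grid")
        idx.append(hits[0])
    idx = np.asarray(idx)
    return PhenotypeVector(
        time_h=t,
        mu=mu.to_numpy()[idx],
        q=q.to_numpy()[idx],
        dcw_g_l=tc.column("dcw_g_l")[idx],
    )
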