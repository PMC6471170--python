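"""Non-compartmental analysis of concentration–time profiles.

AUC uses the linear-up/log-down trapezoid (linear trapezoid on rising or flat
segments, log trapezoid on declining segments), the convention of standard
NCA software. Extrapolation to infinity comes from a log-linear regression on
the last ``n_terminal`` positive concentrations; a non-negative terminal slope
flags ``auc_inf`` (and everything derived from it) as unavailable instead of
guessing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import ConcentrationProfile

__all__ = ["PKParameters", "compute_nca", "summarize", "params_to_frame"]


@dataclass(frozen=True)
class PKParameters:
    """NCA outputs for one profile.

    cmax in the profile's concentration units (ng/mL); tmax h; auc_last and
    auc_inf in conc·h; cl_f in L/h (dose/AUC∞); f is the model-reported oral
    bioavailability when the profile carries it; vss in L (model-reported).
    ``lambda_z`` is the terminal slope (1/h). ``auc_inf``/``cl_f`` are NaN
    when the terminal phase could not be characterized.
    """

    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    cl_f: float
    lambda_z: float
    f: float = float("nan")
    vss: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "cmax": self.cmax,
            "tmax": self.tmax,
            "auc_last": self.auc_last,
            "auc_inf": self.auc_inf,
            "cl_f": self.cl_f,
            "lambda_z": self.lambda_z,
            "f": self.f,
            "vss": self.vss,
        }


def _auc_lin_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    lin = (c1 + c2) / 2.0 * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        logseg = (c1 - c2) / (np.log(c1) - np.log(c2)) * dt
    use_log = (c2 < c1) & (c2 > 0) & (c1 > 0)
    return float(np.sum(np.where(use_log, logseg, lin)))


def auc_trapezoid(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-up/log-down AUC over the observed grid."""
    t = np.asarray(t, float)
    c = np.asarray(c, float)
    if t.ndim != 1 or t.shape != c.shape or t.size < 2:
        raise ValueError("need matching 1-D arrays with >= 2 samples")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return _auc_lin_up_log_down(t, c)


def compute_nca(
    profile: ConcentrationProfile,
    dose: float | None = None,
    n_terminal: int = 5,
) -> PKParameters:
    """Compute NCA parameters from one profile.

    ``dose`` defaults to the profile's regimen amount (mg). ``n_terminal``
    is the number of trailing positive samples entering the terminal
    log-linear regression.
    """
    t, c = profile.times, profile.conc
    if dose is None:
        dose = profile.dose.amount
    if not dose > 0:
        raise ValueError("dose must be > 0 for NCA")
    if not np.any(c > 0):
        raise ValueError("profile has no measurable exposure (all zero)")
    if n_terminal < 2:
        raise ValueError("n_terminal must be >= 2")

    imax = int(np.argmax(c))  # earliest index on ties
    cmax = float(c[imax])
    tmax = float(t[imax])
    auc_last = _auc_lin_up_log_down(t, c)

    # ignore samples vanishingly small relative to the peak (numerical floor
    # of the integrator, far below any real quantification limit)
    pos = np.flatnonzero(c > cmax * 1e-9)
    tail = pos[pos > imax][-n_terminal:]
    lambda_z = float("nan")
    auc_inf = float("nan")
    cl_f = float("nan")
    if tail.size >= 2:
        slope, _ = np.polyfit(t[tail], np.log(c[tail]), 1)
        if slope < 0:
            lambda_z = -float(slope)
            auc_inf = auc_last + float(c[pos[-1]]) / lambda_z
            # dose mg, auc ng·h/mL -> L/h
            cl_f = dose / auc_inf * 1000.0
    if math.isnan(auc_inf):
        warnings.warn(
            "terminal slope is non-negative or unidentifiable; auc_inf/cl_f "
            "reported as NaN",
            stacklevel=2,
        )

    return PKParameters(
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        auc_inf=auc_inf,
        cl_f=cl_f,
        lambda_z=lambda_z,
        f=float(profile.meta.get("f", float("nan"))),
        vss=float(profile.meta.get("vss", float("nan"))),
    )


def params_to_frame(records: list[dict]) -> pd.DataFrame:
    """One row per subject; ``records`` are dicts of keys + PKParameters fields."""
    return pd.DataFrame(records)


_PARAM_COLS = ["cmax", "tmax", "auc_inf", "cl_f", "f", "vss"]


def summarize(
    frame: pd.DataFrame,
    grouping: list[str] | None = None,
    params: list[str] | None = None,
) -> pd.DataFrame:
    """Geometric mean, arithmetic mean, median and CV per parameter per group.

    Empty groups are excluded with a warning; row order is deterministic
    (sorted by the grouping keys).
    """
    params = params or [p for p in _PARAM_COLS if p in frame.columns]

    def _agg(g: pd.DataFrame) -> pd.Series:
        out = {}
        for p in params:
            x = g[p].dropna().to_numpy(float)
            x = x[x > 0] if p != "tmax" else x
            if x.size == 0:
                out[f"{p}_geomean"] = np.nan
                out[f"{p}_mean"] = np.nan
                out[f"{p}_median"] = np.nan
                out[f"{p}_cv"] = np.nan
                continue
            out[f"{p}_geomean"] = float(np.exp(np.mean(np.log(x)))) if np.all(x > 0) else np.nan
            out[f"{p}_mean"] = float(np.mean(x))
            out[f"{p}_median"] = float(np.median(x))
            out[f"{p}_cv"] = float(np.std(x, ddof=1) / np.mean(x)) if x.size > 1 else 0.0
        out["n"] = len(g)
        return pd.Series(out)

    if not grouping:
        if frame.empty:
            raise ValueError("cannot summarize an empty table")
        return _agg(frame).to_frame().T
    res = (
        frame.groupby(grouping, sort=True, dropna=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    empty = res["n"] == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} empty group(s) excluded", stacklevel=2)
        res = res[~empty]
    return res
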