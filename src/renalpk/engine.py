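"""Mechanistic PK engine: oral absorption, one-compartment disposition,
well-stirred hepatic clearance with competitive inhibition, renal filtration.

Model
-----
A dose D (mg) enters a gut depot; the absorbable fraction ``f_abs·f_gut``
transfers to the central compartment with first-order rate ``ka`` after
hepatic first pass. Hepatic clearance follows the well-stirred model

    CL_h = Q_h · fu_b · CL_int,u / (Q_h + fu_b · CL_int,u)

with ``fu_b = fu / bp_ratio`` the unbound fraction in blood and the unbound
intrinsic clearance summed over enzyme pathways. Competitive inhibition by an
inhibitor at concentration [I] with constant Ki enters through the factor
``R = [I]/Ki``, which multiplies the apparent Michaelis constant:

    v = Vmax · S / (KM · (1 + R) + S)

In the default linear mode (substrate well below KM) CL_int,u reduces to
``Σ Vmax·abundance/(KM·(1+R))`` and the system has the classic closed-form
one-compartment oral solution, which is evaluated directly. A
Michaelis–Menten mode saturates CL_int with the unbound systemic
concentration and integrates the ODEs numerically. Renal clearance is
filtration only: ``CL_r = fu · GFR · renal_filtration_fraction``.

Oral bioavailability is mechanistic: ``F = f_abs · f_gut · (1 − CL_h/Q_h)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .compounds import CompoundModel
from .population import Subject

__all__ = [
    "DoseRegimen",
    "ConcentrationProfile",
    "SimulationError",
    "mm_rate",
    "intrinsic_clearance",
    "hepatic_clearance",
    "renal_clearance",
    "distribution_volume",
    "simulate",
]

# pmol/min per µM == µL/min; convert to L/h
_UL_PER_MIN_TO_L_PER_H = 60.0 / 1.0e6
_ML_PER_MIN_TO_L_PER_H = 60.0 / 1000.0


class SimulationError(RuntimeError):
    """ODE integration failed; message carries solver diagnostics."""


@dataclass(frozen=True)
class DoseRegimen:
    """Single oral dose; ``amount`` in mg (0 allowed as a null-dose control)."""

    amount: float
    route: str = "oral"
    time: float = 0.0  # h
    fasted: bool = True

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError(f"amount must be >= 0, got {self.amount}")
        if self.route != "oral":
            raise ValueError(f"only oral dosing is supported, got {self.route!r}")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Plasma concentration–time profile (ng/mL on a strictly increasing grid).

    ``meta`` carries the model-derived quantities NCA cannot infer from the
    curve alone: bioavailability F, distribution volume, and the clearance
    decomposition at the linearized operating point.
    """

    times: np.ndarray  # h
    conc: np.ndarray  # ng/mL
    dose: DoseRegimen
    subject: Subject | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and conc must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < -1e-9):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", np.clip(c, 0.0, None))


def mm_rate(s: float, vmax: float, km: float, r: float = 0.0):
    """Michaelis–Menten rate with competitive inhibition.

    ``v = vmax·s / (km·(1+r) + s)``: increasing R lowers the apparent
    affinity (KM multiplied by ``1+r``) without changing Vmax.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("substrate concentration must be >= 0")
    if not vmax > 0 or not km > 0:
        raise ValueError("vmax and km must be > 0")
    if r < 0:
        raise ValueError("r must be >= 0")
    out = vmax * s / (km * (1.0 + r) + s)
    return float(out) if out.ndim == 0 else out


def intrinsic_clearance(compound: CompoundModel, subject: Subject) -> float:
    """Unbound hepatic intrinsic clearance in the linear range, L/h.

    ``Σ_pathways Vmax·abundance / (KM·(1+R))`` with Vmax in pmol/min/pmol
    enzyme, total abundance in pmol, KM in µM. Additive over pathways.
    """
    if not compound.pathways:
        return 0.0
    total = 0.0
    for p in compound.pathways:
        abundance = subject.enzyme_abundance.get(p.enzyme)
        if abundance is None:
            raise KeyError(
                f"subject lacks abundance for {p.enzyme}; has "
                f"{sorted(subject.enzyme_abundance)}"
            )
        total += p.vmax * abundance / (p.km * (1.0 + p.r_inhibition))
    return total * _UL_PER_MIN_TO_L_PER_H


def hepatic_clearance(clint_u: float, fu_b: float, q_h: float) -> float:
    """Well-stirred hepatic blood clearance, L/h; bounded above by ``q_h``."""
    if clint_u < 0 or not fu_b > 0 or not q_h > 0:
        raise ValueError("clint_u must be >= 0; fu_b and q_h must be > 0")
    x = fu_b * clint_u
    return q_h * x / (q_h + x)


def renal_clearance(compound: CompoundModel, subject: Subject) -> float:
    """Filtration renal plasma clearance ``fu·GFR·filtered fraction``, L/h."""
    return (
        compound.fu
        * subject.gfr
        * compound.renal_filtration_fraction
        * _ML_PER_MIN_TO_L_PER_H
    )


def distribution_volume(compound: CompoundModel, subject: Subject) -> float:
    """Distribution volume (L), scaled ∝ fu relative to the compound's base fu."""
    return compound.vss_per_kg * subject.weight * (compound.fu / compound.fu_reference)


def _operating_point(compound: CompoundModel, subject: Subject) -> dict:
    clint_u = intrinsic_clearance(compound, subject)
    fu_b = compound.fu / compound.bp_ratio
    cl_h_blood = hepatic_clearance(clint_u, fu_b, subject.q_h) if clint_u > 0 else 0.0
    e_h = cl_h_blood / subject.q_h
    cl_h_plasma = cl_h_blood * compound.bp_ratio
    cl_r = renal_clearance(compound, subject)
    vss = distribution_volume(compound, subject)
    f_oral = compound.f_abs * compound.f_gut * (1.0 - e_h)
    return {
        "clint_u": clint_u,
        "fu_b": fu_b,
        "cl_h_blood": cl_h_blood,
        "cl_h_plasma": cl_h_plasma,
        "cl_r_plasma": cl_r,
        "cl_plasma": cl_h_plasma + cl_r,
        "extraction_ratio": e_h,
        "f": f_oral,
        "vss": vss,
    }


def _closed_form_conc(t, dose_mg, f, v, ka, k):
    """One-compartment first-order-absorption oral solution, mg/L."""
    if np.isclose(ka, k, rtol=1e-9):
        return dose_mg * f / v * ka * t * np.exp(-ka * t)
    return (
        dose_mg
        * f
        / v
        * ka
        / (ka - k)
        * (np.exp(-k * t) - np.exp(-ka * t))
    )


def simulate(
    compound: CompoundModel,
    subject: Subject,
    regimen: DoseRegimen,
    t_end: float = 48.0,
    n_points: int = 241,
    mode: str = "linear",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationProfile:
    """Simulate one subject's plasma concentration–time profile.

    ``mode='linear'`` (default) evaluates the exact closed-form solution for
    linear-range clearance; ``mode='mm'`` integrates the ODE system with
    concentration-dependent (saturable) intrinsic clearance. The output grid
    is ``n_points`` uniform samples on [0, t_end] hours.
    """
    if mode not in {"linear", "mm"}:
        raise ValueError(f"mode must be 'linear' or 'mm', got {mode!r}")
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    op = _operating_point(compound, subject)
    times = np.linspace(0.0, t_end, n_points)
    if op["cl_plasma"] <= 0:
        raise ValueError(f"compound {compound.name} has zero total clearance")

    k_el = op["cl_plasma"] / op["vss"]
    t_half = np.log(2.0) / k_el
    if t_end < 5 * t_half:
        warnings.warn(
            f"t_end={t_end} h covers only {t_end / t_half:.1f} elimination "
            "half-lives (< 5); terminal extrapolation may be unreliable",
            stacklevel=2,
        )

    meta = dict(op)
    meta["mode"] = mode
    meta["k_el"] = k_el

    if regimen.amount == 0:
        return ConcentrationProfile(times, np.zeros_like(times), regimen, subject, meta)

    if mode == "linear":
        conc_mg_l = _closed_form_conc(
            times, regimen.amount, op["f"], op["vss"], compound.ka, k_el
        )
        meta["mass_balance_error"] = 0.0
        return ConcentrationProfile(times, conc_mg_l * 1000.0, regimen, subject, meta)

    # Michaelis–Menten mode: saturable CLint driven by unbound systemic
    # concentration (static well-stirred approximation, applied to both
    # first-pass and systemic extraction).
    v = op["vss"]
    fu_b = op["fu_b"]
    q_h = subject.q_h
    cl_r = op["cl_r_plasma"]
    bp = compound.bp_ratio
    a0 = regimen.amount * compound.f_abs * compound.f_gut  # mg entering portal

    abund = np.array(
        [subject.enzyme_abundance[p.enzyme] for p in compound.pathways]
    )
    vmaxes = np.array([p.vmax for p in compound.pathways])
    km_app = np.array([p.km * (1.0 + p.r_inhibition) for p in compound.pathways])

    def clint_at(cu_um: float) -> float:
        return float(np.sum(vmaxes * abund / (km_app + cu_um))) * _UL_PER_MIN_TO_L_PER_H

    def rhs(_t, y):
        a_gut, a_c, _a_elim = y
        conc_mg_l = max(a_c, 0.0) / v
        cu_um = compound.fu * conc_mg_l / compound.mw * 1000.0
        clint = clint_at(cu_um)
        x = fu_b * clint
        cl_h_b = q_h * x / (q_h + x)
        e_h = cl_h_b / q_h
        absorbed = compound.ka * max(a_gut, 0.0)
        elim_sys = (cl_h_b * bp + cl_r) * conc_mg_l
        return [
            -compound.ka * a_gut,
            absorbed * (1.0 - e_h) - elim_sys,
            absorbed * e_h + elim_sys,
        ]

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [a0, 0.0, 0.0],
        t_eval=times,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"ODE integration failed for {compound.name}, subject {subject.id}: "
            f"{sol.message}"
        )
    a_gut, a_c, a_elim = sol.y
    meta["mass_balance_error"] = float(
        np.max(np.abs(a_gut + a_c + a_elim - a0)) / a0
    )
    conc_mg_l = np.clip(a_c, 0.0, None) / v  # solver wiggle below zero
    return ConcentrationProfile(times, conc_mg_l * 1000.0, regimen, subject, meta)
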