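"""Virtual populations: healthy, moderate and severe renal impairment.

A :class:`PopulationSpec` describes the generating distributions for one
population class — demographics, hepatic blood flow, liver scalars, per-enzyme
microsomal abundance — plus the renal-impairment handles: ``gfr_fraction``
(fraction of normal glomerular filtration rate; 1.0 / 0.5 / 0.1 for healthy,
moderate and severe classes) and an optional per-enzyme expression multiplier
applied in impaired classes (hepatic CYP expression is reduced in renal
disease).

Inter-individual variability is lognormal around the stated mean with the
stated coefficient of variation, the standard convention for physiological
and enzymological quantities.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LognormalParam",
    "PopulationSpec",
    "Subject",
    "sample_population",
    "make_standard_populations",
    "subjects_to_frame",
    "DEFAULT_ENZYME_ABUNDANCE",
    "DEFAULT_RI_EXPRESSION",
]

# Mean microsomal abundance (pmol/mg microsomal protein) and CV for adult
# human liver; literature-typical values.
DEFAULT_ENZYME_ABUNDANCE: dict[str, tuple[float, float]] = {
    "CYP3A4": (137.0, 0.41),
    "CYP3A5": (20.0, 0.80),
    "CYP2C9": (73.0, 0.50),
    "UGT2B7": (70.0, 0.45),
}

# Hepatic CYP expression multipliers applied in renally impaired classes when
# "modified expression" is enabled (UGTs are left unchanged). The magnitude of
# the reduction is not established quantitatively; these defaults are
# configurable per class, either as a scalar for all CYPs or per enzyme.
DEFAULT_RI_EXPRESSION: dict[str, float] = {"moderate": 0.85, "severe": 0.75}


@dataclass(frozen=True)
class LognormalParam:
    """Mean and coefficient of variation of a lognormally distributed quantity."""

    mean: float
    cv: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError(f"mean must be > 0, got {self.mean}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.cv == 0:
            return np.full(size, self.mean)
        sigma2 = np.log1p(self.cv**2)
        mu = np.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    gfr_fraction: float = 1.0  # fraction of normal GFR for the class
    gfr_reference: float = 120.0  # mL/min, normal adult
    gfr_cv: float = 0.15
    age_range: tuple[float, float] = (21.0, 65.0)
    sex_proportion_female: float = 0.0
    weight_male: LognormalParam = field(default_factory=lambda: LognormalParam(81.0, 0.18))
    weight_female: LognormalParam = field(default_factory=lambda: LognormalParam(66.0, 0.18))
    hepatic_blood_flow: LognormalParam = field(default_factory=lambda: LognormalParam(90.0, 0.20))  # L/h
    mppgl: LognormalParam = field(default_factory=lambda: LognormalParam(40.0, 0.30))  # mg/g liver
    liver_weight: LognormalParam = field(default_factory=lambda: LognormalParam(1650.0, 0.23))  # g
    enzyme_abundance: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ENZYME_ABUNDANCE)
    )
    ri_expression_multiplier: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.gfr_fraction <= 1):
            raise ValueError(f"gfr_fraction must be in (0, 1], got {self.gfr_fraction}")
        if not (0 <= self.sex_proportion_female <= 1):
            raise ValueError("sex_proportion_female must be in [0, 1]")
        for enz, mult in self.ri_expression_multiplier.items():
            if not (0 < mult <= 1):
                raise ValueError(
                    f"ri_expression_multiplier[{enz}] must be in (0, 1], got {mult}"
                )


@dataclass(frozen=True)
class Subject:
    """One sampled virtual individual.

    ``enzyme_abundance`` holds total hepatic enzyme in pmol (microsomal
    abundance × mg microsomal protein per g liver × liver weight), after any
    renal-impairment expression multiplier.
    """

    id: int
    trial_id: int
    sex: str
    age: float  # years
    weight: float  # kg
    gfr: float  # mL/min
    q_h: float  # hepatic blood flow, L/h
    enzyme_abundance: Mapping[str, float]  # enzyme -> total pmol

    def __post_init__(self) -> None:
        for name in ("age", "weight", "gfr", "q_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


def sample_population(
    spec: PopulationSpec, n_trials: int, n_subjects: int, seed: int
) -> list[list[Subject]]:
    """Sample ``n_trials`` trials of ``n_subjects`` virtual subjects.

    Identical ``seed`` yields identical subjects. Returns a nested list
    (trial-major); :func:`subjects_to_frame` flattens it to a table.
    """
    if n_trials < 1 or n_subjects < 1:
        raise ValueError(
            f"n_trials and n_subjects must be >= 1, got {n_trials}, {n_subjects}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_trials * n_subjects

    female = rng.random(n) < spec.sex_proportion_female
    age = rng.uniform(*spec.age_range, size=n)
    w_m = spec.weight_male.sample(rng, n)
    w_f = spec.weight_female.sample(rng, n)
    weight = np.where(female, w_f, w_m)
    gfr = LognormalParam(spec.gfr_reference * spec.gfr_fraction, spec.gfr_cv).sample(rng, n)
    q_h = spec.hepatic_blood_flow.sample(rng, n)
    mppgl = spec.mppgl.sample(rng, n)
    liver = spec.liver_weight.sample(rng, n)
    # female physiology scaled by body-size proxy only
    q_h = q_h * np.where(female, 0.85, 1.0)
    liver = liver * np.where(female, 0.85, 1.0)

    abundance: dict[str, np.ndarray] = {}
    for enzyme, (mean, cv) in spec.enzyme_abundance.items():
        per_mg = LognormalParam(mean, cv).sample(rng, n)
        mult = spec.ri_expression_multiplier.get(enzyme, 1.0)
        abundance[enzyme] = per_mg * mppgl * liver * mult  # total pmol

    trials: list[list[Subject]] = []
    idx = 0
    for t in range(n_trials):
        trial = []
        for _ in range(n_subjects):
            trial.append(
                Subject(
                    id=idx,
                    trial_id=t,
                    sex="F" if female[idx] else "M",
                    age=float(age[idx]),
                    weight=float(weight[idx]),
                    gfr=float(gfr[idx]),
                    q_h=float(q_h[idx]),
                    enzyme_abundance={e: float(a[idx]) for e, a in abundance.items()},
                )
            )
            idx += 1
        trials.append(trial)
    return trials


def subjects_to_frame(trials: list[list[Subject]]) -> pd.DataFrame:
    """Flatten sampled trials to one row per subject."""
    rows = []
    for trial in trials:
        for s in trial:
            row = {
                "id": s.id,
                "trial_id": s.trial_id,
                "sex": s.sex,
                "age": s.age,
                "weight": s.weight,
                "gfr": s.gfr,
                "q_h": s.q_h,
            }
            row.update({f"abundance_{e}": v for e, v in s.enzyme_abundance.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def make_standard_populations(
    modified_expression: bool = False,
    ri_expression: Mapping[str, float] | None = None,
    enzyme_abundance: Mapping[str, tuple[float, float]] | None = None,
    sex_proportion_female: float = 0.0,
    **overrides,
) -> dict[str, PopulationSpec]:
    """Build the three standard population classes.

    healthy / moderate / severe renal impairment at 100 % / 50 % / 10 % of the
    normal glomerular filtration rate. With ``modified_expression=True`` the
    impaired classes also reduce hepatic CYP expression by the per-class
    multiplier in ``ri_expression`` (default: all CYPs × 0.85 moderate,
    × 0.75 severe; a per-enzyme mapping may be given instead); otherwise
    enzyme expression matches the healthy class.
    """
    ri_expression = dict(ri_expression or DEFAULT_RI_EXPRESSION)
    abundance = dict(enzyme_abundance or DEFAULT_ENZYME_ABUNDANCE)
    gfr_fractions = {"healthy": 1.0, "moderate": 0.5, "severe": 0.1}
    specs = {}
    for name, frac in gfr_fractions.items():
        if modified_expression and name in ri_expression:
            entry = ri_expression[name]
            if isinstance(entry, Mapping):
                mult = dict(entry)
            else:
                mult = {e: float(entry) for e in abundance if e.startswith("CYP")}
        else:
            mult = {}
        specs[name] = PopulationSpec(
            name=name,
            gfr_fraction=frac,
            sex_proportion_female=sex_proportion_female,
            enzyme_abundance=abundance,
            ri_expression_multiplier=mult,
            **overrides,
        )
    return specs
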