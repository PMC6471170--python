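"""Synthetic inputs: uremic-toxin panels, observed-PK generators, random
compound fixtures, and candidate-scenario enumerations.

Everything the pipeline consumes can be generated here without external
data: toxin panels give competitive-inhibition R factors via ``Σ [I]/Ki``;
:func:`generate_observed_pk` produces noisy "observed" clinical PK parameter
sets from a known generating scenario (the truth), enabling parameter-
recovery studies of the Σδ ranking; :func:`generate_compound_fixture` draws
physiologically plausible random compounds for property tests.

The shipped default toxin panel is *synthetic*: per-toxin inhibition
constants are back-constructed so the aggregate R bounds for severe renal
impairment are 26.6 (CYP3A4), 2.4 (CYP2C9) and 2.5 (UGT2B7); the individual
splits are not literature measurements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .compounds import CompoundModel, EnzymePathway, apply_perturbation, load_compound
from .engine import DoseRegimen, simulate
from .grids import scenario_seed
from .nca import compute_nca, summarize
from .population import (
    DEFAULT_ENZYME_ABUNDANCE,
    make_standard_populations,
    sample_population,
)
from .ranking import ObservedPK, rank

__all__ = [
    "Toxin",
    "ToxinPanel",
    "compute_r",
    "ic50_to_ki",
    "load_toxin_panel",
    "CandidateScenario",
    "candidate_scenarios",
    "predict_candidate",
    "SyntheticObservedSpec",
    "generate_observed_pk",
    "generate_compound_fixture",
    "recovery_study",
]

PARAMETER_SET = ("cmax", "tmax", "auc", "cl_f", "f")


@dataclass(frozen=True)
class Toxin:
    """One uremic solute: plasma concentration in RI (µM) and per-enzyme Ki (µM)."""

    name: str
    concentration: float
    ki: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.name}: concentration must be >= 0")
        for enz, k in self.ki.items():
            if not k > 0:
                raise ValueError(f"{self.name}: Ki[{enz}] must be > 0, got {k}")


@dataclass(frozen=True)
class ToxinPanel:
    name: str
    toxins: tuple[Toxin, ...]

    def enzymes(self) -> set[str]:
        return {e for t in self.toxins for e in t.ki}


def compute_r(panel: ToxinPanel, enzyme: str) -> float:
    """Aggregate competitive-inhibition factor ``R = Σ_toxins [I]/Ki``.

    Contributions from competitive inhibitors at a single site are additive;
    toxins without a Ki for the enzyme contribute 0.
    """
    return float(
        sum(t.concentration / t.ki[enzyme] for t in panel.toxins if enzyme in t.ki)
    )


def ic50_to_ki(ic50: float) -> float:
    """Ki from IC50 for a competitive inhibitor assayed at substrate ≪ KM.

    In that regime IC50 ≈ Ki, the standard screening-assay simplification.
    """
    if not ic50 > 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    return float(ic50)


def load_toxin_panel(source: str | Path = "uremic_default") -> ToxinPanel:
    """Load a toxin panel from a shipped name or a YAML document."""
    path = Path(source)
    if not (path.suffix in {".yaml", ".yml"} and path.exists()):
        path = Path(
            str(resources.files("renalpk").joinpath("data", "toxins", f"{source}.yaml"))
        )
        if not path.exists():
            raise KeyError(f"unknown toxin panel {source!r}")
    doc = yaml.safe_load(path.read_text())
    toxins = tuple(
        Toxin(t["name"], float(t["concentration"]), {k: float(v) for k, v in t["ki"].items()})
        for t in doc["toxins"]
    )
    return ToxinPanel(doc.get("name", path.stem), toxins)


# ---------------------------------------------------------------------------
# Candidate scenarios and predictions


@dataclass(frozen=True)
class CandidateScenario:
    """One candidate mechanistic modification of a base compound/population."""

    label: str
    fu_multiplier: float | None = None
    fu_target: float | None = None
    r_map: Mapping[str, float] = field(default_factory=dict)
    modified_expression: bool = False


def _fu_label(mult: float | None, target: float | None) -> str:
    if target is not None:
        return f"fu={target:g}"
    if mult is None or mult == 1.0:
        return "fu+0%"
    return f"fu{(mult - 1) * 100:+g}%"


def _make_candidates(
    fu_multipliers: Sequence[float | None],
    fu_targets: Sequence[float],
    r_levels: Mapping[str, Sequence[float]],
    expression_sets: Sequence[bool],
) -> list[CandidateScenario]:
    import itertools

    enzymes = sorted(r_levels)
    out = []
    fu_opts: list[tuple[float | None, float | None]] = [
        (m, None) for m in fu_multipliers
    ] + [(None, t) for t in fu_targets]
    for (mult, target), rs, mod in itertools.product(
        fu_opts, itertools.product(*(r_levels[e] for e in enzymes)), expression_sets
    ):
        r_map = {e: r for e, r in zip(enzymes, rs)}
        r_part = " ".join(f"{e} R{r:g}" for e, r in r_map.items() if r > 0) or "no-inh"
        label = f"{_fu_label(mult, target)} {r_part} " + (
            "modified" if mod else "unmodified"
        )
        out.append(
            CandidateScenario(
                label=label,
                fu_multiplier=mult,
                fu_target=target,
                r_map=r_map,
                modified_expression=mod,
            )
        )
    return out


def candidate_scenarios(kind: str) -> list[CandidateScenario]:
    """Candidate-modification enumerations for the three study compounds.

    Level grids are constructed to match the study sizes (30 nifedipine-like,
    126 sildenafil-like, 15 zidovudine-like candidates): binding increases up
    to +50 %, inhibition factors R ∈ {0, 1, 10} per relevant enzyme, and —
    for the CYP substrates — reduced vs. healthy hepatic expression in the
    impaired population.
    """
    if kind == "nifedipine":
        return _make_candidates(
            [1.0, 1.05, 1.10, 1.25, 1.50], [], {"CYP3A4": [0, 1, 10]}, [False, True]
        )
    if kind == "sildenafil":
        return _make_candidates(
            [1.0, 1.05, 1.10, 1.15, 1.20, 1.25, 1.50],
            [],
            {"CYP3A4": [0, 1, 10], "CYP2C9": [0, 1, 10]},
            [False, True],
        )
    if kind == "zidovudine":
        # fu raised up to its maximum of 1.0; single UGT pathway, one
        # expression set (UGTs are not expression-modified in the RI classes)
        return _make_candidates(
            [1.0, 1.05, 1.10, 1.25], [1.0], {"UGT2B7": [0, 1, 10]}, [False]
        )
    raise KeyError(f"unknown candidate enumeration {kind!r}")


def predict_candidate(
    compound: CompoundModel,
    candidate: CandidateScenario,
    population: str = "moderate",
    dose: float = 50.0,
    n_trials: int = 10,
    n_subjects: int = 10,
    seed: int = 0,
    t_end: float = 96.0,
) -> dict[str, float]:
    """Run the pipeline for one candidate and return summary PK parameters.

    Population subjects are drawn with a seed derived from (seed, population)
    only — common random numbers across candidates, including across the
    modified/unmodified expression sets (the expression multiplier applies
    deterministically on top of the shared abundance draws), so candidate
    comparisons are fully paired.
    """
    perturbed = apply_perturbation(
        compound,
        fu_multiplier=candidate.fu_multiplier,
        fu_target=candidate.fu_target,
        r_map=dict(candidate.r_map),
    )
    specs = make_standard_populations(modified_expression=candidate.modified_expression)
    spec = specs[population]
    pop_seed = scenario_seed(seed, population)
    trials = sample_population(spec, n_trials, n_subjects, pop_seed)
    regimen = DoseRegimen(amount=dose)
    rows = []
    import warnings

    with warnings.catch_warnings():
        # linear-mode terminal phases are exactly log-linear, so AUC
        # extrapolation is exact even on grids short of 5 half-lives
        warnings.filterwarnings("ignore", message="t_end=.*half-lives")
        for trial in trials:
            for subj in trial:
                prof = simulate(perturbed, subj, regimen, t_end=t_end)
                rows.append(compute_nca(prof).as_dict())
    summary = summarize(pd.DataFrame(rows)).iloc[0]
    return {
        "cmax": float(summary["cmax_geomean"]),
        "tmax": float(summary["tmax_median"]),
        "auc": float(summary["auc_inf_geomean"]),
        "cl_f": float(summary["cl_f_geomean"]),
        "f": float(summary["f_geomean"]),
    }


# ---------------------------------------------------------------------------
# Synthetic observed PK


@dataclass(frozen=True)
class SyntheticObservedSpec:
    """Recipe for a noisy synthetic 'observed' clinical PK parameter set.

    The truth scenario (compound + candidate modification + population) is
    run through the full pipeline; each summary parameter is then multiplied
    by lognormal noise ``exp(N(0, σ))`` with ``σ² = ln(1 + CV²)``.
    """

    compound: str | CompoundModel
    truth: CandidateScenario
    population: str = "moderate"
    dose: float = 50.0
    noise_cv: float | Mapping[str, float] = 0.05
    n_trials: int = 10
    n_subjects: int = 10
    seed: int = 0
    parameter_set: tuple[str, ...] = PARAMETER_SET

    def cv_for(self, param: str) -> float:
        if isinstance(self.noise_cv, Mapping):
            return float(self.noise_cv.get(param, 0.0))
        return float(self.noise_cv)


def generate_observed_pk(
    spec: SyntheticObservedSpec,
    truth_params: Mapping[str, float] | None = None,
) -> tuple[ObservedPK, dict[str, float]]:
    """Generate a noisy observed-PK set; returns (observed, truth parameters).

    ``truth_params`` short-circuits the pipeline when the truth prediction
    has already been computed (replicated noise draws over one truth).
    """
    compound = (
        spec.compound
        if isinstance(spec.compound, CompoundModel)
        else load_compound(spec.compound)
    )
    if truth_params is None:
        truth_params = predict_candidate(
            compound,
            spec.truth,
            population=spec.population,
            dose=spec.dose,
            n_trials=spec.n_trials,
            n_subjects=spec.n_subjects,
            seed=spec.seed,
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    values = {}
    for p in spec.parameter_set:
        cv = spec.cv_for(p)
        sigma = np.sqrt(np.log1p(cv**2))
        values[p] = truth_params[p] * float(np.exp(rng.normal(0.0, sigma)))
    return (
        ObservedPK(values=values, source=f"synthetic truth: {spec.truth.label}"),
        dict(truth_params),
    )


# ---------------------------------------------------------------------------
# Random compound fixtures


_FIXTURE_ENZYMES = tuple(DEFAULT_ENZYME_ABUNDANCE)


def generate_compound_fixture(
    seed: int, n_pathways: int = 1, regime: str = "low"
) -> CompoundModel:
    """Draw a physiologically plausible random compound.

    ``regime`` controls the hepatic extraction ratio at mean physiology:
    'low' targets E ≈ 0.05–0.25 (restrictive clearance), 'high' E ≈ 0.7–0.9.
    """
    if n_pathways < 1 or n_pathways > len(_FIXTURE_ENZYMES):
        raise ValueError(f"n_pathways must be in [1, {len(_FIXTURE_ENZYMES)}]")
    if regime not in {"low", "high"}:
        raise ValueError("regime must be 'low' or 'high'")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fu = float(rng.uniform(0.02, 0.9))
    bp = float(rng.uniform(0.6, 1.2))
    e_target = float(rng.uniform(0.05, 0.25) if regime == "low" else rng.uniform(0.7, 0.9))
    q_h = 90.0  # mean hepatic blood flow, L/h
    # mean total abundance per enzyme at reference liver scalars
    mean_liver = 40.0 * 1650.0  # mg microsomal protein
    enzymes = list(rng.choice(_FIXTURE_ENZYMES, size=n_pathways, replace=False))
    clint_target = q_h * e_target / (1.0 - e_target) / (fu / bp)  # L/h unbound
    shares = rng.dirichlet(np.ones(n_pathways))
    pathways = []
    for enz, share in zip(enzymes, shares):
        km = float(rng.uniform(5.0, 50.0))
        abundance = DEFAULT_ENZYME_ABUNDANCE[enz][0] * mean_liver  # pmol
        # vmax chosen so this pathway contributes its share of CLint
        vmax = share * clint_target / 60.0e-6 * km / abundance
        pathways.append(EnzymePathway(enz, float(vmax), km))
    return CompoundModel(
        name=f"synthetic_{regime}_{seed}",
        mw=float(rng.uniform(200.0, 600.0)),
        fu=fu,
        bp_ratio=bp,
        ka=float(rng.uniform(0.5, 3.0)),
        f_abs=float(rng.uniform(0.8, 1.0)),
        f_gut=float(rng.uniform(0.7, 1.0)),
        vss_per_kg=float(rng.uniform(0.5, 2.0)),
        pathways=tuple(pathways),
        renal_filtration_fraction=0.0,
    )


# ---------------------------------------------------------------------------
# Parameter-recovery study


def recovery_study(
    compound: str | CompoundModel = "nifedipine",
    truth_label: str = "fu+50% CYP3A4 R10 modified",
    n_replicates: int = 50,
    noise_cv: float = 0.05,
    population: str = "severe",
    dose: float = 20.0,
    seed: int = 0,
    candidates: Sequence[CandidateScenario] | None = None,
    n_trials: int = 10,
    n_subjects: int = 10,
    parameter_set: tuple[str, ...] = PARAMETER_SET,
) -> dict:
    """Can Σδ ranking recover a known generating scenario from noisy data?

    One truth candidate generates replicated noisy observed-PK sets; every
    candidate's prediction is ranked against each replicate. Returns top-1
    and top-3 recovery rates plus the per-replicate winners.
    """
    compound = (
        compound if isinstance(compound, CompoundModel) else load_compound(compound)
    )
    if candidates is None:
        candidates = candidate_scenarios(compound.name)
    by_label = {c.label: c for c in candidates}
    if truth_label not in by_label:
        raise KeyError(
            f"truth {truth_label!r} not among candidates; e.g. {list(by_label)[:5]}"
        )

    predictions = {
        c.label: predict_candidate(
            compound,
            c,
            population=population,
            dose=dose,
            n_trials=n_trials,
            n_subjects=n_subjects,
            seed=seed,
        )
        for c in candidates
    }
    truth_params = predictions[truth_label]
    cand_list = [(label, preds) for label, preds in predictions.items()]

    winners = []
    top3_hits = 0
    for i in range(n_replicates):
        spec = SyntheticObservedSpec(
            compound=compound,
            truth=by_label[truth_label],
            population=population,
            dose=dose,
            noise_cv=noise_cv,
            seed=scenario_seed(seed, f"replicate-{i}"),
            parameter_set=parameter_set,
        )
        observed, _ = generate_observed_pk(spec, truth_params=truth_params)
        result = rank(cand_list, observed, parameter_set)
        order = result.order()
        winners.append(order[0])
        if truth_label in order[:3]:
            top3_hits += 1
    top1 = sum(w == truth_label for w in winners) / n_replicates
    return {
        "truth": truth_label,
        "n_replicates": n_replicates,
        "noise_cv": noise_cv,
        "top1_rate": top1,
        "top3_rate": top3_hits / n_replicates,
        "winners": winners,
    }
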