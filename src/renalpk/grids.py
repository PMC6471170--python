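"""Systematic scenario grids: dose × fu × expression × inhibition × population.

A :class:`ScenarioGrid` enumerates the Cartesian product of perturbation
levels; :func:`run_grid` executes the full pipeline per scenario (perturb the
compound, sample the population, simulate every subject, run NCA, summarize)
and :func:`fold_change` turns summary exposures into fold-change tables
relative to a reference scenario.

Per-scenario seeds are derived by hashing (grid seed, scenario id), so adding
scenarios to a grid never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .compounds import CompoundModel, apply_perturbation, load_compound
from .engine import DoseRegimen, simulate
from .nca import compute_nca, summarize
from .population import PopulationSpec, make_standard_populations, sample_population

__all__ = [
    "ScenarioGrid",
    "ScenarioResult",
    "scenario_seed",
    "run_grid",
    "results_to_frame",
    "summaries_to_frame",
    "fold_change",
]


def scenario_seed(grid_seed: int, scenario_id: str) -> int:
    """Stable 31-bit seed from (grid seed, scenario id)."""
    digest = hashlib.sha256(f"{grid_seed}|{scenario_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class ScenarioGrid:
    """Factor levels to cross. ``fu_values`` are absolute targets and
    ``fu_multipliers`` relative changes (use one); ``None`` in either list
    means "base fu". ``expression_folds`` / ``r_values`` map enzyme → list of
    levels crossed independently per enzyme."""

    compound: str | CompoundModel
    doses: Sequence[float] = (60.0,)
    fu_values: Sequence[float | None] = (None,)
    fu_multipliers: Sequence[float | None] | None = None
    expression_folds: Mapping[str, Sequence[float]] = field(default_factory=dict)
    r_values: Mapping[str, Sequence[float]] = field(default_factory=dict)
    populations: Sequence[str] = ("healthy", "moderate", "severe")
    modified_expression: bool = False
    n_trials: int = 10
    n_subjects: int = 10
    seed: int = 0
    t_end: float = 48.0
    mode: str = "linear"

    def _fu_levels(self) -> list[tuple[str, float | None]]:
        if self.fu_multipliers is not None:
            return [("mult", m) for m in self.fu_multipliers]
        return [("abs", v) for v in self.fu_values]

    def scenarios(self) -> list[dict]:
        """Enumerate all factor combinations with deterministic identifiers."""
        enz_expr = sorted(self.expression_folds)
        enz_r = sorted(self.r_values)
        expr_combos = list(
            itertools.product(*(self.expression_folds[e] for e in enz_expr))
        ) or [()]
        r_combos = list(itertools.product(*(self.r_values[e] for e in enz_r))) or [()]
        out = []
        for dose, (fu_kind, fu_val), expr, rs, pop in itertools.product(
            self.doses, self._fu_levels(), expr_combos, r_combos, self.populations
        ):
            expr_map = dict(zip(enz_expr, expr))
            r_map = dict(zip(enz_r, rs))
            fu_part = (
                "base"
                if fu_val is None
                else (f"x{fu_val:g}" if fu_kind == "mult" else f"{fu_val:g}")
            )
            sid = "|".join(
                [
                    f"pop={pop}",
                    f"dose={dose:g}",
                    f"fu={fu_part}",
                    "expr=" + (",".join(f"{e}x{f:g}" for e, f in expr_map.items()) or "base"),
                    "r=" + (",".join(f"{e}:{r:g}" for e, r in r_map.items()) or "none"),
                ]
            )
            out.append(
                {
                    "scenario_id": sid,
                    "population": pop,
                    "dose": dose,
                    "fu_kind": fu_kind,
                    "fu_value": fu_val,
                    "expression_fold": expr_map,
                    "r_map": r_map,
                }
            )
        return out

    @property
    def size(self) -> int:
        return len(self.scenarios())


@dataclass(frozen=True)
class ScenarioResult:
    scenario_id: str
    levels: dict
    subjects: pd.DataFrame | None  # one row of NCA parameters per subject
    summary: pd.Series | None  # geometric means etc. across subjects
    error: str | None = None


def _run_one(
    compound: CompoundModel,
    scen: dict,
    spec: PopulationSpec,
    grid: ScenarioGrid,
) -> ScenarioResult:
    kwargs = {}
    if scen["fu_value"] is not None:
        kwargs["fu_multiplier" if scen["fu_kind"] == "mult" else "fu_target"] = scen[
            "fu_value"
        ]
    perturbed = apply_perturbation(
        compound,
        expression_fold=scen["expression_fold"],
        r_map=scen["r_map"],
        **kwargs,
    )
    seed = scenario_seed(grid.seed, scen["scenario_id"])
    trials = sample_population(spec, grid.n_trials, grid.n_subjects, seed)
    regimen = DoseRegimen(amount=scen["dose"])
    rows = []
    for trial in trials:
        for subj in trial:
            prof = simulate(
                perturbed, subj, regimen, t_end=grid.t_end, mode=grid.mode
            )
            rec = compute_nca(prof).as_dict()
            rec.update(
                scenario_id=scen["scenario_id"],
                population=scen["population"],
                dose=scen["dose"],
                subject_id=subj.id,
                trial_id=subj.trial_id,
            )
            rows.append(rec)
    frame = pd.DataFrame(rows)
    summary = summarize(frame).iloc[0]
    summary["scenario_id"] = scen["scenario_id"]
    summary["population"] = scen["population"]
    return ScenarioResult(scen["scenario_id"], scen, frame, summary)


def run_grid(
    grid: ScenarioGrid,
    population_specs: Mapping[str, PopulationSpec] | None = None,
) -> list[ScenarioResult]:
    """Execute every scenario of the grid; failures are recorded per scenario
    without aborting the rest."""
    compound = (
        grid.compound
        if isinstance(grid.compound, CompoundModel)
        else load_compound(grid.compound)
    )
    if population_specs is None:
        population_specs = make_standard_populations(
            modified_expression=grid.modified_expression
        )
    results = []
    for scen in grid.scenarios():
        spec = population_specs.get(scen["population"])
        if spec is None:
            results.append(
                ScenarioResult(
                    scen["scenario_id"],
                    scen,
                    None,
                    None,
                    error=f"unknown population {scen['population']!r}",
                )
            )
            continue
        try:
            results.append(_run_one(compound, scen, spec, grid))
        except Exception as exc:  # per-scenario isolation
            results.append(
                ScenarioResult(scen["scenario_id"], scen, None, None, error=str(exc))
            )
    return results


def results_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Long-format per-subject table across all successful scenarios."""
    frames = [r.subjects for r in results if r.subjects is not None]
    if not frames:
        raise ValueError("no successful scenarios")
    return pd.concat(frames, ignore_index=True)


def summaries_to_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    rows = [r.summary for r in results if r.summary is not None]
    if not rows:
        raise ValueError("no successful scenarios")
    return pd.DataFrame(rows).reset_index(drop=True)


def fold_change(
    results: list[ScenarioResult],
    reference: str,
    params: Sequence[str] = ("auc_inf", "cmax", "cl_f", "vss"),
    stat: str = "geomean",
) -> pd.DataFrame:
    """Fold changes of summary statistics relative to a reference scenario.

    The reported convention matches fold-increase/fold-decrease language:
    ``fold`` is scenario/reference; ``fold_decrease`` = reference/scenario
    where the ratio is < 1, so a 25× exposure drop reads as ``25``.
    """
    summaries = summaries_to_frame(results)
    ref_rows = summaries[summaries["scenario_id"] == reference]
    if ref_rows.empty:
        raise KeyError(f"reference scenario {reference!r} not in results")
    ref = ref_rows.iloc[0]
    rows = []
    for _, row in summaries.iterrows():
        rec = {"scenario_id": row["scenario_id"], "population": row["population"]}
        for p in params:
            col = f"{p}_{stat}"
            if col not in summaries.columns or not np.isfinite(ref[col]):
                continue
            ratio = row[col] / ref[col]
            rec[f"{p}_fold"] = ratio
            rec[f"{p}_direction"] = "increase" if ratio >= 1 else "decrease"
            rec[f"{p}_fold_reported"] = ratio if ratio >= 1 else 1.0 / ratio
        rows.append(rec)
    return pd.DataFrame(rows)
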