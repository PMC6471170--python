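"""Ranking candidate simulations against observed clinical PK.

Each candidate simulation predicts a set of PK parameters (Cmax, tmax, AUC,
CL/F, optionally F). The per-parameter loss is the absolute base-10 log
fold-error

    δ = |log10(predicted / observed)|

and candidates are ranked ascending by the sum Σδ over the declared
parameter set — values closest to 0 are the best simulations. δ is symmetric
in over-/under-prediction and invariant to the units shared by predicted and
observed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ObservedPK",
    "RankingResult",
    "delta",
    "rank",
    "comparison_report",
    "read_observed",
    "write_observed",
]


@dataclass(frozen=True)
class ObservedPK:
    """Observed clinical PK parameters: name → value (units/source optional)."""

    values: Mapping[str, float]
    units: Mapping[str, str] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if not v > 0:
                raise ValueError(f"observed {k} must be > 0 (log-ratio), got {v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass(frozen=True)
class RankingResult:
    """Per-candidate δ table sorted ascending by Σδ (ties broken by label)."""

    table: pd.DataFrame  # columns: label, <param>_pred, <param>_ratio, <param>_delta, sigma_delta_all
    parameter_set: tuple[str, ...]
    observed: ObservedPK

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["label"])

    def order(self) -> list[str]:
        return list(self.table["label"])


def delta(predicted: float, observed: float) -> float:
    """Absolute base-10 log prediction error ``|log10(predicted/observed)|``."""
    if not predicted > 0 or not observed > 0:
        raise ValueError(
            f"delta requires positive inputs, got predicted={predicted}, "
            f"observed={observed}"
        )
    return abs(math.log10(predicted / observed))


def rank(
    candidates: Sequence[tuple[str, Mapping[str, float]]],
    observed: ObservedPK,
    parameter_set: Sequence[str],
) -> RankingResult:
    """Rank candidate simulations ascending by Σδ over ``parameter_set``."""
    if not candidates:
        raise ValueError("no candidates to rank")
    parameter_set = tuple(parameter_set)
    missing_obs = [p for p in parameter_set if p not in observed.values]
    if missing_obs:
        raise KeyError(f"observed data lacks parameter(s) {missing_obs}")
    rows = []
    for label, pred in candidates:
        row: dict = {"label": label}
        total = 0.0
        for p in parameter_set:
            if p not in pred:
                raise KeyError(f"candidate {label!r} lacks parameter {p!r}")
            ratio = pred[p] / observed[p]
            d = delta(pred[p], observed[p])
            row[f"{p}_pred"] = pred[p]
            row[f"{p}_ratio"] = ratio
            row[f"{p}_delta"] = d
            total += d
        row["sigma_delta_all"] = total
        rows.append(row)
    table = (
        pd.DataFrame(rows)
        .sort_values(["sigma_delta_all", "label"], kind="stable")
        .reset_index(drop=True)
    )
    return RankingResult(table, parameter_set, observed)


def comparison_report(ranking: RankingResult, base_label: str) -> pd.DataFrame:
    """Comparison table flagging per-parameter improvement over the base run.

    A parameter is flagged improved when the candidate's |log10 ratio| is
    strictly smaller than the base simulation's for that parameter (the
    report analogue of bolding improved predicted/observed ratios).
    """
    t = ranking.table
    base_rows = t[t["label"] == base_label]
    if base_rows.empty:
        raise KeyError(
            f"base label {base_label!r} not among candidates {list(t['label'])}"
        )
    base = base_rows.iloc[0]
    out = t.copy()
    for p in ranking.parameter_set:
        out[f"{p}_improved"] = out[f"{p}_delta"] < base[f"{p}_delta"]
    out["is_base"] = out["label"] == base_label
    return out


def read_observed(path: str | Path) -> ObservedPK:
    """Read an observed-PK table (CSV/TSV: parameter, value[, units, source])."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    values = dict(zip(df["parameter"], df["value"].astype(float)))
    units = dict(zip(df["parameter"], df["units"])) if "units" in df else None
    source = str(df["source"].iloc[0]) if "source" in df else ""
    return ObservedPK(values=values, units=units, source=source)


def write_observed(obs: ObservedPK, path: str | Path) -> None:
    rows = [
        {
            "parameter": k,
            "value": v,
            "units": (obs.units or {}).get(k, ""),
            "source": obs.source,
        }
        for k, v in obs.values.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
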