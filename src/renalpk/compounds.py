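"""Compound parameterizations: enzyme pathways, disposition, perturbation.

A :class:`CompoundModel` bundles everything the simulator needs to know about
one drug: plasma protein binding (``fu``), blood:plasma partitioning,
first-order oral absorption, a distribution volume scalar, one
:class:`EnzymePathway` per metabolic route (Michaelis–Menten kinetics with an
optional competitive-inhibition factor ``R``), and the fraction of unbound
glomerular filtration contributing to renal clearance.

Shipped fixtures (``nifedipine``, ``sildenafil``, ``zidovudine``) carry
literature-plausible parameter sets; see the YAML headers under
``data/compounds/`` for provenance notes.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import yaml

__all__ = [
    "EnzymePathway",
    "CompoundModel",
    "CompoundNotFoundError",
    "CompoundValidationError",
    "available_fixtures",
    "load_compound",
    "apply_perturbation",
    "compound_to_dict",
    "compound_from_dict",
]


class CompoundNotFoundError(KeyError):
    """Requested fixture name does not exist."""


class CompoundValidationError(ValueError):
    """A compound parameter violates its physical constraint; names the field."""


@dataclass(frozen=True)
class EnzymePathway:
    """One metabolic route with Michaelis–Menten kinetics.

    Parameters
    ----------
    enzyme:
        Enzyme identifier, e.g. ``CYP3A4``, ``CYP2C9``, ``UGT2B7``.
    vmax:
        Maximal rate, pmol product/min/pmol enzyme.
    km:
        Michaelis constant, µM, on an unbound-substrate basis.
    r_inhibition:
        Dimensionless competitive-inhibition factor R = [I]/Ki (>= 0).
        Multiplies the apparent KM by ``(1 + R)``.
    """

    enzyme: str
    vmax: float
    km: float
    r_inhibition: float = 0.0

    def __post_init__(self) -> None:
        if not self.enzyme:
            raise CompoundValidationError("enzyme: identifier must be non-empty")
        if not self.vmax > 0:
            raise CompoundValidationError(f"vmax: must be > 0, got {self.vmax}")
        if not self.km > 0:
            raise CompoundValidationError(f"km: must be > 0, got {self.km}")
        if self.r_inhibition < 0:
            raise CompoundValidationError(
                f"r_inhibition: must be >= 0, got {self.r_inhibition}"
            )


@dataclass(frozen=True)
class CompoundModel:
    """Drug-specific parameters for simulation.

    ``vss_per_kg`` is referenced to ``fu_reference`` (the fraction unbound at
    which the distribution volume was characterized); raising fu above that
    reference proportionally raises the effective Vss used by the simulator.
    """

    name: str
    mw: float  # g/mol
    fu: float  # fraction unbound in plasma, (0, 1]
    bp_ratio: float  # blood:plasma concentration ratio
    ka: float  # first-order absorption rate, 1/h
    f_abs: float  # fraction absorbed, (0, 1]
    f_gut: float  # fraction escaping gut extraction, (0, 1]
    vss_per_kg: float  # L/kg at fu_reference
    pathways: tuple[EnzymePathway, ...] = ()
    renal_filtration_fraction: float = 0.0  # of fu·GFR, [0, 1]
    fu_reference: float | None = None  # defaults to fu at construction

    def __post_init__(self) -> None:
        if not (0 < self.fu <= 1):
            raise CompoundValidationError(f"fu: must be in (0, 1], got {self.fu}")
        if not self.mw > 0:
            raise CompoundValidationError(f"mw: must be > 0, got {self.mw}")
        if not self.bp_ratio > 0:
            raise CompoundValidationError(f"bp_ratio: must be > 0, got {self.bp_ratio}")
        if not self.ka > 0:
            raise CompoundValidationError(f"ka: must be > 0, got {self.ka}")
        if not (0 < self.f_abs <= 1):
            raise CompoundValidationError(f"f_abs: must be in (0, 1], got {self.f_abs}")
        if not (0 < self.f_gut <= 1):
            raise CompoundValidationError(f"f_gut: must be in (0, 1], got {self.f_gut}")
        if not self.vss_per_kg > 0:
            raise CompoundValidationError(
                f"vss_per_kg: must be > 0, got {self.vss_per_kg}"
            )
        if not (0 <= self.renal_filtration_fraction <= 1):
            raise CompoundValidationError(
                "renal_filtration_fraction: must be in [0, 1], got "
                f"{self.renal_filtration_fraction}"
            )
        object.__setattr__(self, "pathways", tuple(self.pathways))
        names = [p.enzyme for p in self.pathways]
        if len(names) != len(set(names)):
            raise CompoundValidationError(
                f"pathways: duplicate enzyme identifiers in {names}"
            )
        if not self.pathways and self.renal_filtration_fraction == 0:
            raise CompoundValidationError(
                "pathways/renal_filtration_fraction: compound has no elimination "
                "route (needs >= 1 pathway or renal_filtration_fraction > 0)"
            )
        if self.fu_reference is None:
            object.__setattr__(self, "fu_reference", self.fu)
        elif not (0 < self.fu_reference <= 1):
            raise CompoundValidationError(
                f"fu_reference: must be in (0, 1], got {self.fu_reference}"
            )

    @property
    def enzymes(self) -> tuple[str, ...]:
        return tuple(p.enzyme for p in self.pathways)

    def pathway(self, enzyme: str) -> EnzymePathway:
        for p in self.pathways:
            if p.enzyme == enzyme:
                return p
        raise KeyError(f"{self.name} has no {enzyme} pathway; known: {self.enzymes}")


def _data_dir() -> Path:
    return Path(str(resources.files("renalpk").joinpath("data", "compounds")))


def available_fixtures() -> list[str]:
    """Names of compound fixtures shipped with the package."""
    return sorted(p.stem for p in _data_dir().glob("*.yaml"))


def compound_from_dict(doc: Mapping) -> CompoundModel:
    """Build a validated CompoundModel from a plain mapping (parsed config)."""
    doc = dict(doc)
    pathways = tuple(
        EnzymePathway(
            enzyme=p["enzyme"],
            vmax=float(p["vmax"]),
            km=float(p["km"]),
            r_inhibition=float(p.get("r_inhibition", 0.0)),
        )
        for p in doc.pop("pathways", [])
    )
    known = {f.name for f in dataclasses.fields(CompoundModel)}
    extra = set(doc) - known
    if extra:
        raise CompoundValidationError(f"unknown compound config keys: {sorted(extra)}")
    return CompoundModel(pathways=pathways, **doc)


def compound_to_dict(compound: CompoundModel) -> dict:
    """Serialize a CompoundModel to a plain mapping (YAML/JSON-ready)."""
    d = dataclasses.asdict(compound)
    d["pathways"] = [dict(p) if isinstance(p, dict) else p for p in d["pathways"]]
    return d


def load_compound(source: Union[str, Path, Mapping]) -> CompoundModel:
    """Load a compound from a shipped fixture name, a YAML file, or a mapping.

    Raises
    ------
    CompoundNotFoundError
        If ``source`` is a name that matches no shipped fixture or file.
    CompoundValidationError
        If any parameter violates its constraint (message names the field).
    """
    if isinstance(source, Mapping):
        return compound_from_dict(source)
    path = Path(source)
    if path.suffix in {".yaml", ".yml", ".json"} and path.exists():
        doc = yaml.safe_load(path.read_text())
    else:
        fixture = _data_dir() / f"{source}.yaml"
        if not fixture.exists():
            raise CompoundNotFoundError(
                f"unknown compound {source!r}; shipped fixtures: {available_fixtures()}"
            )
        doc = yaml.safe_load(fixture.read_text())
    return compound_from_dict(doc)


def save_compound(compound: CompoundModel, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(compound_to_dict(compound), sort_keys=False))


def apply_perturbation(
    compound: CompoundModel,
    fu_multiplier: float | None = None,
    fu_target: float | None = None,
    expression_fold: Mapping[str, float] | None = None,
    r_map: Mapping[str, float] | None = None,
) -> CompoundModel:
    """Return a new compound with perturbed binding, expression and inhibition.

    Parameters
    ----------
    fu_multiplier:
        Multiply fu by this factor (a "+10 %" change is multiplier 1.10);
        result is clamped at 1.0.
    fu_target:
        Set fu to this absolute value instead (mutually exclusive with
        ``fu_multiplier``).
    expression_fold:
        Map enzyme → fold change of effective Vmax. A "−k-fold" expression
        change corresponds to multiplier ``1/k``.
    r_map:
        Map enzyme → competitive-inhibition factor R (replaces the pathway's
        current value). Enzymes absent from the map are untouched.

    The input compound is never modified; ``fu_reference`` is preserved so the
    distribution volume keeps scaling against the original binding.
    """
    if fu_multiplier is not None and fu_target is not None:
        raise ValueError("give fu_multiplier or fu_target, not both")
    fu = compound.fu
    if fu_multiplier is not None:
        if not fu_multiplier > 0:
            raise CompoundValidationError(
                f"fu_multiplier: must be > 0, got {fu_multiplier}"
            )
        fu = min(1.0, fu * fu_multiplier)
    elif fu_target is not None:
        if not (0 < fu_target <= 1):
            raise CompoundValidationError(
                f"fu_target: must be in (0, 1], got {fu_target}"
            )
        fu = fu_target

    expression_fold = dict(expression_fold or {})
    r_map = dict(r_map or {})
    known = set(compound.enzymes)
    for label, mapping in (("expression_fold", expression_fold), ("r_map", r_map)):
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(
                f"{label}: enzyme(s) {sorted(unknown)} not in compound "
                f"{compound.name}; known enzymes: {sorted(known)}"
            )
    for enzyme, fold in expression_fold.items():
        if not fold > 0:
            raise CompoundValidationError(
                f"expression_fold[{enzyme}]: must be > 0, got {fold}"
            )
    for enzyme, r in r_map.items():
        if r < 0:
            raise CompoundValidationError(f"r_map[{enzyme}]: must be >= 0, got {r}")

    new_pathways = []
    for p in compound.pathways:
        vmax = p.vmax * expression_fold.get(p.enzyme, 1.0)
        r = r_map.get(p.enzyme, p.r_inhibition)
        new_pathways.append(EnzymePathway(p.enzyme, vmax, p.km, r))

    return dataclasses.replace(
        compound,
        fu=fu,
        pathways=tuple(new_pathways),
        fu_reference=compound.fu_reference,
    )
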