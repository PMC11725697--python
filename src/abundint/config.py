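"""Model declaration: species roles, state variables, and the directed interaction graph.

A multispecies model is a DAG over species.  Each species contributes a
*state* submodel (Poisson abundance ``N`` on the log scale, or Bernoulli
occupancy ``z`` on the logit scale) and an *observation* submodel (binomial
counts over ``K`` subsamples for abundance-state species, Bernoulli
detections for occupancy-state species).  A directed edge means the latent
abundance of the source species enters a linear predictor of the target
species with coefficient ``gamma0`` (optionally ``gamma1 * N * x`` for an
environmental modifier ``x``).  In the occupancy-mediated comparison
variant the contribution is the indicator ``1{N > 0}`` instead of ``N``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "StudyDesign",
    "InteractionTerm",
    "SpeciesModel",
    "ParamSpec",
    "ModelGraph",
    "build_model_graph",
    "topological_order",
    "as_occupancy_mediated",
]

_ROLE_RANK = {"dominant": 0, "intermediate": 1, "subordinate": 2}
_STATE_VARS = ("abundance", "occupancy")
_SUBMODELS = ("state", "detection")


class ConfigurationError(ValueError):
    """Raised when a model declaration is internally inconsistent."""


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout: I sites, J occasions, K subsamples per occasion.

    ``year_index`` (optional, one integer per site-row) enables fixed
    year-specific intercepts via dummy coding; rows of ``observed_mask``
    that are False mark occasions that were never sampled.
    """

    n_sites: int
    n_occasions: int
    n_subsamples: int = 1
    year_index: np.ndarray | None = None
    observed_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.n_sites < 1 or self.n_occasions < 1 or self.n_subsamples < 1:
            raise ConfigurationError("I, J and K must all be >= 1")
        if self.observed_mask is None:
            object.__setattr__(
                self,
                "observed_mask",
                np.ones((self.n_sites, self.n_occasions), dtype=bool),
            )
        mask = np.asarray(self.observed_mask, dtype=bool)
        if mask.shape != (self.n_sites, self.n_occasions):
            raise ConfigurationError(
                f"observed_mask shape {mask.shape} != (I={self.n_sites}, J={self.n_occasions})"
            )
        object.__setattr__(self, "observed_mask", mask)
        if self.year_index is not None:
            yi = np.asarray(self.year_index, dtype=int)
            if yi.shape != (self.n_sites,):
                raise ConfigurationError("year_index must have one entry per site-row")
            object.__setattr__(self, "year_index", yi)

    def validate(self, allow_unsampled: bool = False) -> "StudyDesign":
        if not allow_unsampled and not self.observed_mask.any(axis=1).all():
            bad = np.flatnonzero(~self.observed_mask.any(axis=1))
            raise ConfigurationError(
                f"site rows {bad[:5].tolist()} have no sampled occasion"
            )
        return self

    @property
    def n_years(self) -> int:
        if self.year_index is None:
            return 1
        return len(np.unique(self.year_index))

    @property
    def years(self) -> np.ndarray:
        if self.year_index is None:
            return np.array([0])
        return np.unique(self.year_index)


@dataclass(frozen=True)
class InteractionTerm:
    """A directed edge: the source species' latent abundance shifts one
    submodel (state or detection) of the species that owns this term."""

    source_species: str
    target_submodel: str = "state"
    modifier_covariate: str | None = None
    occupancy_mediated: bool = False
    gamma0_name: str | None = None
    gamma1_name: str | None = None

    def __post_init__(self):
        if self.target_submodel not in _SUBMODELS:
            raise ConfigurationError(
                f"target_submodel must be one of {_SUBMODELS}, got {self.target_submodel!r}"
            )
        if (self.gamma1_name is not None) and self.modifier_covariate is None:
            raise ConfigurationError("gamma1 requires a modifier covariate")


@dataclass(frozen=True)
class SpeciesModel:
    name: str
    role: str
    state_variable: str
    state_formula: tuple = ()
    detection_formula: tuple = ()
    incoming_interactions: tuple = ()

    def __post_init__(self):
        if self.role not in _ROLE_RANK:
            raise ConfigurationError(f"unknown role {self.role!r}")
        if self.state_variable not in _STATE_VARS:
            raise ConfigurationError(f"unknown state variable {self.state_variable!r}")
        object.__setattr__(self, "state_formula", tuple(self.state_formula))
        object.__setattr__(self, "detection_formula", tuple(self.detection_formula))
        object.__setattr__(
            self, "incoming_interactions", tuple(self.incoming_interactions)
        )


@dataclass(frozen=True)
class ParamSpec:
    """One entry of the flat parameter index."""

    name: str
    species: str
    submodel: str  # "state" | "detection"
    kind: str  # "intercept" | "year" | "covariate" | "gamma0" | "gamma1"
    covariate: str | None = None
    source: str | None = None


@dataclass(frozen=True)
class ModelGraph:
    """Validated multispecies model in stable topological order."""

    species: tuple  # tuple[SpeciesModel]
    covariate_names: frozenset
    parameter_index: tuple  # tuple[ParamSpec]
    year_effects: bool = False
    n_years: int = 1

    @property
    def species_names(self) -> list:
        return [s.name for s in self.species]

    def species_model(self, name: str) -> SpeciesModel:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def parameter_names(self) -> list:
        return [p.name for p in self.parameter_index]

    def params_for(self, species: str, submodel: str) -> list:
        return [
            p
            for p in self.parameter_index
            if p.species == species and p.submodel == submodel
        ]

    def interaction_param(
        self, source: str, target: str, submodel: str = "state", order: int = 0
    ) -> str:
        """Name of the gamma0 (order=0) or gamma1 (order=1) parameter on the
        ``source -> target`` edge."""
        kind = "gamma0" if order == 0 else "gamma1"
        for p in self.parameter_index:
            if (
                p.kind == kind
                and p.source == source
                and p.species == target
                and p.submodel == submodel
            ):
                return p.name
        raise KeyError(f"no {kind} for edge {source}->{target} ({submodel})")

    def to_config(self) -> dict:
        """Serializable configuration; ``build_model_graph`` round-trips it."""
        return {
            "species": [
                {
                    "name": s.name,
                    "role": s.role,
                    "state": s.state_variable,
                    "state_covariates": list(s.state_formula),
                    "detection_covariates": list(s.detection_formula),
                    "interactions": [
                        {
                            "source": t.source_species,
                            "target": t.target_submodel,
                            "modifier": t.modifier_covariate,
                            "occupancy_mediated": t.occupancy_mediated,
                        }
                        for t in s.incoming_interactions
                    ],
                }
                for s in self.species
            ],
            "year_effects": self.year_effects,
            "n_years": self.n_years,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_config(), fh, indent=1)


def topological_order(species: list) -> list:
    """Stable topological sort of SpeciesModel declarations.

    Ties are broken by role rank (dominant < intermediate < subordinate)
    then declaration order, so the order is unique given the roles.
    Raises ConfigurationError on a cycle.
    """
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate species names")
    index = {n: i for i, n in enumerate(names)}
    incoming = {s.name: set() for s in species}
    for s in species:
        for t in s.incoming_interactions:
            if t.source_species not in index:
                raise ConfigurationError(
                    f"unknown interaction source {t.source_species!r}"
                )
            if t.source_species == s.name:
                raise ConfigurationError(f"self-interaction on {s.name!r}")
            incoming[s.name].add(t.source_species)
    ordered, placed = [], set()
    remaining = list(species)
    while remaining:
        ready = [s for s in remaining if incoming[s.name] <= placed]
        if not ready:
            raise ConfigurationError(
                "cyclic interaction graph involving "
                + ", ".join(s.name for s in remaining)
            )
        ready.sort(key=lambda s: (_ROLE_RANK[s.role], index[s.name]))
        nxt = ready[0]
        ordered.append(nxt)
        placed.add(nxt.name)
        remaining.remove(nxt)
    return ordered


def _species_params(sp: SpeciesModel, submodel: str, formula, edges, year_effects, n_years):
    tag = "state" if submodel == "state" else "det"
    out = [ParamSpec(f"{sp.name}:{tag}:Intercept", sp.name, submodel, "intercept")]
    if year_effects:
        for y in range(1, n_years):
            out.append(
                ParamSpec(
                    f"{sp.name}:{tag}:year{y}",
                    sp.name,
                    submodel,
                    "year",
                    covariate=f"year{y}",
                )
            )
    for cov in formula:
        out.append(
            ParamSpec(f"{sp.name}:{tag}:{cov}", sp.name, submodel, "covariate", covariate=cov)
        )
    for t in edges:
        out.append(
            ParamSpec(
                f"{sp.name}:{tag}:gamma0<{t.source_species}>",
                sp.name,
                submodel,
                "gamma0",
                source=t.source_species,
            )
        )
        if t.modifier_covariate is not None:
            out.append(
                ParamSpec(
                    f"{sp.name}:{tag}:gamma1<{t.source_species}*{t.modifier_covariate}>",
                    sp.name,
                    submodel,
                    "gamma1",
                    covariate=t.modifier_covariate,
                    source=t.source_species,
                )
            )
    return out


def build_model_graph(config: dict) -> ModelGraph:
    """Build and validate a ModelGraph from a configuration mapping.

    The mapping follows the JSON dialect documented in the README
    (``species`` list with per-species state, covariates and incoming
    interactions; optional ``year_effects``/``n_years``; an optional
    ``covariates`` list against which all names are checked).
    """
    if not config.get("species"):
        raise ConfigurationError("config declares no species")
    species = []
    for sc in config["species"]:
        terms = tuple(
            InteractionTerm(
                source_species=tc["source"],
                target_submodel=tc.get("target", "state"),
                modifier_covariate=tc.get("modifier"),
                occupancy_mediated=bool(tc.get("occupancy_mediated", False)),
            )
            for tc in sc.get("interactions", [])
        )
        species.append(
            SpeciesModel(
                name=sc["name"],
                role=sc.get("role", "dominant"),
                state_variable=sc["state"],
                state_formula=tuple(sc.get("state_covariates", [])),
                detection_formula=tuple(sc.get("detection_covariates", [])),
                incoming_interactions=terms,
            )
        )
    ordered = topological_order(species)

    by_name = {s.name: s for s in ordered}
    used_covs = set()
    for s in ordered:
        used_covs.update(s.state_formula)
        used_covs.update(s.detection_formula)
        for t in s.incoming_interactions:
            if t.modifier_covariate is not None:
                used_covs.add(t.modifier_covariate)
            src = by_name[t.source_species]
            if src.state_variable == "occupancy" and not t.occupancy_mediated:
                raise ConfigurationError(
                    f"occupancy-state species {src.name!r} can only source an "
                    "interaction flagged occupancy_mediated"
                )
    declared = config.get("covariates")
    if declared is not None:
        unknown = used_covs - set(declared)
        if unknown:
            raise ConfigurationError(f"unknown covariates {sorted(unknown)}")

    year_effects = bool(config.get("year_effects", False))
    n_years = int(config.get("n_years", 1))
    if year_effects and n_years < 2:
        raise ConfigurationError("year_effects needs n_years >= 2")

    params = []
    for s in ordered:
        st_edges = [t for t in s.incoming_interactions if t.target_submodel == "state"]
        dt_edges = [t for t in s.incoming_interactions if t.target_submodel == "detection"]
        params.extend(_species_params(s, "state", s.state_formula, st_edges, year_effects, n_years))
        params.extend(_species_params(s, "detection", s.detection_formula, dt_edges, year_effects, n_years))
    names = [p.name for p in params]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate parameter names in index")

    return ModelGraph(
        species=tuple(ordered),
        covariate_names=frozenset(used_covs),
        parameter_index=tuple(params),
        year_effects=year_effects,
        n_years=n_years,
    )


def load_model_graph(path) -> ModelGraph:
    with open(path) as fh:
        return build_model_graph(json.load(fh))


def as_occupancy_mediated(graph: ModelGraph) -> ModelGraph:
    """The co-occurrence comparison variant of a model graph.

    Every species that sources an interaction is re-declared as an
    occupancy state (z ~ Bernoulli, Bernoulli detections) and every edge
    is flagged occupancy-mediated, so interactions enter downstream linear
    predictors as gamma0 * z instead of gamma0 * N.  This is the classic
    presence/absence interaction model that the abundance-mediated
    framework is compared against; parameter names are unchanged (state
    intercepts are then on the logit-occupancy scale).
    """
    sources = {t.source_species for s in graph.species for t in s.incoming_interactions}
    new_species = []
    for s in graph.species:
        terms = tuple(
            replace(t, occupancy_mediated=True) for t in s.incoming_interactions
        )
        sv = "occupancy" if s.name in sources else s.state_variable
        new_species.append(replace(s, state_variable=sv, incoming_interactions=terms))
    return replace(graph, species=tuple(new_species))
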