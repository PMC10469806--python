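"""Model structure for microbiota count GLMMs.

A model is a family (Poisson log-link for raw counts, Gaussian identity for
CLR-transformed values), one optional categorical fixed effect alongside the
global intercept, and a set of Gaussian random terms. Each random term is an
interaction of observation-table factors (``asv:group`` reads "one level per
observed (asv, group) pair"); the Poisson model carries over-dispersion
through a row-level residual term whose factor combination identifies each
row uniquely.

Two templates mirror the standard study designs:

* :func:`two_group_single_sample_spec` — each host sampled once, hosts split
  into two groups (e.g. age classes). Random: host, asv, asv:group;
  residual: asv:host (row level when there is one sample per host).
* :func:`two_group_repeated_spec` — each host sampled once per group level
  (e.g. two seasons). Random: host, asv, host:group, asv:host, asv:group;
  residual: asv:host:group (row level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import LongObservations, TaxonomyTable, UNCLASSIFIED

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "DesignRealization",
    "two_group_single_sample_spec",
    "two_group_repeated_spec",
    "add_taxonomy_terms",
    "build_design",
    "spec_to_dict",
    "spec_from_dict",
]

POISSON = "poisson_log"
GAUSSIAN = "gaussian_identity"


@dataclass(frozen=True)
class RandomTerm:
    """A Gaussian random effect over the observed level tuples of one or
    more observation-table factors."""

    name: str
    factors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError(f"random term {self.name!r} has no factors")


@dataclass
class ModelSpec:
    """Family, fixed effect and random structure of one GLMM.

    The intercept is always present. ``fixed_group`` names the categorical
    fixed-effect column (or None for intercept-only). ``residual_term`` is
    the row-level over-dispersion term for the Poisson family; the Gaussian
    family uses its own residual variance instead and leaves it None.
    """

    family: str = POISSON
    fixed_group: str | None = "group"
    random_terms: list[RandomTerm] = field(default_factory=list)
    residual_term: RandomTerm | None = None

    def __post_init__(self) -> None:
        if self.family not in (POISSON, GAUSSIAN):
            raise ValueError(f"unknown family {self.family!r}")
        names = [t.name for t in self.all_terms]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate term names: {names}")

    @property
    def all_terms(self) -> list[RandomTerm]:
        terms = list(self.random_terms)
        if self.residual_term is not None:
            terms.append(self.residual_term)
        return terms


def two_group_single_sample_spec(drop_host: bool = False) -> ModelSpec:
    """Poisson template for one sample per host, two host groups.

    Random terms: host (library size; host == sample here), asv (overall
    taxon abundance), asv:group (the differential-abundance term). The
    residual asv:host term is row-level because each host contributes a
    single sample.
    """
    random_terms = [
        RandomTerm("host", ("host_id",)),
        RandomTerm("asv", ("asv_id",)),
        RandomTerm("asv:group", ("asv_id", "group")),
    ]
    if drop_host:
        random_terms = random_terms[1:]
    return ModelSpec(
        family=POISSON,
        fixed_group="group",
        random_terms=random_terms,
        residual_term=RandomTerm("asv:host", ("asv_id", "host_id")),
    )


def two_group_repeated_spec(drop_host: bool = False) -> ModelSpec:
    """Poisson template for repeated sampling: each host measured at both
    group levels (e.g. two seasons).

    Random terms: host, asv, host:group (per-sample library size), asv:host
    (individual compositional signature, the repeatability numerator) and
    asv:group (compositional shift between groups); residual asv:host:group
    is row-level. ``drop_host`` removes the host main effect for designs
    where it is confounded with host:group.
    """
    random_terms = [
        RandomTerm("host", ("host_id",)),
        RandomTerm("asv", ("asv_id",)),
        RandomTerm("host:group", ("host_id", "group")),
        RandomTerm("asv:host", ("asv_id", "host_id")),
        RandomTerm("asv:group", ("asv_id", "group")),
    ]
    if drop_host:
        random_terms = [t for t in random_terms if t.name != "host"]
    return ModelSpec(
        family=POISSON,
        fixed_group="group",
        random_terms=random_terms,
        residual_term=RandomTerm("asv:host:group", ("asv_id", "host_id", "group")),
    )


def add_taxonomy_terms(
    spec: ModelSpec,
    tax: TaxonomyTable,
    ranks: list[str],
    group_column: str = "group",
) -> ModelSpec:
    """Append hierarchical rank-by-group random terms (e.g. Phylum:group,
    Family:group) so differential abundance can be decomposed across
    taxonomic levels. Missing rank labels were pooled to ``unclassified``
    at read time, so every ASV has a level."""
    for rank in ranks:
        if rank not in tax.ranks:
            raise ValueError(f"rank {rank!r} not in taxonomy (has {tax.ranks})")
    new_terms = list(spec.random_terms)
    for rank in ranks:
        new_terms.append(RandomTerm(f"{rank}:{group_column}", (rank, group_column)))
    return replace(spec, random_terms=new_terms)


@dataclass
class DesignRealization:
    """Per-row level indices for every term plus fixed-effect indicators.

    ``term_index[name]`` maps each observation row to a level in
    ``term_labels[name]`` (levels sorted lexicographically by label tuple,
    so realisation is deterministic). Fixed effects use treatment coding:
    the first sorted group level is the reference.
    """

    n_rows: int
    term_index: dict[str, np.ndarray]
    term_labels: dict[str, list[tuple[str, ...]]]
    fixed_names: list[str]
    fixed_columns: np.ndarray  # (n_rows, n_fixed) 0/1, intercept first
    group_levels: list[str]
    response: np.ndarray

    def n_levels(self, term: str) -> int:
        return len(self.term_labels[term])


def build_design(obs: LongObservations, spec: ModelSpec) -> DesignRealization:
    """Realise a model spec against an observation table.

    Pure function of its inputs: level indexing is lexicographic over
    observed label tuples, so identical inputs give identical designs.
    """
    df = obs.data
    term_index: dict[str, np.ndarray] = {}
    term_labels: dict[str, list[tuple[str, ...]]] = {}
    for term in spec.all_terms:
        for col in term.factors:
            if col not in df.columns:
                raise ValueError(f"term {term.name!r} references missing column {col!r}")
        key = pd.MultiIndex.from_frame(df[list(term.factors)].astype(str))
        labels = sorted(set(key))
        lookup = {lab: i for i, lab in enumerate(labels)}
        term_index[term.name] = np.fromiter(
            (lookup[k] for k in key), dtype=np.int64, count=len(df)
        )
        term_labels[term.name] = labels
    if spec.residual_term is not None:
        name = spec.residual_term.name
        if len(term_labels[name]) != len(df):
            raise ValueError(
                f"residual term {name!r} has {len(term_labels[name])} levels for "
                f"{len(df)} rows; it must identify rows uniquely"
            )
    fixed_names = ["intercept"]
    cols = [np.ones(len(df))]
    group_levels: list[str] = []
    if spec.fixed_group is not None:
        if spec.fixed_group not in df.columns:
            raise ValueError(f"fixed-effect column {spec.fixed_group!r} missing")
        group_levels = sorted(df[spec.fixed_group].astype(str).unique())
        for lev in group_levels[1:]:  # treatment coding, first level = reference
            fixed_names.append(f"{spec.fixed_group}[{lev}]")
            cols.append((df[spec.fixed_group].astype(str) == lev).to_numpy(float))
    response = df[obs.response].to_numpy(float)
    return DesignRealization(
        n_rows=len(df),
        term_index=term_index,
        term_labels=term_labels,
        fixed_names=fixed_names,
        fixed_columns=np.column_stack(cols),
        group_levels=group_levels,
        response=response,
    )


def spec_to_dict(spec: ModelSpec) -> dict:
    """Serialisable form: factors colon-joined, as in config files."""
    return {
        "family": spec.family,
        "fixed": spec.fixed_group,
        "random": {t.name: ":".join(t.factors) for t in spec.random_terms},
        "residual": (
            {spec.residual_term.name: ":".join(spec.residual_term.factors)}
            if spec.residual_term
            else None
        ),
    }


def spec_from_dict(d: dict) -> ModelSpec:
    random_terms = [
        RandomTerm(name, tuple(f.split(":"))) for name, f in d.get("random", {}).items()
    ]
    residual = d.get("residual")
    residual_term = None
    if residual:
        (name, f), = residual.items()
        residual_term = RandomTerm(name, tuple(f.split(":")))
    return ModelSpec(
        family=d.get("family", POISSON),
        fixed_group=d.get("fixed"),
        random_terms=random_terms,
        residual_term=residual_term,
    )
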