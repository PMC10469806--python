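import numpy as np
import pandas as pd
import pytest

from asvglmm import (
    CountMatrix,
    LongObservations,
    MCMCConfig,
    PosteriorSamples,
    SampleMetadata,
    TaxonomyTable,
)
from asvglmm.model_spec import POISSON, GAUSSIAN, ModelSpec, RandomTerm, spec_to_dict


@pytest.fixture
def tiny_counts():
    return CountMatrix(pd.DataFrame(
        [[10, 0, 3, 1], [0, 5, 2, 0], [7, 1, 0, 4]],
        index=["ASV1", "ASV2", "ASV3"],
        columns=["S1", "S2", "S3", "S4"],
    ))


@pytest.fixture
def tiny_meta():
    return SampleMetadata(pd.DataFrame(
        {"host_id": ["H1", "H1", "H2", "H2"], "group": ["G1", "G2", "G1", "G2"]},
        index=pd.Index(["S1", "S2", "S3", "S4"], name="sample_id"),
    ))


@pytest.fixture
def tiny_tax():
    return TaxonomyTable(pd.DataFrame(
        {"Kingdom": ["Bacteria"] * 3,
         "Phylum": ["PhylumA", "PhylumB", None],
         "Family": ["Fam1", "Fam2", "Fam1"]},
        index=pd.Index(["ASV1", "ASV2", "ASV3"], name="asv_id"),
    ))


def make_posterior(
    variances: dict[str, np.ndarray],
    fixed: dict[str, np.ndarray] | None = None,
    random: dict[str, np.ndarray] | None = None,
    term_labels: dict[str, list[tuple[str, ...]]] | None = None,
    family: str = POISSON,
    group_levels=("G1", "G2"),
    residual_name: str | None = None,
) -> PosteriorSamples:
    """Assemble a PosteriorSamples by hand, e.g. with constant draws."""
    variances = {k: np.atleast_2d(np.asarray(v, float)) for k, v in variances.items()}
    n_chains, n_draws = next(iter(variances.values())).shape
    fixed = {k: np.atleast_2d(np.asarray(v, float)) for k, v in (fixed or {}).items()}
    random = {k: np.asarray(v, float)[None] if np.asarray(v).ndim == 2 else np.asarray(v, float)
              for k, v in (random or {}).items()}
    spec_dict = {
        "family": family,
        "fixed": "group",
        "random": {},
        "residual": {residual_name: residual_name} if residual_name else None,
    }
    cfg = MCMCConfig(n_iterations=n_draws * 2 + 1, burn_in=1, thin=2,
                     n_chains=n_chains, seed=0)
    return PosteriorSamples(
        family=family,
        fixed=fixed,
        random=random,
        variances=variances,
        term_labels=term_labels or {},
        group_levels=list(group_levels),
        spec_dict=spec_dict,
        config=cfg,
    )


def four_term_spec() -> ModelSpec:
    """Poisson spec with the four variance components of the default
    synthetic scenario: asv, per-sample (host:group), asv:group, and the
    row-level residual."""
    return ModelSpec(
        family=POISSON,
        fixed_group="group",
        random_terms=[
            RandomTerm("asv", ("asv_id",)),
            RandomTerm("host:group", ("host_id", "group")),
            RandomTerm("asv:group", ("asv_id", "group")),
        ],
        residual_term=RandomTerm("asv:host:group", ("asv_id", "host_id", "group")),
    )


def short_chain(seed: int, n_iterations: int = 3000, burn_in: int = 1000,
                thin: int = 4) -> MCMCConfig:
    return MCMCConfig(n_iterations=n_iterations, burn_in=burn_in, thin=thin,
                      n_chains=1, seed=seed)
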