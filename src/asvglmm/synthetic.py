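"""Synthetic ASV count data from the model's own generative form.

Counts are lognormal-Poisson: for each (asv, host, group) cell,

    log lambda = beta0 + beta1 * 1[group = last]
                 + u_host + u_asv + u_host:group + u_asv:host
                 + u_asv:group + u_residual

with each ``u`` drawn once per level from N(0, sigma2_term) and the count
drawn as Poisson(lambda). One sample per host-by-group combination. The
host:group (per-sample) term injects library-size heterogeneity; the
row-level residual term injects over-dispersion.

A configurable fraction of ASVs can carry a *spiked* group effect: the
spiked ASV's asv:group draws are replaced by a fixed offset of magnitude
``spike_delta`` on the last group level, with signs alternating across
spiked ASVs, so power checks have exact, balanced targets.

Defaults emulate a modest repeated-sampling field study: 30 hosts, 2
groups, 150 ASVs (9,000 observation rows), log-mean count 3 (about 20
reads) and variance components dominated by among-taxon spread and
row-level over-dispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_tables import CountMatrix, SampleMetadata, TaxonomyTable

__all__ = ["SynthConfig", "SyntheticTruth", "simulate_dataset", "null_dataset"]

TERM_NAMES = ("host", "asv", "host:group", "asv:host", "asv:group", "residual")

DEFAULT_SIGMA2 = {
    "host": 0.0,
    "asv": 1.0,
    "host:group": 0.1,
    "asv:host": 0.0,
    "asv:group": 0.2,
    "residual": 0.5,
}


@dataclass
class SynthConfig:
    n_hosts: int = 30
    n_groups: int = 2
    n_asvs: int = 150
    beta0: float = 3.0
    beta1: float = 0.0
    sigma2: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA2))
    spike_fraction: float = 0.0
    spike_delta: float = 1.5
    n_taxa_phyla: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        full = dict(DEFAULT_SIGMA2)
        full.update(self.sigma2)
        unknown = set(full) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown sigma2 terms: {sorted(unknown)}")
        if any(v < 0 for v in full.values()):
            raise ValueError("sigma2 values must be >= 0")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction must be in [0, 1]")
        if min(self.n_hosts, self.n_groups, self.n_asvs, self.n_taxa_phyla) < 1:
            raise ValueError("dimensions must be positive")
        self.sigma2 = full


@dataclass
class SyntheticTruth:
    """Everything the generator knew: realised effects, true variances,
    spiked ASVs and their offsets."""

    sigma2: dict[str, float]
    u: dict[str, dict[str, float]]
    spiked: dict[str, float]
    beta0: float
    beta1: float

    def to_json(self) -> str:
        return json.dumps({
            "beta0": self.beta0,
            "beta1": self.beta1,
            "sigma2": self.sigma2,
            "spiked": self.spiked,
            "u": self.u,
        }, indent=2)


def _ids(prefix: str, n: int) -> list[str]:
    w = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{w}d}" for i in range(n)]


def simulate_dataset(
    cfg: SynthConfig,
) -> tuple[CountMatrix, SampleMetadata, TaxonomyTable, SyntheticTruth]:
    """Draw one complete dataset; byte-identical for a given config."""
    rng = np.random.default_rng(cfg.seed)
    hosts = _ids("H", cfg.n_hosts)
    groups = _ids("G", cfg.n_groups)
    asvs = _ids("ASV", cfg.n_asvs)
    s2 = cfg.sigma2

    def draw(term: str, size) -> np.ndarray:
        sd = np.sqrt(s2[term])
        return rng.normal(0.0, sd, size=size) if sd > 0 else np.zeros(size)

    u_host = draw("host", cfg.n_hosts)
    u_asv = draw("asv", cfg.n_asvs)
    u_hg = draw("host:group", (cfg.n_hosts, cfg.n_groups))
    u_ah = draw("asv:host", (cfg.n_asvs, cfg.n_hosts))
    u_ag = draw("asv:group", (cfg.n_asvs, cfg.n_groups))

    n_spiked = int(round(cfg.spike_fraction * cfg.n_asvs))
    spiked_idx = rng.choice(cfg.n_asvs, size=n_spiked, replace=False) if n_spiked else np.array([], int)
    spiked_idx = np.sort(spiked_idx)
    spiked: dict[str, float] = {}
    for k, i in enumerate(spiked_idx):
        delta = cfg.spike_delta if k % 2 == 0 else -cfg.spike_delta
        u_ag[i, :] = 0.0
        u_ag[i, -1] = delta  # offset on the last group level; contrast = delta
        spiked[asvs[i]] = delta

    u_res = draw("residual", (cfg.n_asvs, cfg.n_hosts, cfg.n_groups))

    log_lam = (
        cfg.beta0
        + u_host[None, :, None]
        + u_asv[:, None, None]
        + u_hg[None, :, :]
        + u_ah[:, :, None]
        + u_ag[:, None, :]
        + u_res
    )
    log_lam[:, :, -1] += cfg.beta1 if cfg.n_groups > 1 else 0.0
    lam = np.exp(log_lam)
    if np.any(lam > 1e9):
        raise ValueError(
            "simulated rate exceeds 1e9; reduce beta0 or the variance components"
        )
    counts3 = rng.poisson(lam)

    sample_ids = [f"{h}.{g}" for h in hosts for g in groups]
    counts = CountMatrix(pd.DataFrame(
        counts3.reshape(cfg.n_asvs, -1), index=asvs, columns=sample_ids
    ))
    meta = SampleMetadata(pd.DataFrame(
        {
            "host_id": [h for h in hosts for _ in groups],
            "group": [g for _ in hosts for g in groups],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    n_families = 3 * cfg.n_taxa_phyla
    tax = TaxonomyTable(pd.DataFrame(
        {
            "Kingdom": ["Bacteria"] * cfg.n_asvs,
            "Phylum": [f"Phylum{(i % cfg.n_taxa_phyla) + 1}" for i in range(cfg.n_asvs)],
            "Family": [f"Family{(i % n_families) + 1}" for i in range(cfg.n_asvs)],
        },
        index=pd.Index(asvs, name="asv_id"),
    ))

    u_named = {
        "host": dict(zip(hosts, u_host.round(10).tolist())),
        "asv": dict(zip(asvs, u_asv.round(10).tolist())),
        "host:group": {
            f"{h}|{g}": float(u_hg[i, j])
            for i, h in enumerate(hosts) for j, g in enumerate(groups)
        },
        "asv:host": {
            f"{a}|{h}": float(u_ah[i, j])
            for i, a in enumerate(asvs) for j, h in enumerate(hosts)
        },
        "asv:group": {
            f"{a}|{g}": float(u_ag[i, j])
            for i, a in enumerate(asvs) for j, g in enumerate(groups)
        },
    }
    truth = SyntheticTruth(
        sigma2=dict(s2), u=u_named, spiked=spiked, beta0=cfg.beta0, beta1=cfg.beta1
    )
    return counts, meta, tax, truth


def null_dataset(
    cfg: SynthConfig,
) -> tuple[CountMatrix, SampleMetadata, TaxonomyTable, SyntheticTruth]:
    """Same generator with the group-shift machinery switched off:
    sigma2[asv:group] = 0 and no spikes. The type-I-error harness."""
    sigma2 = dict(cfg.sigma2)
    sigma2["asv:group"] = 0.0
    return simulate_dataset(replace(cfg, sigma2=sigma2, spike_fraction=0.0))
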