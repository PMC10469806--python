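"""Posterior summaries: variance partitioning, repeatability, and
differential abundance.

All quantities are computed *per draw* and then summarised, so every
reported proportion comes with a credible interval instead of being a ratio
of point estimates.

Variance partitioning follows the latent-scale decomposition for Poisson
log-link mixed models: the distribution-specific variance is
``omega = ln(1 + 1/lambda_bar)`` with ``lambda_bar = exp(beta0 + 0.5 *
sum_t sigma2_t)`` (the lognormal mean at the fixed-effect reference level),
and each term's share is ``sigma2_t / (sum sigma2 + omega)``. For the
Gaussian family the residual variance plays omega's role.

Repeatability is the share of non-technical compositional variance carried
by among-host differences in taxon abundance:
``R = s2[asv:host] / (s2[asv:group] + s2[asv:host] + s2[residual])``.

Differential abundance subtracts the posterior draws of a taxon's
group-level random effects (e.g. ``u[asv, summer] - u[asv, spring]``); a
shift is called robust when the highest-posterior-density interval of that
contrast excludes zero.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import LongObservations, TaxonomyTable
from .mcmc import GAUSSIAN, POISSON, RESIDUAL_KEY, PosteriorSamples

__all__ = [
    "Interval",
    "VariancePartition",
    "RepeatabilityResult",
    "DifferentialAbundanceTable",
    "ShiftSummary",
    "hpdi",
    "partition_variance",
    "repeatability",
    "differential_abundance",
    "summarize_shifts",
]

DISTRIBUTION_ROW = "distribution"


@dataclass(frozen=True)
class Interval:
    lower: float
    upper: float
    prob: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("interval lower bound exceeds upper bound")
        if not 0.0 < self.prob < 1.0:
            raise ValueError("interval probability must be in (0, 1)")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0


def hpdi(draws, prob: float = 0.95) -> Interval:
    """Highest posterior density interval: the shortest contiguous window
    of sorted draws containing ``ceil(prob * n)`` of them.

    Ties are broken towards the lowest start index, so the result is
    deterministic for lattice-valued draws.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 10:
        raise ValueError(f"need at least 10 draws for an HPDI, got {x.size}")
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    s = np.sort(x)
    m = math.ceil(prob * s.size)
    widths = s[m - 1:] - s[: s.size - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return Interval(float(s[i]), float(s[i + m - 1]), prob)


# ---------------------------------------------------------------------------
# variance partitioning


@dataclass
class VariancePartition:
    """Per-term variance components and their latent-scale proportions.

    ``proportions[term]`` holds the per-draw proportion series (including a
    ``"distribution"`` entry); ``table`` summarises mean and HPDI of each
    sigma2 and proportion. ``lambda_bar`` is the per-draw expected-count
    scale entering the Poisson distribution-specific variance (None for the
    Gaussian family).
    """

    family: str
    table: pd.DataFrame
    proportions: dict[str, np.ndarray]
    sigma2: dict[str, np.ndarray]
    lambda_bar: np.ndarray | None
    prob: float = 0.95

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "prob": self.prob,
                "terms": self.table.set_index("term").to_dict(orient="index"),
            },
            indent=2,
        )


def partition_variance(
    ps: PosteriorSamples,
    family: str | None = None,
    prob: float = 0.95,
    include_fixed: bool = False,
    obs: LongObservations | None = None,
) -> VariancePartition:
    """Decompose the latent-scale variance across model terms, per draw.

    ``include_fixed`` adds the variance of the fixed-effect predictor to
    the denominator (the full marginal-R2 convention); it requires ``obs``
    to recover the group composition of the rows. The default partition
    lists only random components plus the distribution-specific row.
    """
    family = family or ps.family
    terms = list(ps.variances.keys())
    if family == GAUSSIAN:
        if RESIDUAL_KEY not in terms:
            raise ValueError("Gaussian partition needs residual variance draws")
        omega_name = RESIDUAL_KEY
        terms = [t for t in terms if t != RESIDUAL_KEY]
    sig = {t: ps.flat_variance(t) for t in terms}
    n = next(iter(sig.values())).size
    total_random = np.sum([sig[t] for t in terms], axis=0)

    lambda_bar = None
    if family == POISSON:
        if "intercept" not in ps.fixed:
            raise ValueError("Poisson partition needs intercept draws for lambda_bar")
        beta0 = ps.flat_fixed("intercept")
        lambda_bar = np.exp(beta0 + 0.5 * total_random)
        omega = np.log1p(1.0 / lambda_bar)
    else:
        omega = ps.flat_variance(omega_name)

    fixed_var = None
    if include_fixed:
        if obs is None:
            raise ValueError("include_fixed=True requires the observation table")
        fixed_var = _fixed_effect_variance(ps, obs)

    denom = total_random + omega
    if fixed_var is not None:
        denom = denom + fixed_var
    # the omega row is named "distribution" for Poisson; for the Gaussian
    # family the residual variance itself plays that role and keeps its name
    omega_row = DISTRIBUTION_ROW if family == POISSON else RESIDUAL_KEY
    props = {t: sig[t] / denom for t in terms}
    props[omega_row] = omega / denom
    sig_all = dict(sig)
    sig_all[omega_row] = omega
    if fixed_var is not None:
        props["fixed"] = fixed_var / denom
        sig_all["fixed"] = fixed_var

    rows = []
    for name in sig_all:
        s_i = hpdi(sig_all[name], prob)
        p_i = hpdi(props[name], prob)
        rows.append({
            "term": name,
            "sigma2_mean": float(sig_all[name].mean()),
            "sigma2_lo": s_i.lower,
            "sigma2_hi": s_i.upper,
            "prop_mean": float(props[name].mean()),
            "prop_lo": p_i.lower,
            "prop_hi": p_i.upper,
        })
    assert n == denom.size
    return VariancePartition(
        family=family,
        table=pd.DataFrame(rows),
        proportions=props,
        sigma2=sig_all,
        lambda_bar=lambda_bar,
        prob=prob,
    )


def _fixed_effect_variance(ps: PosteriorSamples, obs: LongObservations) -> np.ndarray:
    """Per-draw variance over rows of the fixed-effect predictor."""
    group_col = ps.spec_dict.get("fixed")
    if group_col is None:
        return np.zeros(ps.n_draws_total)
    groups = obs.data[group_col].astype(str)
    levels = ps.group_levels
    fracs = np.array([(groups == lev).mean() for lev in levels])
    # treatment coding: predictor is 0 at reference, beta_l at level l
    betas = [np.zeros(ps.n_draws_total)]
    for lev in levels[1:]:
        betas.append(ps.flat_fixed(f"{group_col}[{lev}]"))
    B = np.column_stack(betas)  # (draws, levels)
    mean = B @ fracs
    return (B - mean[:, None]) ** 2 @ fracs


# ---------------------------------------------------------------------------
# repeatability


@dataclass
class RepeatabilityResult:
    mean: float
    interval: Interval
    draws: np.ndarray

    def to_json(self) -> str:
        return json.dumps({
            "repeatability_mean": self.mean,
            "hpdi_lower": self.interval.lower,
            "hpdi_upper": self.interval.upper,
            "prob": self.interval.prob,
        }, indent=2)


def repeatability(
    ps: PosteriorSamples,
    host_term: str = "asv:host",
    group_term: str = "asv:group",
    residual_term: str | None = None,
    prob: float = 0.95,
) -> RepeatabilityResult:
    """Among-host share of compositional variance, per draw:
    ``R = s2[host_term] / (s2[group_term] + s2[host_term] + s2[residual])``.

    Only the compositional (taxon-structured) terms enter the denominator;
    library-size and whole-sample technical terms do not.
    """
    if residual_term is None:
        residual_term = RESIDUAL_KEY if ps.family == GAUSSIAN else None
        if residual_term is None:
            residual = ps.spec_dict.get("residual") or {}
            residual_term = next(iter(residual), None)
    for t in (host_term, group_term, residual_term):
        if t not in ps.variances:
            raise ValueError(f"posterior has no variance draws for term {t!r}")
    h = ps.flat_variance(host_term)
    g = ps.flat_variance(group_term)
    r = ps.flat_variance(residual_term)
    draws = h / (g + h + r)
    return RepeatabilityResult(float(draws.mean()), hpdi(draws, prob), draws)


# ---------------------------------------------------------------------------
# differential abundance


@dataclass
class DifferentialAbundanceTable:
    """Per-taxon posterior contrast between two group levels.

    ``table`` columns: asv_id, mean_diff (link scale, level_b minus
    level_a), hpdi_lo, hpdi_hi, robust, inv_var, missing [, rank columns].
    """

    term: str
    level_a: str
    level_b: str
    prob: float
    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def robust_fraction(self) -> float:
        ok = self.table[~self.table["missing"]]
        return float(ok["robust"].mean()) if len(ok) else 0.0


def differential_abundance(
    ps: PosteriorSamples,
    term: str = "asv:group",
    level_a: str | None = None,
    level_b: str | None = None,
    prob: float = 0.95,
    tax: TaxonomyTable | None = None,
    bh_adjust: bool = False,
) -> DifferentialAbundanceTable:
    """Contrast a taxon-by-group random term between two group levels.

    For each taxon the contrast draws are ``u[taxon, level_b] - u[taxon,
    level_a]``; the mean, the HPDI at ``prob`` and a robustness flag
    (interval excludes zero) are reported, along with the inverse variance
    of the contrast (a natural point size for forest plots). Taxa lacking
    one of the levels are kept with ``missing=True`` rather than dropped.

    ``bh_adjust`` adds a Benjamini–Hochberg-adjusted posterior tail
    probability column (``q_value``) and a ``robust_bh`` flag; the plain
    HPDI rule remains the primary caller.
    """
    if term not in ps.random:
        raise ValueError(f"posterior has no random term {term!r}")
    labels = ps.term_labels[term]
    width = len(labels[0])
    if width != 2:
        raise ValueError(f"term {term!r} is not a two-factor interaction")
    if level_a is None or level_b is None:
        if len(ps.group_levels) < 2:
            raise ValueError("level_a and level_b must be given explicitly")
        level_a = level_a or ps.group_levels[0]
        level_b = level_b or ps.group_levels[-1]

    positions = [
        p for p in range(width)
        if any(l[p] == level_a for l in labels) and any(l[p] == level_b for l in labels)
    ]
    if not positions:
        raise ValueError(
            f"levels {level_a!r}/{level_b!r} not found in term {term!r}"
        )
    gpos = positions[-1]
    tpos = 1 - gpos
    lookup = {lab: i for i, lab in enumerate(labels)}
    taxa = sorted({lab[tpos] for lab in labels})

    flat = ps.flat_random(term)
    rows = []
    tails = []
    for taxon in taxa:
        key_a = tuple(taxon if p == tpos else level_a for p in range(width))
        key_b = tuple(taxon if p == tpos else level_b for p in range(width))
        ia, ib = lookup.get(key_a), lookup.get(key_b)
        if ia is None or ib is None:
            rows.append({
                "asv_id": taxon, "mean_diff": np.nan, "hpdi_lo": np.nan,
                "hpdi_hi": np.nan, "robust": False, "inv_var": np.nan,
                "missing": True,
            })
            tails.append(np.nan)
            continue
        contrast = flat[:, ib] - flat[:, ia]
        iv = hpdi(contrast, prob)
        var = float(contrast.var(ddof=1))
        rows.append({
            "asv_id": taxon,
            "mean_diff": float(contrast.mean()),
            "hpdi_lo": iv.lower,
            "hpdi_hi": iv.upper,
            "robust": iv.excludes_zero(),
            "inv_var": (1.0 / var) if var > 0 else np.inf,
            "missing": False,
        })
        p_pos = float((contrast > 0).mean())
        tails.append(2.0 * min(p_pos, 1.0 - p_pos))
    table = pd.DataFrame(rows)
    if bh_adjust:
        q = _bh(np.asarray(tails, dtype=float))
        table["q_value"] = q
        table["robust_bh"] = (q <= 1.0 - prob) & ~table["missing"]
    if tax is not None:
        ann = tax.table.reindex(table["asv_id"])
        for r in tax.ranks:
            table[r] = ann[r].fillna("unclassified").to_numpy()
    return DifferentialAbundanceTable(term, level_a, level_b, prob, table)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, NaNs passed through."""
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


# ---------------------------------------------------------------------------
# shift summaries


@dataclass
class ShiftSummary:
    """Counts and rank-level composition of robust differential shifts."""

    rank: str
    n_taxa: int
    n_robust: int
    pct_robust: float
    n_positive: int
    n_negative: int
    pct_positive: float
    pct_negative: float
    positive_by_rank: dict[str, float] = field(default_factory=dict)
    negative_by_rank: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def summarize_shifts(da: DifferentialAbundanceTable, rank: str) -> ShiftSummary:
    """Tally robust shifts by direction and break each direction down by a
    taxonomic rank (percent composition within direction)."""
    if rank not in da.table.columns:
        raise ValueError(f"differential-abundance table has no rank column {rank!r}")
    t = da.table[~da.table["missing"]]
    robust = t[t["robust"]]
    pos = robust[robust["mean_diff"] > 0]
    neg = robust[robust["mean_diff"] <= 0]

    def composition(sub: pd.DataFrame) -> dict[str, float]:
        if len(sub) == 0:
            return {}
        counts = sub[rank].value_counts()
        return {k: round(100.0 * v / len(sub), 2) for k, v in counts.items()}

    n, nr = len(t), len(robust)
    return ShiftSummary(
        rank=rank,
        n_taxa=n,
        n_robust=nr,
        pct_robust=round(100.0 * nr / n, 2) if n else 0.0,
        n_positive=len(pos),
        n_negative=len(neg),
        pct_positive=round(100.0 * len(pos) / nr, 2) if nr else 0.0,
        pct_negative=round(100.0 * len(neg) / nr, 2) if nr else 0.0,
        positive_by_rank=composition(pos),
        negative_by_rank=composition(neg),
    )
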