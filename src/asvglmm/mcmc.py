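"""Posterior sampling for the count GLMM.

The model on the link scale is

    eta_i = x_i' beta + sum_t u_{t, level_t(i)},    u_{t,l} ~ N(0, sigma2_t)

with ``y_i ~ Poisson(exp(eta_i))`` (log link; over-dispersion carried by a
row-level random term) or ``y_i ~ N(eta_i, sigma2_e)`` for the Gaussian
identity family used with CLR-transformed data. Priors follow the common
mixed-model convention: fixed effects are zero-mean Gaussian with a very
large variance, and each variance component gets an inverse-gamma prior
parameterised by a scale V and a degree of belief nu (shape nu/2, rate
nu*V/2), weakly informative at the defaults V=1, nu=0.002.

Sampling scheme
---------------
Gaussian family: fully conjugate Gibbs (random-effect levels and fixed
effects from their Gaussian conditionals, variances from inverse-gamma
conditionals). Poisson family: Metropolis-within-Gibbs — all levels of a
term are proposed and accepted/rejected simultaneously (valid because each
observation belongs to exactly one level per term, so level conditionals
are independent given the rest), fixed effects by scalar random-walk MH,
variances by their conjugate inverse-gamma conditionals. Proposal scales
adapt towards ~44% acceptance during burn-in and are frozen afterwards.

Two exact auxiliary Metropolis moves repair the notoriously slow directions
of this posterior: a likelihood-invariant *translation* that trades the
mean of a random term against the intercept (and group-level subsets
against the group coefficient), and a joint *rescale* of (u_t, sigma2_t)
that decorrelates a term's spread from its variance component — important
for the observation-level term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import LongObservations
from .model_spec import (
    GAUSSIAN,
    POISSON,
    DesignRealization,
    ModelSpec,
    build_design,
    spec_from_dict,
    spec_to_dict,
)

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorSamples",
    "Diagnostics",
    "fit_glmm",
    "diagnostics",
    "predicted_zero_ratio",
]

#: linear predictors are clamped here inside exp() for numeric safety
ETA_CLAMP = 50.0

RESIDUAL_KEY = "residual"  # Gaussian-family residual variance name


@dataclass
class PriorSpec:
    """Priors for one fit.

    ``V``/``nu`` are the default inverse-gamma scale and degree of belief
    for every variance component; ``term_V``/``term_nu`` override single
    terms by name (the Gaussian residual variance is addressed as
    ``"residual"``). ``fixed_variance`` is the prior variance of each fixed
    effect. ``expand`` toggles the parameter-expanded rescale move, either
    globally (bool) or per term (dict).
    """

    V: float = 1.0
    nu: float = 0.002
    term_V: dict[str, float] = field(default_factory=dict)
    term_nu: dict[str, float] = field(default_factory=dict)
    fixed_variance: float = 1e8
    expand: bool | dict[str, bool] = True

    def __post_init__(self) -> None:
        if self.V <= 0 or self.nu <= 0:
            raise ValueError("prior V and nu must be > 0")
        for d in (self.term_V, self.term_nu):
            for k, v in d.items():
                if v <= 0:
                    raise ValueError(f"prior override for {k!r} must be > 0")

    def ig_params(self, term: str) -> tuple[float, float]:
        """Inverse-gamma (shape, rate) for a term's variance."""
        V = self.term_V.get(term, self.V)
        nu = self.term_nu.get(term, self.nu)
        return nu / 2.0, nu * V / 2.0

    def expands(self, term: str) -> bool:
        if isinstance(self.expand, dict):
            return self.expand.get(term, False)
        return bool(self.expand)


@dataclass
class MCMCConfig:
    """Chain lengths. Defaults yield ~2,000 retained draws over 2 chains."""

    n_iterations: int = 65_000
    burn_in: int = 15_000
    thin: int = 50
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, per chain.

    ``fixed[name]`` has shape (chains, draws); ``variances[term]`` likewise;
    ``random[term]`` has shape (chains, draws, n_levels) aligned with
    ``term_labels[term]`` (lexicographically sorted level label tuples).
    """

    family: str
    fixed: dict[str, np.ndarray]
    random: dict[str, np.ndarray]
    variances: dict[str, np.ndarray]
    term_labels: dict[str, list[tuple[str, ...]]]
    group_levels: list[str]
    spec_dict: dict
    config: MCMCConfig

    @property
    def n_draws_total(self) -> int:
        for table in (self.variances, self.fixed):
            if table:
                arr = next(iter(table.values()))
                return arr.shape[0] * arr.shape[1]
        raise ValueError("posterior holds no draws")

    def flat_fixed(self, name: str) -> np.ndarray:
        return self.fixed[name].reshape(-1)

    def flat_variance(self, term: str) -> np.ndarray:
        return self.variances[term].reshape(-1)

    def flat_random(self, term: str) -> np.ndarray:
        arr = self.random[term]
        return arr.reshape(-1, arr.shape[-1])

    def level_index(self, term: str, label: tuple[str, ...]) -> int:
        try:
            return self.term_labels[term].index(tuple(label))
        except ValueError:
            raise KeyError(f"term {term!r} has no level {label!r}") from None

    # --- interchange -----------------------------------------------------

    def to_tsv(self, path, include_terms: list[str] | None = None) -> None:
        """Long-format TSV: chain, iteration, parameter, value.

        Random-effect levels are encoded ``term[lab1|lab2]``. ``include_terms``
        limits which terms' level draws are written (variance draws are
        always written for every term).
        """
        rows = []
        n_chains = self.config.n_chains
        for name, arr in self.fixed.items():
            for c in range(n_chains):
                rows.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(arr.shape[1]),
                    "parameter": f"beta:{name}", "value": arr[c]}))
        for term, arr in self.variances.items():
            for c in range(n_chains):
                rows.append(pd.DataFrame({
                    "chain": c, "iteration": np.arange(arr.shape[1]),
                    "parameter": f"sigma2:{term}", "value": arr[c]}))
        for term, arr in self.random.items():
            if include_terms is not None and term not in include_terms:
                continue
            labels = self.term_labels[term]
            for li, lab in enumerate(labels):
                pname = f"u:{term}[{'|'.join(lab)}]"
                for c in range(n_chains):
                    rows.append(pd.DataFrame({
                        "chain": c, "iteration": np.arange(arr.shape[1]),
                        "parameter": pname, "value": arr[c, :, li]}))
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, meta: dict) -> "PosteriorSamples":
        """Rebuild from :meth:`to_tsv` output plus the JSON metadata dict
        written alongside it (family, spec, group levels, config)."""
        df = pd.read_csv(path, sep="\t")
        cfg = MCMCConfig(**meta["config"])
        n_chains = cfg.n_chains
        fixed: dict[str, np.ndarray] = {}
        variances: dict[str, np.ndarray] = {}
        random: dict[str, list] = {}
        labels: dict[str, list[tuple[str, ...]]] = {}
        for pname, sub in df.groupby("parameter", sort=False):
            pivot = sub.pivot(index="chain", columns="iteration", values="value").to_numpy()
            if pname.startswith("beta:"):
                fixed[pname[5:]] = pivot
            elif pname.startswith("sigma2:"):
                variances[pname[7:]] = pivot
            elif pname.startswith("u:"):
                term, lab = pname[2:-1].split("[", 1)
                random.setdefault(term, []).append(pivot)
                labels.setdefault(term, []).append(tuple(lab.split("|")))
            else:
                raise ValueError(f"unrecognised parameter {pname!r}")
        random_arr = {t: np.stack(mats, axis=-1) for t, mats in random.items()}
        return cls(
            family=meta["family"],
            fixed=fixed,
            random=random_arr,
            variances=variances,
            term_labels=labels,
            group_levels=meta["group_levels"],
            spec_dict=meta["spec"],
            config=cfg,
        )

    def meta_dict(self) -> dict:
        return {
            "family": self.family,
            "spec": self.spec_dict,
            "group_levels": self.group_levels,
            "config": {
                "n_iterations": self.config.n_iterations,
                "burn_in": self.config.burn_in,
                "thin": self.config.thin,
                "n_chains": self.config.n_chains,
                "seed": self.config.seed,
            },
            "term_labels": {t: ["|".join(l) for l in labs] for t, labs in self.term_labels.items()},
        }

    def summary(self) -> dict:
        """Means, SDs, quantiles and ESS of fixed effects and variances."""
        out: dict[str, dict] = {}
        for kind, table in (("beta", self.fixed), ("sigma2", self.variances)):
            for name, arr in table.items():
                flat = arr.reshape(-1)
                out[f"{kind}:{name}"] = {
                    "mean": float(flat.mean()),
                    "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q50": float(np.quantile(flat, 0.5)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                    "ess": _ess(arr),
                }
        return out


@dataclass
class Diagnostics:
    """Per-parameter mixing summaries for fixed effects and variances."""

    ess: dict[str, float]
    lag1_autocorr: dict[str, float]
    rhat: dict[str, float] | None
    flagged: list[str]

    def as_dict(self) -> dict:
        return {
            "ess": self.ess,
            "lag1_autocorr": self.lag1_autocorr,
            "rhat": self.rhat,
            "flagged": self.flagged,
        }


# ---------------------------------------------------------------------------
# sampler internals


def _clamped_exp(eta: np.ndarray) -> np.ndarray:
    if np.any(np.abs(eta) > ETA_CLAMP):
        warnings.warn("linear predictor clamped at +/-50 on the log scale", RuntimeWarning)
        eta = np.clip(eta, -ETA_CLAMP, ETA_CLAMP)
    return np.exp(eta)


def _draw_ig(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


class _ChainState:
    """Mutable state of one chain over one design realisation."""

    def __init__(self, design: DesignRealization, spec: ModelSpec, prior: PriorSpec,
                 rng: np.random.Generator, prior_only: bool):
        self.design = design
        self.spec = spec
        self.prior = prior
        self.rng = rng
        self.prior_only = prior_only
        self.y = design.response
        self.X = design.fixed_columns
        self.terms = [t.name for t in spec.all_terms]
        self.gaussian = spec.family == GAUSSIAN

        self.beta = np.zeros(len(design.fixed_names))
        self.u = {t: np.zeros(design.n_levels(t)) for t in self.terms}
        self.s2 = {t: self.prior.term_V.get(t, prior.V) for t in self.terms}
        self.s2_e = prior.term_V.get(RESIDUAL_KEY, prior.V) if self.gaussian else None

        # per-fixed-column row subsets and response sums (columns are 0/1)
        self.fixed_rows = [np.nonzero(self.X[:, j] != 0)[0] for j in range(self.X.shape[1])]
        self.fixed_ysum = [float(self.y[r].sum()) for r in self.fixed_rows]

        if not prior_only:
            self._moment_init()
        self.eta = self.X @ self.beta
        for t in self.terms:
            self.eta += self.u[t][design.term_index[t]]
        self.lam = None if self.gaussian else _clamped_exp(self.eta)

        # adaptive proposal scales: per level for random terms, scalar per beta
        self.step_u = {t: np.full(design.n_levels(t), 0.5) for t in self.terms}
        self.step_b = [0.1] * len(self.beta)
        self.acc_u = {t: [np.zeros(design.n_levels(t)), 0] for t in self.terms}
        self.acc_b = [[0, 0] for _ in self.beta]

        # nested-term pairings: parent factors strictly contained in child's.
        # Shifting a parent level against its child levels leaves the linear
        # predictor unchanged; these moves kill the mean-trade slow modes.
        factors = {t.name: t.factors for t in spec.all_terms}
        self.hier_pairs: list[tuple[str, str, np.ndarray, np.ndarray]] = []
        for t1 in self.terms:
            for t2 in self.terms:
                if t1 == t2 or not set(factors[t1]) < set(factors[t2]):
                    continue
                pos = [factors[t2].index(f) for f in factors[t1]]
                lookup = {lab: i for i, lab in enumerate(design.term_labels[t1])}
                parent_of = np.array(
                    [lookup[tuple(lab[p] for p in pos)] for lab in design.term_labels[t2]],
                    dtype=np.int64,
                )
                k = np.bincount(parent_of, minlength=design.n_levels(t1)).astype(float)
                self.hier_pairs.append((t1, t2, parent_of, k))

        # translation pairings: (fixed index, term, level mask or None=all)
        self.translations: list[tuple[int, str, np.ndarray | None]] = []
        for t in self.terms:
            self.translations.append((0, t, None))
        if spec.fixed_group is not None:
            gcol = spec.fixed_group
            for j, name in enumerate(design.fixed_names):
                if not name.startswith(f"{gcol}["):
                    continue
                lev = name[len(gcol) + 1:-1]
                for term_obj in spec.all_terms:
                    if gcol not in term_obj.factors:
                        continue
                    pos = term_obj.factors.index(gcol)
                    labs = design.term_labels[term_obj.name]
                    mask = np.array([lab[pos] == lev for lab in labs])
                    if mask.any():
                        self.translations.append((j, term_obj.name, mask))

    def _moment_init(self) -> None:
        """Start the chain at a crude link-scale decomposition of the data.

        Sequentially assigns per-level means of the working response to
        each term (the row-level term absorbs the remainder), which places
        the chain in the posterior's basin instead of at zero — the random
        walk would otherwise need thousands of iterations to travel there.
        Deterministic: uses no randomness.
        """
        r = self.y.astype(float) if self.gaussian else np.log(self.y + 0.5)
        self.beta[0] = float(r.mean())
        r = r - self.beta[0]
        for j in range(1, len(self.beta)):
            rows = self.fixed_rows[j]
            self.beta[j] = float(r[rows].mean())
            r[rows] -= self.beta[j]
        for t in self.terms:
            idx = self.design.term_index[t]
            nl = self.design.n_levels(t)
            n_l = np.bincount(idx, minlength=nl)
            m = np.bincount(idx, weights=r, minlength=nl) / np.maximum(n_l, 1)
            self.u[t] = m
            r = r - m[idx]
            self.s2[t] = max(float((m * m).mean()), 0.05)

    # -- Poisson updates ---------------------------------------------------

    def update_fixed_mh(self) -> None:
        for j in range(len(self.beta)):
            rows = self.fixed_rows[j]
            prop = self.beta[j] + self.rng.normal(0.0, self.step_b[j])
            d = prop - self.beta[j]
            d_ll = 0.0
            if not self.prior_only:
                new_eta = self.eta[rows] + d
                d_ll = d * self.fixed_ysum[j] - float(
                    _clamped_exp(new_eta).sum() - self.lam[rows].sum()
                )
            d_lp = (self.beta[j] ** 2 - prop ** 2) / (2 * self.prior.fixed_variance)
            self.acc_b[j][1] += 1
            if np.log(self.rng.uniform()) < d_ll + d_lp:
                self.beta[j] = prop
                self.eta[rows] += d
                if not self.prior_only:
                    self.lam = _clamped_exp(self.eta)
                self.acc_b[j][0] += 1

    def update_terms_mh(self) -> None:
        for t in self.terms:
            idx = self.design.term_index[t]
            u = self.u[t]
            nl = u.size
            if self.prior_only:
                # exact prior draw keeps the no-data chain a valid Gibbs pass
                new_u = self.rng.normal(0.0, np.sqrt(self.s2[t]), nl)
                self.eta += (new_u - u)[idx]
                self.u[t] = new_u
                continue
            prop = u + self.rng.normal(size=nl) * self.step_u[t]
            d_eta = (prop - u)[idx]
            new_lam = _clamped_exp(self.eta + d_eta)
            d_ll_row = self.y * d_eta - (new_lam - self.lam)
            d_ll = np.bincount(idx, weights=d_ll_row, minlength=nl)
            d_lp = (u ** 2 - prop ** 2) / (2 * self.s2[t])
            acc = np.log(self.rng.uniform(size=nl)) < d_ll + d_lp
            self.acc_u[t][0] += acc
            self.acc_u[t][1] += 1
            if acc.any():
                du = np.where(acc, prop - u, 0.0)
                self.u[t] = np.where(acc, prop, u)
                self.eta += du[idx]
                self.lam = _clamped_exp(self.eta)

    # -- Gaussian (conjugate) updates -------------------------------------

    def update_fixed_gibbs(self) -> None:
        for j in range(len(self.beta)):
            rows = self.fixed_rows[j]
            if self.prior_only:
                prop = self.rng.normal(0.0, np.sqrt(self.prior.fixed_variance))
            else:
                r = self.y[rows] - self.eta[rows] + self.beta[j]
                prec = len(rows) / self.s2_e + 1.0 / self.prior.fixed_variance
                mean = r.sum() / self.s2_e / prec
                prop = mean + self.rng.normal(0.0, 1.0 / np.sqrt(prec))
            self.eta[rows] += prop - self.beta[j]
            self.beta[j] = prop

    def update_terms_gibbs(self) -> None:
        for t in self.terms:
            idx = self.design.term_index[t]
            u = self.u[t]
            nl = u.size
            if self.prior_only:
                new_u = self.rng.normal(0.0, np.sqrt(self.s2[t]), nl)
            else:
                r = self.y - self.eta + u[idx]
                sum_r = np.bincount(idx, weights=r, minlength=nl)
                n_l = np.bincount(idx, minlength=nl)
                prec = n_l / self.s2_e + 1.0 / self.s2[t]
                mean = sum_r / self.s2_e / prec
                new_u = mean + self.rng.normal(size=nl) / np.sqrt(prec)
            self.eta += (new_u - u)[idx]
            self.u[t] = new_u

    def update_sigma2_e(self) -> None:
        a, b = self.prior.ig_params(RESIDUAL_KEY)
        if self.prior_only:
            self.s2_e = _draw_ig(self.rng, a, b)
            return
        sse = float(((self.y - self.eta) ** 2).sum())
        self.s2_e = _draw_ig(self.rng, a + 0.5 * self.y.size, b + 0.5 * sse)

    # -- shared updates ----------------------------------------------------

    def update_variances(self) -> None:
        for t in self.terms:
            a, b = self.prior.ig_params(t)
            u = self.u[t]
            self.s2[t] = _draw_ig(self.rng, a + 0.5 * u.size, b + 0.5 * float(u @ u))

    def translation_moves(self) -> None:
        """Shift mass between a fixed effect and a random term's levels.

        The linear predictor is unchanged, so the acceptance ratio involves
        only the Gaussian priors; the proposal scale sqrt(s2_t/n) depends
        only on state invariant under the move, keeping it symmetric.
        """
        for j, t, mask in self.translations:
            u = self.u[t]
            sub = u if mask is None else u[mask]
            n = sub.size
            m = self.rng.normal(0.0, np.sqrt(self.s2[t] / n))
            # prior on shifted levels: -sum((u-m)^2 - u^2)/(2 s2) = (2m*sum - n m^2)/(2 s2)
            d_lp = (2.0 * m * float(sub.sum()) - n * m * m) / (2.0 * self.s2[t])
            bj = self.beta[j]
            d_lp += (bj ** 2 - (bj + m) ** 2) / (2 * self.prior.fixed_variance)
            if np.log(self.rng.uniform()) < d_lp:
                if mask is None:
                    self.u[t] = u - m
                else:
                    u = u.copy()
                    u[mask] -= m
                    self.u[t] = u
                self.beta[j] = bj + m

    def hier_translation_moves(self) -> None:
        """Trade each parent level's effect against its child levels.

        For parent term p and child term c with nested factors, propose
        u_p += m, u_c[children] -= m per parent level; eta is unchanged, the
        moves for different parent levels touch disjoint coordinates, so
        they accept independently. Proposal scale sqrt(s2_c / k) depends
        only on quantities the move leaves fixed (symmetric proposal).
        """
        for t1, t2, parent_of, k in self.hier_pairs:
            u_p, u_c = self.u[t1], self.u[t2]
            s2p, s2c = self.s2[t1], self.s2[t2]
            m = self.rng.normal(size=u_p.size) * np.sqrt(s2c / k)
            child_sum = np.bincount(parent_of, weights=u_c, minlength=u_p.size)
            d_lp = (2.0 * m * child_sum - k * m * m) / (2.0 * s2c)
            d_lp += -(2.0 * u_p * m + m * m) / (2.0 * s2p)
            acc = np.log(self.rng.uniform(size=u_p.size)) < d_lp
            if acc.any():
                m_acc = np.where(acc, m, 0.0)
                self.u[t1] = u_p + m_acc
                self.u[t2] = u_c - m_acc[parent_of]

    def rescale_moves(self) -> None:
        """Joint (u_t, sigma2_t) -> (c u_t, c^2 sigma2_t) Metropolis move."""
        for t in self.terms:
            if not self.prior.expands(t):
                continue
            u = self.u[t]
            nl = u.size
            logc = self.rng.normal(0.0, 0.15)
            c = np.exp(logc)
            d_ll = 0.0
            d_eta = None
            if not self.prior_only:
                idx = self.design.term_index[t]
                d_eta = (c - 1.0) * u[idx]
                if self.gaussian:
                    new_res = self.y - (self.eta + d_eta)
                    old_res = self.y - self.eta
                    d_ll = -0.5 * float((new_res @ new_res) - (old_res @ old_res)) / self.s2_e
                else:
                    new_lam = _clamped_exp(self.eta + d_eta)
                    d_ll = float((self.y * d_eta - (new_lam - self.lam)).sum())
            a, b = self.prior.ig_params(t)
            s2, s2p = self.s2[t], c * c * self.s2[t]
            d_prior = (-(a + 1.0) * (np.log(s2p) - np.log(s2))) - b / s2p + b / s2
            # u|s2 density change and Jacobian collapse to +2 log c
            if np.log(self.rng.uniform()) < d_ll + d_prior + 2.0 * logc:
                self.u[t] = c * u
                self.s2[t] = s2p
                if d_eta is not None:
                    self.eta += d_eta
                    if not self.gaussian:
                        self.lam = _clamped_exp(self.eta)

    def adapt(self) -> None:
        for t in self.terms:
            acc, tot = self.acc_u[t]
            if tot >= 50:
                rate = acc / tot
                self.step_u[t] = np.clip(
                    self.step_u[t] * np.exp(np.clip(rate - 0.44, -0.5, 0.5)),
                    1e-4, 20.0,
                )
                self.acc_u[t] = [np.zeros_like(acc), 0]
        for j in range(len(self.beta)):
            acc, tot = self.acc_b[j]
            if tot >= 50:
                rate = acc / tot
                self.step_b[j] *= float(np.exp(np.clip(rate - 0.44, -0.5, 0.5)))
                self.step_b[j] = float(np.clip(self.step_b[j], 1e-5, 10.0))
                self.acc_b[j] = [0, 0]

    def iterate(self, adapting: bool) -> None:
        if self.gaussian:
            self.update_fixed_gibbs()
            self.update_terms_gibbs()
            self.update_variances()
            self.update_sigma2_e()
        else:
            self.update_fixed_mh()
            self.update_terms_mh()
            self.update_variances()
        self.translation_moves()
        self.hier_translation_moves()
        self.rescale_moves()
        if adapting:
            self.adapt()
        if not self.gaussian and not self.prior_only:
            if not np.isfinite(self.lam).all() or not np.isfinite(self.eta).all():
                raise RuntimeError("divergent chain: non-finite linear predictor")


def fit_glmm(
    obs: LongObservations,
    spec: ModelSpec,
    prior: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Draw from the posterior of the specified GLMM.

    Fully deterministic given (data, spec, prior, cfg): chains are seeded by
    spawning the config seed. ``prior_only`` switches the likelihood off so
    variance draws reproduce the prior — used for prior-recovery checks.
    """
    prior = prior or PriorSpec()
    cfg = cfg or MCMCConfig()
    if spec.family == POISSON and not prior_only:
        y = obs.data[obs.response].to_numpy()
        if (y < 0).any() or not np.allclose(y, np.floor(y)):
            raise ValueError("Poisson family requires non-negative integer counts")
    design = build_design(obs, spec)
    term_names = [t.name for t in spec.all_terms]

    n_draws = cfg.n_draws
    if n_draws < 1:
        raise ValueError("config yields no retained draws")

    fixed_draws = {n: np.empty((cfg.n_chains, n_draws)) for n in design.fixed_names}
    var_names = list(term_names)
    if spec.family == GAUSSIAN:
        var_names.append(RESIDUAL_KEY)
    var_draws = {t: np.empty((cfg.n_chains, n_draws)) for t in var_names}
    u_draws = {
        t: np.empty((cfg.n_chains, n_draws, design.n_levels(t))) for t in term_names
    }

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(children[c])
        state = _ChainState(design, spec, prior, rng, prior_only)
        k = 0
        for it in range(cfg.n_iterations):
            state.iterate(adapting=it < cfg.burn_in)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < n_draws:
                for j, name in enumerate(design.fixed_names):
                    fixed_draws[name][c, k] = state.beta[j]
                for t in term_names:
                    var_draws[t][c, k] = state.s2[t]
                    u_draws[t][c, k] = state.u[t]
                if spec.family == GAUSSIAN:
                    var_draws[RESIDUAL_KEY][c, k] = state.s2_e
                k += 1

    return PosteriorSamples(
        family=spec.family,
        fixed=fixed_draws,
        random=u_draws,
        variances=var_draws,
        term_labels={t: design.term_labels[t] for t in term_names},
        group_levels=design.group_levels,
        spec_dict=spec_to_dict(spec),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# diagnostics


def _ess(arr2d: np.ndarray) -> float:
    """Bulk effective sample size of (chains, draws) draws."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            val = float(az.ess(np.atleast_2d(np.asarray(arr2d))))
        except Exception:
            return float("nan")
    return val


def diagnostics(ps: PosteriorSamples, ess_floor: float = 100.0) -> Diagnostics:
    """Effective sample sizes, lag-1 autocorrelation and (multi-chain)
    potential scale reduction for every fixed effect and variance component.

    Parameters with ESS below ``ess_floor`` — or with undefined
    autocorrelation, e.g. constant draws — are flagged.
    """
    import arviz as az

    n_retained = ps.n_draws_total
    if n_retained < 50:
        raise ValueError(f"need >= 50 retained draws for diagnostics, have {n_retained}")
    params: dict[str, np.ndarray] = {}
    for name, arr in ps.fixed.items():
        params[f"beta:{name}"] = arr
    for term, arr in ps.variances.items():
        params[f"sigma2:{term}"] = arr

    ess: dict[str, float] = {}
    lag1: dict[str, float] = {}
    rhat: dict[str, float] | None = {} if ps.config.n_chains >= 2 else None
    flagged: list[str] = []
    for name, arr in params.items():
        e = _ess(arr)
        flat = arr.reshape(-1)
        if np.ptp(flat) == 0.0:
            ac = float("nan")
        else:
            a, b = flat[:-1], flat[1:]
            denom = a.std() * b.std()
            ac = float(np.mean((a - a.mean()) * (b - b.mean())) / denom) if denom > 0 else float("nan")
        ess[name] = e
        lag1[name] = ac
        if rhat is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    rhat[name] = float(az.rhat(np.asarray(arr)))
                except Exception:
                    rhat[name] = float("nan")
        if not np.isfinite(e) or e < ess_floor or not np.isfinite(ac):
            flagged.append(name)
    return Diagnostics(ess=ess, lag1_autocorr=lag1, rhat=rhat, flagged=flagged)


# ---------------------------------------------------------------------------
# posterior-predictive zero adequacy


def predicted_zero_ratio(
    ps: PosteriorSamples, obs: LongObservations, max_draws: int = 400
) -> float:
    """Observed zeros over posterior-predicted zeros (Poisson family).

    For each retained draw the linear predictor gives per-row rates
    lambda_i; the predicted number of zeros is sum_i exp(-lambda_i), and the
    diagnostic averages that over draws. A well-specified over-dispersed
    Poisson fit yields a ratio close to 1; ratios far above 1 indicate zero
    inflation the model cannot absorb.
    """
    if ps.family != POISSON:
        raise ValueError("zero-ratio diagnostic applies to the Poisson family")
    spec = spec_from_dict(ps.spec_dict)
    design = build_design(obs, spec)
    y = design.response
    observed = int((y == 0).sum())

    n_total = ps.n_draws_total
    take = np.linspace(0, n_total - 1, min(max_draws, n_total)).astype(int)
    X = design.fixed_columns
    beta_flat = np.column_stack([ps.flat_fixed(n) for n in design.fixed_names])
    term_names = list(ps.random.keys())
    flats = {t: ps.flat_random(t) for t in term_names}

    expected = 0.0
    for d in take:
        eta = X @ beta_flat[d]
        for t in term_names:
            eta = eta + flats[t][d][design.term_index[t]]
        lam = np.exp(np.clip(eta, -ETA_CLAMP, ETA_CLAMP))
        expected += float(np.exp(-lam).sum())
    expected /= len(take)

    if expected <= 0.0:
        warnings.warn("model predicts no zeros; ratio is infinite", RuntimeWarning)
        return float("inf")
    if observed == 0:
        warnings.warn("data contain no zeros; zero-ratio is 0", RuntimeWarning)
    return observed / expected
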