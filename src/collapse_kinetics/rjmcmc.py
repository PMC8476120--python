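"""Reversible-jump MCMC for univariate normal mixtures with unknown k.

A full Bayesian route from pixel/peak intensities to myosin counts that is
independent of the histogram-calibration route, used to cross-check it for
bias.  The hierarchical model follows the classic reversible-jump
construction for normal mixtures:

* k ~ uniform on {1..k_max}
* weights w | k ~ Dirichlet(delta, ..., delta)
* means mu_j ~ Normal(xi, kappa^-1), constrained increasing
* precisions 1/sigma_j^2 ~ Gamma(alpha, beta), with the hyperprior
  beta ~ Gamma(g, h) making the variance prior weakly informative
* allocations z_i | w ~ Categorical(w)

Defaults: alpha = 2, g = 0.2, h = 10/R^2, xi = mid-range, kappa = 1/R^2 and
delta = 1, where R is the range of the observations.  Each sweep performs
the Gibbs updates (weights, means with an ordering rejection, variances,
allocations, beta) followed by a split/combine move and a birth/death move
for empty components, with the standard dimension-matching acceptance
ratios.  Because fluorescence intensity is linear in the number of bound
heads, the strict mean ordering acts as the identifiability constraint and
a post-hoc linearity check reports how equally spaced the recovered class
means are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import betaln, gammaln, logsumexp

__all__ = [
    "MixtureHyperParams",
    "MixtureState",
    "ComponentSummary",
    "run_chain",
    "run_chains",
    "summarize",
    "linearity_check",
    "cutoffs_from_means",
    "assign_counts_by_cutoff",
    "NINE_COMPONENT_REFERENCE",
    "SEVEN_COMPONENT_REFERENCE",
]

# Published reference posterior summaries for the intensity mixture of one
# kymograph (mean / dispersion / weight per occupancy class, class 0 being
# background).  Used as inputs when defining count thresholds without
# re-running the sampler.
SEVEN_COMPONENT_REFERENCE = {
    "means": (57.17, 150.75, 198.26, 254.73, 314.23, 401.37, 551.86),
    "sds": (34.73, 42.07, 50.68, 60.71, 69.58, 85.73, 111.40),
    "weights": (0.12, 0.21, 0.20, 0.15, 0.14, 0.11, 0.07),
}
NINE_COMPONENT_REFERENCE = {
    "means": (24.52, 138.57, 173.87, 210.90, 264.22, 322.20, 382.67, 490.73, 652.38),
    "sds": (35.58, 41.54, 46.04, 51.35, 55.51, 62.04, 80.58, 72.01, 91.13),
    "weights": (0.10, 0.15, 0.16, 0.16, 0.14, 0.11, 0.08, 0.05, 0.04),
}


@dataclass(frozen=True)
class MixtureHyperParams:
    """Hyperparameters; None fields are resolved from the data range R."""

    alpha: float = 2.0
    g: float = 0.2
    h: float | None = None      # default 10 / R^2
    xi: float | None = None     # default mid-range
    kappa: float | None = None  # default 1 / R^2
    delta: float = 1.0
    k_max: int = 9

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.g <= 0 or self.delta <= 0:
            raise ValueError("alpha, g and delta must be > 0")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    def resolve(self, data: np.ndarray) -> "MixtureHyperParams":
        lo, hi = float(np.min(data)), float(np.max(data))
        r = hi - lo
        if r <= 0:
            raise ValueError("data have zero range")
        return replace(
            self,
            h=self.h if self.h is not None else 10.0 / r**2,
            xi=self.xi if self.xi is not None else 0.5 * (lo + hi),
            kappa=self.kappa if self.kappa is not None else 1.0 / r**2,
        )


@dataclass(frozen=True)
class MixtureState:
    """One retained sweep: component count, ordered parameters, hyper beta."""

    k: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    beta: float
    allocations: np.ndarray | None = None


def _log_norm_pdf(y, mu, var):
    return -0.5 * np.log(2.0 * np.pi * var) - (y - mu) ** 2 / (2.0 * var)


class _Sampler:
    def __init__(self, data: np.ndarray, hyper: MixtureHyperParams,
                 rng: np.random.Generator):
        self.y = np.asarray(data, dtype=np.float64).ravel()
        self.n = self.y.size
        self.hp = hyper.resolve(self.y)
        self.rng = rng
        # initial state: a single component
        self.k = 1
        self.mu = np.array([float(self.y.mean())])
        self.var = np.array([float(self.y.var()) or 1.0])
        self.w = np.array([1.0])
        self.z = np.zeros(self.n, dtype=np.int64)
        self.beta = self.hp.g / self.hp.h

    # ------------------------------------------------------------------ Gibbs
    def _counts(self):
        return np.bincount(self.z, minlength=self.k)

    def update_weights(self):
        nj = self._counts()
        self.w = self.rng.dirichlet(self.hp.delta + nj)

    def update_means(self):
        hp = self.hp
        nj = self._counts()
        sums = np.bincount(self.z, weights=self.y, minlength=self.k)
        for j in range(self.k):
            tau = 1.0 / self.var[j]
            prec = hp.kappa + tau * nj[j]
            mean = (tau * sums[j] + hp.kappa * hp.xi) / prec
            prop = self.rng.normal(mean, 1.0 / math.sqrt(prec))
            lo = self.mu[j - 1] if j > 0 else -np.inf
            hi = self.mu[j + 1] if j + 1 < self.k else np.inf
            if lo < prop < hi:  # reject moves that break the ordering
                self.mu[j] = prop

    def update_variances(self):
        hp = self.hp
        nj = self._counts()
        for j in range(self.k):
            resid = self.y[self.z == j] - self.mu[j]
            shape = hp.alpha + 0.5 * nj[j]
            rate = self.beta + 0.5 * float(resid @ resid)
            self.var[j] = 1.0 / self.rng.gamma(shape, 1.0 / rate)

    def update_allocations(self):
        logp = (np.log(self.w)[None, :]
                + _log_norm_pdf(self.y[:, None], self.mu[None, :],
                                self.var[None, :]))
        logp -= logsumexp(logp, axis=1, keepdims=True)
        p = np.exp(logp)
        u = self.rng.random(self.n)
        self.z = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        np.clip(self.z, 0, self.k - 1, out=self.z)

    def update_beta(self):
        hp = self.hp
        shape = hp.g + self.k * hp.alpha
        rate = hp.h + np.sum(1.0 / self.var)
        self.beta = self.rng.gamma(shape, 1.0 / rate)

    # ------------------------------------------------------- dimension moves
    def _b(self, k):  # probability of proposing a dimension-increasing move
        return 0.0 if k >= self.hp.k_max else 0.5

    def _d(self, k):  # probability of proposing a dimension-decreasing move
        return 0.0 if k <= 1 else 0.5

    def split_combine(self):
        if self.rng.random() < 0.5:
            if self._b(self.k) > 0:
                self._try_split()
        else:
            if self._d(self.k) > 0:
                self._try_combine()

    def _split_log_terms(self, k, wj, muj, varj, w1, w2, mu1, mu2, var1, var2,
                         l1, l2, u1, u2, u3):
        """log acceptance ratio of a split, excluding likelihood and P_alloc."""
        hp = self.hp
        la = 0.0
        la += math.log(k + 1)  # ordered-means prior: (k+1)!/k!
        la += ((hp.delta - 1 + l1) * math.log(w1)
               + (hp.delta - 1 + l2) * math.log(w2)
               - (hp.delta - 1 + l1 + l2) * math.log(wj)
               - betaln(hp.delta, k * hp.delta))
        la += (0.5 * math.log(hp.kappa / (2.0 * math.pi))
               - 0.5 * hp.kappa * ((mu1 - hp.xi) ** 2 + (mu2 - hp.xi) ** 2
                                   - (muj - hp.xi) ** 2))
        la += (hp.alpha * math.log(self.beta) - gammaln(hp.alpha)
               - (hp.alpha + 1) * math.log(var1 * var2 / varj)
               - self.beta * (1.0 / var1 + 1.0 / var2 - 1.0 / varj))
        la += math.log(self._d(k + 1)) - math.log(self._b(k))
        # proposal densities of u1, u2 ~ Beta(2,2) and u3 ~ U(0,1)
        la -= math.log(6.0 * u1 * (1 - u1)) + math.log(6.0 * u2 * (1 - u2))
        # Jacobian
        la += math.log(wj * abs(mu1 - mu2) * var1 * var2
                       / (u2 * (1 - u2**2) * u3 * (1 - u3) * varj))
        return la

    def _try_split(self):
        rng = self.rng
        k = self.k
        j = int(rng.integers(k))
        wj, muj, varj = self.w[j], self.mu[j], self.var[j]
        u1 = rng.beta(2, 2)
        u2 = rng.beta(2, 2)
        u3 = rng.random()
        if min(u1, 1 - u1, u2, 1 - u2, u3, 1 - u3) <= 0:
            return
        w1, w2 = wj * u1, wj * (1 - u1)
        sd = math.sqrt(varj)
        mu1 = muj - u2 * sd * math.sqrt(w2 / w1)
        mu2 = muj + u2 * sd * math.sqrt(w1 / w2)
        var1 = u3 * (1 - u2**2) * varj * wj / w1
        var2 = (1 - u3) * (1 - u2**2) * varj * wj / w2
        lo = self.mu[j - 1] if j > 0 else -np.inf
        hi = self.mu[j + 1] if j + 1 < k else np.inf
        if not (lo < mu1 and mu2 < hi):
            return  # adjacency condition fails
        members = np.flatnonzero(self.z == j)
        lf1 = math.log(w1) + _log_norm_pdf(self.y[members], mu1, var1)
        lf2 = math.log(w2) + _log_norm_pdf(self.y[members], mu2, var2)
        denom = np.logaddexp(lf1, lf2)
        p1 = np.exp(lf1 - denom)
        pick1 = rng.random(members.size) < p1
        log_palloc = float(np.sum(np.where(pick1, lf1, lf2) - denom))
        l1 = int(pick1.sum())
        l2 = members.size - l1
        loglik_new = (float(np.sum(_log_norm_pdf(self.y[members[pick1]], mu1, var1)))
                      + float(np.sum(_log_norm_pdf(self.y[members[~pick1]], mu2, var2))))
        loglik_old = float(np.sum(_log_norm_pdf(self.y[members], muj, varj)))
        la = loglik_new - loglik_old
        la += self._split_log_terms(k, wj, muj, varj, w1, w2, mu1, mu2,
                                    var1, var2, l1, l2, u1, u2, u3)
        la -= log_palloc
        if math.log(rng.random() + 1e-300) < la:
            self.mu = np.insert(np.delete(self.mu, j), j, [mu1, mu2])
            self.var = np.insert(np.delete(self.var, j), j, [var1, var2])
            self.w = np.insert(np.delete(self.w, j), j, [w1, w2])
            z = self.z.copy()
            z[z > j] += 1
            z[members[~pick1]] = j + 1
            z[members[pick1]] = j
            self.z = z
            self.k = k + 1

    def _try_combine(self):
        rng = self.rng
        k = self.k  # current count, combine goes to k-1
        j1 = int(rng.integers(k - 1))  # adjacent pair (j1, j1+1)
        j2 = j1 + 1
        w1, w2 = self.w[j1], self.w[j2]
        mu1, mu2 = self.mu[j1], self.mu[j2]
        var1, var2 = self.var[j1], self.var[j2]
        wj = w1 + w2
        muj = (w1 * mu1 + w2 * mu2) / wj
        varj = (w1 * (mu1**2 + var1) + w2 * (mu2**2 + var2)) / wj - muj**2
        if varj <= 0 or wj <= 0:
            return
        u1 = w1 / wj
        u2 = (muj - mu1) / (math.sqrt(varj) * math.sqrt(w2 / w1))
        u3 = var1 * w1 / ((1 - u2**2) * varj * wj) if (1 - u2**2) > 0 else -1.0
        if not (0 < u1 < 1 and 0 < u2 < 1 and 0 < u3 < 1):
            return  # outside the image of the split proposal
        members = np.flatnonzero((self.z == j1) | (self.z == j2))
        lf1 = math.log(w1) + _log_norm_pdf(self.y[members], mu1, var1)
        lf2 = math.log(w2) + _log_norm_pdf(self.y[members], mu2, var2)
        denom = np.logaddexp(lf1, lf2)
        in1 = self.z[members] == j1
        log_palloc = float(np.sum(np.where(in1, lf1, lf2) - denom))
        l1 = int(in1.sum())
        l2 = members.size - l1
        loglik_split = (float(np.sum(_log_norm_pdf(self.y[members[in1]], mu1, var1)))
                        + float(np.sum(_log_norm_pdf(self.y[members[~in1]], mu2, var2))))
        loglik_merged = float(np.sum(_log_norm_pdf(self.y[members], muj, varj)))
        la = loglik_split - loglik_merged
        la += self._split_log_terms(k - 1, wj, muj, varj, w1, w2, mu1, mu2,
                                    var1, var2, l1, l2, u1, u2, u3)
        la -= log_palloc
        # combine acceptance is the reciprocal of the corresponding split
        if math.log(rng.random() + 1e-300) < -la:
            self.mu = np.insert(np.delete(self.mu, [j1, j2]), j1, muj)
            self.var = np.insert(np.delete(self.var, [j1, j2]), j1, varj)
            self.w = np.insert(np.delete(self.w, [j1, j2]), j1, wj)
            z = self.z.copy()
            z[z == j2] = j1
            z[z > j2] -= 1
            self.z = z
            self.k = k - 1

    def birth_death(self):
        if self.rng.random() < 0.5:
            if self._b(self.k) > 0:
                self._try_birth()
        else:
            if self._d(self.k) > 0:
                self._try_death()

    def _birth_log_ratio(self, k, wstar, k_empty_after):
        hp = self.hp
        la = ((hp.delta - 1) * math.log(wstar)
              + (self.n + k * (hp.delta - 1)) * math.log1p(-wstar)
              - betaln(k * hp.delta, hp.delta)
              + math.log((k + 1) / k)
              + math.log(self._d(k + 1)) - math.log(self._b(k))
              - math.log(k_empty_after))
        return la

    def _try_birth(self):
        rng = self.rng
        k = self.k
        hp = self.hp
        wstar = rng.beta(1, k)
        if not (0 < wstar < 1):
            return
        mustar = rng.normal(hp.xi, 1.0 / math.sqrt(hp.kappa))
        varstar = 1.0 / rng.gamma(hp.alpha, 1.0 / self.beta)
        nj = self._counts()
        k_empty_after = int((nj == 0).sum()) + 1
        la = self._birth_log_ratio(k, wstar, k_empty_after)
        if math.log(rng.random() + 1e-300) < la:
            pos = int(np.searchsorted(self.mu, mustar))
            self.mu = np.insert(self.mu, pos, mustar)
            self.var = np.insert(self.var, pos, varstar)
            self.w = np.insert(self.w * (1 - wstar), pos, wstar)
            z = self.z.copy()
            z[z >= pos] += 1
            self.z = z
            self.k = k + 1

    def _try_death(self):
        rng = self.rng
        k = self.k
        nj = self._counts()
        empty = np.flatnonzero(nj == 0)
        if empty.size == 0:
            return
        j = int(rng.choice(empty))
        wstar = self.w[j]
        if not (0 < wstar < 1):
            return
        la = -self._birth_log_ratio(k - 1, wstar, int(empty.size))
        if math.log(rng.random() + 1e-300) < la:
            self.mu = np.delete(self.mu, j)
            self.var = np.delete(self.var, j)
            self.w = np.delete(self.w, j) / (1 - wstar)
            z = self.z.copy()
            z[z > j] -= 1
            self.z = z
            self.k = k - 1

    # ------------------------------------------------------------------ sweep
    def sweep(self, fix_k: bool = False):
        self.update_weights()
        self.update_means()
        self.update_variances()
        self.update_allocations()
        self.update_beta()
        if not fix_k:
            self.split_combine()
            self.birth_death()

    def state(self, store_allocations: bool = False) -> MixtureState:
        return MixtureState(
            k=self.k, means=self.mu.copy(), variances=self.var.copy(),
            weights=self.w.copy(), beta=float(self.beta),
            allocations=self.z.copy() if store_allocations else None,
        )


def run_chain(
    data: np.ndarray,
    hyper: MixtureHyperParams | None = None,
    n_sweeps: int = 5000,
    seed: int = 0,
    fix_k: bool = False,
    store_allocations: bool = False,
) -> list[MixtureState]:
    """Run one reversible-jump chain and return the retained sweeps.

    With ``fix_k=True`` the dimension-changing moves are disabled and the
    sampler reduces to an ordinary Gibbs sampler at the initial k (one
    component), useful for validating the conditional updates.
    """
    y = np.asarray(data, dtype=np.float64).ravel()
    if y.size < 50:
        raise ValueError(f"need >= 50 data points, got {y.size}")
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    hyper = hyper or MixtureHyperParams()
    rng = np.random.default_rng(seed)
    sampler = _Sampler(y, hyper, rng)
    chain = []
    for _ in range(n_sweeps):
        sampler.sweep(fix_k=fix_k)
        chain.append(sampler.state(store_allocations))
    return chain


def run_chains(
    data: np.ndarray,
    hyper: MixtureHyperParams | None = None,
    n_sweeps: int = 5000,
    n_chains: int = 4,
    seed: int = 0,
) -> list[list[MixtureState]]:
    """Run several independent chains with seeds derived from ``seed``."""
    state = np.random.SeedSequence(seed).generate_state(n_chains)
    return [run_chain(data, hyper, n_sweeps, seed=int(s) & 0x7FFFFFFF)
            for s in state]


@dataclass(frozen=True)
class ComponentSummary:
    """Posterior component summaries conditional on a component count."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    occupancy_fraction: float
    n_chains: int
    convergence_ratio: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "component": np.arange(self.k),
            "mean": self.means,
            "sd": self.sds,
            "variance": self.variances,
            "weight": self.weights,
        })


def modal_k(chains: list[list[MixtureState]], burn_in_frac: float = 0.5) -> int:
    """Posterior modal component count across chains (after burn-in)."""
    ks = []
    for chain in chains:
        start = int(len(chain) * burn_in_frac)
        ks.extend(s.k for s in chain[start:])
    return int(np.bincount(ks).argmax())


def summarize(
    chains: list[list[MixtureState]],
    k_condition: int,
    burn_in_frac: float = 0.5,
) -> ComponentSummary:
    """Average component parameters over sweeps with ``k == k_condition``.

    The first half of each chain is discarded as burn-in by default.  The
    convergence ratio is a between/within-chain variance ratio (a PSRF-style
    diagnostic) maximised over component means; 1.0 indicates perfect
    agreement between chains.
    """
    if not chains:
        raise ValueError("need at least one chain")
    per_chain_means = []
    per_chain_sds = []
    per_chain_w = []
    per_chain_var_of_mean = []
    occ = []
    for chain in chains:
        start = int(len(chain) * burn_in_frac)
        kept = [s for s in chain[start:] if s.k == k_condition]
        occ.append(len(kept) / max(len(chain) - start, 1))
        if not kept:
            continue
        mus = np.stack([s.means for s in kept])
        sds = np.sqrt(np.stack([s.variances for s in kept]))
        ws = np.stack([s.weights for s in kept])
        per_chain_means.append(mus.mean(axis=0))
        per_chain_sds.append(sds.mean(axis=0))
        per_chain_w.append(ws.mean(axis=0))
        per_chain_var_of_mean.append(mus.var(axis=0, ddof=1) if len(kept) > 1
                                     else np.zeros(k_condition))
    if not per_chain_means:
        raise ValueError(f"no post-burn-in sweeps with k = {k_condition}")
    means = np.mean(per_chain_means, axis=0)
    sds = np.mean(per_chain_sds, axis=0)
    weights = np.mean(per_chain_w, axis=0)
    total = weights.sum()
    if total > 0:
        weights = weights / total
    if len(per_chain_means) >= 2:
        between = np.var(np.stack(per_chain_means), axis=0, ddof=1)
        within = np.mean(np.stack(per_chain_var_of_mean), axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.sqrt(1.0 + between / np.where(within > 0, within, np.nan))
        conv = float(np.nanmax(ratio)) if np.isfinite(ratio).any() else 1.0
    else:
        conv = float("nan")
    return ComponentSummary(
        k=k_condition, means=means, sds=sds, variances=sds**2,
        weights=weights, occupancy_fraction=float(np.mean(occ)),
        n_chains=len(per_chain_means), convergence_ratio=conv,
    )


def linearity_check(summary: ComponentSummary | np.ndarray) -> tuple[float, float]:
    """OLS of conditional posterior means against component index.

    The background component (index 0) is excluded; with class means
    ``m_1..m_{K-1}`` the regression is against 1..K-1.  Intensity linear in
    the number of binders predicts r^2 close to 1.
    """
    means = summary.means if isinstance(summary, ComponentSummary) \
        else np.asarray(summary, dtype=np.float64)
    if means.size < 3:
        raise ValueError("need >= 3 components for a linearity check")
    y = means[1:]
    x = np.arange(1, y.size + 1, dtype=np.float64)
    from scipy.stats import linregress

    fit = linregress(x, y)
    return float(fit.slope), float(fit.rvalue ** 2)


def cutoffs_from_means(means: np.ndarray) -> np.ndarray:
    """Mid-point intensity boundaries between successive class means."""
    m = np.asarray(means, dtype=np.float64)
    if m.size < 2:
        raise ValueError("need >= 2 means")
    if not np.all(np.diff(m) > 0):
        raise ValueError("means must be strictly increasing")
    return 0.5 * (m[:-1] + m[1:])


def assign_counts_by_cutoff(intensities: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Count = number of boundaries below the intensity (class 0 = background).

    An intensity exactly on a boundary is assigned to the upper class.
    """
    b = np.asarray(boundaries, dtype=np.float64)
    if np.any(np.diff(b) < 0):
        raise ValueError("boundaries must be sorted")
    x = np.atleast_1d(np.asarray(intensities, dtype=np.float64))
    out = np.searchsorted(b, x, side="right")
    return out if np.ndim(intensities) else int(out[0])
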