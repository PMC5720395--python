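"""Distribution of dN/dS across genes: binomial mixture EM, selection budgets,
and power to detect negative selection.

Conditioning on the total number of mutations observed in a gene, the split
between synonymous and non-synonymous counts is binomial with success
probability rho_m,j(omega) — the expected non-synonymous fraction given the
gene's composition, the cohort substitution rates and a selection strength
omega.  This conditioning removes any dependence on the gene's absolute
mutation rate, so the mixture over a discrete omega grid can be fitted by EM
without a background rate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_GRID = np.array(
    [round(0.1 * k, 1) for k in range(21)] + [3.0, 4.0, 5.0, 10.0, 15.0, 20.0])

# Pancancer-scale defaults for power calculations: neutral fractions of
# synonymous / missense / truncating substitutions and the NB overdispersion.
PANCANCER_RHO = (0.287, 0.649, 0.064)
PANCANCER_THETA = 6.03


class MixtureError(ValueError):
    pass


def rho(L_j: np.ndarray, rates: np.ndarray, omega: float, impact_col: int = 1):
    """Expected (synonymous, non-synonymous) substitution fractions in a gene.

    rho_s = sum_i r_i L[i,s] / sum_i r_i (L[i,s] + L[i,x] * omega) and the
    complementary rho_x, where x is the impact column (1 missense, 2 nonsense,
    3 splice); the relative rates may be u_i or r_i (scale cancels).
    """
    if omega < 0:
        raise MixtureError("omega must be >= 0")
    L_j = np.asarray(L_j, dtype=float)
    s_part = float(rates @ L_j[:, 0])
    x_part = float(rates @ L_j[:, impact_col])
    denom = s_part + x_part * omega
    if denom <= 0:
        raise MixtureError("all-zero composition for the requested impact")
    return s_part / denom, x_part * omega / denom


def gene_mixture_loglik(n_s: int, n_x: int, grid: np.ndarray, L_j: np.ndarray,
                        rates: np.ndarray, impact_col: int = 1) -> np.ndarray:
    """Binomial log-likelihood of a gene's (n_s, n_x) split at each grid omega."""
    total = n_s + n_x
    if total == 0:
        return np.zeros(len(grid))
    p_x = np.array([rho(L_j, rates, float(om), impact_col)[1] for om in grid])
    return stats.binom.logpmf(n_x, total, p_x)


@dataclass
class MixtureFit:
    grid: np.ndarray
    p: np.ndarray
    loglik_trace: list
    posteriors: np.ndarray          # J x K responsibilities
    summaries: dict = field(default_factory=dict)
    summary_ci: dict = field(default_factory=dict)

    def mass(self, lo: float = -np.inf, hi: float = np.inf) -> float:
        sel = (self.grid >= lo) & (self.grid <= hi)
        return float(self.p[sel].sum())


def _em(loglik: np.ndarray, tol: float, max_iter: int, p_init=None):
    J, K = loglik.shape
    p = np.full(K, 1.0 / K) if p_init is None else np.asarray(p_init, float).copy()
    # row-normalized likelihoods keep the iteration in linear space safely
    row_max = loglik.max(axis=1)
    lik = np.exp(loglik - row_max[:, None])
    const = float(row_max.sum())
    trace = []
    last = -np.inf
    resp = None
    for _ in range(max_iter):
        w = lik * p[None, :]
        denom = w.sum(axis=1)
        resp = w / denom[:, None]
        ll = float(np.log(denom).sum()) + const
        trace.append(ll)
        p = resp.mean(axis=0)
        if ll - last < tol and len(trace) > 1:
            break
        last = ll
    # responsibilities consistent with the returned p
    w = lik * p[None, :]
    resp = w / w.sum(axis=1)[:, None]
    return p, resp, trace


def fit_mixture_em(loglik_table: np.ndarray, grid: np.ndarray | None = None,
                   tol: float = 1e-8, max_iter: int = 5000,
                   n_boot: int = 0, seed: int = 0,
                   summaries: dict | None = None) -> MixtureFit:
    """EM fit of the probability masses p_k over the omega grid.

    ``loglik_table`` is the J x K matrix of per-gene log-likelihoods from
    :func:`gene_mixture_loglik` (only genes with at least one mutation carry
    information; zero-count rows are flat and may be excluded upstream).
    Bootstrap CIs (genes resampled with replacement) are computed for the
    summary masses when ``n_boot`` > 0.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    loglik_table = np.asarray(loglik_table, dtype=float)
    if loglik_table.ndim != 2 or loglik_table.shape[1] != len(grid):
        raise MixtureError("loglik_table must be J x K with K = len(grid)")
    if loglik_table.shape[0] < 2:
        raise MixtureError("mixture fitting needs at least 2 genes with mutations")
    if np.any(np.diff(grid) <= 0):
        raise MixtureError("omega grid must be strictly increasing")

    p, resp, trace = _em(loglik_table, tol, max_iter)
    summaries = summaries or {
        "mass_ge_1.5": (1.5, np.inf),
        "mass_le_0.75": (-np.inf, 0.75),
        "mass_near_1": (0.9, 1.1),
    }
    fit = MixtureFit(grid=grid, p=p, loglik_trace=trace, posteriors=resp)
    for name, (lo, hi) in summaries.items():
        fit.summaries[name] = fit.mass(lo, hi)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = {name: [] for name in summaries}
        J = loglik_table.shape[0]
        for _ in range(n_boot):
            pick = rng.integers(0, J, size=J)
            # warm start at the full-data optimum: bootstrap optima are close,
            # which cuts EM iterations by orders of magnitude
            pb, _, _ = _em(loglik_table[pick], tol, max_iter, p_init=p)
            for name, (lo, hi) in summaries.items():
                sel = (grid >= lo) & (grid <= hi)
                boot[name].append(float(pb[sel].sum()))
        for name, vals in boot.items():
            fit.summary_ci[name] = tuple(np.percentile(vals, [2.5, 97.5]))
    return fit


@dataclass
class SelectionBudget:
    delta_pos: float
    delta_neg: float
    n_samples: int
    ci_pos: tuple = (np.nan, np.nan)
    ci_neg: tuple = (np.nan, np.nan)


def _budget_terms(posteriors, grid, n_s, n_x, rho_x_neutral):
    """Per-gene contributions to (delta_pos, delta_neg) before the 1/N factor."""
    J = len(n_s)
    pos = np.zeros(J)
    neg = np.zeros(J)
    for k, om in enumerate(grid):
        if om == 1:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            neutral_expect = (np.where(om > 0, n_x / max(om, 1e-300), 0.0) + n_s) \
                * rho_x_neutral
        term = posteriors[:, k] * np.abs(1.0 - om) * neutral_expect
        if om > 1:
            pos += term
        else:
            neg += term
    return pos, neg


def selection_budget(fit: MixtureFit, n_s, n_x, rho_x_neutral, n_samples: int,
                     n_boot: int = 500, seed: int = 0) -> SelectionBudget:
    """Average mutations per tumor gained (delta_pos) / lost (delta_neg) by selection.

    Posterior-weighted over the omega grid: each gene contributes
    P(omega_k | counts) * |1 - omega_k| * ((n_x/omega_k) + n_s) * rho_x_neutral,
    split into the positive (omega > 1) and negative (omega < 1) sides and
    divided by the number of samples N.  ``rho_x_neutral`` is the gene's
    neutral (omega = 1) non-synonymous fraction.
    """
    if n_samples <= 0:
        raise MixtureError("n_samples must be positive")
    n_s = np.asarray(n_s, dtype=float)
    n_x = np.asarray(n_x, dtype=float)
    rho_x_neutral = np.asarray(rho_x_neutral, dtype=float)
    pos, neg = _budget_terms(fit.posteriors, fit.grid, n_s, n_x, rho_x_neutral)
    budget = SelectionBudget(delta_pos=float(pos.sum() / n_samples),
                             delta_neg=float(neg.sum() / n_samples),
                             n_samples=n_samples)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        J = len(n_s)
        bp, bn = [], []
        for _ in range(n_boot):
            pick = rng.integers(0, J, size=J)
            bp.append(pos[pick].sum() / n_samples)
            bn.append(neg[pick].sum() / n_samples)
        budget.ci_pos = tuple(np.percentile(bp, [2.5, 97.5]))
        budget.ci_neg = tuple(np.percentile(bn, [2.5, 97.5]))
    return budget


def power_negative_selection(m: float, omega_m: float, omega_t: float = 1.0,
                             rho_smt: tuple = PANCANCER_RHO,
                             theta: float = PANCANCER_THETA,
                             n_sim: int = 5000, alpha: float = 0.05,
                             seed: int = 0, background: str = "loc") -> float:
    """Simulated power of the two-sided 1-df missense test at a given effect size.

    Per replicate the gene's mutation intensity is Gamma-distributed
    (shape theta, mean m) and counts are Poisson:
    n_s ~ Pois(m_j rho_s), n_m ~ Pois(m_j rho_m omega_m),
    n_t ~ Pois(m_j rho_t omega_t).  Power is the fraction of replicates with
    p < alpha under the chosen background model.
    """
    from .dndscv import gene_lrt

    rho_s, rho_m, rho_t = rho_smt
    if not np.isclose(rho_s + rho_m + rho_t, 1.0, atol=1e-6):
        raise MixtureError("rho_s + rho_m + rho_t must sum to 1")
    rng = np.random.default_rng(seed)
    m_j = rng.gamma(shape=theta, scale=m / theta, size=n_sim)
    n_s = rng.poisson(m_j * rho_s)
    n_m = rng.poisson(m_j * rho_m * omega_m)
    n_t = rng.poisson(m_j * rho_t * omega_t)

    rel = np.array([1.0, rho_m / rho_s, rho_t / rho_s, 0.0])
    if background == "cv":
        a, b = theta, theta / (m * rho_s)
        kwargs = dict(background="cv", alpha=a, beta=b)
    elif background == "loc":
        kwargs = dict(background="loc")
    else:
        raise MixtureError(f"unknown background {background!r}")

    hits = 0
    for k in range(n_sim):
        res = gene_lrt((int(n_s[k]), int(n_m[k]), int(n_t[k]), 0), rel,
                       test="missense_1df", **kwargs)
        if res["p"] < alpha:
            hits += 1
    return hits / n_sim
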