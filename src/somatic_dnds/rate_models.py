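"""Context-dependent Poisson dN/dS models at cohort / gene-set level.

The observed count of substitutions of class *i* and impact *c* across a
cohort is modeled as

    n[i, s] ~ Poisson(t * r_i * L[i, s])
    n[i, c] ~ Poisson(t * r_i * L[i, c] * omega_c)   for c in {m, n, e}

where t is the substitution density, r_i the relative rate of class i (one
class pinned to 1), L the site-composition matrix and omega_c the dN/dS ratio
of impact class c.  Maximum-likelihood estimates come from alternating
closed-form coordinate updates of the Poisson log-likelihood (each conditional
update is exact, so the log-likelihood increases monotonically); 95% CIs on
each omega come from the profile likelihood with the chi-square(1) cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .genome_model import IMPACTS

_CHI2_95_1DF = stats.chi2.ppf(0.95, 1)


@dataclass
class SubstitutionModelSpec:
    """Parameterization of the substitution model.

    ``context_width`` 0/1/2 gives 12/192/3072 rate classes; ``single_rate``
    collapses all classes into one shared rate (the Nei-Gojobori-style model,
    kept for bias studies).
    """
    context_width: int = 1
    single_rate: bool = False


class FitError(ValueError):
    pass


@dataclass
class GlobalFit:
    t: float
    r: np.ndarray              # relative rates per class (reference class = 1)
    u: np.ndarray              # absolute per-class rates u_i = t * r_i
    reference_class: int
    omega: dict                # impact -> MLE
    omega_ci: dict             # impact -> (lo, hi)
    loglik: float
    n_params: int
    aic: float
    omega_structure: str
    context_width: int
    single_rate: bool = False
    data_fingerprint: tuple = ()
    class_mask: np.ndarray = field(default=None, repr=False)

    def summary(self) -> dict:
        return {
            "t": self.t,
            "omega": self.omega,
            "omega_ci": {k: list(v) for k, v in self.omega_ci.items()},
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "omega_structure": self.omega_structure,
            "context_width": self.context_width,
            "reference_class": int(self.reference_class),
        }


_STRUCTURES = {
    # impact columns (1=m, 2=n, 3=e) grouped by shared omega parameter
    "free": (("m", (1,)), ("n", (2,)), ("e", (3,))),
    "tied_truncating": (("m", (1,)), ("t", (2, 3))),
    "single": (("all", (1, 2, 3)),),
}


def _omega_vector(groups, omega_values):
    """Expand per-group omegas into a length-4 multiplier (s pinned at 1)."""
    w = np.ones(4)
    for (name, cols), val in zip(groups, omega_values):
        for c in cols:
            w[c] = val
    return w


def _fit_counts(n, L, groups, fixed=None, tol=1e-10, max_iter=10000):
    """Alternating MLE for (u_i, omega_g); ``fixed`` maps group name -> value."""
    fixed = fixed or {}
    C = n.shape[0]
    names = [g[0] for g in groups]
    omegas = np.array([fixed.get(g[0], 1.0) for g in groups], dtype=float)
    w = _omega_vector(groups, omegas)
    rowsum_n = n.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(L.sum(axis=1) > 0, rowsum_n / np.maximum(L.sum(axis=1), 1e-300), 0.0)
    u = np.maximum(u, 1e-300)

    def loglik(u, w):
        lam = u[:, None] * L * w[None, :]
        mask = L > 0
        ll = float((n[mask] * np.log(np.maximum(lam[mask], 1e-300)) - lam[mask]).sum())
        ll -= float(special.gammaln(n[mask] + 1).sum())
        return ll

    last = -np.inf
    for _ in range(max_iter):
        denom = (L * w[None, :]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(denom > 0, rowsum_n / np.maximum(denom, 1e-300), 0.0)
        for k, (name, cols) in enumerate(groups):
            if name in fixed:
                continue
            num = n[:, cols].sum()
            den = (u[:, None] * L[:, cols]).sum()
            omegas[k] = num / den if den > 0 else np.nan
        w = _omega_vector(groups, omegas)
        ll = loglik(u, w)
        if abs(ll - last) < tol:
            break
        last = ll
    return u, dict(zip(names, omegas)), loglik(u, w)


def fit_global_model(n: np.ndarray, L: np.ndarray,
                     spec: SubstitutionModelSpec | None = None,
                     omega_structure: str = "free",
                     compute_ci: bool = True) -> GlobalFit:
    """Fit the Poisson dN/dS model to aggregated counts and composition.

    Parameters
    ----------
    n, L : arrays of shape (class_count, 4), observed counts and site
        composition with impact columns (s, m, n, e).
    omega_structure : "free" (omega_m, omega_n, omega_e), "tied_truncating"
        (omega_n = omega_e) or "single" (one omega for all non-synonymous).
    """
    spec = spec or SubstitutionModelSpec()
    n = np.asarray(n, dtype=float)
    L = np.asarray(L, dtype=float)
    if n.shape != L.shape or n.ndim != 2 or n.shape[1] != 4:
        raise FitError("n and L must both have shape (class_count, 4)")
    if ((L == 0) & (n > 0)).any():
        bad = np.argwhere((L == 0) & (n > 0))[0]
        raise FitError(f"observed count in cell with zero sites (class {bad[0]}, "
                       f"impact {IMPACTS[bad[1]]})")
    if n[:, 0].sum() == 0:
        raise FitError("no synonymous mutations: omega is unidentifiable")
    if omega_structure not in _STRUCTURES:
        raise FitError(f"unknown omega_structure {omega_structure!r}")

    groups = _STRUCTURES[omega_structure]
    if spec.single_rate:
        # one shared rate across classes: fit on the collapsed matrix (same
        # MLE) but report the likelihood cell-wise so AICs are comparable
        # with context-dependent fits of the same data
        n_fit = n.sum(axis=0, keepdims=True)
        L_fit = L.sum(axis=0, keepdims=True)
        mask = L.sum(axis=1) > 0
        u1, omega, ll_ci_basis = _fit_counts(n_fit, L_fit, groups)
        u = np.full(int(mask.sum()), float(u1[0]))
        w = _omega_vector(groups, np.array([omega[g[0]] for g in groups]))
        lam = u[:, None] * L[mask] * w[None, :]
        cell = L[mask] > 0
        ll = float((n[mask][cell] * np.log(np.maximum(lam[cell], 1e-300))
                    - lam[cell]).sum())
        ll -= float(special.gammaln(n[mask][cell] + 1).sum())
        k_params = 1 + len(groups)
    else:
        mask = L.sum(axis=1) > 0
        u, omega, ll = _fit_counts(n[mask], L[mask], groups)
        ll_ci_basis = ll
        n_fit, L_fit = n[mask], L[mask]
        k_params = int(mask.sum()) + len(groups)

    u_full = np.zeros(len(mask))
    u_full[mask] = u
    ref_candidates = np.where(mask)[0]
    reference = int(ref_candidates[np.argmax(L[mask, 0])])
    t = float(u_full[reference])
    r = np.where(u_full > 0, u_full / t, 0.0)

    aic = 2 * k_params - 2 * ll

    ci = {}
    if compute_ci:
        for gname in omega:
            ci[gname] = _profile_ci(n_fit, L_fit, groups, gname,
                                    omega[gname], ll_ci_basis)
    fingerprint = (int(n.sum()), float((n * np.arange(1, 5)).sum()),
                   float(L.sum()))
    return GlobalFit(t=t, r=r, u=u_full, reference_class=reference, omega=omega,
                     omega_ci=ci, loglik=ll, n_params=k_params, aic=aic,
                     omega_structure=omega_structure,
                     context_width=spec.context_width, single_rate=spec.single_rate,
                     data_fingerprint=fingerprint, class_mask=mask)


def _profile_ci(n, L, groups, gname, mle, ll_max, level_chi2=_CHI2_95_1DF):
    if not np.isfinite(mle) or mle <= 0:
        return (np.nan, np.nan)

    def deviance(value):
        _, _, ll = _fit_counts(n, L, groups, fixed={gname: value})
        return 2 * (ll_max - ll) - level_chi2

    lo, hi = np.nan, np.nan
    lo_bound = mle
    for _ in range(60):
        lo_bound /= 2
        if lo_bound < 1e-9 or deviance(lo_bound) > 0:
            break
    if deviance(lo_bound) > 0:
        lo = optimize.brentq(deviance, lo_bound, mle, xtol=1e-6 * max(mle, 1e-6))
    else:
        lo = 0.0
    hi_bound = mle
    for _ in range(60):
        hi_bound *= 2
        if hi_bound > 1e9 or deviance(hi_bound) > 0:
            break
    if deviance(hi_bound) > 0:
        hi = optimize.brentq(deviance, mle, hi_bound, xtol=1e-6 * max(mle, 1e-6))
    else:
        hi = np.inf
    return (float(lo), float(hi))


def aggregate_counts(gene_counts, compositions, gene_set=None):
    """Sum per-gene count and composition matrices (optionally over a gene set)."""
    comp = {c.gene_id: c for c in compositions}
    ids = [gc.gene_id for gc in gene_counts]
    if gene_set is not None:
        gene_set = set(gene_set)
        missing = gene_set - set(ids)
        if missing:
            raise FitError(f"gene set members absent from the model: {sorted(missing)[:5]}")
        ids_used = [g for g in ids if g in gene_set]
        if not ids_used:
            raise FitError("gene set has empty intersection with the catalog")
    else:
        ids_used = ids
    by_id = {gc.gene_id: gc for gc in gene_counts}
    n = sum(by_id[g].n for g in ids_used)
    L = sum(comp[g].L for g in ids_used)
    return np.asarray(n), np.asarray(L)


def geneset_dnds(gene_counts, compositions, gene_set=None,
                 spec: SubstitutionModelSpec | None = None,
                 omega_structure: str = "free", compute_ci: bool = True) -> GlobalFit:
    """dN/dS on a group of genes (cancer-gene lists, essentiality bins, GO sets).

    Aggregates counts and composition over ``gene_set`` (all genes when None)
    and fits the global Poisson model.
    """
    n, L = aggregate_counts(gene_counts, compositions, gene_set)
    return fit_global_model(n, L, spec=spec, omega_structure=omega_structure,
                            compute_ci=compute_ci)


def compare_models_aic(fits: list[GlobalFit]):
    """Rank fits of the same data by AIC (lower is better)."""
    if not fits:
        raise FitError("no fits to compare")
    fp0 = fits[0].data_fingerprint
    for f in fits[1:]:
        if f.data_fingerprint != fp0:
            raise FitError("fits were made on different data (fingerprint mismatch)")
    order = sorted(fits, key=lambda f: f.aic)
    best = order[0].aic
    return [(f, f.aic - best) for f in order]


# --- excess formula --------------------------------------------------------


def driver_fraction(omega: float) -> float:
    """Fraction of observed mutations in excess of neutrality: (omega-1)/omega.

    Under positive selection without negative selection this is the fraction
    of observed mutations of that class that are genuine drivers; 0 for
    omega <= 1.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    return (omega - 1) / omega if omega > 1 else 0.0


def lost_fraction(omega: float) -> float:
    """Fraction of mutations removed by negative selection: 1 - omega for omega < 1."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    return 1 - omega if omega < 1 else 0.0


def driver_count(omega: float, n_obs: float) -> float:
    return driver_fraction(omega) * n_obs


# --- excess over a negative-binomial background ----------------------------


@dataclass
class ExcessResult:
    table: "pd.DataFrame"
    theta: float
    set_obs: float
    set_expected: float
    set_ratio: float
    driver_fraction: float
    driver_count: float
    ci_ratio: tuple
    ci_driver_count: tuple


def excess_background_test(gene_counts, compositions, global_fit: GlobalFit,
                           target_set, passenger_mask=None, covariates=None,
                           channel: str = "synonymous", n_boot: int = 1000,
                           seed: int = 0, min_passengers: int = 20) -> ExcessResult:
    """Observed/expected excess of a mutation channel in target genes.

    A negative-binomial regression is fitted to the per-gene counts of the
    requested channel on passenger genes only (offset: the expected neutral
    channel rate under the context model for substitutions, log CDS length
    for indels; optional covariates).  Applied to ``target_set`` it yields
    per-gene upper-tail NB p-values with BH q-values, and a set-level excess
    converted to driver fractions/counts with bootstrap CIs.
    """
    import pandas as pd
    from .dndscv import fit_nb_background, nb_sf

    comp = {c.gene_id: c for c in compositions}
    ids = [gc.gene_id for gc in gene_counts]
    target_set = list(target_set)
    missing = set(target_set) - set(ids)
    if missing:
        raise FitError(f"target genes absent from model: {sorted(missing)[:5]}")
    if passenger_mask is None:
        passenger_mask = [g for g in ids if g not in set(target_set)]
    passenger_mask = [g for g in passenger_mask if g not in set(target_set)]
    if len(passenger_mask) < min_passengers:
        raise FitError(f"passenger set too small for NB fit "
                       f"({len(passenger_mask)} < {min_passengers} genes)")

    col = {"synonymous": 0, "missense": 1, "nonsense": 2, "splice": 3}.get(channel)
    by_id = {gc.gene_id: gc for gc in gene_counts}
    obs = {}
    offset = {}
    for g in ids:
        if channel == "indel":
            obs[g] = by_id[g].n_indel_sites
            offset[g] = np.log(max(len(comp[g].L) and comp[g].L.sum() / 3, 1.0))
        else:
            obs[g] = int(by_id[g].n[:, col].sum())
            exp = float((global_fit.u[:, None] * comp[g].L)[:, col].sum())
            offset[g] = np.log(max(exp, 1e-12))
    obs_s = pd.Series(obs)
    off_s = pd.Series(offset)

    cov = None
    if covariates is not None:
        cov = covariates.loc[ids]
    nb = fit_nb_background(obs_s.loc[passenger_mask].to_numpy(float),
                           np.exp(off_s.loc[passenger_mask].to_numpy(float)),
                           covariates=None if cov is None else cov.loc[passenger_mask].to_numpy(float))
    # predict mu for all genes from fitted coefficients
    if cov is None:
        X = np.ones((len(ids), 1))
    else:
        X = np.column_stack([np.ones(len(ids)), cov.to_numpy(float)[:, nb.kept_covariates]])
    mu_all = np.exp(off_s.to_numpy(float) + X @ nb.coefficients)
    mu = pd.Series(mu_all, index=ids)

    pvals = np.array([nb_sf(obs_s[g], mu[g], nb.theta) for g in target_set])
    from statsmodels.stats.multitest import multipletests
    qvals = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame({
        "gene_id": target_set,
        "observed": [obs_s[g] for g in target_set],
        "expected": [mu[g] for g in target_set],
        "obs_exp_ratio": [obs_s[g] / mu[g] if mu[g] > 0 else np.nan for g in target_set],
        "p": pvals, "q": qvals,
    }).set_index("gene_id")

    set_obs = float(obs_s.loc[target_set].sum())
    set_exp = float(mu.loc[target_set].sum())
    ratio = set_obs / set_exp if set_exp > 0 else np.nan
    frac = max(0.0, (set_obs - set_exp) / set_obs) if set_obs > 0 else 0.0
    excess = max(0.0, set_obs - set_exp)

    rng = np.random.default_rng(seed)
    ratios, excesses = [], []
    tgt = np.array(target_set)
    for _ in range(n_boot):
        pick = rng.choice(len(tgt), size=len(tgt), replace=True)
        o = float(obs_s.loc[tgt[pick]].sum())
        e = float(mu.loc[tgt[pick]].sum())
        ratios.append(o / e if e > 0 else np.nan)
        excesses.append(max(0.0, o - e))
    ci_ratio = tuple(np.nanpercentile(ratios, [2.5, 97.5]))
    ci_excess = tuple(np.nanpercentile(excesses, [2.5, 97.5]))

    return ExcessResult(table=table, theta=nb.theta, set_obs=set_obs,
                        set_expected=set_exp, set_ratio=ratio,
                        driver_fraction=frac, driver_count=excess,
                        ci_ratio=ci_ratio, ci_driver_count=ci_excess)
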