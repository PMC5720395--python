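"""Gene-level driver discovery: dNdSunif, dNdSloc and dNdScv.

Per gene j the neutral expectations are E_c,j = sum_i u_i L[i,c,j] for each
impact class c, with u_i = t*r_i from the cohort-level fit.  dNdScv layers a
negative-binomial regression of the observed synonymous counts on covariates
(offset log E_s,j), which yields a per-gene Gamma prior on the local rate:
shape alpha = theta, rate beta_j = theta / mu_j.  The joint per-gene
likelihood is

    L(s_j) = Poisson(n_s,j | s_j) * Gamma(s_j | alpha, beta_j)
             * prod_c Poisson(n_c,j | s_j * rho_c,j * omega_c)

on the expected-synonymous-count scale s_j = t_j * E_s,j, with relative
exposures rho_c,j = E_c,j / E_s,j.  Every hypothesis in the likelihood-ratio
tests admits a closed-form profile over s_j: free omega groups contribute
terms independent of s_j at their conditional MLE omega_c = n_c / (s rho_c),
so

    s_j* = (n_s,j + sum_fixed n_c,j + alpha - 1) /
           (1 + beta_j + sum_fixed rho_c,j * omega_c^fixed).

dNdSloc is the special case alpha = 1, beta_j = 0 (no Gamma information);
dNdSunif fixes s_j = E_s,j (shared t).  Under the free alternative
s_j* = (n_s,j + alpha - 1)/(1 + beta_j), the shrunk expected synonymous
count, and omega_c = n_c,j / (s_j* rho_c,j): observed over shrunk-expected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .catalog_io import count_by_gene
from .rate_models import FitError, GlobalFit, SubstitutionModelSpec, aggregate_counts, fit_global_model

_EPS = 1e-12
_CHI2_95_1DF = stats.chi2.ppf(0.95, 1)


# --- negative-binomial background -----------------------------------------


@dataclass
class NBBackgroundFit:
    theta: float                  # overdispersion (Gamma shape); inf => Poisson
    mu: np.ndarray                # predicted counts per gene
    coefficients: np.ndarray      # intercept + kept covariate coefficients
    kept_covariates: np.ndarray   # indices of covariate columns retained
    converged: bool = True
    message: str = ""

    @property
    def alpha(self) -> float:
        return self.theta

    def beta(self) -> np.ndarray:
        return self.theta / np.maximum(self.mu, _EPS)


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Indices of covariate columns to keep (greedy rank-preserving scan)."""
    keep: list[int] = []
    base = np.ones((X.shape[0], 1))
    for j in range(X.shape[1]):
        cand = np.column_stack([base] + [X[:, keep]] * 0 + [X[:, keep + [j]]]) \
            if keep else np.column_stack([base, X[:, [j]]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(j)
    return np.array(keep, dtype=int)


def fit_nb_background(n_syn, expected_syn, covariates=None,
                      theta_poisson_cutoff: float = 1e6) -> NBBackgroundFit:
    """Negative-binomial regression of synonymous counts on covariates.

    Equivalent to ``glm.nb(n_syn ~ offset(log(expected_syn)) + covariates)``:
    estimates the overdispersion theta of the Gamma mixing distribution and
    the predicted synonymous count mu_j per gene.  Falls back to a Poisson
    GLM (theta = inf) on non-convergence; collinear covariates are dropped.
    """
    import statsmodels.api as sm

    n_syn = np.asarray(n_syn, dtype=float)
    expected_syn = np.asarray(expected_syn, dtype=float)
    if (expected_syn <= 0).any():
        raise FitError("expected_syn must be positive for every gene")
    offset = np.log(expected_syn)

    kept = np.array([], dtype=int)
    X = np.ones((len(n_syn), 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        kept = _drop_collinear(C)
        X = np.column_stack([np.ones(len(n_syn)), C[:, kept]])

    message = ""
    theta = np.inf
    coefs = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = sm.NegativeBinomial(n_syn, X, offset=offset, loglike_method="nb2")
            res = nb.fit(disp=0, maxiter=200)
        alpha_sm = float(res.params[-1])
        if not np.isfinite(alpha_sm) or alpha_sm <= 1 / theta_poisson_cutoff:
            raise RuntimeError("degenerate overdispersion estimate")
        theta = 1.0 / alpha_sm
        coefs = np.asarray(res.params[:-1], dtype=float)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception as exc:   # fall back to Poisson: theta -> inf
        message = f"NB fit failed ({exc}); Poisson fallback"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(n_syn, X, family=sm.families.Poisson(), offset=offset).fit()
        coefs = np.asarray(res.params, dtype=float)
        theta = np.inf
        converged = True

    mu = np.exp(offset + X @ coefs)
    return NBBackgroundFit(theta=theta, mu=mu, coefficients=coefs,
                           kept_covariates=kept, converged=converged, message=message)


def shrunk_expected_syn(n_s_j: float, alpha: float, beta_j: float) -> float:
    """Shrunk expected synonymous count E'_s,j = (n_s,j + alpha - 1) / (1 + beta_j).

    Joint Poisson x Gamma MLE of the expected synonymous count of a gene; the
    prior dominates for small counts and the observation for large ones.  In
    the theta -> inf limit this tends to mu_j.  Clamped at 0 when
    n_s,j + alpha - 1 < 0.
    """
    if beta_j < 0:
        raise ValueError("beta_j must be non-negative")
    if not np.isfinite(beta_j) or not np.isfinite(alpha):
        # theta -> inf limit: prior contracts to mu = alpha/beta
        raise ValueError("alpha and beta_j must be finite; use mu_j directly for the Poisson limit")
    return max(0.0, (n_s_j + alpha - 1.0)) / (1.0 + beta_j)


def nb_sf(observed: float, mu: float, theta: float) -> float:
    """Upper-tail P(X >= observed) under NB(mean mu, dispersion theta)."""
    if observed <= 0:
        return 1.0
    if not np.isfinite(theta):
        return float(stats.poisson.sf(observed - 1, mu))
    p = theta / (theta + mu)
    return float(stats.nbinom.sf(observed - 1, theta, p))


# --- per-gene joint likelihood and LRTs ------------------------------------


def _gene_loglik(counts, rho, s, omegas, alpha, beta):
    """Joint log-likelihood at (s, omega) dropping count-factorial constants."""
    ll = counts[0] * np.log(max(s, _EPS)) - s
    for c in range(1, 4):
        lam = s * rho[c] * omegas[c]
        if counts[c] > 0:
            ll += counts[c] * np.log(max(lam, _EPS))
        ll -= lam
    if np.isfinite(alpha) and (alpha != 1.0 or beta != 0.0):
        ll += (alpha - 1.0) * np.log(max(s, _EPS)) - beta * s
    return ll


def _optimize_gene(counts, rho, alpha, beta, fixed, tied, s_fixed=None):
    """Closed-form profile of the joint likelihood for one hypothesis.

    ``fixed`` maps impact column (1, 2, 3) to a fixed omega value; ``tied``
    is True when columns 2 and 3 (nonsense, splice) share one free omega.
    Returns (s_hat, omega_vector, loglik).
    """
    counts = np.asarray(counts, dtype=float)
    rho = np.asarray(rho, dtype=float)
    free_cols = [c for c in (1, 2, 3) if c not in fixed and rho[c] > 0]
    if s_fixed is not None:
        s = float(s_fixed)
    else:
        num = counts[0] + sum(counts[c] for c in fixed) + alpha - 1.0
        den = 1.0 + beta + sum(rho[c] * fixed[c] for c in fixed)
        s = max(num, 0.0) / den
        s = max(s, _EPS)
    omegas = np.ones(4)
    for c, v in fixed.items():
        omegas[c] = v
    if tied and 2 in free_cols and 3 in free_cols:
        num = counts[2] + counts[3]
        den = s * (rho[2] + rho[3])
        val = num / den if den > 0 else np.nan
        omegas[2] = omegas[3] = val
        free_cols = [c for c in free_cols if c == 1]
    for c in free_cols:
        omegas[c] = counts[c] / (s * rho[c]) if s * rho[c] > 0 else np.nan
    ll = _gene_loglik(counts, rho, s, np.nan_to_num(omegas, nan=1.0), alpha, beta)
    return s, omegas, ll


@dataclass
class GeneTestResult:
    gene_id: str
    n_s: int
    n_m: int
    n_n: int
    n_e: int
    omega_m: float = np.nan
    omega_n: float = np.nan
    omega_e: float = np.nan
    omega_t: float = np.nan
    expected_syn_shrunk: float = np.nan
    p_sub: float = 1.0
    p_mis: float = 1.0
    p_neg: float = 1.0
    p_indel: float = np.nan
    p_global: float = np.nan
    omega_m_ci: tuple = (np.nan, np.nan)
    omega_t_ci: tuple = (np.nan, np.nan)


def gene_lrt(counts, rho, background: str = "cv", alpha: float = 1.0,
             beta: float = 0.0, s_unif: float | None = None,
             test: str = "tied_truncating_2df", compute_ci: bool = False):
    """Likelihood-ratio test for selection in one gene.

    Parameters
    ----------
    counts : (n_s, n_m, n_n, n_e) observed counts.
    rho : relative neutral exposures (1, E_m/E_s, E_n/E_s, E_e/E_s).
    background : "cv" (Gamma-informed, pass alpha/beta), "loc" (local
        synonymous counts only) or "unif" (shared rate; pass ``s_unif`` =
        E_s,j under the global t).
    test : "tied_truncating_2df", "free_3df", "missense_1df" or
        "negative_1sided".

    Returns a dict with omega MLEs, the shrunk expected synonymous count and
    the p-value.
    """
    counts = np.asarray(counts, dtype=float)
    if background == "loc":
        alpha, beta = 1.0, 0.0
        s_fixed = None
    elif background == "cv":
        s_fixed = None
        if not np.isfinite(alpha):
            raise FitError("cv background requires finite alpha (theta); "
                           "use background='unif' for the Poisson limit")
    elif background == "unif":
        if s_unif is None:
            raise FitError("background='unif' requires s_unif (global expected syn)")
        alpha, beta = 1.0, 0.0
        s_fixed = s_unif
    else:
        raise FitError(f"unknown background {background!r}")

    if background == "loc" and counts.sum() == 0:
        return {"p": 1.0, "omegas": np.full(4, np.nan), "s": np.nan, "df": 0,
                "omega_ci": {}}

    # alternative: omega_m free, truncating tied or free per test
    if test in ("tied_truncating_2df",):
        s1, om1, ll1 = _optimize_gene(counts, rho, alpha, beta, fixed={}, tied=True,
                                      s_fixed=s_fixed)
        s0, om0, ll0 = _optimize_gene(counts, rho, alpha, beta,
                                      fixed={1: 1.0, 2: 1.0, 3: 1.0}, tied=False,
                                      s_fixed=s_fixed)
        df = 2
    elif test == "free_3df":
        s1, om1, ll1 = _optimize_gene(counts, rho, alpha, beta, fixed={}, tied=False,
                                      s_fixed=s_fixed)
        s0, om0, ll0 = _optimize_gene(counts, rho, alpha, beta,
                                      fixed={1: 1.0, 2: 1.0, 3: 1.0}, tied=False,
                                      s_fixed=s_fixed)
        df = 3
    elif test in ("missense_1df", "negative_1sided"):
        s1, om1, ll1 = _optimize_gene(counts, rho, alpha, beta, fixed={}, tied=False,
                                      s_fixed=s_fixed)
        s0, om0, ll0 = _optimize_gene(counts, rho, alpha, beta, fixed={1: 1.0},
                                      tied=False, s_fixed=s_fixed)
        df = 1
    else:
        raise FitError(f"unknown test {test!r}")

    stat = max(0.0, 2 * (ll1 - ll0))
    p = float(stats.chi2.sf(stat, df))
    if test == "negative_1sided":
        omega_m = om1[1]
        p = p / 2 if (np.isnan(omega_m) or omega_m < 1) else 1 - p / 2

    result = {"p": p, "omegas": om1, "s": s1, "df": df, "loglik": ll1,
              "omega_ci": {}}
    if compute_ci:
        result["omega_ci"]["m"] = _gene_profile_ci(counts, rho, alpha, beta,
                                                   s_fixed, col=1)
        result["omega_ci"]["t"] = _gene_profile_ci(counts, rho, alpha, beta,
                                                   s_fixed, col="t")
    return result


def _gene_profile_ci(counts, rho, alpha, beta, s_fixed, col):
    """Profile-likelihood 95% CI for omega_m (col=1) or tied omega_t (col='t').

    The nuisance rate s_j (and the other omega, tied for truncating) is
    re-profiled at every candidate value, matching the 2-df alternative.
    """
    s1, om1, ll1 = _optimize_gene(counts, rho, alpha, beta, fixed={}, tied=True,
                                  s_fixed=s_fixed)
    if col == "t":
        if rho[2] + rho[3] <= 0:
            return (np.nan, np.nan)
        mle = om1[2]

        def prof(v):
            _, _, ll = _optimize_gene(counts, rho, alpha, beta,
                                      fixed={2: v, 3: v}, tied=False, s_fixed=s_fixed)
            return ll
    else:
        if rho[col] <= 0:
            return (np.nan, np.nan)
        mle = om1[col]

        def prof(v):
            _, _, ll = _optimize_gene(counts, rho, alpha, beta, fixed={col: v},
                                      tied=True, s_fixed=s_fixed)
            return ll

    if not np.isfinite(mle):
        return (np.nan, np.nan)

    def deviance(v):
        return 2 * (ll1 - prof(v)) - _CHI2_95_1DF

    center = max(mle, 1e-9)
    lo_edge = 1e-9
    lo = 0.0 if deviance(lo_edge) <= 0 else optimize.brentq(deviance, lo_edge, center,
                                                            xtol=1e-7)
    hi_bound = max(center, 1.0)
    for _ in range(80):
        hi_bound *= 2
        if deviance(hi_bound) > 0 or hi_bound > 1e9:
            break
    hi = np.inf if deviance(hi_bound) <= 0 else optimize.brentq(deviance, center, hi_bound,
                                                                xtol=1e-6 * hi_bound)
    return (float(lo), float(hi))


def indel_test(n_indel: int, n_indel_sites: int, mu: float, theta: float,
               mode: str = "unique_sites") -> float:
    """Upper-tail NB recurrence p-value for indels in a gene.

    ``mode='unique_sites'`` tests the number of distinct indel start sites,
    which is robust to indel hotspots and recurrent artifacts; ``'total'``
    tests the raw indel count.
    """
    if mode not in ("unique_sites", "total"):
        raise FitError(f"unknown indel mode {mode!r}")
    obs = n_indel_sites if mode == "unique_sites" else n_indel
    return nb_sf(obs, mu, theta)


def combine_fisher(p_sub: float, p_indel: float) -> float:
    """Fisher combination of the substitution and indel p-values (chi2, df=4)."""
    tiny = np.finfo(float).tiny
    p1 = min(max(p_sub, tiny), 1.0)
    p2 = min(max(p_indel, tiny), 1.0)
    stat = -2.0 * (np.log(p1) + np.log(p2))
    return float(stats.chi2.sf(stat, 4))


def significance(pvalues, mode: str = "per_dataset_bh", restricted_genes=None,
                 index=None):
    """Benjamini-Hochberg q-values, optionally matrix-wide or restricted.

    ``pvalues`` may be a Series/array (per-dataset), a DataFrame (dataset x
    gene matrix, corrected globally) or, with ``mode='restricted'``, only the
    entries of ``restricted_genes`` (by ``index``) are corrected and returned.
    """
    if mode == "global_matrix_bh":
        df = pd.DataFrame(pvalues)
        flat = df.to_numpy(float).ravel()
        ok = np.isfinite(flat)
        q = np.full(flat.shape, np.nan)
        q[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        return pd.DataFrame(q.reshape(df.shape), index=df.index, columns=df.columns)
    p = pd.Series(np.asarray(pvalues, dtype=float),
                  index=index if index is not None else getattr(pvalues, "index", None))
    if mode == "per_dataset_bh":
        q = pd.Series(np.nan, index=p.index)
        ok = p.notna()
        q[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
        return q
    if mode == "restricted":
        if restricted_genes is None or len(restricted_genes) == 0:
            raise FitError("restricted hypothesis testing requires a non-empty gene list")
        sub = p.loc[[g for g in restricted_genes if g in p.index]]
        if sub.empty:
            raise FitError("restricted gene list has no overlap with tested genes")
        q = pd.Series(multipletests(sub.to_numpy(), method="fdr_bh")[1], index=sub.index)
        return q
    raise FitError(f"unknown significance mode {mode!r}")


# --- end-to-end pipeline ----------------------------------------------------


@dataclass
class DndscvResult:
    table: pd.DataFrame
    global_fit: GlobalFit
    nb_background: NBBackgroundFit | None
    indel_background: NBBackgroundFit | None
    count_report: object = None


def run_dndscv(records, genes, index=None, covariates: pd.DataFrame | None = None,
               background: str = "cv", test: str = "tied_truncating_2df",
               indel_mode: str = "unique_sites", known_cancer_genes=(),
               exclude_genes=(), compute_ci: bool = False,
               compositions=None, omega_structure: str = "tied_truncating"):
    """End-to-end driver-gene screen on a mutation catalog.

    Stages: annotate counts -> global context-model fit -> NB background
    regression -> per-gene LRTs -> indel recurrence test -> Fisher combination
    -> BH correction.  ``known_cancer_genes`` are excluded from the NB
    background fits (not from testing); ``exclude_genes`` are dropped
    entirely.  Deterministic given inputs.
    """
    from .genome_model import SubstitutionClassIndex, composition_matrix

    index = index or SubstitutionClassIndex(1)
    genes = [g for g in genes if g.gene_id not in set(exclude_genes)]
    if compositions is None:
        compositions = [composition_matrix(g, index) for g in genes]
    comp = {c.gene_id: c for c in compositions}

    gene_counts, count_report = count_by_gene(records, genes, index)
    by_id = {gc.gene_id: gc for gc in gene_counts}
    ids = [g.gene_id for g in genes]

    n_tot, L_tot = aggregate_counts(gene_counts, compositions)
    spec = SubstitutionModelSpec(context_width=index.context_width)
    global_fit = fit_global_model(n_tot, L_tot, spec=spec,
                                  omega_structure=omega_structure, compute_ci=False)

    # neutral expected counts per gene and impact under the global rates
    E = {g: global_fit.u @ comp[g].L for g in ids}   # length-4 vector per gene
    expected_syn = np.array([max(E[g][0], _EPS) for g in ids])

    passengers = [g for g in ids if g not in set(known_cancer_genes)]
    pass_idx = [k for k, g in enumerate(ids) if g in set(passengers)]

    nb = None
    alpha_beta = {}
    if background == "cv":
        n_syn = np.array([by_id[g].n_s for g in ids], dtype=float)
        cov_arr = covariates.loc[ids].to_numpy(float) if covariates is not None else None
        nb = fit_nb_background(n_syn[pass_idx], expected_syn[pass_idx],
                               None if cov_arr is None else cov_arr[pass_idx])
        # predict mu for every gene (including excluded-from-fit targets)
        if cov_arr is None:
            X = np.ones((len(ids), 1))
        else:
            X = np.column_stack([np.ones(len(ids)), cov_arr[:, nb.kept_covariates]])
        mu_all = np.exp(np.log(expected_syn) + X @ nb.coefficients)
        if np.isfinite(nb.theta):
            alpha_beta = {g: (nb.theta, nb.theta / max(mu_all[k], _EPS))
                          for k, g in enumerate(ids)}
        else:  # Poisson limit: treat background as uninformative-local
            alpha_beta = {g: (1.0, 0.0) for g in ids}

    # indel background (NB on unique sites, offset log CDS length), passengers only
    indel_nb = None
    any_indels = any(by_id[g].n_indel > 0 for g in ids)
    if any_indels:
        n_sites = np.array([by_id[g].n_indel_sites if indel_mode == "unique_sites"
                            else by_id[g].n_indel for g in ids], dtype=float)
        cds_len = np.array([comp[g].L[:, :3].sum() / 3 for g in ids], dtype=float)
        cov_arr = covariates.loc[ids].to_numpy(float) if covariates is not None else None
        indel_nb = fit_nb_background(n_sites[pass_idx], cds_len[pass_idx],
                                     None if cov_arr is None else cov_arr[pass_idx])
        if cov_arr is None:
            Xi = np.ones((len(ids), 1))
        else:
            Xi = np.column_stack([np.ones(len(ids)), cov_arr[:, indel_nb.kept_covariates]])
        mu_indel = np.exp(np.log(cds_len) + Xi @ indel_nb.coefficients)

    rows = []
    for k, gid in enumerate(ids):
        gc = by_id[gid]
        counts = (gc.n_s, gc.n_m, gc.n_n, gc.n_e)
        Eg = E[gid]
        rho = np.array([1.0,
                        Eg[1] / max(Eg[0], _EPS),
                        Eg[2] / max(Eg[0], _EPS),
                        Eg[3] / max(Eg[0], _EPS)])
        kwargs = {}
        if background == "cv":
            a, b = alpha_beta[gid]
            kwargs = dict(alpha=a, beta=b)
        elif background == "unif":
            kwargs = dict(s_unif=max(Eg[0], _EPS))
        res = gene_lrt(counts, rho, background=background, test=test,
                       compute_ci=compute_ci, **kwargs)
        res_mis = gene_lrt(counts, rho, background=background,
                           test="missense_1df", **kwargs)
        res_neg = gene_lrt(counts, rho, background=background,
                           test="negative_1sided", **kwargs)
        om = res["omegas"]
        row = GeneTestResult(
            gene_id=gid, n_s=gc.n_s, n_m=gc.n_m, n_n=gc.n_n, n_e=gc.n_e,
            omega_m=om[1], omega_n=om[2], omega_e=om[3],
            omega_t=om[2] if test == "tied_truncating_2df" else np.nan,
            expected_syn_shrunk=res["s"],
            p_sub=res["p"], p_mis=res_mis["p"], p_neg=res_neg["p"],
        )
        if compute_ci:
            row.omega_m_ci = res["omega_ci"].get("m", (np.nan, np.nan))
            row.omega_t_ci = res["omega_ci"].get("t", (np.nan, np.nan))
        if any_indels:
            row.p_indel = indel_test(gc.n_indel, gc.n_indel_sites,
                                     float(mu_indel[k]),
                                     indel_nb.theta, mode=indel_mode)
            row.p_global = combine_fisher(row.p_sub, row.p_indel)
        else:
            row.p_global = row.p_sub
        rows.append(row)

    table = pd.DataFrame([r.__dict__ for r in rows]).set_index("gene_id")
    table["q_sub"] = significance(table["p_sub"])
    table["q_global"] = significance(table["p_global"])
    table["q_neg"] = significance(table["p_neg"])
    return DndscvResult(table=table, global_fit=global_fit, nb_background=nb,
                        indel_background=indel_nb, count_report=count_report)
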