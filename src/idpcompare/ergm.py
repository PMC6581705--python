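"""Exponential random graph models (ERGMs) for PSN ensembles.

The model places an exponential-family distribution over simple graphs on the
residue set, conditional on the backbone path being present:

    Pr(G = g | theta, X)  propto  exp(theta^T t(g, X)),

with a ten-term statistic vector t: edge count, backbone-distance absdiff,
hydrophobicity/volume/mass/termini node covariates (summed over edge
endpoints), a charge-mixing edge covariate, polar/nonpolar and polar/polar
mixing counts (nonpolar/nonpolar is the reference), and a fixed-decay
geometrically weighted edgewise-shared-partner term GWESP(tau = 0.5).

Fitting maximizes the sigma-integrated penalized pseudo-likelihood

    log ∫ p(theta | sigma) p(sigma | kappa, zeta) prod_i PL(Y_i | theta) dsigma,

with Laplace(0, sigma) coefficient priors and an Inv-Gamma(kappa, zeta)
hyperprior on the scale.  The sigma integral is a Gamma integral with the
closed form  -(p + kappa) * log(sum|theta| + zeta) + const, and the
conditional sigma | theta is Inv-Gamma(p + kappa, sum|theta| + zeta).
Changescores are rescaled to unit variance during optimization so that the
common prior scale is meaningful across terms; estimates are reported on the
original scale.  Posterior uncertainty comes from a Bayesian bootstrap with
graphs as the resampled units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .properties import ResidueProperties
from .psn import PSN

__all__ = [
    "TERM_NAMES",
    "ErgmModel",
    "ErgmPosterior",
    "FavorabilityResult",
    "graph_statistics",
    "change_statistics",
    "changescore_design",
    "pseudo_loglik",
    "fit_ergm_map",
    "bayesian_bootstrap",
    "simulate_ergm",
    "favorability_ratio",
    "rank_by_favorability",
]

TERM_NAMES = [
    "edges",
    "backbone_dist",
    "hydrophobicity",
    "charge_mix",
    "polar_nonpolar_mix",
    "polar_polar_mix",
    "volume",
    "mass",
    "termini",
    "gwesp",
]
N_TERMS = len(TERM_NAMES)
GWESP_TAU = 0.5


@dataclass
class ErgmModel:
    """Fitted (or specified) ERGM: coefficients on the original term scale."""

    theta: np.ndarray
    sigma: float = 1.0
    term_names: tuple = tuple(TERM_NAMES)
    tau: float = GWESP_TAU
    kappa: float = 0.1
    zeta: float = 1.1
    scaling: np.ndarray | None = None  # per-term changescore SDs used in fitting
    converged: bool = True

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape[0] != len(self.term_names):
            raise ValueError("theta length must equal the number of terms")
        if self.sigma <= 0:
            raise ValueError("prior scale must be positive")

    @classmethod
    def from_terms(cls, **coef) -> "ErgmModel":
        """Convenience constructor: unspecified terms are zero."""
        theta = np.zeros(N_TERMS)
        for name, value in coef.items():
            theta[TERM_NAMES.index(name)] = value
        return cls(theta)


def _gwesp_weight(p, tau: float = GWESP_TAU):
    """w(p) = e^tau * (1 - (1 - e^-tau)^p); the GWESP credit of an edge with p shared partners."""
    p = np.asarray(p)
    return np.exp(tau) * (1.0 - (1.0 - np.exp(-tau)) ** p)


def _dyad_covariates(props: ResidueProperties) -> np.ndarray:
    """(n, n, 9) array of the dyad-independent term contributions.

    Entry [i, j, t] is the amount term t changes when dyad (i, j) toggles on;
    for these nine terms it is also the per-edge contribution to t(g).
    """
    n = props.n_residues
    i = np.arange(n)
    out = np.zeros((n, n, N_TERMS - 1))
    out[:, :, 0] = 1.0  # edges
    out[:, :, 1] = np.abs(i[:, None] - i[None, :])  # backbone distance
    out[:, :, 2] = props.hydrophobicity[:, None] + props.hydrophobicity[None, :]
    out[:, :, 3] = props.charge[:, None] * props.charge[None, :]  # +1 like, -1 unlike
    pol = props.polar.astype(int)
    out[:, :, 4] = (pol[:, None] != pol[None, :]).astype(float)  # polar/nonpolar
    out[:, :, 5] = (pol[:, None] & pol[None, :]).astype(float)   # polar/polar
    out[:, :, 6] = props.volume[:, None] + props.volume[None, :]
    out[:, :, 7] = props.mass[:, None] + props.mass[None, :]
    out[:, :, 8] = props.termini[:, None] + props.termini[None, :]
    return out


def graph_statistics(psn: PSN, props: ResidueProperties,
                     tau: float = GWESP_TAU) -> np.ndarray:
    """The ten-term sufficient statistic vector t(g, X)."""
    if props.n_residues != psn.n_nodes:
        raise ValueError("property table length must equal PSN node count")
    a = psn.adjacency
    cov = _dyad_covariates(props)
    triu = np.triu(a, 1)
    t = np.empty(N_TERMS)
    t[:9] = np.tensordot(triu, cov, axes=([0, 1], [0, 1]))
    ai = a.astype(np.int64)
    common = ai @ ai  # shared-partner counts for every pair
    iu, ju = np.nonzero(triu)
    t[9] = float(_gwesp_weight(common[iu, ju], tau).sum())
    return t


def _gwesp_change(a: np.ndarray, i: int, j: int, tau: float = GWESP_TAU) -> float:
    """GWESP change for toggling dyad (i, j) on (0-based), holding the rest fixed.

    `a` is a boolean adjacency matrix; its (i, j) state may be either — the
    computation is done in the edge-off state and restored.
    """
    was = bool(a[i, j])
    if was:
        a[i, j] = a[j, i] = False
    cn = a[i] & a[j]
    ks = np.nonzero(cn)[0]
    delta = float(_gwesp_weight(len(ks), tau))
    if len(ks):
        sub = a[ks].astype(np.int64)
        esp_i = sub @ a[i].astype(np.int64)
        esp_j = sub @ a[j].astype(np.int64)
        delta += float((_gwesp_weight(esp_i + 1, tau) - _gwesp_weight(esp_i, tau)).sum())
        delta += float((_gwesp_weight(esp_j + 1, tau) - _gwesp_weight(esp_j, tau)).sum())
    if was:
        a[i, j] = a[j, i] = True
    return delta


def change_statistics(psn: PSN, props: ResidueProperties,
                      dyad: tuple[int, int], tau: float = GWESP_TAU) -> np.ndarray:
    """Delta t for toggling one free dyad (1-based pair): t(g+) - t(g-)."""
    i, j = dyad
    if abs(i - j) == 1:
        raise ValueError(f"dyad {dyad} is a backbone edge and cannot be toggled")
    if i == j:
        raise ValueError("dyad endpoints must differ")
    cov = _dyad_covariates(props)
    delta = np.empty(N_TERMS)
    delta[:9] = cov[i - 1, j - 1]
    delta[9] = _gwesp_change(psn.adjacency, i - 1, j - 1, tau)
    return delta


def changescore_design(psn: PSN, props: ResidueProperties,
                       tau: float = GWESP_TAU,
                       cov: np.ndarray | None = None):
    """Changescores for every free dyad of one graph.

    Returns (X, y): X is (n_free, 10) with rows Delta t at each free dyad
    (holding the rest of the graph at its observed state), y the observed
    edge indicator.  Dyads are ordered as PSN.free_dyads().
    """
    if cov is None:
        cov = _dyad_covariates(props)
    a = psn.adjacency
    n = psn.n_nodes
    iu, ju = np.triu_indices(n, 2)
    X = np.empty((iu.size, N_TERMS))
    X[:, :9] = cov[iu, ju]
    y = a[iu, ju].astype(float)

    # GWESP column: vectorized for absent dyads, explicit toggle for present.
    ai = a.astype(np.int64)
    common = ai @ ai
    g = _gwesp_weight(common + 1, tau) - _gwesp_weight(common, tau)
    h = ai * g
    t2 = h @ ai + ai @ h
    gw = _gwesp_weight(common[iu, ju], tau) + t2[iu, ju]
    present = np.nonzero(y > 0)[0]
    for idx in present:
        gw[idx] = _gwesp_change(a, int(iu[idx]), int(ju[idx]), tau)
    X[:, 9] = gw
    return X, y


def _stack_design(ensemble: list[PSN], props: ResidueProperties,
                  tau: float = GWESP_TAU):
    cov = _dyad_covariates(props)
    xs, ys = [], []
    for g in ensemble:
        X, y = changescore_design(g, props, tau, cov)
        xs.append(X)
        ys.append(y)
    return np.vstack(xs), np.concatenate(ys), xs[0].shape[0]


def _log_sigmoid(z):
    return -np.logaddexp(0.0, -z)


def pseudo_loglik(theta, ensemble: list[PSN], props: ResidueProperties,
                  weights=None, tau: float = GWESP_TAU) -> float:
    """Weighted conditional pseudo-log-likelihood of an ensemble.

    Sum over graphs and free dyads of the Bernoulli log-likelihood with
    logit theta^T Delta t, conditional on the rest of the graph and on the
    backbone support.
    """
    theta = np.asarray(theta, dtype=float)
    X, y, n_free = _stack_design(ensemble, props, tau)
    if weights is None:
        weights = np.ones(len(ensemble))
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    w_rows = np.repeat(weights, n_free)
    logit = X @ theta
    ll = y * _log_sigmoid(logit) + (1 - y) * _log_sigmoid(-logit)
    return float(np.sum(w_rows * ll))


def _penalized_objective(theta_s, X, y, w_rows, p_kappa, zeta, eps,
                         fixed_sigma):
    """Negative (log-prior + weighted PL) and gradient, standardized scale,
    with pseudo-Huber-smoothed |theta|.  With `fixed_sigma` the prior is
    Laplace(0, sigma) directly; otherwise sigma is integrated out."""
    from scipy.special import expit

    logit = X @ theta_s
    ll = y * _log_sigmoid(logit) + (1 - y) * _log_sigmoid(-logit)
    nll = -np.sum(w_rows * ll)
    p_hat = expit(logit)
    grad_nll = X.T @ (w_rows * (p_hat - y))
    habs = np.sqrt(theta_s ** 2 + eps ** 2) - eps
    dhabs = theta_s / np.sqrt(theta_s ** 2 + eps ** 2)
    if fixed_sigma is not None:
        pen = habs.sum() / fixed_sigma
        grad_pen = dhabs / fixed_sigma
    else:
        s = habs.sum() + zeta
        pen = p_kappa * np.log(s)
        grad_pen = p_kappa * dhabs / s
    return nll + pen, grad_nll + grad_pen


def _fit_standardized(X, y, w_rows, kappa, zeta, eps=1e-6, maxiter=500,
                      fixed_sigma=None):
    p = X.shape[1]
    p_kappa = p + kappa
    # Continuation on the smoothing width: the near-kink curvature at the
    # target eps defeats line searches from a cold start, so optimize at a
    # mild smoothing first and warm-start the sharp problem from there.
    theta = np.zeros(p)
    grad_scale = max(np.sum(w_rows), 1.0)
    for stage_eps in (1e-3, eps):
        res = minimize(_penalized_objective, theta, jac=True,
                       method="L-BFGS-B",
                       args=(X, y, w_rows, p_kappa, zeta, stage_eps,
                             fixed_sigma),
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-8})
        gnorm = float(np.max(np.abs(res.jac)))
        if not res.success and gnorm > 1e-3 * grad_scale:
            raise RuntimeError(
                f"ERGM MAP optimization failed: {res.message} "
                f"(max|grad| = {gnorm:.3g})")
        theta = res.x

    # Hard-threshold pass: the smoothed objective cannot reach exact zeros;
    # accept a coordinate at 0 whenever that does not worsen the exact
    # (non-smoothed) objective.
    def exact_obj(t):
        logit = X @ t
        ll = y * _log_sigmoid(logit) + (1 - y) * _log_sigmoid(-logit)
        pll = -np.sum(w_rows * ll)
        if fixed_sigma is not None:
            return pll + np.abs(t).sum() / fixed_sigma
        return pll + p_kappa * np.log(np.abs(t).sum() + zeta)

    base = exact_obj(theta)
    for k in np.argsort(np.abs(theta)):
        if theta[k] == 0:
            continue
        trial = theta.copy()
        trial[k] = 0.0
        val = exact_obj(trial)
        if val <= base + 1e-9:
            theta, base = trial, val
    return theta, res.success


def fit_ergm_map(ensemble: list[PSN], props: ResidueProperties,
                 kappa: float = 0.1, zeta: float = 1.1,
                 weights=None, tau: float = GWESP_TAU,
                 design=None, fixed_sigma: float | None = None) -> ErgmModel:
    """MAP fit of the regularized pseudo-likelihood ERGM.

    Changescores are standardized to unit variance for optimization; the
    returned coefficients are on the original term scale.  `design` may carry
    a precomputed (X, y, n_free) triple (used by the bootstrap to avoid
    recomputing changescores).  `fixed_sigma` bypasses the scale hyperprior
    and fits at a fixed Laplace scale (pure L1 at strength 1/sigma).
    """
    if not ensemble and design is None:
        raise ValueError("ensemble must be non-empty")
    if design is None:
        design = _stack_design(ensemble, props, tau)
    X, y, n_free = design
    n_graphs = X.shape[0] // n_free
    if weights is None:
        weights = np.ones(n_graphs)
    weights = np.asarray(weights, dtype=float)
    w_rows = np.repeat(weights, n_free)

    sd = np.sqrt(np.average((X - np.average(X, axis=0, weights=w_rows)) ** 2,
                            axis=0, weights=w_rows))
    scale = sd.copy()
    # relative tolerance: constant columns under floating weights have SD
    # ~1e-14 rather than exactly 0
    zero_var = scale <= 1e-9 * np.maximum(1.0, np.abs(X).max(axis=0))
    if np.any(zero_var):
        # the edges changescore is constant by construction (the density
        # offset); only other degenerate terms are worth a warning
        unexpected = zero_var.copy()
        unexpected[0] = False
        if np.any(unexpected):
            warnings.warn("zero-variance changescore term(s) left unscaled: "
                          + ", ".join(np.array(TERM_NAMES)[unexpected]))
        scale[zero_var] = 1.0
    Xs = X / scale

    theta_s, ok = _fit_standardized(Xs, y, w_rows, kappa, zeta,
                                    fixed_sigma=fixed_sigma)
    p = X.shape[1]
    if fixed_sigma is not None:
        sigma = float(fixed_sigma)
    else:
        # posterior-mean sigma: sigma | theta ~ Inv-Gamma(p+kappa, S+zeta)
        sigma = (np.abs(theta_s).sum() + zeta) / (p + kappa - 1.0)
    return ErgmModel(theta=theta_s / scale, sigma=float(sigma),
                     kappa=kappa, zeta=zeta, tau=tau,
                     scaling=scale, converged=bool(ok))


@dataclass
class ErgmPosterior:
    """Bayesian-bootstrap posterior summary (Table-style: 10 terms + prior scale)."""

    summary: pd.DataFrame
    replicates: np.ndarray  # (m_ok, 11) raw replicate draws
    n_failed: int = 0

    @property
    def m(self) -> int:
        return self.replicates.shape[0]

    def sd(self, term: str) -> float:
        return float(self.summary.loc[term, "post_sd"])

    def mean(self, term: str) -> float:
        return float(self.summary.loc[term, "post_mean"])


def bayesian_bootstrap(ensemble: list[PSN], props: ResidueProperties,
                       kappa: float = 0.1, zeta: float = 1.1,
                       m: int = 100, seed: int = 0,
                       tau: float = GWESP_TAU) -> ErgmPosterior:
    """Bayesian bootstrap over graphs: m refits under Dirichlet(1,...,1) weights.

    Replicate weights are assigned by a canonical ordering of the graphs
    (adjacency bytes), so summaries do not depend on ensemble list order for
    a fixed seed.
    """
    if m < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    n = len(ensemble)
    design = _stack_design(ensemble, props, tau)
    canonical = np.argsort([g.adjacency.tobytes() for g in ensemble],
                           kind="stable")
    rng = np.random.default_rng(seed)
    draws = []
    n_failed = 0
    for _ in range(m):
        w_sorted = rng.dirichlet(np.ones(n)) * n
        w = np.empty(n)
        w[canonical] = w_sorted
        try:
            model = fit_ergm_map(ensemble, props, kappa, zeta, weights=w,
                                 tau=tau, design=design)
        except RuntimeError:
            n_failed += 1
            continue
        draws.append(np.append(model.theta, model.sigma))
    if n_failed > 0.05 * m:
        warnings.warn(f"{n_failed}/{m} bootstrap replicates failed to fit")
    if not draws:
        raise RuntimeError("all bootstrap replicates failed")
    reps = np.array(draws)
    names = TERM_NAMES + ["prior_scale"]
    summary = pd.DataFrame({
        "post_mean": reps.mean(axis=0),
        "post_sd": reps.std(axis=0, ddof=1),
        "q2.5": np.quantile(reps, 0.025, axis=0),
        "q97.5": np.quantile(reps, 0.975, axis=0),
    }, index=names)
    return ErgmPosterior(summary, reps, n_failed)


def simulate_ergm(model: ErgmModel, props: ResidueProperties, n: int,
                  burn: int | None = None, thin: int | None = None,
                  seed: int = 0, start: PSN | None = None) -> list[PSN]:
    """Metropolis sampling of PSNs from the model.

    Single-dyad-toggle chain over free (non-backbone) dyads only; the
    backbone path is part of the support and never toggled.  Defaults:
    burn = 50 * n_free, thin = n_free, start = backbone-only graph.
    """
    n_res = props.n_residues
    iu, ju = np.triu_indices(n_res, 2)
    n_free = iu.size
    if burn is None:
        burn = 50 * n_free
    if thin is None:
        thin = n_free
    rng = np.random.default_rng(seed)

    if start is None:
        a = np.zeros((n_res, n_res), dtype=bool)
        idx = np.arange(n_res - 1)
        a[idx, idx + 1] = a[idx + 1, idx] = True
    else:
        a = start.adjacency.copy()

    cov = _dyad_covariates(props)
    eta9 = cov[iu, ju] @ model.theta[:9]  # state-independent part of the logit
    th_gw = model.theta[9]
    out: list[PSN] = []
    total = burn + n * thin
    choices = rng.integers(0, n_free, size=total)
    us = rng.random(size=total)
    for step in range(total):
        d = choices[step]
        i, j = int(iu[d]), int(ju[d])
        logit = eta9[d] + th_gw * _gwesp_change(a, i, j, model.tau)
        if a[i, j]:  # propose removal
            if logit < 0 or us[step] < np.exp(-logit):
                a[i, j] = a[j, i] = False
        else:  # propose addition
            if logit > 0 or us[step] < np.exp(logit):
                a[i, j] = a[j, i] = True
        if step >= burn and (step - burn + 1) % thin == 0:
            out.append(PSN(a.copy(), provenance=f"sim{len(out)}"))
    return out


@dataclass
class FavorabilityResult:
    """Cross-variant log favorability of one PSN."""

    f: float
    stats_a: np.ndarray
    stats_b: np.ndarray
    provenance: str = ""


def favorability_ratio(model_a: ErgmModel, model_b: ErgmModel, psn: PSN,
                       props_a: ResidueProperties,
                       props_b: ResidueProperties) -> FavorabilityResult:
    """Log favorability of a PSN for variant B over variant A:

        f(G) = theta_b . t(G, X_b) - theta_a . t(G, X_a),

    the log probability ratio of G under the two models up to an additive
    constant (only differences between graphs are interpretable).
    """
    if model_a.term_names != model_b.term_names:
        raise ValueError("models must share the same term list")
    ta = graph_statistics(psn, props_a, model_a.tau)
    tb = graph_statistics(psn, props_b, model_b.tau)
    f = float(model_b.theta @ tb - model_a.theta @ ta)
    return FavorabilityResult(f, ta, tb, psn.provenance)


def rank_by_favorability(ensemble: list[PSN], model_a: ErgmModel,
                         model_b: ErgmModel, props_a: ResidueProperties,
                         props_b: ResidueProperties, top: int = 5):
    """Top-`top` PSNs most favored by variant B and by variant A.

    Returns (favored_b, favored_a, table): two lists of (PSN,
    FavorabilityResult) and the full score table.  Ties break on provenance.
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    results = [favorability_ratio(model_a, model_b, g, props_a, props_b)
               for g in ensemble]
    order = sorted(range(len(ensemble)),
                   key=lambda k: (-results[k].f, str(results[k].provenance)))
    fav_b = [(ensemble[k], results[k]) for k in order[:top]]
    order_a = sorted(range(len(ensemble)),
                     key=lambda k: (results[k].f, str(results[k].provenance)))
    fav_a = [(ensemble[k], results[k]) for k in order_a[:top]]
    table = pd.DataFrame({
        "provenance": [r.provenance for r in results],
        "favorability": [r.f for r in results],
    })
    return fav_b, fav_a, table
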