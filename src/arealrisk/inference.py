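"""MCMC inference for the spatiotemporal Poisson relative-risk model.

The observation model is

    Y_it | mu_it ~ Poisson(E_it * mu_it)
    log mu_it = alpha + x_it' beta + phi_i + delta_it

with expected counts ``E_it`` as offset, areal spatial effect ``phi_i``
and independent-normal space-time interaction ``delta_it`` (Knorr-Held
Type I).  ``phi`` carries one of several priors:

* ``bym``          — phi_i = u_i + v_i, u ~ ICAR(tau_u) with sum-to-zero
                     per connected component, v ~ iid N(0, 1/tau_v);
* ``besag_proper`` — phi ~ N(0, [tau*(D - gamma*W)]^-1), gamma in [0,1);
* ``leroux``       — phi ~ N(0, [(rho*(D-W) + (1-rho)*I)/sigma2]^-1);
* ``iid``          — phi ~ iid N(0, 1/tau);
* ``none``         — phi = 0.

Posterior sampling is by adaptive Metropolis-within-Gibbs:

* a joint adaptive-Metropolis block for (alpha, beta), with covariates
  centred internally so the intercept and slopes decorrelate;
* graph-coloured single-site random-walk updates for CAR fields (areas
  of one colour share no edge, so a whole colour class updates in one
  vectorised step);
* fully vectorised single-site updates for iid effects and the
  interaction (their full conditionals are independent);
* conjugate Gibbs draws for the Gamma-priored precisions;
* reflected random walks for rho / gamma with log-determinants from a
  one-off eigendecomposition of the adjacency structure.

Proposal scales adapt only during warm-up (Robbins-Monro towards the
standard acceptance targets) and are frozen afterwards.  Split-R-hat
and bulk ESS come from ``arviz``; a ``ConvergenceWarning`` is raised
when any monitored scalar exceeds R-hat 1.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .lattice import Lattice

__all__ = [
    "HyperPriors",
    "ModelSpec",
    "Posterior",
    "ConvergenceWarning",
    "fit",
    "rr_covariates",
    "fitted_rr",
    "exceedance",
]

_FAMILIES = ("bym", "besag_proper", "leroux", "iid", "none")


class ConvergenceWarning(UserWarning):
    """Sampler diagnostics exceeded their thresholds."""


@dataclass(frozen=True)
class HyperPriors:
    """Hyperprior settings (weakly informative defaults).

    Fixed effects get independent N(0, sd^2) priors on the log-RR
    scale; random-effect precisions get Gamma(shape, rate); rho is
    Uniform(0, 1) and gamma Uniform(0, gamma_max).  ``fixed`` pins
    named hyperparameters (e.g. ``{"tau_phi": 4.0}``) instead of
    sampling them — useful for oracle comparisons.
    """

    alpha_sd: float = 10.0
    beta_sd: float = 10.0
    prec_shape: float = 1.0
    prec_rate: float = 0.01
    gamma_max: float = 0.99
    fixed: Mapping[str, float] | None = None

    def __post_init__(self):
        for name in ("alpha_sd", "beta_sd", "prec_shape", "prec_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.gamma_max < 1:
            raise ValueError("gamma_max must lie in (0, 1)")

    def fixed_value(self, name):
        return None if self.fixed is None else self.fixed.get(name)


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration: spatial prior, interaction, covariates."""

    spatial_family: str = "bym"
    interaction: bool = True
    covariates: tuple = ()
    hyperpriors: HyperPriors = field(default_factory=HyperPriors)
    temporal_trend: bool = False  # optional yearly main effect, off by default

    def __post_init__(self):
        if self.spatial_family not in _FAMILIES:
            raise ValueError(
                f"unknown spatial family {self.spatial_family!r}; "
                f"expected one of {_FAMILIES}"
            )
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class Posterior:
    """Retained MCMC draws plus the data they condition on.

    ``draws[name]`` has shape ``(chains, S, ...)``.  ``alpha`` is stored
    on the original (uncentred-covariate) scale; ``alpha_c`` is the
    internally centred intercept actually sampled.
    """

    draws: dict
    area_ids: tuple
    years: tuple
    covariates: tuple
    X: np.ndarray        # (n, T, p), uncentred design
    xbar: np.ndarray     # (p,) covariate means used for centring
    Y: np.ndarray        # (n, T)
    E: np.ndarray        # (n, T)
    spec: ModelSpec
    seed: int
    chains: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        ac = self.draws["alpha_c"]
        return int(ac.shape[0] * ac.shape[1])

    def alpha(self) -> np.ndarray:
        """Intercept draws on the original (uncentred-covariate) scale."""
        ac = self.stacked("alpha_c")
        if len(self.covariates) == 0:
            return ac
        return ac - self.stacked("beta") @ self.xbar

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter with chains flattened: (S_total, ...)."""
        d = self.draws[name]
        return d.reshape((-1,) + d.shape[2:])

    def linear_predictor(self) -> np.ndarray:
        """Per-draw log relative risk, shape (S_total, n, T)."""
        n, T, p = self.X.shape
        ac = self.stacked("alpha_c")                      # (S,)
        lp = np.tile(ac[:, None, None], (1, n, T))
        if p:
            beta = self.stacked("beta")                   # (S, p)
            Xc = (self.X - self.xbar).reshape(n * T, p)
            lp += (beta @ Xc.T).reshape(-1, n, T)
        if "phi" in self.draws:
            lp += self.stacked("phi")[:, :, None]
        if "delta" in self.draws:
            lp += self.stacked("delta")
        if "gamma_t" in self.draws:
            lp += self.stacked("gamma_t")[:, None, :]
        return lp

    def mu(self) -> np.ndarray:
        """Per-draw relative-risk surface exp(linear predictor)."""
        return np.exp(self.linear_predictor())


# ---------------------------------------------------------------------------
# data preparation


def _prepare(panel, covariates, lattice, spec):
    need = {"area_id", "year", "Y", "E"}
    if not need <= set(panel.columns):
        raise ValueError(f"panel must have columns {sorted(need)}")
    ids = [str(a) for a in lattice.area_ids]
    years = sorted(panel["year"].unique())
    pnl = panel.set_index(["area_id", "year"])
    if set(panel["area_id"].astype(str)) != set(ids):
        raise ValueError("panel areas do not match the lattice")
    n, T = len(ids), len(years)
    Y = np.empty((n, T))
    E = np.empty((n, T))
    for i, a in enumerate(ids):
        for t_idx, t in enumerate(years):
            row = pnl.loc[(a, t)]
            Y[i, t_idx] = row["Y"]
            E[i, t_idx] = row["E"]
    if np.any(E <= 0):
        raise ValueError("expected counts must be strictly positive")

    p = len(spec.covariates)
    X = np.zeros((n, T, p))
    if p:
        if covariates is None:
            raise ValueError("model names covariates but none supplied")
        missing = set(spec.covariates) - set(covariates.columns)
        if missing:
            raise ValueError(f"covariate table lacks {sorted(missing)}")
        cov = covariates.set_index(["area_id", "year"])
        for i, a in enumerate(ids):
            for t_idx, t in enumerate(years):
                row = cov.loc[(a, t)]
                X[i, t_idx] = [row[c] for c in spec.covariates]
        if np.isnan(X).any():
            raise ValueError("covariate table has missing cells")
    return ids, years, Y, E, X


def _color_classes(lattice: Lattice) -> list[np.ndarray]:
    """Greedy proper colouring: within a class no two areas are adjacent."""
    import networkx as nx

    G = nx.from_scipy_sparse_array(lattice.W)
    coloring = nx.greedy_color(G, strategy="largest_first")
    ncol = max(coloring.values()) + 1 if coloring else 1
    classes = [[] for _ in range(ncol)]
    for node, c in coloring.items():
        classes[c].append(node)
    return [np.array(sorted(c), dtype=int) for c in classes if c]


# ---------------------------------------------------------------------------
# sampler


def _expc(x):
    """exp with the argument capped to avoid overflow on drifting chains."""
    return np.exp(np.minimum(x, 700.0))


class _Chain:
    """One MCMC chain; all state arrays are in lattice / year order."""

    def __init__(self, Y, E, Xc, lattice, spec, rng, prior_only=False):
        self.Y, self.E, self.Xc = Y, E, Xc
        self.n, self.T, self.p = Xc.shape
        self.spec = spec
        self.hp = spec.hyperpriors
        self.rng = rng
        self.like = 0.0 if prior_only else 1.0
        self.family = spec.spatial_family

        self.deg = lattice.n_neighbors.astype(float)
        self.W = lattice.W
        ncomp, labels = lattice.components()
        self.ncomp, self.labels = ncomp, labels
        self.colors = _color_classes(lattice) if self.family in (
            "bym", "besag_proper", "leroux"
        ) else []
        self.Wrows = [self.W[c] for c in self.colors]

        L = (sp.diags(self.deg) - self.W).toarray()
        if self.family == "leroux":
            self.lap_evals = np.linalg.eigvalsh(L)
        if self.family == "besag_proper":
            pos = self.deg > 0
            if pos.any():
                Dh = np.diag(1.0 / np.sqrt(self.deg[pos]))
                Wsub = self.W.toarray()[np.ix_(pos, pos)]
                self.car_evals = np.linalg.eigvalsh(Dh @ Wsub @ Dh)
            else:
                self.car_evals = np.array([])
        self.L = sp.csr_matrix(L)

        # state
        self.a = 0.0
        self.beta = np.zeros(self.p)
        self.u = np.zeros(self.n)
        self.v = np.zeros(self.n)
        self.phi = np.zeros(self.n)
        self.delta = np.zeros((self.n, self.T))
        self.gam_t = np.zeros(self.T)
        self.tau_u = self._init_prec("tau_u")
        self.tau_v = self._init_prec("tau_v")
        self.tau_phi = self._init_prec("tau_phi")
        self.tau_delta = self._init_prec("tau_delta")
        self.tau_gam = self._init_prec("tau_gam")
        self.rho = self._hp_or("rho", 0.5)
        self.car_gamma = self._hp_or("gamma", 0.5)

        # start (alpha, beta) at the fixed-effects Poisson MLE (IWLS):
        # burn-in shortens and the AM proposal starts near the right scale
        self._iwls_cov = None
        self._init_fixed_effects()

        self.eta = np.full((self.n, self.T), self.a)
        if self.p:
            self.eta += self.Xc.reshape(-1, self.p).dot(self.beta).reshape(
                self.n, self.T
            )
        self.M = self.E * np.exp(self.eta)  # Poisson means
        self.Ysum = Y.sum(axis=1)

        # covariate/spatial-field ridge-move precomputations: the
        # per-area time-mean of each centred covariate is the direction
        # along which x'beta and the spatial field trade off
        if self.p and self.family != "none":
            A = self.Xc.mean(axis=1)                         # (n, p)
            self.A_ridge = A
            self.Xdev = self.Xc - A[:, None, :]              # (n, T, p)
            L = self.L
            self.La = L @ A                                  # (n, p)
            self.aLa = np.einsum("np,np->p", A, self.La)
            self.aa = np.einsum("np,np->p", A, A)
            Wa = self.W @ A
            self.Wa = Wa
            self.aWa = np.einsum("np,np->p", A, Wa)
            dtil = np.where(self.deg > 0, self.deg, 1.0)
            self.da_ridge = dtil[:, None] * A
            self.ada = np.einsum("np,np->p", A, self.da_ridge)
        else:
            self.A_ridge = None

        # adaptation state
        d = self.p + 1
        self.am_mean = np.zeros(d)
        self.am_cov = np.eye(d) * 1e-4
        self.am_count = 0
        self.am_log_lam = np.log(0.1 / np.sqrt(d))
        self.am_chol = np.eye(d) * 0.1 / np.sqrt(d)
        if self._iwls_cov is not None:
            self.am_cov = self._iwls_cov
            self.am_log_lam = 0.0
            try:
                self.am_chol = np.linalg.cholesky(
                    (2.38**2 / d) * (self._iwls_cov + 1e-12 * np.eye(d))
                )
            except np.linalg.LinAlgError:
                pass
        self.ls_ridge = np.full(self.p, np.log(0.05))
        self.ls_u = np.full(self.n, np.log(0.5))
        self.ls_v = np.full(self.n, np.log(0.5))
        self.ls_phi = np.full(self.n, np.log(0.5))
        self.ls_delta = np.full((self.n, self.T), np.log(0.8))
        self.ls_gam = np.full(self.T, np.log(0.3))
        self.ls_rho = np.log(0.2)
        self.ls_cgam = np.log(0.2)
        self.ls_scale_u = np.log(0.2)
        self.ls_scale_v = np.log(0.2)
        self.ls_scale_phi = np.log(0.2)
        self.ls_scale_delta = np.log(0.2)
        self.adapting = True
        self._sweep = 0

    def _init_fixed_effects(self):
        """A few IWLS steps on the fixed-effects-only Poisson model."""
        if self.like == 0.0:
            return
        nT = self.n * self.T
        Z = np.column_stack([np.ones(nT)] + (
            [self.Xc.reshape(-1, self.p)] if self.p else []
        ))
        y = self.Y.ravel()
        e = self.E.ravel()
        th = np.zeros(self.p + 1)
        th[0] = np.log(max(y.sum(), 1.0) / e.sum())
        try:
            for _ in range(25):
                lam = e * np.exp(np.clip(Z @ th, -30, 30))
                g = Z.T @ (y - lam)
                H = (Z * lam[:, None]).T @ Z + 1e-8 * np.eye(self.p + 1)
                step = np.linalg.solve(H, g)
                th = th + step
                if np.abs(step).max() < 1e-10:
                    break
            if np.all(np.isfinite(th)):
                self.a = float(th[0])
                self.beta = th[1:].copy()
                self._iwls_cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            pass

    def _init_prec(self, name):
        fixed = self.hp.fixed_value(name)
        return float(fixed) if fixed is not None else 1.0

    def _hp_or(self, name, default):
        fixed = self.hp.fixed_value(name)
        return float(fixed) if fixed is not None else default

    # -- update blocks ------------------------------------------------------

    def _rm_step(self):
        """Robbins-Monro step size for scale adaptation."""
        return min(0.1, 1.0 / np.sqrt(1 + self._sweep / 10))

    def update_fixed_effects(self):
        d = self.p + 1
        th = np.concatenate(([self.a], self.beta))
        prop = th + self.am_chol @ self.rng.standard_normal(d)
        da = prop[0] - self.a
        if self.p:
            dlin = da + (self.Xc.reshape(-1, self.p) @ (prop[1:] - self.beta)).reshape(
                self.n, self.T
            )
        else:
            dlin = np.full((self.n, self.T), da)
        M_new = self.M * _expc(dlin)
        dll = self.like * np.sum(self.Y * dlin - (M_new - self.M))
        sds = np.concatenate(([self.hp.alpha_sd], np.full(self.p, self.hp.beta_sd)))
        dlp = -0.5 * np.sum((prop**2 - th**2) / sds**2)
        accept = np.log(self.rng.uniform()) < dll + dlp
        if accept:
            self.a, self.beta = prop[0], prop[1:].copy()
            self.eta = self.eta + dlin
            self.M = M_new
        if self.adapting:
            self.am_count += 1
            w = 1.0 / (self.am_count + 1)
            cur = np.concatenate(([self.a], self.beta))
            dm = cur - self.am_mean
            self.am_mean += w * dm
            self.am_cov = (1 - w) * self.am_cov + w * np.outer(dm, dm)
            self.am_log_lam += self._rm_step() * ((1.0 if accept else 0.0) - 0.25)
            if self.am_count >= 50 and self.am_count % 25 == 0:
                cov = (2.38**2 / d) * np.exp(2 * self.am_log_lam) * (
                    self.am_cov + 1e-9 * np.eye(d)
                )
                try:
                    self.am_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    pass

    def _site_update(self, idx, x, dx, prior_prec, prior_mean, ls, key):
        """Vectorised single-site MH for areas in idx (no two adjacent)."""
        Msum = self.M[idx].sum(axis=1)
        dll = self.like * (self.Ysum[idx] * dx - Msum * np.expm1(dx))
        xn = x[idx] + dx
        dlp = -0.5 * prior_prec * ((xn - prior_mean) ** 2 - (x[idx] - prior_mean) ** 2)
        acc = np.log(self.rng.uniform(size=idx.size)) < dll + dlp
        if acc.any():
            sel = idx[acc]
            x[sel] += dx[acc]
            self.eta[sel] += dx[acc][:, None]
            self.M[sel] *= _expc(dx[acc])[:, None]
        if self.adapting:
            ls[idx] += self._rm_step() * (acc.astype(float) - 0.44)

    def update_u(self):
        for C, Wc in zip(self.colors, self.Wrows):
            mask = self.deg[C] > 0
            idx = C[mask]
            if idx.size == 0:
                continue
            nb = np.asarray(Wc.dot(self.u)).ravel()[mask]
            degc = self.deg[idx]
            dx = np.exp(self.ls_u[idx]) * self.rng.standard_normal(idx.size)
            self._site_update(idx, self.u, dx, self.tau_u * degc, nb / degc,
                              self.ls_u, "u")
        # recentre per component, absorbing the mean shift into the intercept
        self._recenter_u()

    def update_v(self):
        dx = np.exp(self.ls_v) * self.rng.standard_normal(self.n)
        Msum = self.M.sum(axis=1)
        dll = self.like * (self.Ysum * dx - Msum * np.expm1(dx))
        vn = self.v + dx
        dlp = -0.5 * self.tau_v * (vn**2 - self.v**2)
        acc = np.log(self.rng.uniform(size=self.n)) < dll + dlp
        if acc.any():
            self.v[acc] += dx[acc]
            self.eta[acc] += dx[acc][:, None]
            self.M[acc] *= _expc(dx[acc])[:, None]
        if self.adapting:
            self.ls_v += self._rm_step() * (acc.astype(float) - 0.44)
        self.phi = self.u + self.v

    def update_phi_car(self):
        """Single-field CAR updates (leroux / besag_proper / iid)."""
        if self.family == "iid":
            dx = np.exp(self.ls_phi) * self.rng.standard_normal(self.n)
            Msum = self.M.sum(axis=1)
            dll = self.like * (self.Ysum * dx - Msum * np.expm1(dx))
            pn = self.phi + dx
            dlp = -0.5 * self.tau_phi * (pn**2 - self.phi**2)
            acc = np.log(self.rng.uniform(size=self.n)) < dll + dlp
            if acc.any():
                self.phi[acc] += dx[acc]
                self.eta[acc] += dx[acc][:, None]
                self.M[acc] *= _expc(dx[acc])[:, None]
            if self.adapting:
                self.ls_phi += self._rm_step() * (acc.astype(float) - 0.44)
            return
        for C, Wc in zip(self.colors, self.Wrows):
            nb = np.asarray(Wc.dot(self.phi)).ravel()
            degc = self.deg[C]
            if self.family == "leroux":
                cond_prec = self.tau_phi * (self.rho * degc + 1 - self.rho)
                cond_mean = self.rho * nb / (self.rho * degc + 1 - self.rho)
            else:  # besag_proper; isolated areas fall back to iid precision
                cond_prec = self.tau_phi * np.where(degc > 0, degc, 1.0)
                cond_mean = np.where(
                    degc > 0, self.car_gamma * nb / np.maximum(degc, 1.0), 0.0
                )
            dx = np.exp(self.ls_phi[C]) * self.rng.standard_normal(C.size)
            self._site_update(C, self.phi, dx, cond_prec, cond_mean,
                              self.ls_phi, "phi")

    def update_ridge(self):
        """Trade a coefficient change against the spatial field.

        Covariates that vary mostly in space are near-confounded with
        the spatial effect: the likelihood constrains x'beta + phi but
        only the field prior separates them.  This move proposes
        beta_j -> beta_j + db while subtracting the per-area time-mean
        pattern from the field, so the chain walks along that ridge;
        acceptance is governed by the (cheap) field and coefficient
        priors plus the small likelihood change from the time-varying
        covariate component.
        """
        if self.A_ridge is None:
            return
        fam = self.family
        field = self.u if fam == "bym" else self.phi
        for j in range(self.p):
            db = np.exp(self.ls_ridge[j]) * self.rng.standard_normal()
            a_j = self.A_ridge[:, j]
            if fam == "bym":
                s1 = self.tau_u * self.aLa[j]
                s2 = self.tau_u * float(field @ self.La[:, j])
            elif fam == "leroux":
                s1 = self.tau_phi * (
                    self.rho * self.aLa[j] + (1 - self.rho) * self.aa[j]
                )
                s2 = self.tau_phi * (
                    self.rho * float(field @ self.La[:, j])
                    + (1 - self.rho) * float(field @ a_j)
                )
            elif fam == "besag_proper":
                s1 = self.tau_phi * (self.ada[j] - self.car_gamma * self.aWa[j])
                s2 = self.tau_phi * (
                    float(field @ self.da_ridge[:, j])
                    - self.car_gamma * float(field @ self.Wa[:, j])
                )
            else:  # iid
                s1 = self.tau_phi * self.aa[j]
                s2 = self.tau_phi * float(field @ a_j)
            # field prior: -(1/2)[(f - a db)' M (f - a db) - f' M f]
            dlp_field = -0.5 * db**2 * s1 + db * s2
            dlp_beta = -(2 * self.beta[j] * db + db**2) / (2 * self.hp.beta_sd**2)
            deta = self.Xdev[:, :, j] * db
            M_new = self.M * _expc(deta)
            dll = self.like * np.sum(self.Y * deta - (M_new - self.M))
            acc = np.log(self.rng.uniform()) < dll + dlp_field + dlp_beta
            if acc:
                self.beta[j] += db
                field -= a_j * db
                self.eta += deta
                self.M = M_new
            if self.adapting:
                self.ls_ridge[j] += self._rm_step() * ((1.0 if acc else 0.0) - 0.44)
        if fam == "bym":
            self._recenter_u()
        else:
            self.phi = field

    def _recenter_u(self):
        shifts = np.zeros(self.n)
        for c in range(self.ncomp):
            m = self.labels == c
            shifts[m] = self.u[m].mean()
        da = shifts.mean()
        self.u -= shifts
        self.a += da
        deta = da - shifts
        if np.abs(deta).max() > 1e-14:
            self.eta += deta[:, None]
            self.M *= _expc(deta)[:, None]
        self.phi = self.u + self.v

    def update_delta(self):
        dx = np.exp(self.ls_delta) * self.rng.standard_normal((self.n, self.T))
        dll = self.like * (self.Y * dx - self.M * np.expm1(dx))
        dn = self.delta + dx
        dlp = -0.5 * self.tau_delta * (dn**2 - self.delta**2)
        acc = np.log(self.rng.uniform(size=(self.n, self.T))) < dll + dlp
        self.delta = np.where(acc, dn, self.delta)
        self.eta = np.where(acc, self.eta + dx, self.eta)
        self.M = np.where(acc, self.M * _expc(dx), self.M)
        if self.adapting:
            self.ls_delta += self._rm_step() * (acc.astype(float) - 0.44)
        # centre per year; the mean level moves to the intercept (or the
        # yearly trend when one is in the model)
        m_t = self.delta.mean(axis=0)
        self.delta -= m_t[None, :]
        if self.spec.temporal_trend:
            self.gam_t += m_t
        else:
            da = m_t.mean()
            self.a += da
            deta = da - m_t
            if np.abs(deta).max() > 1e-14:
                self.eta += deta[None, :]
                self.M *= _expc(deta)[None, :]

    def _scale_move(self, field_name, tau_attr, quad_fn, dim_eff, ls_attr):
        """Joint rescale (f, tau) -> (c*f, tau/c^2) of one random-effect
        field and its precision.

        This is the non-centred move that traverses the variance funnel
        single-site updates cross slowly: the Gaussian field prior is
        invariant under the map, so acceptance reduces to the likelihood
        change plus the Gamma prior on the precision (or, when the
        precision is pinned, the field prior quadratic form).
        """
        f = getattr(self, field_name)
        c = np.exp(np.exp(getattr(self, ls_attr)) * self.rng.standard_normal())
        deta = (c - 1.0) * (f[:, None] if f.ndim == 1 else f)
        M_new = self.M * _expc(deta)
        dll = self.like * np.sum(self.Y * deta - (M_new - self.M))
        tau = getattr(self, tau_attr)
        tau_fixed = self.hp.fixed_value(tau_attr) is not None
        if tau_fixed:
            quad = quad_fn()
            dlp = -0.5 * tau * (c**2 - 1.0) * quad + dim_eff * np.log(c)
        else:
            tau_new = tau / c**2
            dlp = -2.0 * self.hp.prec_shape * np.log(c) - self.hp.prec_rate * (
                tau_new - tau
            )
        acc = np.log(self.rng.uniform()) < dll + dlp
        if acc:
            setattr(self, field_name, f * c)
            if not tau_fixed:
                setattr(self, tau_attr, tau / c**2)
            self.eta = self.eta + deta
            self.M = M_new
        if self.adapting:
            setattr(
                self, ls_attr,
                getattr(self, ls_attr) + self._rm_step() * ((1.0 if acc else 0.0) - 0.3),
            )
        return acc

    def update_scales(self):
        if self.family == "bym":
            self._scale_move(
                "u", "tau_u",
                lambda: float(self.u @ (self.L @ self.u)),
                self.n - self.ncomp, "ls_scale_u",
            )
            self._scale_move(
                "v", "tau_v", lambda: float(self.v @ self.v),
                self.n, "ls_scale_v",
            )
            self.phi = self.u + self.v
        elif self.family == "leroux":
            def q():
                return (
                    self.rho * float(self.phi @ (self.L @ self.phi))
                    + (1 - self.rho) * float(self.phi @ self.phi)
                )
            self._scale_move("phi", "tau_phi", q, self.n, "ls_scale_phi")
        elif self.family == "besag_proper":
            def q():
                dtil = np.where(self.deg > 0, self.deg, 1.0)
                return (
                    float(np.sum(dtil * self.phi**2))
                    - self.car_gamma * float(self.phi @ (self.W @ self.phi))
                )
            self._scale_move("phi", "tau_phi", q, self.n, "ls_scale_phi")
        elif self.family == "iid":
            self._scale_move(
                "phi", "tau_phi", lambda: float(self.phi @ self.phi),
                self.n, "ls_scale_phi",
            )
        if self.spec.interaction:
            # delta is centred per year, so the field-only variant lives
            # on an (n-1)*T-dimensional subspace
            self._scale_move(
                "delta", "tau_delta",
                lambda: float(np.sum(self.delta**2)),
                (self.n - 1) * self.T, "ls_scale_delta",
            )

    def update_gamma_t(self):
        dx = np.exp(self.ls_gam) * self.rng.standard_normal(self.T)
        Ycol = self.Y.sum(axis=0)
        Mcol = self.M.sum(axis=0)
        dll = self.like * (Ycol * dx - Mcol * np.expm1(dx))
        gn = self.gam_t + dx
        dlp = -0.5 * self.tau_gam * (gn**2 - self.gam_t**2)
        acc = np.log(self.rng.uniform(size=self.T)) < dll + dlp
        if acc.any():
            self.gam_t[acc] += dx[acc]
            self.eta[:, acc] += dx[acc][None, :]
            self.M[:, acc] *= _expc(dx[acc])[None, :]
        if self.adapting:
            self.ls_gam += self._rm_step() * (acc.astype(float) - 0.44)
        # centre exactly, absorbing into the intercept
        m = self.gam_t.mean()
        self.gam_t -= m
        self.a += m

    def _gibbs_prec(self, name, shape_add, quad):
        if self.hp.fixed_value(name) is not None:
            return getattr(self, name)
        return self.rng.gamma(
            self.hp.prec_shape + shape_add, 1.0 / (self.hp.prec_rate + 0.5 * quad)
        )

    def update_hyper(self):
        if self.family == "bym":
            quad_u = float(self.u @ (self.L @ self.u))
            self.tau_u = self._gibbs_prec("tau_u", (self.n - self.ncomp) / 2, quad_u)
            self.tau_v = self._gibbs_prec("tau_v", self.n / 2, float(self.v @ self.v))
        elif self.family == "leroux":
            quad = self.rho * float(self.phi @ (self.L @ self.phi)) + (
                1 - self.rho
            ) * float(self.phi @ self.phi)
            self.tau_phi = self._gibbs_prec("tau_phi", self.n / 2, quad)
            self._update_rho()
        elif self.family == "besag_proper":
            qD = float(np.sum(np.where(self.deg > 0, self.deg, 1.0) * self.phi**2))
            qW = float(self.phi @ (self.W @ self.phi))
            self.tau_phi = self._gibbs_prec(
                "tau_phi", self.n / 2, qD - self.car_gamma * qW
            )
            self._update_car_gamma(qD, qW)
        elif self.family == "iid":
            self.tau_phi = self._gibbs_prec(
                "tau_phi", self.n / 2, float(self.phi @ self.phi)
            )
        if self.spec.interaction:
            self.tau_delta = self._gibbs_prec(
                "tau_delta", self.n * self.T / 2, float(np.sum(self.delta**2))
            )
        if self.spec.temporal_trend:
            self.tau_gam = self._gibbs_prec(
                "tau_gam", self.T / 2, float(self.gam_t @ self.gam_t)
            )

    def _rho_logpost(self, rho):
        lam = self.lap_evals
        with np.errstate(divide="ignore"):
            logdet = np.sum(np.log(np.maximum(rho * lam + 1 - rho, 0.0)))
        if not np.isfinite(logdet):
            return -np.inf
        quad = rho * self._qL + (1 - rho) * self._qI
        return 0.5 * logdet - 0.5 * self.tau_phi * quad

    def _update_rho(self):
        if self.hp.fixed_value("rho") is not None:
            return
        self._qL = float(self.phi @ (self.L @ self.phi))
        self._qI = float(self.phi @ self.phi)
        prop = self.rho + np.exp(self.ls_rho) * self.rng.standard_normal()
        # reflect into [0, 1]
        prop = abs(prop) % 2.0
        prop = 2.0 - prop if prop > 1.0 else prop
        lr = self._rho_logpost(prop) - self._rho_logpost(self.rho)
        acc = np.log(self.rng.uniform()) < lr
        if acc:
            self.rho = prop
        if self.adapting:
            self.ls_rho += self._rm_step() * ((1.0 if acc else 0.0) - 0.44)

    def _cgam_logpost(self, g, qD, qW):
        with np.errstate(divide="ignore", invalid="ignore"):
            logdet = np.sum(np.log(np.maximum(1 - g * self.car_evals, 0.0)))
        if not np.isfinite(logdet):
            return -np.inf
        return 0.5 * logdet - 0.5 * self.tau_phi * (qD - g * qW)

    def _update_car_gamma(self, qD, qW):
        if self.hp.fixed_value("gamma") is not None:
            return
        gmax = self.hp.gamma_max
        prop = self.car_gamma + np.exp(self.ls_cgam) * self.rng.standard_normal()
        prop = abs(prop) % (2 * gmax)
        prop = 2 * gmax - prop if prop > gmax else prop
        lr = self._cgam_logpost(prop, qD, qW) - self._cgam_logpost(
            self.car_gamma, qD, qW
        )
        acc = np.log(self.rng.uniform()) < lr
        if acc:
            self.car_gamma = prop
        if self.adapting:
            self.ls_cgam += self._rm_step() * ((1.0 if acc else 0.0) - 0.44)

    def sweep(self):
        self._sweep += 1
        self.update_fixed_effects()
        if self.family == "bym":
            self.update_u()
            self.update_v()
        elif self.family in ("leroux", "besag_proper", "iid"):
            self.update_phi_car()
        self.update_ridge()
        if self.spec.temporal_trend:
            self.update_gamma_t()
        if self.spec.interaction:
            self.update_delta()
        self.update_scales()
        self.update_hyper()


def fit(
    panel: pd.DataFrame,
    covariates: pd.DataFrame | None,
    lattice: Lattice,
    spec: ModelSpec,
    chains: int = 2,
    iters: int = 2000,
    warmup: int | None = None,
    thin: int = 1,
    seed: int = 0,
    prior_only: bool = False,
) -> Posterior:
    """Sample the joint posterior of the relative-risk model by MCMC.

    Parameters
    ----------
    panel
        Area x year DataFrame with ``area_id, year, Y, E`` (``E`` from
        :func:`arealrisk.standardize.expected_counts`).
    covariates
        Area x year DataFrame carrying every column named in
        ``spec.covariates`` (ignored for intercept-only models).
    chains, iters, warmup, thin
        ``iters`` post-warmup iterations per chain (thinned by
        ``thin``); warm-up defaults to ``iters`` and is where proposal
        adaptation happens.
    prior_only
        Drop the likelihood: draws then target the prior, which is how
        prior-predictive checks are run.
    """
    ids, years, Y, E, X = _prepare(panel, covariates, lattice, spec)
    n, T, p = X.shape
    xbar = X.reshape(-1, p).mean(axis=0) if p else np.zeros(0)
    Xc = X - xbar if p else X
    warmup = iters if warmup is None else warmup
    keep = iters // thin
    if keep < 1:
        raise ValueError("iters/thin must be at least 1")

    names = ["alpha_c", "beta", "phi", "delta"]
    store = {
        "alpha_c": np.empty((chains, keep)),
        "beta": np.empty((chains, keep, p)),
        "phi": np.empty((chains, keep, n)),
        "delta": np.empty((chains, keep, n, T)),
    }
    fam = spec.spatial_family
    if fam == "bym":
        store["u"] = np.empty((chains, keep, n))
        store["v"] = np.empty((chains, keep, n))
        store["tau_u"] = np.empty((chains, keep))
        store["tau_v"] = np.empty((chains, keep))
    elif fam in ("leroux", "besag_proper", "iid"):
        store["tau_phi"] = np.empty((chains, keep))
        if fam == "leroux":
            store["rho"] = np.empty((chains, keep))
        if fam == "besag_proper":
            store["gamma"] = np.empty((chains, keep))
    if spec.interaction:
        store["tau_delta"] = np.empty((chains, keep))
    if spec.temporal_trend:
        store["gamma_t"] = np.empty((chains, keep, T))

    for c in range(chains):
        rng = np.random.default_rng([int(seed), c])
        chain = _Chain(Y, E, Xc, lattice, spec, rng, prior_only=prior_only)
        for _ in range(warmup):
            chain.sweep()
        chain.adapting = False
        k = 0
        for it in range(iters):
            chain.sweep()
            if (it + 1) % thin == 0 and k < keep:
                store["alpha_c"][c, k] = chain.a
                store["beta"][c, k] = chain.beta
                store["phi"][c, k] = chain.phi
                store["delta"][c, k] = chain.delta
                if fam == "bym":
                    store["u"][c, k] = chain.u
                    store["v"][c, k] = chain.v
                    store["tau_u"][c, k] = chain.tau_u
                    store["tau_v"][c, k] = chain.tau_v
                elif fam in ("leroux", "besag_proper", "iid"):
                    store["tau_phi"][c, k] = chain.tau_phi
                    if fam == "leroux":
                        store["rho"][c, k] = chain.rho
                    if fam == "besag_proper":
                        store["gamma"][c, k] = chain.car_gamma
                if spec.interaction:
                    store["tau_delta"][c, k] = chain.tau_delta
                if spec.temporal_trend:
                    store["gamma_t"][c, k] = chain.gam_t
                k += 1

    post = Posterior(
        draws=store,
        area_ids=tuple(ids),
        years=tuple(int(t) for t in years),
        covariates=spec.covariates,
        X=X,
        xbar=xbar,
        Y=Y,
        E=E,
        spec=spec,
        seed=int(seed),
        chains=chains,
    )
    post.diagnostics = _diagnose(post)
    return post


def _diagnose(post: Posterior) -> dict:
    """Split-R-hat and bulk ESS on the monitored scalars via arviz."""
    import arviz as az

    monitored = {"alpha_c": post.draws["alpha_c"]}
    for j, name in enumerate(post.covariates):
        monitored[f"beta_{name}"] = post.draws["beta"][:, :, j]
    # under BYM only u+v is identified, so the monitored spatial scalar
    # is the realised spread of phi rather than the separate precisions
    if post.spec.spatial_family != "none":
        monitored["sd_phi"] = post.draws["phi"].std(axis=-1)
    for name in ("tau_delta", "rho", "gamma"):
        if name in post.draws:
            monitored[name] = post.draws[name]
    if post.chains == 1:
        # arviz needs >= 2 chains; halve the single chain (split R-hat)
        monitored = {
            k: v[:, : v.shape[1] // 2 * 2].reshape(2, -1)
            for k, v in monitored.items()
        }
    idata = az.from_dict({k: v for k, v in monitored.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    diag = {
        "rhat": {k: float(rhat[k].values) for k in monitored},
        "ess_bulk": {k: float(ess[k].values) for k in monitored},
    }
    worst = max(diag["rhat"].values())
    diag["max_rhat"] = worst
    diag["min_ess"] = min(diag["ess_bulk"].values())
    if worst > 1.01:
        bad = [k for k, v in diag["rhat"].items() if v > 1.01]
        warnings.warn(
            f"split R-hat exceeds 1.01 for {bad}; consider longer chains",
            ConvergenceWarning,
        )
    return diag


# ---------------------------------------------------------------------------
# posterior summaries


def rr_covariates(posterior: Posterior) -> pd.DataFrame:
    """Covariate relative risks: per-draw exp(beta), posterior mean and
    equal-tailed 95% credible interval, one row per covariate."""
    if len(posterior.covariates) == 0:
        raise ValueError("posterior has no covariate coefficients")
    rr = np.exp(posterior.stacked("beta"))
    lo, hi = np.percentile(rr, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "covariate": list(posterior.covariates),
            "RR": rr.mean(axis=0),
            "RR_lo": lo,
            "RR_hi": hi,
        }
    )


def fitted_rr(posterior: Posterior) -> pd.DataFrame:
    """Model-based relative-risk surface: posterior mean and 95% interval
    of mu_it per (area, year) — the smoothed counterpart of the SIR."""
    mu = posterior.mu()
    lo, hi = np.percentile(mu, [2.5, 97.5], axis=0)
    mean = mu.mean(axis=0)
    rows = []
    for i, a in enumerate(posterior.area_ids):
        for t_idx, t in enumerate(posterior.years):
            rows.append(
                {"area_id": a, "year": t, "RR": mean[i, t_idx],
                 "RR_lo": lo[i, t_idx], "RR_hi": hi[i, t_idx]}
            )
    return pd.DataFrame(rows)


def exceedance(posterior: Posterior, rr_threshold: float = 1.0) -> pd.DataFrame:
    """Posterior hotspot probabilities P(mu_it > threshold | data)."""
    if rr_threshold <= 0:
        raise ValueError("rr_threshold must be positive")
    mu = posterior.mu()
    prob = (mu > rr_threshold).mean(axis=0)
    rows = []
    for i, a in enumerate(posterior.area_ids):
        for t_idx, t in enumerate(posterior.years):
            rows.append({"area_id": a, "year": t, "P_exceed": prob[i, t_idx]})
    return pd.DataFrame(rows)
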