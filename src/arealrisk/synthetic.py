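"""Synthetic areal panels with known generative truth.

The real incident data this package is designed around (EMS overdose
calls in 84 Houston zip codes, 2015-2019) are not publicly deposited,
so every downstream stage is exercised on synthetic panels that share
the study's statistical structure:

* a contiguity lattice of ~84 areas over 5 yearly periods;
* populations with mean ~30,000 and coefficient of variation ~45%;
* spatially correlated socioeconomic covariates on their natural scales
  (percent renters, percent non-Hispanic white, percent crowded
  housing, ...);
* counts drawn from the log-linear relative-risk model

      Y_it ~ Poisson(E_it * mu_it),
      log mu_it = alpha + x_it' beta + phi_i + delta_it,

  with ``phi`` from a BYM / proper-CAR / Leroux prior and ``delta``
  independent normal space-time interaction (Knorr-Held Type I).

Every generator is deterministic given its seed, and
:func:`simulate_counts` returns a :class:`GeneratorTruth` that
reproduces ``log mu_it`` exactly for every cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .lattice import (
    Lattice,
    PrecisionSpec,
    grid_lattice,
    icar_precision,
    leroux_precision,
    proper_car_precision,
)

__all__ = [
    "CovariateSpec",
    "TruthSpec",
    "GeneratorTruth",
    "sample_gmrf",
    "simulate_covariates",
    "simulate_counts",
    "simulate_events",
    "events_from_panel",
    "paper_scale_scenario",
    "HOUSTON_COVARIATES",
    "HOUSTON_YEARLY_TOTALS",
]

# Yearly study totals used to build event fixtures at the study's scale.
HOUSTON_YEARLY_TOTALS = {2015: 449, 2016: 487, 2017: 473, 2018: 555, 2019: 666}


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal scale and spatial smoothness of one synthetic covariate.

    ``mean`` and ``cv`` (coefficient of variation, in percent) set the
    marginal scale; ``spatial_rho`` sets the Leroux smoothness of the
    latent field inducing spatial autocorrelation.  ``kind`` controls
    the support: ``percent`` values are clipped to [0, 100],
    ``positive`` values are generated log-normally (populations,
    income), ``raw`` values are unconstrained Gaussian.
    """

    name: str
    mean: float
    cv: float  # percent
    spatial_rho: float = 0.6
    kind: str = "percent"
    year_jitter: float = 0.1  # yearly within-area wobble, fraction of marginal sd

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("CV must be nonnegative")
        if self.kind not in ("percent", "positive", "raw"):
            raise ValueError("kind must be percent, positive or raw")
        if not 0.0 <= self.spatial_rho < 1.0:
            raise ValueError("spatial_rho must lie in [0, 1)")
        if self.year_jitter < 0:
            raise ValueError("year_jitter must be nonnegative")


# Marginal scales of the zip-code socioeconomic panel the generator
# emulates (2018 American Community Survey values for the study region;
# income in thousands of dollars).
HOUSTON_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("population", 30237, 45.5, kind="positive"),
    CovariateSpec("white", 23.8, 97.0),
    CovariateSpec("hispanic", 48.4, 53.9),
    CovariateSpec("unemployed", 4.12, 42.9),
    CovariateSpec("bachelor", 28.9, 87.1),
    CovariateSpec("crowded", 6.97, 64.3),
    CovariateSpec("renters", 50.9, 31.5),
    CovariateSpec("blue_collar", 29.2, 52.9),
    CovariateSpec("income_k", 34.586, 89.6, kind="positive"),
    CovariateSpec("poverty", 17.3, 54.7),
    CovariateSpec("uninsured", 22.5, 47.0),
)


@dataclass(frozen=True)
class TruthSpec:
    """Generating-side model configuration for :func:`simulate_counts`.

    ``rr`` maps covariate names to true relative risks per unit (log-RR
    coefficients are ``log(rr)``).  ``family`` picks the spatial prior
    for ``phi``; the sd_* fields are the generating standard deviations
    of the random effects.  ``target_total`` calibrates the baseline
    rate so the expected total count over the whole panel equals it.
    """

    family: str = "bym"
    rr: Mapping[str, float] = field(
        default_factory=lambda: {"renters": 1.03, "white": 0.97, "crowded": 0.90}
    )
    interaction: bool = True
    sd_u: float = 0.5       # BYM structured (ICAR) marginal scale
    sd_v: float = 0.3       # BYM unstructured scale
    sd_phi: float = 0.5     # Leroux / proper-CAR scale
    rho: float = 0.7        # Leroux spatial correlation
    gamma: float = 0.9      # proper-CAR propriety parameter
    sd_delta: float = 0.15  # space-time interaction scale
    target_total: float = 2630.0

    def __post_init__(self):
        if self.family not in ("bym", "leroux", "besag_proper", "iid", "none"):
            raise ValueError(f"unknown spatial family {self.family!r}")


@dataclass(frozen=True)
class GeneratorTruth:
    """Exact generative record accompanying a simulated panel.

    ``log mu_it = alpha + x_it' beta + phi_i + delta_it`` holds exactly
    for every cell; ``mu`` is the true relative-risk surface relative
    to the true pooled rate, and ``E_true`` the corresponding expected
    counts (so the Poisson mean is ``E_true * mu``).
    """

    alpha: float
    beta: dict            # covariate name -> log-RR
    phi: np.ndarray       # per area, lattice order
    u: np.ndarray | None  # BYM structured part (None otherwise)
    v: np.ndarray | None  # BYM unstructured part
    delta: np.ndarray     # (n_areas, n_years)
    mu: np.ndarray        # (n_areas, n_years) true relative risks
    E_true: np.ndarray    # (n_areas, n_years)
    family: str
    params: dict
    seed: int

    def log_mu(self, X: np.ndarray, order: Sequence[str]) -> np.ndarray:
        """Reconstruct log mu from the stored effects and a design array
        ``X`` of shape (n_areas, n_years, p) in covariate ``order``."""
        b = np.array([self.beta[c] for c in order])
        return (
            self.alpha
            + np.einsum("itp,p->it", X, b)
            + self.phi[:, None]
            + self.delta
        )


# ---------------------------------------------------------------------------
# GMRF sampling


def _dense_symmetric(precision) -> np.ndarray:
    Q = precision.toarray() if sp.issparse(precision) else np.asarray(precision, float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("precision must be square")
    if not np.allclose(Q, Q.T, atol=1e-8 * max(1.0, np.abs(Q).max())):
        raise ValueError("precision must be symmetric")
    return 0.5 * (Q + Q.T)


def sample_gmrf(
    precision,
    seed,
    sum_to_zero: bool = False,
    size: int = 1,
    components: np.ndarray | None = None,
) -> np.ndarray:
    """Draw from a Gaussian Markov random field given its precision.

    The draw is computed through the eigendecomposition of the (dense)
    precision.  A singular precision (ICAR) is only accepted with
    ``sum_to_zero``; its null directions are simply excluded, which for
    a graph Laplacian makes every draw sum to zero on each connected
    component.  With a nonsingular precision, ``sum_to_zero`` applies
    the conditioning-by-kriging correction, optionally per block of
    ``components`` labels.

    Returns an array of shape ``(n,)`` for ``size=1`` else ``(size, n)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = _dense_symmetric(precision)
    n = Q.shape[0]
    evals, evecs = np.linalg.eigh(Q)
    tol = 1e-10 * max(evals.max(), 1.0)
    null = evals < tol
    if null.any() and not sum_to_zero:
        raise ValueError(
            "singular precision requires sum_to_zero (ICAR-type prior)"
        )
    if (evals < -tol).any():
        raise ValueError("precision has negative eigenvalues")

    pos = ~null
    z = rng.standard_normal((size, int(pos.sum())))
    x = (evecs[:, pos] / np.sqrt(evals[pos])) @ z.T  # (n, size)

    if sum_to_zero and not null.any():
        # kriging correction: x - Sigma A' (A Sigma A')^{-1} A x
        labels = np.zeros(n, int) if components is None else np.asarray(components)
        A = np.stack([(labels == c).astype(float) for c in np.unique(labels)])
        Sigma_At = (evecs[:, pos] / evals[pos]) @ (evecs[:, pos].T @ A.T)
        M = A @ Sigma_At
        x = x - Sigma_At @ np.linalg.solve(M, A @ x)
    out = x.T
    return out[0] if size == 1 else out


def _standardized_field(lattice: Lattice, rho: float, rng) -> np.ndarray:
    """Leroux GMRF draw rescaled to unit marginal variance per area."""
    if rho == 0.0 or lattice.n == 1:
        return rng.standard_normal(lattice.n)
    Q = leroux_precision(lattice, rho, 1.0).toarray()
    marg_sd = np.sqrt(np.diag(np.linalg.inv(Q)))
    draw = sample_gmrf(Q, rng)
    return draw / marg_sd


# ---------------------------------------------------------------------------
# covariates


def simulate_covariates(
    lattice: Lattice,
    years: Sequence[int],
    specs: Sequence[CovariateSpec] = HOUSTON_COVARIATES,
    seed: int = 0,
) -> pd.DataFrame:
    """Area x year covariate panel with the requested marginal scales.

    Each covariate is a spatially smooth area-level surface (Leroux
    latent field standardized to unit marginal variance, scaled to the
    requested mean/CV), moving slowly over years: the per-year value
    adds independent noise at ``year_jitter`` times the cross-sectional
    spread, mirroring the modest yearly drift of rolling survey
    estimates.  ``percent`` covariates are clipped to [0, 100];
    ``positive`` covariates are log-normal with matching mean and CV.
    """
    rng = np.random.default_rng(seed)
    years = list(years)
    n, T = lattice.n, len(years)
    panels = {}
    for cov in specs:
        z = _standardized_field(lattice, cov.spatial_rho, rng)
        zt = z[:, None] + cov.year_jitter * rng.standard_normal((n, T))
        cvfrac = cov.cv / 100.0
        if cov.cv == 0:
            vals = np.full((n, T), float(cov.mean))
        elif cov.kind == "positive":
            s2 = np.log1p(cvfrac**2)
            mu_log = np.log(cov.mean) - s2 / 2.0
            vals = np.exp(mu_log + np.sqrt(s2) * zt)
        else:
            vals = cov.mean + cov.mean * cvfrac * zt
            if cov.kind == "percent":
                vals = np.clip(vals, 0.0, 100.0)
        panels[cov.name] = vals
    rows = []
    for i, aid in enumerate(lattice.area_ids):
        for t_idx, t in enumerate(years):
            row = {"area_id": str(aid), "year": t}
            row.update({k: v[i, t_idx] for k, v in panels.items()})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counts


def _draw_spatial_effect(lattice: Lattice, truth: TruthSpec, rng):
    """phi (plus u, v for BYM) at the generating scales."""
    n = lattice.n
    _, labels = lattice.components()
    u = v = None
    if truth.family == "none":
        phi = np.zeros(n)
    elif truth.family == "iid":
        phi = truth.sd_phi * rng.standard_normal(n)
    elif truth.family == "bym":
        Q = icar_precision(lattice, 1.0)
        u_raw = sample_gmrf(Q, rng, sum_to_zero=True)
        sd = u_raw.std()
        u = truth.sd_u * (u_raw / sd) if sd > 0 else u_raw
        v = truth.sd_v * rng.standard_normal(n)
        phi = u + v
    elif truth.family == "leroux":
        Q = leroux_precision(lattice, truth.rho, 1.0)
        raw = sample_gmrf(Q, rng)
        sd = raw.std()
        phi = truth.sd_phi * (raw - raw.mean()) / sd if sd > 0 else raw
    else:  # besag_proper
        Q = proper_car_precision(lattice, truth.gamma, 1.0)
        raw = sample_gmrf(Q, rng)
        sd = raw.std()
        phi = truth.sd_phi * (raw - raw.mean()) / sd if sd > 0 else raw
    return phi, u, v


def simulate_counts(
    lattice: Lattice,
    covariates: pd.DataFrame,
    truth_spec: TruthSpec = TruthSpec(),
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneratorTruth]:
    """Draw a Poisson count panel from the log-linear relative-risk model.

    The covariate table must contain a ``population`` column and every
    covariate named in ``truth_spec.rr``.  The baseline rate is
    calibrated so the expected total count equals
    ``truth_spec.target_total`` given the realized effects; the returned
    panel has columns ``area_id, year, Y, N`` and the accompanying
    :class:`GeneratorTruth` stores every effect plus the true
    relative-risk surface.
    """
    rng = np.random.default_rng(seed)
    years = sorted(covariates["year"].unique())
    n, T = lattice.n, len(years)
    cov = covariates.set_index(["area_id", "year"])
    order = list(truth_spec.rr.keys())
    for name in order + ["population"]:
        if name not in covariates.columns:
            raise ValueError(f"covariate table lacks column {name!r}")

    ids = [str(a) for a in lattice.area_ids]
    X = np.empty((n, T, len(order)))
    N = np.empty((n, T))
    for i, aid in enumerate(ids):
        for t_idx, t in enumerate(years):
            row = cov.loc[(aid, t)]
            X[i, t_idx] = [row[c] for c in order]
            N[i, t_idx] = row["population"]

    beta = np.log(np.array([truth_spec.rr[c] for c in order]))
    phi, u, v = _draw_spatial_effect(lattice, truth_spec, rng)
    delta = (
        truth_spec.sd_delta * rng.standard_normal((n, T))
        if truth_spec.interaction
        else np.zeros((n, T))
    )

    g = np.einsum("itp,p->it", X, beta) + phi[:, None] + delta
    # baseline rate r0 such that sum of Poisson means hits target_total
    lam_unscaled = N * np.exp(g)
    r0 = truth_spec.target_total / lam_unscaled.sum()
    lam = r0 * lam_unscaled
    Y = rng.poisson(lam)

    # true pooled rate -> true expected counts and relative risks
    pooled = lam.sum() / N.sum()
    E_true = pooled * N
    mu = lam / E_true
    alpha = np.log(r0) - np.log(pooled)  # makes log mu = alpha + g exact

    rows = []
    for i, aid in enumerate(ids):
        for t_idx, t in enumerate(years):
            rows.append(
                {"area_id": aid, "year": int(t), "Y": int(Y[i, t_idx]),
                 "N": float(N[i, t_idx])}
            )
    panel = pd.DataFrame(rows)
    truth = GeneratorTruth(
        alpha=float(alpha),
        beta={c: float(b) for c, b in zip(order, beta)},
        phi=phi, u=u, v=v, delta=delta, mu=mu, E_true=E_true,
        family=truth_spec.family,
        params={
            "sd_u": truth_spec.sd_u, "sd_v": truth_spec.sd_v,
            "sd_phi": truth_spec.sd_phi, "rho": truth_spec.rho,
            "gamma": truth_spec.gamma, "sd_delta": truth_spec.sd_delta,
            "target_total": truth_spec.target_total,
            "interaction": truth_spec.interaction,
        },
        seed=int(seed) if np.isscalar(seed) else -1,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# event-level fixtures


def simulate_events(
    yearly_totals: Mapping[int, int],
    area_ids: Sequence,
    seed: int = 0,
) -> pd.DataFrame:
    """Event records matching given yearly totals exactly.

    Each year's events are assigned to areas multinomially (uniform
    weights) and given timestamps uniform within the year.  Useful for
    building fixtures whose yearly histogram is fixed, e.g. the study's
    449/487/473/555/666 totals.
    """
    rng = np.random.default_rng(seed)
    ids = [str(a) for a in area_ids]
    rows = []
    for year in sorted(yearly_totals):
        total = int(yearly_totals[year])
        areas = rng.choice(len(ids), size=total)
        rows.extend(_uniform_timestamps(year, total, rng, [ids[a] for a in areas]))
    return pd.DataFrame(rows, columns=["area_id", "timestamp"])


def events_from_panel(panel: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Event records that aggregate back exactly to the panel's counts.

    Each (area, year) cell with count ``Y`` yields ``Y`` events with
    timestamps uniform within that calendar year.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in panel.iterrows():
        rows.extend(
            _uniform_timestamps(int(r["year"]), int(r["Y"]), rng,
                                [str(r["area_id"])] * int(r["Y"]))
        )
    return pd.DataFrame(rows, columns=["area_id", "timestamp"])


def _uniform_timestamps(year: int, count: int, rng, area_ids: list) -> list[dict]:
    start = pd.Timestamp(year=year, month=1, day=1)
    end = pd.Timestamp(year=year + 1, month=1, day=1)
    span = (end - start).total_seconds()
    secs = rng.uniform(0, span, size=count)
    return [
        {"area_id": aid, "timestamp": start + pd.Timedelta(seconds=float(s))}
        for aid, s in zip(area_ids, secs)
    ]


# ---------------------------------------------------------------------------
# scenarios


def paper_scale_scenario(
    seed: int = 0,
    rows: int = 7,
    cols: int = 12,
    years: Sequence[int] = (2015, 2016, 2017, 2018, 2019),
    truth_spec: TruthSpec = TruthSpec(),
):
    """The default study-scale scenario: an 84-cell contiguity lattice,
    5 yearly periods, survey-scale covariates and ~2630 expected events.

    Returns ``(lattice, covariates, panel, truth)`` where the panel has
    Y and N columns (expected counts and SIR are added downstream).
    """
    lat = grid_lattice(rows, cols, "rook")
    cov = simulate_covariates(lat, list(years), HOUSTON_COVARIATES, seed=seed)
    panel, truth = simulate_counts(lat, cov, truth_spec, seed=seed + 1)
    return lat, cov, panel, truth
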