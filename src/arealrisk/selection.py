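"""Bayesian model comparison: DIC, WAIC and CPO.

All three criteria are computed from the matrix of pointwise Poisson
log-likelihoods ``ll[s, c] = log Poisson(Y_c | E_c * mu_c^(s))`` over
retained draws *s* and panel cells *c*, and all are oriented so that
smaller values indicate better fit:

* **DIC** = D-bar + pD, with D-bar the posterior mean deviance and
  pD = D-bar − D(mu-bar) the effective number of parameters, plugging
  the posterior mean of mu (rate scale) into the deviance.
* **WAIC** = −2 (lppd − pWAIC) with the variance-based pWAIC2 form,
  pWAIC = sum of per-cell variances of the log-likelihood.
* **CPO score** = −Σ log CPO_c, where CPO_c is the leave-one-out
  predictive density estimated by the harmonic-mean identity
  CPO_c = [mean_s exp(−ll_sc)]^{-1}.  The harmonic mean is fragile
  when a few draws dominate; a warning is raised when any cell's
  estimate rests on less than 1% of the draws (importance-weight ESS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .inference import Posterior

__all__ = [
    "loglik_matrix",
    "dic",
    "waic",
    "cpo_score",
    "compare",
    "SelectionReport",
]


def loglik_matrix(posterior: Posterior, panel: pd.DataFrame | None = None) -> np.ndarray:
    """Pointwise Poisson log-likelihoods, shape (draws, cells).

    Cells are the flattened (area, year) grid in posterior order.  If a
    ``panel`` is supplied, its counts and expected counts must match
    those stored in the posterior (guard against mixing fits and data).
    """
    Y, E = posterior.Y, posterior.E
    if panel is not None:
        other = panel.set_index(["area_id", "year"])
        for i, a in enumerate(posterior.area_ids):
            for t_idx, t in enumerate(posterior.years):
                row = other.loc[(a, t)]
                if row["Y"] != Y[i, t_idx] or not np.isclose(row["E"], E[i, t_idx]):
                    raise ValueError(
                        f"panel does not match posterior data at ({a}, {t})"
                    )
    mu = posterior.mu().reshape(posterior.n_draws, -1)  # (S, cells)
    y = Y.ravel()
    e = E.ravel()
    lam = e[None, :] * mu
    return y[None, :] * np.log(lam) - lam - gammaln(y + 1.0)[None, :]


def _poisson_ll(y, lam):
    return y * np.log(lam) - lam - gammaln(y + 1.0)


def dic(posterior: Posterior, panel: pd.DataFrame | None = None) -> tuple[float, float]:
    """Deviance information criterion and effective parameters pD.

    pD can come out negative on pathological posteriors; it is still
    reported, with a warning.
    """
    ll = loglik_matrix(posterior, panel)
    dbar = float(-2.0 * ll.sum(axis=1).mean())
    mu_bar = posterior.mu().reshape(posterior.n_draws, -1).mean(axis=0)
    lam_bar = posterior.E.ravel() * mu_bar
    dhat = float(-2.0 * _poisson_ll(posterior.Y.ravel(), lam_bar).sum())
    pd_ = dbar - dhat
    if pd_ < 0:
        warnings.warn(f"negative effective parameter count pD = {pd_:.3f}", UserWarning)
    return dbar + pd_, pd_


def waic(ll: np.ndarray) -> tuple[float, float]:
    """WAIC and pWAIC (variance form) from a (draws, cells) matrix."""
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws, cells) matrix with at least 2 draws")
    S = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(S)))
    p_waic = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def cpo_score(ll: np.ndarray) -> tuple[float, np.ndarray]:
    """Harmonic-mean CPO per cell and the summary score −Σ log CPO."""
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws, cells) matrix with at least 2 draws")
    S = ll.shape[0]
    if np.any(np.all(~np.isfinite(ll), axis=0)):
        raise ValueError("a cell has zero predictive probability in every draw")
    # log CPO_c = -(logsumexp(-ll) - log S), computed with max-shift
    log_cpo = -(logsumexp(-ll, axis=0) - np.log(S))
    # importance-weight diagnostics: share of draws carrying the estimate
    w = np.exp(-ll - logsumexp(-ll, axis=0, keepdims=True))
    ess = 1.0 / np.sum(w**2, axis=0)
    frac = ess / S
    if np.any(frac < 0.01):
        k = int(np.sum(frac < 0.01))
        warnings.warn(
            f"harmonic-mean CPO unstable in {k} cell(s): estimate dominated "
            "by <1% of draws",
            UserWarning,
        )
    return float(-np.sum(log_cpo)), np.exp(log_cpo)


@dataclass
class SelectionReport:
    """Per-model criteria and rankings (smaller is always better)."""

    table: pd.DataFrame
    best: dict

    @property
    def agreement(self) -> bool:
        """Do all three criteria pick the same model?"""
        return len(set(self.best.values())) == 1

    def __str__(self):
        lines = [self.table.to_string(index=False)]
        lines.append(
            "best by criterion: "
            + ", ".join(f"{k}={v}" for k, v in self.best.items())
        )
        lines.append("criteria " + ("agree" if self.agreement else "disagree"))
        return "\n".join(lines)


def compare(fits: dict) -> SelectionReport:
    """Compute DIC, WAIC and CPO for each named fit and rank them.

    ``fits`` maps model names to either a Posterior or a
    ``(posterior, panel)`` pair.  All fits must condition on identical
    data (same counts and expected counts); ties rank in stable name
    order.
    """
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    ref = None
    for name in fits:
        item = fits[name]
        post, panel = item if isinstance(item, tuple) else (item, None)
        if ref is None:
            ref = (post.Y, post.E)
        else:
            if post.Y.shape != ref[0].shape or not (
                np.array_equal(post.Y, ref[0]) and np.allclose(post.E, ref[1])
            ):
                raise ValueError(f"fit {name!r} conditions on different data")
        ll = loglik_matrix(post, panel)
        dic_val, pd_val = dic(post, panel)
        waic_val, pwaic_val = waic(ll)
        cpo_val, _ = cpo_score(ll)
        rows.append(
            {"model": name, "DIC": dic_val, "pD": pd_val, "WAIC": waic_val,
             "pWAIC": pwaic_val, "CPO_score": cpo_val}
        )
    table = pd.DataFrame(rows)
    for crit, col in (("dic", "DIC"), ("waic", "WAIC"), ("cpo", "CPO_score")):
        # stable: ties broken by row (name) order
        order = np.argsort(table[col].to_numpy(), kind="stable")
        ranks = np.empty(len(table), dtype=int)
        ranks[order] = np.arange(1, len(table) + 1)
        table[f"rank_{crit}"] = ranks
    best = {
        crit: table.loc[table[f"rank_{crit}"] == 1, "model"].iloc[0]
        for crit in ("dic", "waic", "cpo")
    }
    return SelectionReport(table=table, best=best)
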