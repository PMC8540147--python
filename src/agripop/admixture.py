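"""Maximum-likelihood admixture clustering and the Evanno delta-K selector.

Model: each diploid genotype g_il ~ Binomial(2, theta_il) with
theta_il = sum_k q_ik f_kl, where Q (n x K, rows on the simplex) holds
ancestry proportions and F (K x L) population allele frequencies.  The fit
is plain EM on this likelihood — a deterministic, seedable stand-in for
MCMC samplers of the same admixture model; missing genotypes are skipped
in the likelihood.  The log-likelihood omits the constant binomial
coefficient term and is nondecreasing over iterations.

Model selection across K uses the Evanno statistic: with replicate
log-likelihoods L_r(K), the per-replicate second difference
|L''_r(K)| = |L_r(K+1) - 2 L_r(K) + L_r(K-1)| is averaged and divided by
the sample standard deviation of L_r(K); the K maximizing this ratio is
selected.  A Thorndike-style elbow reading (first K whose delta-K exceeds
all later ones) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix

__all__ = [
    "AdmixtureEM",
    "AdmixtureFit",
    "fit_admixture",
    "replicate_loglik_table",
    "EvannoResult",
    "evanno_delta_k",
    "align_components",
]

_F_EPS = 1e-6


def _as_arrays(gm) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(gm, GenotypeMatrix):
        return gm.dosages.astype(float), ~gm.missing_mask
    g = np.asarray(gm, dtype=float)
    called = ~np.isnan(g)
    return np.where(called, g, 0.0), called


@dataclass
class AdmixtureFit:
    """Converged admixture solution for one K."""

    K: int
    Q: np.ndarray
    F: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    seed: int


class AdmixtureEM(BaseEstimator):
    """EM fit of the binomial admixture model.

    Parameters
    ----------
    n_populations : int, K >= 1.
    seed : int, base seed; restart r uses rng seeded by (seed, r).
    max_iter, tol : stopping rule — stop when the log-likelihood gain
        drops below ``tol`` or after ``max_iter`` iterations.
    n_init : random restarts; the best final log-likelihood is kept.

    Attributes (after fit)
    ----------------------
    Q_ : (n_samples, K) ancestry proportions, rows sum to 1.
    F_ : (K, n_markers) allele frequencies in [1e-6, 1 - 1e-6].
    loglik_ : final log-likelihood (binomial coefficient omitted).
    loglik_path_ : per-iteration log-likelihoods of the winning restart.
    n_iter_, converged_ : stopping diagnostics.
    """

    def __init__(
        self,
        n_populations: int = 2,
        seed: int = 0,
        max_iter: int = 500,
        tol: float = 1e-5,
        n_init: int = 5,
    ):
        self.n_populations = n_populations
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init

    def fit(self, gm, y=None) -> "AdmixtureEM":
        g, called = _as_arrays(gm)
        n, L = g.shape
        k = self.n_populations
        if k < 1:
            raise ValueError("n_populations must be >= 1")
        if k > n:
            raise ValueError(f"K={k} exceeds n_samples={n}")
        gm_alt = g * called
        gm_ref = (2.0 - g) * called
        n_called_row = 2.0 * called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_overall = gm_alt.sum(axis=0) / np.maximum(
                2.0 * called.sum(axis=0), 1.0
            )
        best = None
        for restart in range(self.n_init):
            rng = np.random.default_rng([self.seed, restart])
            q = rng.dirichlet(np.ones(k), size=n)
            f = np.clip(
                p_overall + rng.uniform(-0.05, 0.05, size=(k, L)),
                _F_EPS,
                1.0 - _F_EPS,
            )
            path = []
            prev = -np.inf
            converged = False
            for it in range(1, self.max_iter + 1):
                theta = q @ f
                np.clip(theta, _F_EPS, 1.0 - _F_EPS, out=theta)
                ll = float(
                    np.sum(gm_alt * np.log(theta) + gm_ref * np.log1p(-theta))
                )
                if not np.isfinite(ll):
                    raise FloatingPointError(
                        f"non-finite log-likelihood at iteration {it}"
                    )
                path.append(ll)
                if ll - prev < self.tol and it > 1:
                    converged = True
                    break
                prev = ll
                a = gm_alt / theta
                b = gm_ref / (1.0 - theta)
                f_num = f * (q.T @ a)
                f_den = f_num + (1.0 - f) * (q.T @ b)
                q_num = q * (a @ f.T + b @ (1.0 - f).T)
                f = np.clip(
                    np.where(f_den > 0, f_num / np.maximum(f_den, 1e-300), f),
                    _F_EPS,
                    1.0 - _F_EPS,
                )
                q = q_num / np.maximum(n_called_row, 1.0)[:, None]
                q /= q.sum(axis=1, keepdims=True)
            if best is None or path[-1] > best[0]:
                best = (path[-1], q, f, path, len(path), converged)
        self.loglik_, self.Q_, self.F_, self.loglik_path_, self.n_iter_, self.converged_ = best
        return self

    def result(self) -> AdmixtureFit:
        return AdmixtureFit(
            K=self.n_populations,
            Q=self.Q_,
            F=self.F_,
            loglik=self.loglik_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            seed=self.seed,
        )


def fit_admixture(
    gm, K: int, seed: int = 0, max_iter: int = 500, tol: float = 1e-5, n_init: int = 5
) -> AdmixtureFit:
    """Fit the admixture model once; see :class:`AdmixtureEM`."""
    est = AdmixtureEM(
        n_populations=K, seed=seed, max_iter=max_iter, tol=tol, n_init=n_init
    ).fit(gm)
    return est.result()


def replicate_loglik_table(
    gm,
    k_values,
    n_replicates: int = 4,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """L(K) over replicate single-start EM fits (distinct seeds) per K.

    Returns the LKTable: columns K, replicate, loglik, seed.
    """
    rows = []
    for k in k_values:
        for r in range(n_replicates):
            rep_seed = (seed * 10007 + 131 * int(k) + r) % (2**31)
            fit = fit_admixture(
                gm, int(k), seed=rep_seed, max_iter=max_iter, tol=tol, n_init=1
            )
            rows.append(
                {"K": int(k), "replicate": r, "loglik": fit.loglik, "seed": rep_seed}
            )
    return pd.DataFrame(rows)


@dataclass
class EvannoResult:
    """Per-K Evanno summary and the selected number of clusters."""

    table: pd.DataFrame  # K, mean_loglik, sd_loglik, lprime, mean_abs_lpp, delta_k
    selected_k: int | None
    elbow_k: int | None
    ambiguous: bool


def evanno_delta_k(lk_table: pd.DataFrame) -> EvannoResult:
    """Evanno delta-K from an LKTable (columns K, replicate, loglik).

    delta-K(K) = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_r(L_r(K)),
    defined for interior K with replicate spread sd > 0; replicates are
    paired across K by replicate id.  Adding a constant to every
    log-likelihood leaves delta-K unchanged.
    """
    ks = sorted(lk_table["K"].unique())
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("K range must be contiguous")
    wide = lk_table.pivot(index="replicate", columns="K", values="loglik")
    if wide.isna().any().any():
        raise ValueError("replicates must be paired across all K")
    mean_l = wide.mean(axis=0)
    sd_l = wide.std(axis=0, ddof=1)
    rows = []
    for k in ks:
        row = {"K": k, "mean_loglik": mean_l[k], "sd_loglik": sd_l[k]}
        row["lprime"] = mean_l[k] - mean_l[k - 1] if k - 1 in mean_l else np.nan
        if k - 1 in mean_l.index and k + 1 in mean_l.index:
            lpp = wide[k + 1] - 2.0 * wide[k] + wide[k - 1]
            row["mean_abs_lpp"] = float(lpp.abs().mean())
            row["delta_k"] = (
                row["mean_abs_lpp"] / sd_l[k] if sd_l[k] > 0 else np.nan
            )
        else:
            row["mean_abs_lpp"] = np.nan
            row["delta_k"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["delta_k"])
    if len(valid) and valid["delta_k"].max() > 0:
        selected = int(valid.loc[valid["delta_k"].idxmax(), "K"])
        elbow = None
        for _, r in valid.iterrows():
            later = valid.loc[valid["K"] > r["K"], "delta_k"]
            if (later < r["delta_k"]).all():
                elbow = int(r["K"])
                break
        return EvannoResult(table, selected, elbow, ambiguous=False)
    # no usable delta-K (zero spread or flat curvature): elbow fallback
    interior = table.dropna(subset=["mean_abs_lpp"])
    if len(interior) and interior["mean_abs_lpp"].max() > 0:
        elbow = int(interior.loc[interior["mean_abs_lpp"].idxmax(), "K"])
        return EvannoResult(table, None, elbow, ambiguous=True)
    return EvannoResult(table, None, None, ambiguous=True)


def align_components(q: np.ndarray, q_ref: np.ndarray) -> np.ndarray:
    """Permute columns of ``q`` to best match ``q_ref`` (Hungarian assignment).

    Resolves label switching before comparing ancestry matrices.
    """
    from scipy.optimize import linear_sum_assignment

    cost = -(q.T @ q_ref)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(q.shape[1], dtype=int)
    perm[cols] = rows
    return q[:, perm]
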