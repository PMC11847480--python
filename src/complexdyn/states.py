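"""Conformational-state analysis: features, GMM clustering, PCA, landscapes.

The state description uses four per-frame descriptors -- the two
ligand-receptor angles (degrees) and two cross-receptor domain COM distances
(Å).  Because angles and distances are incommensurate, features are z-scored
before mixture fitting and PCA; the standardization parameters are stored so
cluster means can be reported back in physical units.

The Gaussian mixture is fitted by expectation-maximization with
k-means++-style seeding, full covariances with a diagonal regularization
floor, and best-of-restarts selection by final log-likelihood.  Model order
is chosen by BIC (AIC is reported alongside); the free-energy landscape is
the Boltzmann inversion dG = -kT ln(p / p_max) of the 2-D angle histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .geometry import _as_indices, _com_series, domain_angle
from .structure_io import DomainDefinition, Trajectory

__all__ = [
    "FeatureTable",
    "extract_features",
    "GaussianMixtureEM",
    "GMMModel",
    "fit_gmm",
    "KSelection",
    "select_k",
    "PCAResult",
    "pca_features",
    "representative_frames",
    "LandscapeGrid",
    "free_energy_landscape",
    "KB_KJ_PER_MOL_K",
]

#: Boltzmann constant in kJ/(mol K)
KB_KJ_PER_MOL_K = 0.0083145

FEATURE_COLUMNS = ["angle_a_deg", "angle_b_deg", "dist_1_A", "dist_2_A"]


@dataclass
class FeatureTable:
    """Per-frame geometric descriptors (two angles, two distances)."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def matrix(self) -> np.ndarray:
        return self.df[FEATURE_COLUMNS].to_numpy(float)

    @property
    def n_frames(self) -> int:
        return len(self.df)


def extract_features(trajectory: Trajectory, ligand: DomainDefinition,
                     receptor_a, receptor_b, distance_pairs=None,
                     angle_definition: str = "vertex-at-ligand",
                     mass_weighted: bool = True) -> FeatureTable:
    """Extract the four state descriptors from a trajectory.

    ``receptor_a`` and ``receptor_b`` are (domain, domain) pairs; the angle
    for each receptor subtends its two domain COMs at the ligand COM (or uses
    the ligand-axis definition when requested).  ``distance_pairs`` defaults
    to the crossed pairing ((a1, b2), (a2, b1)): first domain of receptor A
    against second domain of receptor B and vice versa.
    """
    a1, a2 = receptor_a
    b1, b2 = receptor_b
    if distance_pairs is None:
        distance_pairs = ((a1, b2), (a2, b1))
    angle_a = domain_angle(trajectory, ligand, a1, a2,
                           definition=angle_definition,
                           mass_weighted=mass_weighted)
    angle_b = domain_angle(trajectory, ligand, b1, b2,
                           definition=angle_definition,
                           mass_weighted=mass_weighted)
    topo = trajectory.topology
    dists = []
    for da, db in distance_pairs:
        ia = _as_indices(topo, da)
        ib = _as_indices(topo, db)
        ca = _com_series(trajectory, ia, mass_weighted)
        cb = _com_series(trajectory, ib, mass_weighted)
        dists.append(np.linalg.norm(ca - cb, axis=1))
    df = pd.DataFrame(
        {
            "frame": np.arange(trajectory.n_frames),
            "time_ns": trajectory.times,
            "angle_a_deg": angle_a.values,
            "angle_b_deg": angle_b.values,
            "dist_1_A": dists[0],
            "dist_2_A": dists[1],
        }
    )
    meta = {
        "angle_definition": angle_definition,
        "mass_weighted": mass_weighted,
        "ligand": ligand.label,
        "receptor_a": [a1.label, a2.label],
        "receptor_b": [b1.label, b2.label],
        "distance_pairs": [[da.label, db.label] for da, db in distance_pairs],
    }
    return FeatureTable(df=df, meta=meta)


# ----------------------------------------------------------------------
# Gaussian mixture by EM
# ----------------------------------------------------------------------

class GaussianMixtureEM:
    """Full-covariance Gaussian mixture fitted by EM (sklearn-style API).

    Parameters
    ----------
    n_components : number of mixture components K.
    n_restarts : independent k-means++-seeded EM runs; the best final
        log-likelihood wins.
    tol : relative log-likelihood improvement below which EM stops.
    reg_covar : floor added to covariance diagonals each M-step.
    random_state : seed; fits are bit-reproducible for a fixed seed.

    Fitted attributes carry the sklearn trailing underscore: ``weights_``,
    ``means_``, ``covariances_``, ``log_likelihood_``, ``bic_``, ``aic_``,
    ``ll_trace_``.
    """

    def __init__(self, n_components: int, n_restarts: int = 5,
                 max_iter: int = 500, tol: float = 1e-6,
                 reg_covar: float = 1e-6, random_state: int = 0):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.reg_covar = reg_covar
        self.random_state = random_state

    # -- parameters ----------------------------------------------------
    def get_params(self) -> dict:
        return {
            "n_components": self.n_components,
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "reg_covar": self.reg_covar,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "GaussianMixtureEM":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals -----------------------------------------------------
    def _kmeanspp_seeds(self, X: np.ndarray, rng: np.random.Generator):
        n = len(X)
        centers = [X[rng.integers(n)]]
        for _ in range(1, self.n_components):
            d2 = np.min(
                [((X - c) ** 2).sum(axis=1) for c in centers], axis=0
            )
            total = d2.sum()
            if total <= 0:
                centers.append(X[rng.integers(n)])
                continue
            centers.append(X[rng.choice(n, p=d2 / total)])
        return np.array(centers)

    def _log_gauss(self, X: np.ndarray, mean: np.ndarray,
                   cov: np.ndarray) -> np.ndarray:
        d = X.shape[1]
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular component covariance despite regularization; "
                "provide more data or increase reg_covar"
            ) from exc
        diff = X - mean
        sol = np.linalg.solve(L, diff.T)
        maha = (sol**2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)

    def _m_step(self, X: np.ndarray, resp: np.ndarray):
        n, d = X.shape
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = np.empty((self.n_components, d, d))
        for k in range(self.n_components):
            diff = X - means[k]
            covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k]
            covs[k].flat[:: d + 1] += self.reg_covar
        return weights, means, covs

    def _e_step(self, X: np.ndarray, weights, means, covs):
        log_prob = np.stack(
            [
                np.log(weights[k] + 1e-300) + self._log_gauss(X, means[k], covs[k])
                for k in range(self.n_components)
            ],
            axis=1,
        )
        norm = logsumexp(log_prob, axis=1)
        resp = np.exp(log_prob - norm[:, None])
        return resp, float(norm.mean())

    def _single_fit(self, X: np.ndarray, rng: np.random.Generator):
        n, d = X.shape
        centers = self._kmeanspp_seeds(X, rng)
        assign = np.argmin(
            ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        resp = np.zeros((n, self.n_components))
        resp[np.arange(n), assign] = 1.0
        weights, means, covs = self._m_step(X, resp)
        prev = -np.inf
        trace = []
        for _ in range(self.max_iter):
            resp, ll = self._e_step(X, weights, means, covs)
            # EM guarantee: the average log-likelihood never decreases
            if ll < prev - 1e-9 * max(1.0, abs(prev)):
                raise AssertionError(
                    f"EM log-likelihood decreased ({prev} -> {ll})"
                )
            trace.append(ll)
            weights, means, covs = self._m_step(X, resp)
            if ll - prev < self.tol * max(1.0, abs(ll)):
                prev = ll
                break
            prev = ll
        resp, ll = self._e_step(X, weights, means, covs)
        trace.append(ll)
        return weights, means, covs, resp, ll, trace

    # -- public API ----------------------------------------------------
    def fit(self, X: np.ndarray) -> "GaussianMixtureEM":
        X = np.asarray(X, float)
        n, d = X.shape
        if n < 10 * self.n_components:
            raise ValueError(
                f"need at least {10 * self.n_components} rows to fit "
                f"{self.n_components} components (got {n})"
            )
        root = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            rng = np.random.default_rng(root.integers(2**31))
            out = self._single_fit(X, rng)
            if best is None or out[4] > best[4]:
                best = out
        weights, means, covs, resp, ll, trace = best
        self.weights_ = weights
        self.means_ = means
        self.covariances_ = covs
        self.responsibilities_ = resp
        self.labels_ = resp.argmax(axis=1)
        self.log_likelihood_ = ll * n  # total, not per-sample
        self.ll_trace_ = np.array(trace) * n
        p = (self.n_components - 1) + self.n_components * d \
            + self.n_components * d * (d + 1) // 2
        self.n_parameters_ = p
        self.bic_ = -2.0 * self.log_likelihood_ + p * np.log(n)
        self.aic_ = -2.0 * self.log_likelihood_ + 2.0 * p
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        resp, _ = self._e_step(np.asarray(X, float), self.weights_,
                               self.means_, self.covariances_)
        return resp

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


@dataclass
class GMMModel:
    """A fitted mixture over z-scored features, plus the scaler parameters."""

    estimator: GaussianMixtureEM
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    seed: int

    @property
    def n_components(self) -> int:
        return self.estimator.n_components

    @property
    def weights(self) -> np.ndarray:
        return self.estimator.weights_

    @property
    def means_standardized(self) -> np.ndarray:
        return self.estimator.means_

    @property
    def means_physical(self) -> np.ndarray:
        return self.estimator.means_ * self.scaler_sd + self.scaler_mean

    @property
    def labels(self) -> np.ndarray:
        return self.estimator.labels_

    @property
    def bic(self) -> float:
        return self.estimator.bic_

    @property
    def aic(self) -> float:
        return self.estimator.aic_

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.scaler_mean) / self.scaler_sd

    def to_dict(self) -> dict:
        e = self.estimator
        return {
            "n_components": self.n_components,
            "weights": e.weights_.tolist(),
            "means_standardized": e.means_.tolist(),
            "means_physical": self.means_physical.tolist(),
            "covariances": e.covariances_.tolist(),
            "log_likelihood": e.log_likelihood_,
            "bic": e.bic_,
            "aic": e.aic_,
            "seed": self.seed,
            "n_restarts": e.n_restarts,
            "tol": e.tol,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
        }


def _zscore(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd < 1e-12):
        dead = [FEATURE_COLUMNS[i] if i < len(FEATURE_COLUMNS) else str(i)
                for i in np.flatnonzero(sd < 1e-12)]
        raise ValueError(f"zero-variance feature(s): {dead}")
    return (X - mean) / sd, mean, sd


def fit_gmm(features: FeatureTable | np.ndarray, n_components: int,
            seed: int = 0, n_restarts: int = 5, tol: float = 1e-6) -> GMMModel:
    """Fit a K-component mixture to (internally z-scored) features."""
    X = features.matrix() if isinstance(features, FeatureTable) else \
        np.asarray(features, float)
    Z, mean, sd = _zscore(X)
    est = GaussianMixtureEM(
        n_components=n_components, n_restarts=n_restarts, tol=tol,
        random_state=seed,
    ).fit(Z)
    return GMMModel(estimator=est, scaler_mean=mean, scaler_sd=sd, seed=seed)


@dataclass
class KSelection:
    """BIC/AIC across candidate component counts, with the BIC argmin."""

    table: pd.DataFrame
    chosen_k: int
    models: dict[int, GMMModel]


def select_k(features, k_range=range(1, 7), seed: int = 0,
             n_restarts: int = 5) -> KSelection:
    """Fit the mixture for every K in ``k_range``; choose K by min BIC.

    Each K gets its own seed from a shared schedule so runs are reproducible;
    the full BIC/AIC table is returned so the elbow is inspectable.  Ties in
    BIC resolve to the smaller K.
    """
    ss = np.random.SeedSequence(seed)
    k_list = list(k_range)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(k_list))]
    rows = []
    models: dict[int, GMMModel] = {}
    errors = []
    for k, child in zip(k_list, child_seeds):
        try:
            model = fit_gmm(features, k, seed=child, n_restarts=n_restarts)
        except Exception as exc:  # propagate only if every K fails
            errors.append((k, exc))
            warnings.warn(f"GMM fit failed for K={k}: {exc}")
            continue
        models[k] = model
        rows.append({"K": k, "BIC": model.bic, "AIC": model.aic,
                     "log_likelihood": model.estimator.log_likelihood_})
    if not rows:
        raise errors[0][1]
    table = pd.DataFrame(rows)
    best = table.loc[table["BIC"].idxmin()]
    # exact ties resolve to the smaller K
    chosen = int(table[np.isclose(table["BIC"], best["BIC"])]["K"].min())
    return KSelection(table=table, chosen_k=chosen, models=models)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # columns are components
    explained_fractions: np.ndarray


def pca_features(features) -> PCAResult:
    """PCA of z-scored features via eigendecomposition of the correlation
    matrix; component signs fixed so the largest-magnitude loading is
    positive."""
    X = features.matrix() if isinstance(features, FeatureTable) else \
        np.asarray(features, float)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 rows")
    Z, _, _ = _zscore(X)
    corr = (Z.T @ Z) / len(Z)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        lead = np.argmax(np.abs(evecs[:, j]))
        if evecs[lead, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return PCAResult(
        scores=Z @ evecs,
        loadings=evecs,
        explained_fractions=evals / evals.sum(),
    )


# ----------------------------------------------------------------------
# Representatives and the free-energy landscape
# ----------------------------------------------------------------------

def representative_frames(features, model: GMMModel,
                          metric: str = "euclidean") -> dict[int, int]:
    """One representative frame per cluster: the hard-assigned frame closest
    to the cluster mean in standardized feature space (ties -> earliest).

    ``metric="mahalanobis"`` uses the component covariance instead of the
    identity.
    """
    X = features.matrix() if isinstance(features, FeatureTable) else \
        np.asarray(features, float)
    Z = model.standardize(X)
    labels = model.labels
    reps: dict[int, int] = {}
    for k in range(model.n_components):
        member = np.flatnonzero(labels == k)
        if member.size == 0:
            warnings.warn(f"cluster {k} is empty; no representative selected")
            continue
        diff = Z[member] - model.means_standardized[k]
        if metric == "euclidean":
            d2 = (diff**2).sum(axis=1)
        elif metric == "mahalanobis":
            inv = np.linalg.inv(model.estimator.covariances_[k])
            d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        # argmin returns the first minimum, i.e. the earliest frame on ties
        reps[k] = int(member[np.argmin(d2)])
    return reps


@dataclass
class LandscapeGrid:
    """Binned free-energy surface over the two angles, in kT."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    free_energy_kt: np.ndarray
    cap_kt: float
    temperature: float
    min_bin: tuple[int, int]
    min_center: tuple[float, float]
    min_frame: int

    @property
    def free_energy_kj_per_mol(self) -> np.ndarray:
        return self.free_energy_kt * KB_KJ_PER_MOL_K * self.temperature

    def to_frame(self) -> pd.DataFrame:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xi, yi = np.meshgrid(np.arange(len(xc)), np.arange(len(yc)),
                             indexing="ij")
        return pd.DataFrame(
            {
                "angle_a_deg": xc[xi.ravel()],
                "angle_b_deg": yc[yi.ravel()],
                "count": self.counts.ravel(),
                "dG_kT": self.free_energy_kt.ravel(),
                "dG_kJ_per_mol": self.free_energy_kj_per_mol.ravel(),
            }
        )


def free_energy_landscape(angle_a: np.ndarray, angle_b: np.ndarray,
                          n_bins: int = 32,
                          temperature: float = 310.0) -> LandscapeGrid:
    """Boltzmann inversion of the 2-D angle histogram.

    dG_b = -kT ln(p_b / p_max) for occupied bins; empty bins are capped at
    (max occupied dG + 1) kT so the exported surface stays finite.  Returns
    the minimum-energy bin and the frame whose angles lie nearest its center.
    """
    a = np.asarray(angle_a, float)
    b = np.asarray(angle_b, float)
    if len(a) != len(b):
        raise ValueError("angle series must have equal length")
    if len(a) < 100:
        raise ValueError("landscape needs at least 100 samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive")

    def padded_edges(x):
        lo, hi = x.min(), x.max()
        span = hi - lo
        pad = 0.01 * span if span > 0 else 0.5
        return np.linspace(lo - pad, hi + pad, n_bins + 1)

    x_edges = padded_edges(a)
    y_edges = padded_edges(b)
    counts, _, _ = np.histogram2d(a, b, bins=[x_edges, y_edges])
    occupied = counts > 0
    if occupied.sum() <= 1:
        warnings.warn("degenerate landscape: all samples fall in one bin")
    p = counts / counts.sum()
    p_max = p.max()
    dg = np.zeros_like(p)
    dg[occupied] = -np.log(p[occupied] / p_max)
    cap = float(dg[occupied].max() + 1.0)
    dg[~occupied] = cap

    i, j = np.unravel_index(np.argmin(np.where(occupied, dg, np.inf)),
                            dg.shape)
    xc = 0.5 * (x_edges[i] + x_edges[i + 1])
    yc = 0.5 * (y_edges[j] + y_edges[j + 1])
    min_frame = int(np.argmin((a - xc) ** 2 + (b - yc) ** 2))
    return LandscapeGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        free_energy_kt=dg,
        cap_kt=cap,
        temperature=temperature,
        min_bin=(int(i), int(j)),
        min_center=(float(xc), float(yc)),
        min_frame=min_frame,
    )
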