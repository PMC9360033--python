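"""Two-step Dirichlet-process mixture clustering of binary lesion matrices.

This is the ab-initio procedure that derived the molecular classes: a
Dirichlet-process mixture over the patients-by-lesions 0/1 matrix, sampled
by collapsed Gibbs (Chinese-restaurant representation) with a
Gamma(alpha_shape, alpha_rate) hyperprior on the concentration parameter,
followed by cosine-similarity merging of near-duplicate components,
hyperparameter grid search on assignment-confidence criteria, a second
sampling pass over low-confidence patients, and rule-based post-processing
that only keeps a patient in a component whose class-defining lesion they
actually carry.

The default base distribution is Bernoulli–Beta, conjugate for 0/1 lesion
indicators; a Gaussian base (fixed observation variance, conjugate normal
prior on the mean) is also available.  Lesions are free to recur across
components — components are feature-weight profiles, not disjoint feature
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DpHyperParams:
    """Sampler and merging hyperparameters.

    ``alpha_shape`` / ``alpha_rate`` parameterize the Gamma hyperprior on
    the DP concentration (resampled each sweep, Escobar–West); ``beta_a`` /
    ``beta_b`` the Beta prior per lesion under the Bernoulli base.
    """

    cosine_merge_threshold: float = 0.95
    n_init_clusters: int = 8
    base_distribution: str = "bernoulli_beta"  # or "gaussian"
    alpha_shape: float = 2.0
    alpha_rate: float = 1.0
    n_mcmc_iterations: int = 200
    burn_in: int = 100
    seed: int = 0
    beta_a: float = 1.0
    beta_b: float = 1.0
    gaussian_obs_var: float = 0.25
    gaussian_prior_var: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cosine_merge_threshold <= 1.0):
            raise ValueError("cosine_merge_threshold must be in [0, 1]")
        for name in ("alpha_shape", "alpha_rate", "beta_a", "beta_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_mcmc_iterations <= self.burn_in:
            raise ValueError("n_mcmc_iterations must exceed burn_in")
        if self.base_distribution not in {"bernoulli_beta", "gaussian"}:
            raise ValueError("base_distribution must be bernoulli_beta or gaussian")


@dataclass
class ClusteringResult:
    """Mixture components over the lesion matrix with per-patient
    assignment probabilities.

    ``components``: K x F matrix of per-feature posterior means;
    ``probs``: N x K membership probabilities (rows sum to 1);
    ``labels``: argmax assignment; ``high_confidence``: top probability at
    or above ``confidence_threshold``; ``delta``: top1 − top2 probability.
    """

    components: np.ndarray
    sizes: np.ndarray
    probs: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]
    confidence_threshold: float = 0.8
    params: DpHyperParams | None = None

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def top_prob(self) -> np.ndarray:
        return self.probs.max(axis=1)

    @property
    def delta(self) -> np.ndarray:
        if self.probs.shape[1] < 2:
            return self.top_prob.copy()
        part = np.sort(self.probs, axis=1)
        return part[:, -1] - part[:, -2]

    @property
    def high_confidence(self) -> np.ndarray:
        return self.top_prob >= self.confidence_threshold

    def n_high_confidence_components(self) -> int:
        """Components in which at least half of the assigned patients are
        themselves high-confidence."""
        count = 0
        for k in range(self.n_components):
            members = self.labels == k
            if members.sum() == 0:
                continue
            if self.high_confidence[members].mean() >= 0.5:
                count += 1
        return count


def _as_matrix(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(matrix, pd.DataFrame):
        x = matrix.to_numpy(dtype=float)
        names = tuple(str(c) for c in matrix.columns)
    else:
        x = np.asarray(matrix, dtype=float)
        names = tuple(f"f{j}" for j in range(x.shape[1]))
    if x.ndim != 2:
        raise ValueError("lesion matrix must be 2-dimensional")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("lesion matrix entries must be 0/1")
    return x, names


def _resample_alpha(
    alpha: float, n: int, k: int, shape: float, rate: float, rng: np.random.Generator
) -> float:
    # Escobar & West (1995) auxiliary-variable update
    eta = rng.beta(alpha + 1.0, n)
    odds = (shape + k - 1) / (n * (rate - np.log(eta)))
    pi = odds / (1.0 + odds)
    if rng.random() < pi:
        return rng.gamma(shape + k, 1.0 / (rate - np.log(eta)))
    return rng.gamma(shape + k - 1, 1.0 / (rate - np.log(eta)))


def fit_dp_mixture(
    matrix: pd.DataFrame | np.ndarray,
    params: DpHyperParams | None = None,
    confidence_threshold: float = 0.8,
) -> ClusteringResult:
    """Collapsed-Gibbs DP mixture fit on a binary lesion matrix.

    The number of components is learned from the data; a fixed seed gives
    an identical partition.  Per-patient assignment probabilities are the
    posterior membership probabilities of the final partition's components
    (mixture weight times the component likelihood of the patient's lesion
    vector, normalized).
    """
    params = params or DpHyperParams()
    x, names = _as_matrix(matrix)
    n, f = x.shape
    if n == 0:
        raise ValueError("empty lesion matrix")
    rng = np.random.default_rng(params.seed)
    gaussian = params.base_distribution == "gaussian"
    a, b = params.beta_a, params.beta_b
    sigma2, tau2 = params.gaussian_obs_var, params.gaussian_prior_var
    mu0 = float(x.mean())

    k0 = min(params.n_init_clusters, n)
    labels = rng.integers(0, k0, size=n)
    # sufficient statistics per cluster: member count and per-feature sums
    clusters: dict[int, tuple[int, np.ndarray]] = {}
    for k in range(k0):
        members = labels == k
        if members.any():
            clusters[k] = (int(members.sum()), x[members].sum(axis=0))
    next_id = k0
    alpha = params.alpha_shape / params.alpha_rate

    def log_predictive(xi: np.ndarray, nk: int, sk: np.ndarray) -> float:
        if gaussian:
            prec = 1.0 / tau2 + nk / sigma2
            m = (mu0 / tau2 + sk / sigma2) / prec
            v = 1.0 / prec + sigma2
            return float(-0.5 * np.sum(np.log(2 * np.pi * v) + (xi - m) ** 2 / v))
        p1 = (a + sk) / (a + b + nk)
        return float(np.sum(xi * np.log(p1) + (1 - xi) * np.log1p(-p1)))

    for sweep in range(params.n_mcmc_iterations):
        for idx in range(n):
            xi = x[idx]
            k = labels[idx]
            nk, sk = clusters[k]
            if nk == 1:
                del clusters[k]
            else:
                clusters[k] = (nk - 1, sk - xi)
            keys = list(clusters)
            logp = np.empty(len(keys) + 1)
            for t, kk in enumerate(keys):
                nk2, sk2 = clusters[kk]
                logp[t] = np.log(nk2) + log_predictive(xi, nk2, sk2)
            logp[-1] = np.log(alpha) + log_predictive(xi, 0, np.zeros(f))
            logp -= logp.max()
            w = np.exp(logp)
            choice = rng.choice(len(w), p=w / w.sum())
            if choice == len(keys):
                labels[idx] = next_id
                clusters[next_id] = (1, xi.copy())
                next_id += 1
            else:
                kk = keys[choice]
                nk2, sk2 = clusters[kk]
                clusters[kk] = (nk2 + 1, sk2 + xi)
                labels[idx] = kk
        alpha = _resample_alpha(
            alpha, n, len(clusters), params.alpha_shape, params.alpha_rate, rng
        )

    return _result_from_partition(x, names, labels, params, confidence_threshold)


def _result_from_partition(
    x: np.ndarray,
    names: tuple[str, ...],
    labels: np.ndarray,
    params: DpHyperParams | None,
    confidence_threshold: float,
) -> ClusteringResult:
    uniq = [k for k in pd.unique(labels)]
    remap = {k: t for t, k in enumerate(uniq)}
    lab = np.array([remap[k] for k in labels])
    K = len(uniq)
    n, f = x.shape
    gaussian = params is not None and params.base_distribution == "gaussian"
    comps = np.zeros((K, f))
    sizes = np.zeros(K, dtype=int)
    for k in range(K):
        members = lab == k
        sizes[k] = members.sum()
        if gaussian:
            sigma2 = params.gaussian_obs_var
            tau2 = params.gaussian_prior_var
            mu0 = float(x.mean())
            prec = 1.0 / tau2 + sizes[k] / sigma2
            comps[k] = (mu0 / tau2 + x[members].sum(axis=0) / sigma2) / prec
        else:
            a = params.beta_a if params else 1.0
            b = params.beta_b if params else 1.0
            comps[k] = (a + x[members].sum(axis=0)) / (a + b + sizes[k])
    probs = membership_probabilities(x, comps, sizes, gaussian,
                                     params.gaussian_obs_var if params else 0.25)
    return ClusteringResult(
        components=comps,
        sizes=sizes,
        probs=probs,
        labels=probs.argmax(axis=1),
        feature_names=names,
        confidence_threshold=confidence_threshold,
        params=params,
    )


def membership_probabilities(
    x: np.ndarray,
    comps: np.ndarray,
    sizes: np.ndarray,
    gaussian: bool = False,
    sigma2: float = 0.25,
) -> np.ndarray:
    """Posterior membership probabilities of each patient under each
    component profile (mixture weights proportional to component sizes)."""
    eps = 1e-9
    logw = np.log(sizes + eps) - np.log(sizes.sum() + eps * len(sizes))
    if gaussian:
        ll = np.stack([
            -0.5 * np.sum(np.log(2 * np.pi * sigma2) + (x - c) ** 2 / sigma2, axis=1)
            for c in comps
        ], axis=1)
    else:
        theta = np.clip(comps, eps, 1 - eps)
        ll = x @ np.log(theta).T + (1 - x) @ np.log(1 - theta).T
    logp = ll + logw
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def merge_components(
    result: ClusteringResult, threshold: float | None = None
) -> ClusteringResult:
    """Merge components whose feature profiles have cosine similarity at or
    above the threshold (transitive closure), re-aggregating probabilities."""
    if threshold is None:
        threshold = result.params.cosine_merge_threshold if result.params else 0.95
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("cosine threshold must be in [0, 1]")
    comps = result.components
    K = comps.shape[0]
    norms = np.linalg.norm(comps, axis=1)
    norms[norms == 0] = 1.0
    cos = (comps @ comps.T) / np.outer(norms, norms)
    parent = list(range(K))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(K):
        for j in range(i + 1, K):
            if cos[i, j] >= threshold - 1e-12:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(K):
        groups.setdefault(find(i), []).append(i)
    order = sorted(groups.values(), key=lambda g: min(g))
    new_comps = np.stack([
        np.average(comps[g], axis=0, weights=np.maximum(result.sizes[g], 1))
        for g in order
    ])
    new_sizes = np.array([result.sizes[g].sum() for g in order])
    new_probs = np.stack(
        [result.probs[:, g].sum(axis=1) for g in order], axis=1
    )
    return ClusteringResult(
        components=new_comps,
        sizes=new_sizes,
        probs=new_probs,
        labels=new_probs.argmax(axis=1),
        feature_names=result.feature_names,
        confidence_threshold=result.confidence_threshold,
        params=result.params,
    )


def two_step_fit(
    matrix: pd.DataFrame | np.ndarray,
    params: DpHyperParams | None = None,
    confidence_threshold: float = 0.8,
) -> ClusteringResult:
    """Two-pass fit: full-matrix fit (with cosine merging), then a second
    sampling pass restricted to the patients left below the confidence
    threshold.  Step-2 components are appended after step-1 components and
    low-confidence patients take their step-2 assignments."""
    params = params or DpHyperParams()
    x, names = _as_matrix(matrix)
    step1 = merge_components(fit_dp_mixture(x, params, confidence_threshold))
    step1 = replace(
        step1, feature_names=names,
        probs=step1.probs, labels=step1.labels,
    )
    low = ~step1.high_confidence
    if low.sum() < 2:
        return step1
    sub = x[low]
    params2 = replace(params, seed=params.seed + 1)
    step2 = merge_components(fit_dp_mixture(sub, params2, confidence_threshold))
    K1, K2 = step1.n_components, step2.n_components
    n = x.shape[0]
    probs = np.zeros((n, K1 + K2))
    probs[~low, :K1] = step1.probs[~low]
    probs[low, K1:] = step2.probs
    comps = np.vstack([step1.components, step2.components])
    sizes = np.concatenate([
        np.bincount(step1.labels[~low], minlength=K1),
        step2.sizes,
    ])
    return ClusteringResult(
        components=comps,
        sizes=sizes,
        probs=probs,
        labels=probs.argmax(axis=1),
        feature_names=names,
        confidence_threshold=confidence_threshold,
        params=params,
    )


def grid_search(
    matrix: pd.DataFrame | np.ndarray,
    grid: Sequence[DpHyperParams],
    confidence_threshold: float = 0.8,
) -> pd.DataFrame:
    """Score a hyperparameter grid; rank by (1) number of high-confidence
    components, (2) mean top assignment probability, (3) mean top1 − top2
    delta, lexicographically, ties broken by grid order.  Returns the
    ranked table with the winning configuration first."""
    if not len(grid):
        raise ValueError("empty hyperparameter grid")
    rows = []
    for g_idx, p in enumerate(grid):
        res = merge_components(fit_dp_mixture(matrix, p, confidence_threshold))
        rows.append({
            "grid_index": g_idx,
            "n_components": res.n_components,
            "n_high_confidence_components": res.n_high_confidence_components(),
            "mean_top_prob": float(res.top_prob.mean()),
            "mean_delta": float(res.delta.mean()),
            "params": p,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["n_high_confidence_components", "mean_top_prob", "mean_delta", "grid_index"],
        ascending=[False, False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def postprocess_assignments(
    result: ClusteringResult,
    matrix: pd.DataFrame | np.ndarray,
    class_defining_map: Mapping[int, Iterable[str]],
    manual_splits: Sequence[tuple[int, str]] = (),
) -> np.ndarray:
    """Constrain assignments by class-defining lesions and apply manual
    component splits.

    A patient is assigned to the highest-probability component among those
    whose class-defining lesion (any of the listed features) they carry;
    components without an entry in the map are unconstrained (with a
    warning).  Patients eligible for no component are left unassigned
    (label −1; these feed the mNOS path downstream).  ``manual_splits``
    lists (component, feature) pairs: members of the component carrying the
    feature are split into a new component appended at the end.
    """
    x, names = _as_matrix(matrix)
    if len(result.feature_names) == x.shape[1]:
        names = result.feature_names
    name_idx = {nm: i for i, nm in enumerate(names)}
    K = result.n_components
    for k in range(K):
        if k not in class_defining_map:
            warnings.warn(
                f"component {k} has no class-defining lesion entry; "
                "no constraint applied",
                stacklevel=2,
            )
    eligible = np.ones((x.shape[0], K), dtype=bool)
    for k, features in class_defining_map.items():
        cols = [name_idx[f] for f in features]
        eligible[:, k] = x[:, cols].any(axis=1) if cols else True
    masked = np.where(eligible, result.probs, -np.inf)
    labels = masked.argmax(axis=1)
    labels[~np.isfinite(masked.max(axis=1))] = -1
    next_label = K
    for comp, feature in manual_splits:
        col = name_idx[feature]
        members = (labels == comp) & (x[:, col] == 1)
        labels[members] = next_label
        next_label += 1
    return labels
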