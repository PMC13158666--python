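"""Shared statistical machinery.

Everything downstream — proximity dispersion, distance/neighbor regression,
bacterial-object compactness — funnels its permutation nulls through the same
normal-approximation machinery: fit a normal distribution to the permuted
statistics and read the observed statistic's one-sided tail probability off
that fit.  Benjamini-Hochberg correction, exact binomial tails, per-feature
standardisation + PCA embedding and permutation-tested Pearson correlation
also live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA


class DegenerateNullWarning(UserWarning):
    """Raised when a permutation null has zero spread."""


@dataclass(frozen=True)
class PermutationTestResult:
    """Observed statistic, fitted normal null and a one-sided p-value."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_one_sided: float
    n_permutations: int
    tail: str = "upper"
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p": self.p_one_sided,
            "n_permutations": self.n_permutations,
            "tail": self.tail,
        }


@dataclass(frozen=True)
class Embedding:
    """PCA scores with per-component explained-variance fractions."""

    scores: np.ndarray  # samples x components
    explained_variance_fraction: np.ndarray
    component_count: int
    components: np.ndarray = field(default=None, repr=False)  # loadings, comps x features
    feature_names: tuple | None = None


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) on the sorted p-values,
    mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def normal_approx_p(
    observed: float,
    null_samples,
    tail: str = "upper",
    n_permutations: int | None = None,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-sided p-value from a normal fit to permuted statistics.

    ``tail='upper'`` asks how often the null exceeds the observation
    (P[N(mu, sd^2) >= observed]); ``'lower'`` the reverse.
    """
    null = np.asarray(null_samples, dtype=float)
    if null.size < 2:
        raise ValueError("need at least 2 null samples to fit a normal")
    if tail not in ("upper", "lower"):
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    mu = float(np.mean(null))
    sd = float(np.std(null, ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate permutation null (sd = 0)", DegenerateNullWarning)
        if observed == mu:
            p = 0.5
        elif (observed > mu) == (tail == "upper"):
            p = 0.0
        else:
            p = 1.0
        z = 0.0 if observed == mu else np.sign(observed - mu) * np.inf
    else:
        z = (observed - mu) / sd
        p = float(sps.norm.sf(z) if tail == "upper" else sps.norm.cdf(z))
    return PermutationTestResult(
        observed=float(observed),
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p_one_sided=float(p),
        n_permutations=n_permutations if n_permutations is not None else null.size,
        tail=tail,
        seed=seed,
    )


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0).

    Evaluated through the regularised incomplete beta survival function,
    which is computed in log space internally and therefore does not
    underflow even for tails around 1e-73.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p0))


def standardize(matrix, ddof: int = 0, drop_constant: bool = True):
    """Per-feature (column) z-scoring across samples (rows).

    Zero-variance columns are dropped with a warning rather than left as
    NaN; returns ``(z, kept_column_indices)``.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2D matrix with >= 2 samples")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all features are constant; nothing to standardize")
    if drop_constant and not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
        x, mu, sd = x[:, keep], mu[keep], sd[keep]
    z = (x - mu) / sd
    return z, np.flatnonzero(keep)


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    """Deterministic PCA sign convention: the largest-magnitude loading of
    each component is made positive."""
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    return components, scores


def pca_embed(matrix, n_components: int | None = None) -> Embedding:
    """PCA of an already-prepared matrix with the fixed sign convention."""
    x = np.asarray(matrix, dtype=float)
    max_comp = min(x.shape[0], x.shape[1])
    k = max_comp if n_components is None else min(n_components, max_comp)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    comps, scores = _fix_signs(pca.components_.copy(), scores)
    return Embedding(
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        component_count=k,
        components=comps,
    )


def standardize_and_embed(matrix, n_components: int | None = None) -> Embedding:
    """Per-feature z-score followed by PCA with the deterministic sign
    convention.  Matches the standardise-then-project recipe used for both
    expression matrices and -log10(p) program matrices."""
    z, _ = standardize(matrix)
    return pca_embed(z, n_components=n_components)


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    if denom == 0:
        return np.nan
    return float(np.clip((xm * ym).sum() / denom, -1.0, 1.0))


def correlation_with_permutation(
    x,
    y,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
):
    """Pearson correlation with a shuffle-x permutation null.

    The null shuffles ``x`` (e.g. the minimum physical distances) across
    samples, recomputes r each time, fits a normal to the permuted r's and
    evaluates the requested tail.  ``alternative`` is ``'two-sided'``
    (p from |z|), ``'greater'`` or ``'less'``.

    Returns ``(r, PermutationTestResult)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1D vectors, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y: correlation undefined")
    r = pearson_r(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    # vectorised shuffles: r = sum(xs * yc) / norm, with centred/scaled y fixed
    yc = (y - y.mean()) / (y.std() * n)
    xs = (x - x.mean()) / x.std()
    perm_idx = rng.permuted(np.broadcast_to(np.arange(n), (n_perm, n)), axis=1)
    null_r = xs[perm_idx] @ yc
    mu = float(null_r.mean())
    sd = float(null_r.std(ddof=1))
    if sd == 0:
        res = normal_approx_p(r, null_r, tail="upper", seed=seed)
        return r, res
    z = (r - mu) / sd
    if alternative == "two-sided":
        p = float(2.0 * sps.norm.sf(abs(z)))
        tail = "upper"
    elif alternative == "greater":
        p = float(sps.norm.sf(z))
        tail = "upper"
    elif alternative == "less":
        p = float(sps.norm.cdf(z))
        tail = "lower"
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return r, PermutationTestResult(
        observed=r,
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p_one_sided=min(1.0, p),
        n_permutations=n_perm,
        tail=tail,
        seed=seed,
    )
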