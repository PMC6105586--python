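"""Discriminant-posterior crypsis scores and their geographic regressions.

A nest is morphologically cryptic when even a discriminant analysis over
all characters struggles to assign it to its own species.  The score used
here is the linear-discriminant posterior probability of the nest's
a-priori species: a pooled within-species covariance is estimated from
nest means, and the posterior for species s is proportional to

    prior_s * exp(-0.5 * Mahalanobis^2(x, mean_s)).

Low posteriors for the true species mean high crypsis.  The scores are
then regressed (ordinary least squares) on per-nest altitude and
latitude; a negative altitude slope reproduces the pattern that
high-altitude species are harder to tell apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import NestTable, ValidationError


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of crypsis scores on a per-nest covariate."""

    r: float
    slope: float
    intercept: float
    p: float
    n: int
    covariate: str = ""
    transform: str = "identity"

    def to_dict(self) -> dict:
        return {"covariate": self.covariate, "transform": self.transform,
                "r": self.r, "slope": self.slope, "intercept": self.intercept,
                "p": self.p, "n": self.n}


def _fit_lda(X: np.ndarray, groups: np.ndarray,
             species: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-species covariance (unbiased) and species means."""
    n, d = X.shape
    k = len(species)
    means = np.vstack([X[groups == s].mean(axis=0) for s in range(k)])
    pooled = np.zeros((d, d))
    for s in range(k):
        dev = X[groups == s] - means[s]
        pooled += dev.T @ dev
    pooled /= (n - k)
    return means, pooled


def _posteriors(X: np.ndarray, means: np.ndarray, pooled: np.ndarray,
                log_priors: np.ndarray) -> np.ndarray:
    try:
        chol = np.linalg.cholesky(pooled)
    except np.linalg.LinAlgError:
        raise ValidationError(
            "singular pooled covariance; reduce dimensionality first "
            "(prune characters or project onto principal components)")
    from scipy.linalg import solve_triangular

    # Mahalanobis^2 via triangular solves against each species mean
    d2 = np.empty((X.shape[0], means.shape[0]))
    for s in range(means.shape[0]):
        z = solve_triangular(chol, (X - means[s]).T, lower=True)
        d2[:, s] = (z ** 2).sum(axis=0)
    logp = log_priors - 0.5 * d2
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    return post / post.sum(axis=1, keepdims=True)


def lda_posteriors(nests: NestTable, mode: str = "resubstitution",
                   priors: str = "equal",
                   score: str = "posterior") -> pd.DataFrame:
    """Per-nest discriminant scores of correct species identification.

    Returns a frame with columns ``nest_id, true_species,
    assigned_species, posterior_correct, mode``.  ``mode='resubstitution'``
    scores the training nests directly; ``'leave_one_out'`` refits the
    model without the scored nest.  ``priors`` is ``'equal'`` (default) or
    ``'proportional'`` to group sizes.  ``score='typicality'`` replaces
    the posterior with the chi-square tail probability of the Mahalanobis
    distance to the nest's own species mean (an alternative reading of an
    identification p-value; not the default).
    """
    if mode not in ("resubstitution", "leave_one_out"):
        raise ValidationError(f"unknown mode {mode!r}")
    if priors not in ("equal", "proportional"):
        raise ValidationError(f"unknown priors {priors!r}")
    if score not in ("posterior", "typicality"):
        raise ValidationError(f"unknown score {score!r}")
    species = list(dict.fromkeys(nests.data["species"]))
    if len(species) < 2:
        raise ValidationError("discriminant analysis needs >= 2 species")
    unknown = set(nests.data["species"]) - set(species)
    if unknown:
        raise ValidationError(f"unknown species label(s) {sorted(unknown)}")
    X = nests.matrix
    n, d = X.shape
    k = len(species)
    if n - k < d:
        raise ValidationError(
            f"{n} nests minus {k} species leaves fewer degrees of freedom than "
            f"{d} characters; reduce dimensionality (prune or PCA) first")
    groups = np.array([species.index(s) for s in nests.data["species"]])

    def run(train_mask: np.ndarray, eval_idx: np.ndarray) -> np.ndarray:
        Xt, gt = X[train_mask], groups[train_mask]
        counts = np.bincount(gt, minlength=k)
        if (counts < 2).any():
            raise ValidationError("every species needs >= 2 nests for LOO refits")
        means, pooled = _fit_lda(Xt, gt, species)
        if priors == "equal":
            log_priors = np.zeros(k)
        else:
            log_priors = np.log(counts / counts.sum())
        if score == "typicality":
            from scipy.linalg import solve_triangular
            try:
                chol = np.linalg.cholesky(pooled)
            except np.linalg.LinAlgError:
                raise ValidationError(
                    "singular pooled covariance; reduce dimensionality first")
            out = np.empty((len(eval_idx), k))
            for s in range(k):
                z = solve_triangular(chol, (X[eval_idx] - means[s]).T, lower=True)
                out[:, s] = stats.chi2.sf((z ** 2).sum(axis=0), df=d)
            return out
        return _posteriors(X[eval_idx], means, pooled, log_priors)

    if mode == "resubstitution":
        post = run(np.ones(n, dtype=bool), np.arange(n))
    else:
        post = np.empty((n, k))
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            post[i] = run(mask, np.array([i]))[0]
            mask[i] = True
    if score == "posterior":
        sums = post.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValidationError("posteriors do not sum to 1")
    assigned = np.argmax(post, axis=1)
    return pd.DataFrame({
        "nest_id": nests.data["nest_id"].to_numpy(),
        "true_species": nests.data["species"].to_numpy(),
        "assigned_species": [species[a] for a in assigned],
        "posterior_correct": post[np.arange(n), groups],
        "mode": mode,
    })


def regress_scores(scores: pd.DataFrame, covariate: pd.Series | np.ndarray,
                   transform: str = "absolute",
                   covariate_name: str = "") -> RegressionResult:
    """OLS of posterior_correct on a per-nest covariate.

    ``transform='absolute'`` regresses on |covariate| (the convention used
    for altitude and latitude so hemispheres do not cancel);
    ``'identity'`` uses the raw values.  Returns the signed correlation
    coefficient, slope, intercept and the two-sided p-value from the
    t-statistic with n - 2 degrees of freedom.
    """
    if transform not in ("absolute", "identity"):
        raise ValidationError(f"unknown transform {transform!r}")
    y = scores["posterior_correct"].to_numpy(dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(y):
        raise ValidationError("covariate length does not match scores")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite covariate value")
    if len(y) < 3:
        raise ValidationError("need at least 3 nests")
    if transform == "absolute":
        x = np.abs(x)
    if np.std(x) == 0:
        raise ValidationError("constant covariate")
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.rvalue), float(fit.slope),
                            float(fit.intercept), float(fit.pvalue), len(y),
                            covariate=covariate_name, transform=transform)
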