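"""Distance-matrix construction: morphometric, AFLP-phylogenetic, ecological.

The analysis works on Euclidean distances computed from dimension-reduced
data blocks and aggregated to species level.  Morphometric characters are
first divided by the head-size index CS (removing body size), averaged to
nest means, and pruned of near-collinear pairs; the remaining block is
reduced by PCA to the leading components explaining at least 80% of the
variance.  The binary AFLP matrix and the ecological variable block go
through the same PCA -> Euclidean -> species-mean pipeline, yielding the
phylogenetic and ecological distance proxies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .io_formats import (AFLPMatrix, LocalityTable, NestTable, PipelineConfig,
                         ValidationError)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric non-negative matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValidationError(f"distance matrix shape {vals.shape} != ({n}, {n})")
        if n == 0:
            raise ValidationError("empty distance matrix")
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite distance")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-9):
            raise ValidationError("distance matrix diagonal not zero")
        if (vals < -1e-12).any():
            raise ValidationError("negative distance")
        sym = (vals + vals.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        object.__setattr__(self, "values", np.maximum(sym, 0.0))

    def __len__(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper triangle, row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def subset(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class SpeciesDistanceSummary:
    """Species-level arithmetic means of pairwise entity distances.

    ``inter`` holds, for each ordered species pair (s, t), the mean distance
    over all cross pairs (i in s, j in t); its diagonal holds the
    within-species means so the matrix stays symmetric, but Mantel tests
    consume only the off-diagonal part via :meth:`inter_matrix`.  ``intra``
    is the mean over unordered within-species pairs; self-comparisons
    (distance 0 of an entity with itself) are always excluded.  Species with
    a single entity have no within-species pair and get NaN intra.
    """

    species: tuple[str, ...]
    inter: np.ndarray
    intra: np.ndarray  # per-species, NaN for singletons
    n_entities: dict[str, int]

    def inter_matrix(self) -> DistanceMatrix:
        """Interspecific means as a DistanceMatrix (diagonal zeroed)."""
        vals = self.inter.copy()
        np.fill_diagonal(vals, 0.0)
        return DistanceMatrix(self.species, vals)

    def subset(self, species) -> "SpeciesDistanceSummary":
        idx = [self.species.index(s) for s in species]
        return SpeciesDistanceSummary(
            tuple(species), self.inter[np.ix_(idx, idx)], self.intra[idx],
            {s: self.n_entities[s] for s in species})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.inter, index=list(self.species),
                          columns=list(self.species))
        df["intra"] = self.intra
        df["n_entities"] = [self.n_entities[s] for s in self.species]
        return df


@dataclass(frozen=True)
class PCAReduction:
    """Leading principal-component scores retained at a variance threshold."""

    component_scores: np.ndarray
    explained_fractions: np.ndarray
    n_retained: int
    dropped_constant: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# morphometrics


def normalize_by_cs(nests: NestTable) -> NestTable:
    """Divide every character by the row's head-size index CS.

    Removes overall body size, leaving dimensionless shape ratios; the cs
    column itself is kept as metadata but no longer enters the analysis set.
    """
    cs = nests.data["cs"].to_numpy(dtype=float)
    if (cs <= 0).any():
        bad = nests.data["nest_id"].iloc[int(np.argmin(cs))]
        raise ValidationError(f"cs must be > 0 (offending nest {bad!r})")
    df = nests.data.copy()
    for c in nests.characters:
        df[c] = df[c].to_numpy(dtype=float) / cs
    return NestTable(df, nests.characters)


def nest_means(workers: NestTable) -> NestTable:
    """Collapse a worker-level table to unweighted arithmetic nest means.

    cs is averaged alongside the characters; species and locality labels
    must be constant within a nest.
    """
    if len(workers) == 0:
        raise ValidationError("empty worker table")
    df = workers.data
    for col in ("species", "locality_id"):
        if df.groupby("nest_id")[col].nunique().gt(1).any():
            raise ValidationError(f"nest with inconsistent {col!r} labels")
    num = [*workers.characters, "cs"]
    agg = df.groupby("nest_id", sort=False)[num].mean()
    meta = df.groupby("nest_id", sort=False)[["species", "locality_id"]].first()
    out = pd.concat([meta, agg], axis=1).reset_index()
    return NestTable(out, workers.characters)


def prune_correlated_characters(
    nests: NestTable, threshold: float = 0.8, seed: int = 0,
) -> tuple[tuple[str, ...], list[tuple[str, str, float, str]]]:
    """Drop one member of every near-collinear character pair.

    For every unordered pair with |Pearson r| >= ``threshold`` across rows,
    one member is dropped by a seeded uniform draw.  Pairs are processed in
    alphabetical order for reproducibility and a character already dropped
    cannot trigger further drops.

    Returns the retained character tuple and a report of
    ``(dropped, kept, r, reason)`` records.
    """
    if not 0 < threshold <= 1:
        raise ValidationError("threshold must be in (0, 1]")
    if len(nests) < 3:
        raise ValidationError("need at least 3 rows to estimate correlations")
    X = nests.matrix
    chars = nests.characters
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    rng = np.random.default_rng(seed)
    dropped: set[str] = set()
    report: list[tuple[str, str, float, str]] = []
    pairs = sorted(
        (tuple(sorted((chars[i], chars[j]))), corr[i, j])
        for i, j in itertools.combinations(range(len(chars)), 2)
        if np.isfinite(corr[i, j]) and abs(corr[i, j]) >= threshold
    )
    for (a, b), r in pairs:
        if a in dropped or b in dropped:
            continue
        loser, winner = (a, b) if rng.random() < 0.5 else (b, a)
        dropped.add(loser)
        report.append((loser, winner, float(r), f"|r|={abs(r):.3f}>={threshold}"))
        log.warning("pruning %s (|r|=%.3f with %s)", loser, abs(r), winner)
    retained = tuple(c for c in chars if c not in dropped)
    return retained, report


# ---------------------------------------------------------------------------
# PCA and Euclidean distances


def pca_reduce(matrix: np.ndarray, threshold: float = 0.80,
               scaling: str = "covariance",
               variable_names: tuple[str, ...] | None = None) -> PCAReduction:
    """Project onto the fewest leading principal components whose cumulative
    explained-variance fraction reaches ``threshold``.

    ``scaling='covariance'`` centres columns (appropriate when variables
    share a scale, e.g. CS-normalised ratios or 0/1 bands);
    ``scaling='correlation'`` additionally standardises to unit variance
    (heterogeneous units, e.g. the climatic and soil block).  Under
    correlation scaling, zero-variance variables are excluded with a
    warning; under covariance scaling they are harmless (zero loading).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with >= 2 rows")
    names = variable_names or tuple(f"v{j}" for j in range(X.shape[1]))
    sd = X.std(axis=0, ddof=1)
    dropped_constant: tuple[str, ...] = ()
    if scaling == "correlation":
        keep = sd > 0
        if not keep.all():
            dropped_constant = tuple(n for n, k in zip(names, keep) if not k)
            log.warning("excluding constant variable(s) under correlation "
                        "scaling: %s", dropped_constant)
            X, sd = X[:, keep], sd[keep]
        if X.shape[1] == 0:
            raise ValidationError("all variables constant")
        X = (X - X.mean(axis=0)) / sd
    elif scaling == "covariance":
        if (sd > 0).sum() == 0:
            raise ValidationError("all variables constant")
        X = X - X.mean(axis=0)
    else:
        raise ValidationError(f"unknown PCA scaling {scaling!r}")
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    fractions = pca.explained_variance_ratio_
    cumulative = np.cumsum(fractions)
    n_retained = int(np.searchsorted(cumulative, threshold - 1e-12) + 1)
    n_retained = min(n_retained, scores.shape[1])
    return PCAReduction(scores[:, :n_retained], fractions, n_retained,
                        dropped_constant)


def euclidean_distance(matrix: np.ndarray, labels=None) -> DistanceMatrix:
    """Pairwise Euclidean distances between rows."""
    X = np.asarray(matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValidationError("non-finite coordinate")
    labels = tuple(labels) if labels is not None else tuple(
        str(i) for i in range(X.shape[0]))
    return DistanceMatrix(labels, squareform(pdist(X, metric="euclidean")))


def single_character_distance(nests: NestTable, character: str) -> DistanceMatrix:
    """|x_i - x_j| distances on one character (1-D Euclidean)."""
    if character not in nests.characters:
        raise ValidationError(f"unknown character {character!r}")
    x = nests.data[character].to_numpy(dtype=float)
    return euclidean_distance(x[:, None], labels=nests.data["nest_id"])


def species_mean_distances(dist: DistanceMatrix,
                           species_of: dict[str, str]) -> SpeciesDistanceSummary:
    """Aggregate an entity-level distance matrix to species-level means.

    Self-comparisons (the zero diagonal) never enter any mean; the
    within-species mean runs over unordered distinct pairs only.
    """
    unlabelled = [l for l in dist.labels if l not in species_of]
    if unlabelled:
        raise ValidationError(f"entities without species label: {unlabelled[:5]}")
    groups = pd.Series([species_of[l] for l in dist.labels])
    species = tuple(dict.fromkeys(groups))  # first-appearance order
    idx = {s: np.flatnonzero((groups == s).to_numpy()) for s in species}
    k = len(species)
    inter = np.zeros((k, k))
    intra = np.full(k, np.nan)
    for a, s in enumerate(species):
        ii = idx[s]
        if len(ii) > 1:
            block = dist.values[np.ix_(ii, ii)]
            iu = np.triu_indices(len(ii), k=1)
            intra[a] = block[iu].mean()
            inter[a, a] = intra[a]
        for b in range(a + 1, k):
            jj = idx[species[b]]
            m = dist.values[np.ix_(ii, jj)].mean()
            inter[a, b] = inter[b, a] = m
    return SpeciesDistanceSummary(species, inter, intra,
                                  {s: len(idx[s]) for s in species})


# ---------------------------------------------------------------------------
# assembled distance families


def all_character_distance(nests: NestTable, config: PipelineConfig,
                           characters=None) -> tuple[SpeciesDistanceSummary, PCAReduction]:
    """All-character morphological distances among nests, species-aggregated.

    ``nests`` must already be CS-normalised nest means; ``characters``
    restricts to the retained (pruned) set.
    """
    chars = tuple(characters) if characters is not None else nests.characters
    X = nests.data[list(chars)].to_numpy(dtype=float)
    red = pca_reduce(X, config.cumulative_variance_threshold,
                     config.pca_scaling_morphology, chars)
    dist = euclidean_distance(red.component_scores, labels=nests.data["nest_id"])
    return species_mean_distances(dist, nests.species_of()), red


def phylogenetic_distance(aflp: AFLPMatrix,
                          config: PipelineConfig) -> tuple[SpeciesDistanceSummary, PCAReduction]:
    """Genetic distance proxy from the binary AFLP band matrix.

    PCA on the 0/1 matrix (covariance scaling by default), Euclidean
    distances among individuals, then species-level means.
    """
    if len(set(aflp.species)) < 2:
        raise ValidationError("need >= 2 species for phylogenetic distances")
    X = aflp.values.astype(float)
    if (X == X[0]).all():  # no band variation at all: zero distances
        dist = DistanceMatrix(aflp.individual_ids,
                              np.zeros((X.shape[0], X.shape[0])))
        red = PCAReduction(np.zeros((X.shape[0], 1)), np.array([0.0]), 1)
        return species_mean_distances(dist, aflp.species_of()), red
    red = pca_reduce(aflp.values.astype(float),
                     config.cumulative_variance_threshold,
                     config.pca_scaling_aflp, aflp.loci)
    dist = euclidean_distance(red.component_scores, labels=aflp.individual_ids)
    return species_mean_distances(dist, aflp.species_of()), red


def ecological_distance(localities: LocalityTable,
                        config: PipelineConfig) -> tuple[SpeciesDistanceSummary, PCAReduction]:
    """Ecological-niche distance proxy from the climatic and soil block.

    Correlation-scaled PCA by default because the 28 variables carry
    heterogeneous units; Euclidean distances among species-locality rows,
    then species-level means.
    """
    X = localities.data[list(localities.eco_variables)].to_numpy(dtype=float)
    red = pca_reduce(X, config.cumulative_variance_threshold,
                     config.pca_scaling_ecology, localities.eco_variables)
    row_labels = tuple(f"{s}|{l}" for s, l in
                       zip(localities.data["species"], localities.data["locality_id"]))
    dist = euclidean_distance(red.component_scores, labels=row_labels)
    species_of = dict(zip(row_labels, localities.data["species"]))
    return species_mean_distances(dist, species_of), red
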