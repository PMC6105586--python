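"""Synthetic datasets with known ground truth for the whole pipeline.

The study system is a complex of cryptic ant species: species that are
nearly indistinguishable morphologically yet clearly separated by genetic
markers.  The generator emulates the three data blocks such a study rests
on — worker morphometrics aggregated to nest means, a binary AFLP band
matrix, and species-locality rows carrying climatic and soil variables —
under scenarios with a controlled evolutionary signal:

``stasis_bm``
    Character means evolve by Brownian motion along an ultrametric species
    tree, so morphological distance grows (slowly, for small ``bm_rate``)
    with phylogenetic distance: the stasis expectation.
``convergence_mirror``
    Species trait vectors are laid out so that trait distance mirrors
    (anti-correlates with) patristic distance: phylogenetically distant
    species look alike — the convergence alternative.
``null_independent``
    Species means are drawn independently of the tree; every downstream
    test should reject at its nominal rate.

Optional couplings add the remaining effects of interest: selected
characters can track a latent ecological-niche axis (``eco_coupling``),
and the among-nest trait variance can inflate with altitude
(``altitude_variance_slope``), which makes high-altitude species harder
to tell apart — the altitude-crypsis pattern.

All randomness flows from ``scenario.seed``; each generator derives an
independent stream so the four outputs are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (DEFAULT_CHARACTERS, DISCRETE_CHARACTERS,
                         ECO_VARIABLES, AFLPMatrix, LocalityTable, NestTable,
                         ValidationError)

#: Per-species altitude distributions (mean, low, high, metres a.s.l.);
#: defaults follow the published altitude profiles of the ten complex
#: members, spanning lowland (~100 m) to alpine (~2000 m) specialists.
DEFAULT_ALTITUDE_RANGES: tuple[tuple[float, float, float], ...] = (
    (1856, 970, 2400), (586, 1, 2100), (328, 27, 940), (210, 3, 527),
    (1351, 110, 2300), (2009, 1275, 2500), (101, 1, 1200), (623, 1, 2320),
    (909, 1, 2235), (285, 0, 2100),
)

_TRAIT_MODES = ("stasis_bm", "convergence_mirror", "null_independent")

# stream offsets so each generator has an independent but derived rng
_S_TREE, _S_TRAITS, _S_AFLP, _S_LOCALITIES, _S_REGISTRY = 11, 13, 17, 19, 23


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth configuration for one synthetic dataset.

    Default dimensions mirror the real study: 10 species, ~46 nests per
    species (~464 nests), ~2 measured workers per nest (~990 workers),
    31 morphometric characters, 890 AFLP loci on ~27 individuals per
    species (~269), and ~110 localities per species (~1106
    species-locality rows).
    """

    n_species: int = 10
    n_nests_per_species: int = 46
    n_workers_per_nest: int = 2
    n_characters: int = 31
    n_loci: int = 890
    n_aflp_individuals_per_species: int = 27
    n_localities_per_species: int = 110
    tree_mode: str = "random_coalescent"
    fixed_newick: str | None = None
    trait_mode: str = "stasis_bm"
    # cryptic complex: between-species drift sd (sqrt(bm_rate) = 0.02)
    # matches the among-nest sd, so species genuinely overlap
    bm_rate: float = 4e-4            # trait variance per unit tree depth
    within_species_sd: float = 0.02  # among-nest sd on the ratio scale
    worker_sd: float = 0.01          # among-worker sd within a nest
    aflp_liability_rate: float = 0.5
    eco_coupled_characters: tuple[str, ...] = ()
    eco_coupling_strength: float = 0.0
    altitude_variance_slope: float = 0.0  # fractional sd increase per km
    eco_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_species", "n_nests_per_species", "n_loci",
                     "n_aflp_individuals_per_species",
                     "n_localities_per_species"):
            if getattr(self, name) < 2:
                raise ValidationError(f"{name} must be >= 2")
        if self.n_workers_per_nest < 1:
            raise ValidationError("n_workers_per_nest must be >= 1")
        if self.n_characters < 4:
            raise ValidationError("n_characters must be >= 4")
        if self.trait_mode not in _TRAIT_MODES:
            raise ValidationError(f"unknown trait_mode {self.trait_mode!r}")
        for name in ("bm_rate", "within_species_sd", "worker_sd",
                     "aflp_liability_rate", "altitude_variance_slope",
                     "eco_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        object.__setattr__(self, "eco_coupled_characters",
                           tuple(self.eco_coupled_characters))

    @property
    def character_names(self) -> tuple[str, ...]:
        if self.n_characters <= len(DEFAULT_CHARACTERS):
            return DEFAULT_CHARACTERS[: self.n_characters]
        extra = tuple(f"X{i}" for i in range(self.n_characters - len(DEFAULT_CHARACTERS)))
        return DEFAULT_CHARACTERS + extra

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1:02d}" for i in range(self.n_species))


# ---------------------------------------------------------------------------
# species tree


@dataclass(frozen=True)
class SpeciesTree:
    """Ultrametric species tree as parent/branch-length arrays.

    Nodes ``0..n-1`` are tips (in ``labels`` order), ``2n-2`` is the root.
    ``age`` is the node height above the tips; the root age (tree depth)
    is normalised to 1 for random coalescent trees so rates are expressed
    per unit depth.
    """

    labels: tuple[str, ...]
    parent: np.ndarray        # parent index per node; -1 at the root
    branch_length: np.ndarray
    age: np.ndarray

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def depth(self) -> float:
        return float(self.age[-1])

    def children(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {i: [] for i in range(len(self.parent))}
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def patristic(self) -> np.ndarray:
        """Tip-to-tip path-length matrix, 2 x (age of the MRCA)."""
        n = self.n_tips
        ancestors = []
        for tip in range(n):
            chain, node = [], tip
            while node != -1:
                chain.append(node)
                node = int(self.parent[node])
            ancestors.append(chain)
        dist = np.zeros((n, n))
        for i in range(n):
            set_i = set(ancestors[i])
            for j in range(i + 1, n):
                mrca = next(a for a in ancestors[j] if a in set_i)
                dist[i, j] = dist[j, i] = 2.0 * self.age[mrca]
        return dist

    def newick(self) -> str:
        kids = self.children()

        def render(node: int) -> str:
            if not kids[node]:
                name = self.labels[node]
            else:
                name = "(" + ",".join(render(c) for c in kids[node]) + ")"
            if self.parent[node] == -1:
                return name
            return f"{name}:{self.branch_length[node]:.10g}"

        return render(len(self.parent) - 1) + ";"


def simulate_species_tree(n_species: int, seed: int = 0) -> SpeciesTree:
    """Random Kingman-coalescent ultrametric tree, depth normalised to 1.

    Lineage pairs merge at exponential waiting times with rate C(k, 2);
    node ages are then rescaled so the root sits at age 1.
    """
    if n_species < 2:
        raise ValidationError("need at least 2 species")
    rng = _rng(seed, _S_TREE)
    n_nodes = 2 * n_species - 1
    parent = np.full(n_nodes, -1, dtype=np.intp)
    age = np.zeros(n_nodes)
    active = list(range(n_species))
    t = 0.0
    nxt = n_species
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        age[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    age /= age[-1]  # normalise depth to 1
    branch = np.zeros(n_nodes)
    for i in range(n_nodes - 1):
        branch[i] = age[parent[i]] - age[i]
    labels = tuple(f"sp{i + 1:02d}" for i in range(n_species))
    return SpeciesTree(labels, parent, branch, age)


def tree_from_newick(newick: str, labels=None) -> SpeciesTree:
    """Parse an ultrametric newick string into a :class:`SpeciesTree`."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tips = [leaf for leaf in tree.leaf_node_iter()]
    tip_names = [leaf.taxon.label for leaf in tips]
    if labels is not None:
        order = {name: k for k, name in enumerate(labels)}
        tips.sort(key=lambda leaf: order[leaf.taxon.label])
        tip_names = [leaf.taxon.label for leaf in tips]
    nodes = tips + [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
    index = {id(nd): k for k, nd in enumerate(nodes)}
    n_nodes = len(nodes)
    parent = np.full(n_nodes, -1, dtype=np.intp)
    branch = np.zeros(n_nodes)
    for k, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[k] = index[id(nd.parent_node)]
            branch[k] = nd.edge.length or 0.0
    # ages from root depths (assumes ultrametric input)
    depth = np.zeros(n_nodes)
    for k, nd in enumerate(nodes):
        d, cur = 0.0, nd
        while cur.parent_node is not None:
            d += cur.edge.length or 0.0
            cur = cur.parent_node
        depth[k] = d
    age = depth.max() - depth
    return SpeciesTree(tuple(tip_names), parent, branch, age)


def _bm_on_tree(tree: SpeciesTree, rate: float, n_traits: int,
                rng: np.random.Generator) -> np.ndarray:
    """Brownian tip values (n_tips x n_traits), root state 0."""
    kids = tree.children()
    n_nodes = len(tree.parent)
    vals = np.zeros((n_nodes, n_traits))
    stack = [n_nodes - 1]
    while stack:
        node = stack.pop()
        for child in kids[node]:
            sd = np.sqrt(rate * max(tree.branch_length[child], 0.0))
            vals[child] = vals[node] + rng.normal(0.0, sd, n_traits)
            stack.append(child)
    return vals[: tree.n_tips]


def _mirror_tips(tree: SpeciesTree, sigma: float, n_traits: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Tip values whose distances anti-correlate with patristic distances.

    Classical-MDS embedding of the reversed distance matrix
    ``max(P) - P`` gives coordinates whose Euclidean distances mirror the
    tree; a random linear mix spreads them over the traits, each scaled to
    the same marginal sd a Brownian process of variance ``sigma**2`` at the
    root would produce.
    """
    P = tree.patristic()
    D = P.max() - P
    np.fill_diagonal(D, 0.0)
    n = tree.n_tips
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    keep = w > 1e-10 * w.max()
    coords = V[:, keep] * np.sqrt(w[keep])
    mix = rng.normal(size=(coords.shape[1], n_traits))
    raw = coords @ mix
    sd = raw.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return raw / sd * sigma


# ---------------------------------------------------------------------------
# localities and ecological niche


@dataclass(frozen=True)
class LocalitySim:
    table: LocalityTable
    niche_axes: np.ndarray        # n_species x 2 latent niche centroids
    altitude_means: np.ndarray    # realised per-species mean altitude


def _truncated_normal(rng, mean, lo, hi, size):
    """Rejection-sampled normal with sd = min(mean-lo, hi-mean)/3.

    Keeping three sd to the nearer range limit makes the truncation bias
    negligible, so realised per-species means stay close to the targets;
    the published limits are extremes, not typical spread.
    """
    sd = max(min(mean - lo, hi - mean) / 3.0, 1e-6)
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, lo, hi)


def simulate_localities(tree: SpeciesTree, scenario: SimScenario) -> LocalitySim:
    """Species-locality rows with 28 ecological variables and altitudes.

    Each species receives a centroid in a latent 2-axis niche space; every
    ecological variable is an affine image of the two axes plus noise
    (variables get heterogeneous offsets and scales, mimicking mixed
    units).  Altitudes are drawn per locality from species-specific ranges
    patterned on the real complex (lowland to alpine); latitudes from
    species-specific bands.
    """
    rng = _rng(scenario.seed, _S_LOCALITIES)
    n_sp, n_loc = scenario.n_species, scenario.n_localities_per_species
    # anisotropic niche space: the leading axis carries most of the
    # between-species niche variation, as empirical niche ordinations do
    axes = rng.normal(0.0, 1.0, (n_sp, 2)) * np.array([1.0, 0.5])
    n_eco = len(ECO_VARIABLES)
    loadings = rng.uniform(-1.0, 1.0, (2, n_eco))
    offsets = rng.uniform(-5.0, 50.0, n_eco)
    scales = 10.0 ** rng.uniform(-0.5, 1.5, n_eco)
    lat_centres = rng.uniform(38.0, 55.0, n_sp)
    rows = []
    alt_means = np.zeros(n_sp)
    for s, sp in enumerate(scenario.species_names):
        mean, lo, hi = DEFAULT_ALTITUDE_RANGES[s % len(DEFAULT_ALTITUDE_RANGES)]
        alts = _truncated_normal(rng, mean, lo, hi, n_loc)
        alt_means[s] = alts.mean()
        lats = np.clip(rng.normal(lat_centres[s], 2.0, n_loc), -90.0, 90.0)
        lons = rng.uniform(-10.0, 45.0, n_loc)
        latent = axes[s] + rng.normal(0.0, scenario.eco_noise_sd, (n_loc, 2))
        eco = offsets + scales * (latent @ loadings
                                  + rng.normal(0.0, scenario.eco_noise_sd,
                                               (n_loc, n_eco)))
        for i in range(n_loc):
            rows.append({"locality_id": f"{sp}_loc{i + 1:04d}", "species": sp,
                         "latitude": lats[i], "longitude": lons[i],
                         "altitude": alts[i],
                         **dict(zip(ECO_VARIABLES, eco[i]))})
    table = LocalityTable(pd.DataFrame(rows), ECO_VARIABLES)
    return LocalitySim(table, axes, alt_means)


# ---------------------------------------------------------------------------
# morphometric traits


@dataclass(frozen=True)
class TraitSim:
    workers: NestTable            # worker-level rows (with worker_id)
    species_means: pd.DataFrame   # latent per-species ratio means
    nest_localities: dict[str, str]


def simulate_traits(tree: SpeciesTree, scenario: SimScenario,
                    localities: LocalitySim | None = None) -> TraitSim:
    """Worker-level morphometric measurements under the chosen trait mode.

    Latent shape ratios evolve on the tree (or mirror it, or ignore it);
    nests add within-species noise, workers add measurement-scale noise.
    Emitted values are raw (pre-normalisation): continuous characters are
    ratio x head size CS in micrometres, where CS = (CL + CW)/2 per
    worker, so CL/CS and CW/CS are exactly complementary (their sum is 2)
    and strongly negatively correlated, and SPST tracks MPSP closely —
    the two near-collinear pairs the pruning step must find.  Two
    characters are emitted as small integer counts.

    If ``localities`` is given, each nest is pinned to one of its species'
    localities: its altitude can inflate the among-nest sd
    (``altitude_variance_slope``) and niche axis 1 shifts the species
    means of ``eco_coupled_characters`` by ``eco_coupling_strength``.
    """
    if tree.n_tips < 2:
        raise ValidationError("tree needs >= 2 tips")
    rng = _rng(scenario.seed, _S_TRAITS)
    reg = _rng(scenario.seed, _S_REGISTRY)
    chars = scenario.character_names
    species = tree.labels
    # latent traits: one ratio per character except CL/CW (driven by size
    # and the head ratio h = CL/CW) and SPST (slaved to MPSP)
    ratio_names = [c for c in chars if c not in ("CL", "CW", "SPST")]
    baselines = reg.uniform(0.2, 1.2, len(ratio_names))
    n_latent = len(ratio_names) + 2          # + log-size, head ratio
    sigma = np.sqrt(scenario.bm_rate * max(tree.depth, 1e-12))
    if scenario.trait_mode == "stasis_bm":
        tip_dev = _bm_on_tree(tree, scenario.bm_rate, n_latent, rng)
    elif scenario.trait_mode == "convergence_mirror":
        tip_dev = _mirror_tips(tree, sigma, n_latent, rng)
    else:  # null_independent
        tip_dev = rng.normal(0.0, sigma, (tree.n_tips, n_latent))
    ratio_means = baselines + tip_dev[:, : len(ratio_names)]
    log_size_means = np.log(1000.0) + tip_dev[:, -2]
    head_ratio_means = 1.08 + 0.2 * tip_dev[:, -1]

    if localities is not None and scenario.eco_coupled_characters:
        axis1 = localities.niche_axes[:, 0]
        for c in scenario.eco_coupled_characters:
            if c not in ratio_names:
                raise ValidationError(
                    f"eco-coupled character {c!r} is not a latent ratio character")
            ratio_means[:, ratio_names.index(c)] += (
                scenario.eco_coupling_strength * axis1)

    loc_by_species: dict[str, pd.DataFrame] = {}
    if localities is not None:
        for sp, grp in localities.table.data.groupby("species"):
            loc_by_species[sp] = grp.reset_index(drop=True)

    rows = []
    nest_localities: dict[str, str] = {}
    for s, sp in enumerate(species):
        for nest in range(scenario.n_nests_per_species):
            nest_id = f"{sp}_n{nest + 1:03d}"
            altitude_km = 0.0
            locality_id = f"{sp}_loc0000"
            if localities is not None:
                grp = loc_by_species[sp]
                pick = grp.iloc[int(rng.integers(len(grp)))]
                locality_id = pick["locality_id"]
                altitude_km = float(pick["altitude"]) / 1000.0
            nest_localities[nest_id] = locality_id
            nest_sd = scenario.within_species_sd * (
                1.0 + scenario.altitude_variance_slope * altitude_km)
            nest_ratio = ratio_means[s] + rng.normal(0.0, nest_sd, len(ratio_names))
            nest_log_size = log_size_means[s] + rng.normal(0.0, nest_sd)
            nest_h = head_ratio_means[s] + rng.normal(0.0, nest_sd)
            for w in range(scenario.n_workers_per_nest):
                ratio = np.clip(
                    nest_ratio + rng.normal(0.0, scenario.worker_sd,
                                            len(ratio_names)), 0.01, None)
                size = np.exp(nest_log_size + rng.normal(0.0, scenario.worker_sd))
                h = max(nest_h + rng.normal(0.0, scenario.worker_sd), 0.5)
                cl = size * 2.0 * h / (1.0 + h)
                cw = size * 2.0 / (1.0 + h)
                row = {"nest_id": nest_id, "worker_id": f"{nest_id}_w{w + 1}",
                       "species": sp, "locality_id": locality_id,
                       "cs": (cl + cw) / 2.0}
                values = dict(zip(ratio_names, ratio))
                for c in chars:
                    if c == "CL":
                        row[c] = cl
                    elif c == "CW":
                        row[c] = cw
                    elif c == "SPST":
                        spst = values.get("MPSP", 0.5) * (
                            1.0 + rng.normal(0.0, 0.5 * scenario.worker_sd))
                        row[c] = max(spst, 0.01) * row["cs"]
                    elif c in DISCRETE_CHARACTERS:
                        row[c] = float(max(0, round(values[c] * 8.0)))
                    else:
                        row[c] = values[c] * row["cs"]
                rows.append(row)
    workers = NestTable(pd.DataFrame(rows), chars)
    means = pd.DataFrame(ratio_means, index=list(species), columns=ratio_names)
    return TraitSim(workers, means, nest_localities)


# ---------------------------------------------------------------------------
# AFLP bands


def simulate_aflp(tree: SpeciesTree, scenario: SimScenario) -> AFLPMatrix:
    """Binary band matrix: Brownian liabilities clamped to [0.05, 0.95].

    Each locus starts from a uniform root band probability which evolves
    on the tree as a Brownian liability; tip probabilities are clamped and
    individuals draw bands independently, so expected between-species
    band sharing decays with patristic distance.
    """
    if scenario.n_loci < 1:
        raise ValidationError("n_loci must be >= 1")
    rng = _rng(scenario.seed, _S_AFLP)
    root = rng.uniform(0.1, 0.9, scenario.n_loci)
    dev = _bm_on_tree(tree, scenario.aflp_liability_rate, scenario.n_loci, rng)
    probs = np.clip(root + dev, 0.05, 0.95)
    ids, sps, blocks = [], [], []
    for s, sp in enumerate(tree.labels):
        k = scenario.n_aflp_individuals_per_species
        blocks.append((rng.random((k, scenario.n_loci)) < probs[s]).astype(np.uint8))
        ids += [f"{sp}_i{i + 1:03d}" for i in range(k)]
        sps += [sp] * k
    loci = tuple(f"L{j + 1:04d}" for j in range(scenario.n_loci))
    return AFLPMatrix(tuple(ids), tuple(sps), loci, np.vstack(blocks))


# ---------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class SimulatedDataset:
    scenario: SimScenario
    tree: SpeciesTree
    workers: NestTable
    aflp: AFLPMatrix
    localities: LocalityTable
    ground_truth: dict


def simulate_dataset(scenario: SimScenario) -> SimulatedDataset:
    """Generate the full coupled dataset for one scenario."""
    if scenario.tree_mode == "fixed_newick":
        if not scenario.fixed_newick:
            raise ValidationError("tree_mode=fixed_newick requires fixed_newick")
        tree = tree_from_newick(scenario.fixed_newick)
    elif scenario.tree_mode == "random_coalescent":
        tree = simulate_species_tree(scenario.n_species, scenario.seed)
    else:
        raise ValidationError(f"unknown tree_mode {scenario.tree_mode!r}")
    loc = simulate_localities(tree, scenario)
    traits = simulate_traits(tree, scenario, loc)
    aflp = simulate_aflp(tree, scenario)
    truth = {
        "scenario": dataclasses.asdict(scenario),
        "newick": tree.newick(),
        "species": list(tree.labels),
        "niche_axes": loc.niche_axes.tolist(),
        "altitude_means": loc.altitude_means.tolist(),
        "species_ratio_means": traits.species_means.to_dict(orient="index"),
    }
    return SimulatedDataset(scenario, tree, traits.workers, aflp, loc.table, truth)


# ---------------------------------------------------------------------------
# named scenario presets (desk-scale study conditions)

#: Reduced dimensions for replicated Monte-Carlo runs: full species count,
#: but fewer nests/loci/localities so hundreds of replicates stay cheap.
_DESK = dict(n_species=10, n_nests_per_species=6, n_workers_per_nest=2,
             n_loci=150, n_aflp_individuals_per_species=8,
             n_localities_per_species=8)


def scenario_stasis(seed: int = 0, **overrides) -> SimScenario:
    """Strong stasis signal: Brownian drift dominates within-species noise.

    Between-species trait sd is sqrt(bm_rate) = 0.1 on the ratio scale
    against an among-nest sd of 0.02, so morphological distance tracks
    phylogenetic distance clearly.
    """
    kw = {**_DESK, "trait_mode": "stasis_bm", "bm_rate": 0.01,
          "within_species_sd": 0.02, "worker_sd": 0.01, "seed": seed}
    kw.update(overrides)
    return SimScenario(**kw)


def scenario_convergence(seed: int = 0, **overrides) -> SimScenario:
    """Same magnitudes as :func:`scenario_stasis` but trait distances
    mirror (anti-correlate with) the tree."""
    return scenario_stasis(seed, trait_mode="convergence_mirror", **overrides)


def scenario_null(seed: int = 0, **overrides) -> SimScenario:
    """Species means independent of the tree: every test is under its null."""
    return scenario_stasis(seed, trait_mode="null_independent", **overrides)


def scenario_eco_coupled(seed: int = 0, character: str = "PLSP",
                         **overrides) -> SimScenario:
    """One character tracks niche axis 1 strongly; drift is kept small so
    the coupled signal dominates that character's between-species
    variation (sd 0.5 coupling vs sqrt(0.001) ~ 0.03 drift)."""
    return scenario_stasis(seed, bm_rate=0.001,
                           eco_coupled_characters=(character,),
                           eco_coupling_strength=0.5, eco_noise_sd=0.2,
                           **overrides)


def scenario_altitude_crypsis(seed: int = 0, **overrides) -> SimScenario:
    """Overlapping species whose among-nest variance grows with altitude.

    Drift sd (0.02) matches the among-nest sd, so species overlap
    morphologically; the sd of high-altitude nests is inflated up to ~3x
    (slope 1 per km over 0-2.5 km), which lowers their discriminant
    posteriors — the altitude-crypsis pattern.  Score these datasets with
    leave-one-out discriminant posteriors: at a handful of nests per
    species, resubstitution optimism (each nest pulls its own species
    mean toward itself) otherwise swamps the variance effect.
    """
    kw = {**_DESK, "n_nests_per_species": 8, "trait_mode": "stasis_bm",
          "bm_rate": 4e-4, "within_species_sd": 0.02, "worker_sd": 0.01,
          "altitude_variance_slope": 1.0, "seed": seed}
    kw.update(overrides)
    return SimScenario(**kw)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all blocks plus the ground-truth JSON to a directory."""
    from . import io_formats as iof

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "workers": outdir / "workers.csv",
        "aflp": outdir / "aflp.csv",
        "localities": outdir / "localities.csv",
        "tree": outdir / "tree.nwk",
        "ground_truth": outdir / "ground_truth.json",
    }
    iof.write_nest_table(ds.workers, paths["workers"])
    iof.write_aflp_matrix(ds.aflp, paths["aflp"])
    iof.write_locality_table(ds.localities, paths["localities"])
    paths["tree"].write_text(ds.tree.newick() + "\n")
    paths["ground_truth"].write_text(json.dumps(ds.ground_truth, indent=2))
    return paths
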