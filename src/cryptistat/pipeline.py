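"""End-to-end analysis: distances -> Mantel batteries -> crypsis report.

Two test batteries mirror the study design:

* stasis battery: all-character and per-character morphological distances
  against the AFLP-derived phylogenetic distances (Mantel tests) — a
  positive relation indicates stasis, a negative one convergence;
* ecology battery: the same morphological distances against ecological
  distances, controlling for phylogenetics (Partial Mantel tests) — a
  positive relation indicates concerted evolution, a negative one
  character displacement.

Within each battery the single-character family is Holm-corrected, and
the exact binomial probability of seeing at least the observed number of
characters at p <= 0.05 by chance is attached.  The species set of every
test is the intersection of the species present in the blocks it uses,
and is recorded per test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .crypsis import RegressionResult, lda_posteriors, regress_scores
from .distances import (DistanceMatrix, SpeciesDistanceSummary,
                        all_character_distance, ecological_distance,
                        nest_means, normalize_by_cs, phylogenetic_distance,
                        prune_correlated_characters, single_character_distance,
                        species_mean_distances)
from .io_formats import (AFLPMatrix, LocalityTable, NestTable, PipelineConfig,
                         ValidationError)
from .mantel import (HolmOutcome, MantelResult, binomial_exceedance,
                     holm_correct, mantel_test, partial_mantel_test)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Battery:
    """One family of matrix tests (all-character row + per-character rows)."""

    name: str
    species: tuple[str, ...]
    all_character: MantelResult
    characters: tuple[str, ...]
    rows: tuple[MantelResult, ...]
    holm: HolmOutcome
    exceedance_n: int
    exceedance_k: int
    exceedance_p: float
    exceedance_prob: float

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(self.species),
            "n_species": len(self.species),
            "all_character": self.all_character.to_dict(),
            "single_characters": [
                {"character": c, **r.to_dict(),
                 "holm_adjusted_p": adj, "holm_significant": rej}
                for c, r, adj, rej in zip(self.characters, self.rows,
                                          self.holm.adjusted_p,
                                          self.holm.rejected)
            ],
            "exceedance": {"n": self.exceedance_n, "k": self.exceedance_k,
                           "p": self.exceedance_p, "prob": self.exceedance_prob},
        }


@dataclass(frozen=True)
class AnalysisReport:
    h2: Battery | None
    h3: Battery | None
    crypsis: tuple[RegressionResult, ...]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "h2": self.h2.to_dict() if self.h2 else None,
            "h3": self.h3.to_dict() if self.h3 else None,
            "crypsis": [r.to_dict() for r in self.crypsis],
            "provenance": self.provenance,
        }


@dataclass(frozen=True)
class MorphoBlock:
    """CS-normalised nest means with the pruned character set."""

    nests: NestTable
    retained: tuple[str, ...]
    prune_report: list


def prepare_morphometrics(workers: NestTable,
                          config: PipelineConfig) -> MorphoBlock:
    """Normalise by CS, build nest means, prune near-collinear characters."""
    table = normalize_by_cs(workers)
    if "worker_id" in table.data.columns:
        table = nest_means(table)
    retained, report = prune_correlated_characters(
        table, config.correlation_prune_threshold, config.random_seed)
    log.info("morphometrics: %d nests, %d/%d characters retained",
             len(table), len(retained), len(table.characters))
    return MorphoBlock(table, retained, report)


def _shared_species(*summaries: SpeciesDistanceSummary) -> tuple[str, ...]:
    shared = set(summaries[0].species)
    for s in summaries[1:]:
        shared &= set(s.species)
    # keep first summary's order for reproducibility
    ordered = tuple(s for s in summaries[0].species if s in shared)
    if len(ordered) < 3:
        raise ValidationError(
            f"only {len(ordered)} species shared between data blocks; "
            "need >= 3 for Mantel tests")
    return ordered


def _test_seeds(root_seed: int, battery: int, n: int) -> np.ndarray:
    return np.random.SeedSequence([root_seed, battery]).generate_state(n)


def _battery(name: str, morpho: MorphoBlock,
             other: SpeciesDistanceSummary, config: PipelineConfig,
             control: SpeciesDistanceSummary | None = None,
             battery_code: int = 0) -> Battery:
    """Run the all-character and per-character tests of one battery."""
    all_sum, _ = all_character_distance(morpho.nests, config, morpho.retained)
    summaries = [all_sum, other] + ([control] if control is not None else [])
    species = _shared_species(*summaries)
    B = other.subset(species).inter_matrix()
    C = control.subset(species).inter_matrix() if control is not None else None
    seeds = _test_seeds(config.random_seed, battery_code,
                        len(morpho.retained) + 1)

    def run(A: DistanceMatrix, seed: int) -> MantelResult:
        kwargs = dict(n_permutations=config.n_permutations, tail=config.tail,
                      seed=int(seed),
                      exhaustive=True if config.exhaustive else None)
        if C is None:
            return mantel_test(A, B, **kwargs)
        return partial_mantel_test(A, B, C, **kwargs)

    A_all = all_sum.subset(species).inter_matrix()
    all_res = run(A_all, seeds[0])
    rows = []
    species_of = morpho.nests.species_of()
    for i, char in enumerate(morpho.retained):
        dist = single_character_distance(morpho.nests, char)
        summ = species_mean_distances(dist, species_of)
        A = summ.subset(species).inter_matrix()
        rows.append(run(A, seeds[i + 1]))
        log.info("%s battery %s: r=%.3f p=%.4f", name, char,
                 rows[-1].r, rows[-1].p)
    holm = holm_correct([r.p for r in rows], config.alpha)
    k = sum(r.p <= 0.05 for r in rows)
    prob = binomial_exceedance(len(rows), k, 0.05)
    log.info("%s battery: all-character r=%.3f p=%.4f; %d/%d single "
             "characters at p<=0.05 (prob=%.4g)", name, all_res.r, all_res.p,
             k, len(rows), prob)
    return Battery(name, species, all_res, morpho.retained, tuple(rows),
                   holm, len(rows), k, 0.05, prob)


def run_h2(workers: NestTable, aflp: AFLPMatrix, config: PipelineConfig,
           morpho: MorphoBlock | None = None) -> Battery:
    """Stasis battery: morphology vs phylogenetics (Mantel tests)."""
    morpho = morpho or prepare_morphometrics(workers, config)
    phylo, _ = phylogenetic_distance(aflp, config)
    return _battery("phylogenetics", morpho, phylo, config, battery_code=2)


def run_h3(workers: NestTable, localities: LocalityTable, aflp: AFLPMatrix,
           config: PipelineConfig,
           morpho: MorphoBlock | None = None) -> Battery:
    """Ecology battery: morphology vs ecology, controlling phylogenetics."""
    morpho = morpho or prepare_morphometrics(workers, config)
    eco, _ = ecological_distance(localities, config)
    phylo, _ = phylogenetic_distance(aflp, config)
    return _battery("ecology", morpho, eco, config, control=phylo,
                    battery_code=3)


def run_crypsis(workers: NestTable, localities: LocalityTable,
                config: PipelineConfig,
                morpho: MorphoBlock | None = None
                ) -> tuple[pd.DataFrame, tuple[RegressionResult, ...]]:
    """Crypsis scores per nest and their altitude/latitude regressions.

    The discriminant analysis runs on the pruned, CS-normalised nest
    means (the collinear characters would make the pooled covariance
    singular).  Altitude and latitude are joined from each nest's
    locality.
    """
    morpho = morpho or prepare_morphometrics(workers, config)
    nests = NestTable(morpho.nests.data, morpho.retained)
    scores = lda_posteriors(nests, mode=config.lda_mode,
                            priors=config.lda_priors)
    loc = localities.data.set_index("locality_id")
    nest_loc = morpho.nests.data["locality_id"]
    missing = set(nest_loc) - set(loc.index)
    if missing:
        raise ValidationError(
            f"nest locality ids absent from locality table: {sorted(missing)[:5]}")
    alt = loc.loc[nest_loc, "altitude"].to_numpy(dtype=float)
    lat = loc.loc[nest_loc, "latitude"].to_numpy(dtype=float)
    regs = (
        regress_scores(scores, alt, config.covariate_transform, "altitude"),
        regress_scores(scores, lat, config.covariate_transform, "latitude"),
    )
    log.info("crypsis: altitude r=%.4f p=%.3g; latitude r=%.4f p=%.3g",
             regs[0].r, regs[0].p, regs[1].r, regs[1].p)
    return scores, regs


def run_all(workers: NestTable, aflp: AFLPMatrix, localities: LocalityTable,
            config: PipelineConfig) -> AnalysisReport:
    """Full analysis with shared morphometric preparation."""
    morpho = prepare_morphometrics(workers, config)
    h2 = run_h2(workers, aflp, config, morpho=morpho)
    h3 = run_h3(workers, localities, aflp, config, morpho=morpho)
    _, regs = run_crypsis(workers, localities, config, morpho=morpho)
    provenance = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "n_nests": len(morpho.nests),
        "n_workers": len(workers),
        "characters_retained": list(morpho.retained),
        "characters_pruned": [r[0] for r in morpho.prune_report],
        "n_species_h2": len(h2.species),
        "n_species_h3": len(h3.species),
    }
    return AnalysisReport(h2, h3, tuple(regs), provenance)


def render_report(report: AnalysisReport, path: str | Path) -> None:
    """Write the plain-text report and its machine-readable JSON twin."""
    if report.h2 is None and report.h3 is None and not report.crypsis:
        raise ValidationError("refusing to render an empty report")
    path = Path(path)
    lines = ["Mantel-test batteries", "=" * 60]

    def battery_lines(b: Battery, label: str) -> list[str]:
        out = [f"\n{label} ({len(b.species)} species: {', '.join(b.species)})",
               "-" * 60,
               f"{'character':<12}{'R':>9}{'p':>10}  Holm"]
        r = b.all_character
        out.append(f"{'all':<12}{r.r:>9.3f}{r.p:>10.4f}  (not in family)")
        for c, row, adj, rej in zip(b.characters, b.rows, b.holm.adjusted_p,
                                    b.holm.rejected):
            flag = "*" if rej else ""
            out.append(f"{c:<12}{row.r:>9.3f}{row.p:>10.4f}  "
                       f"adj={adj:.4f}{flag}")
        out.append(f"prob(>= {b.exceedance_k} of {b.exceedance_n} at "
                   f"p<=0.05) = {b.exceedance_prob:.6g}")
        return out

    if report.h2:
        lines += battery_lines(report.h2, "Morphology vs phylogenetics "
                                          "(Mantel)")
    if report.h3:
        lines += battery_lines(report.h3, "Morphology vs ecology, "
                                          "phylogenetics-controlled "
                                          "(Partial Mantel)")
    if report.crypsis:
        lines += ["", "Crypsis regressions", "-" * 60]
        for reg in report.crypsis:
            lines.append(f"{reg.covariate:<10} ({reg.transform}): "
                         f"R = {reg.r:.4f}, slope = {reg.slope:.3e}, "
                         f"p = {reg.p:.3g}, n = {reg.n}")
    lines += ["", "Provenance", "-" * 60,
              json.dumps(report.provenance, indent=2, default=str)]
    path.write_text("\n".join(lines) + "\n")
    path.with_suffix(".json").write_text(
        json.dumps(report.to_dict(), indent=2, default=str) + "\n")
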