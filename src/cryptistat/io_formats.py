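"""Readers, writers and validated containers for all pipeline tables.

Every downstream module operates on the typed containers defined here:
:class:`NestTable` (morphometric rows with a head-size index ``cs``),
:class:`AFLPMatrix` (binary presence/absence marker matrix),
:class:`LocalityTable` (species-locality rows with climatic and soil
variables) and :class:`DistanceMatrix` re-exported from
:mod:`cryptistat.distances`.

All on-disk formats are delimited text with a mandatory header row
(comma default, tab accepted); distance matrices can additionally be
written in PHYLIP square format for interoperability with classic
phylogenetics software.  Missing values are rejected unless the caller
explicitly opts into dropping incomplete rows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


class ValidationError(ValueError):
    """Values parsed but violate a domain invariant."""


#: The 31 morphometric characters measured on workers: 29 retained in the
#: single-character analyses plus the two (CW, SPST) that are dropped by
#: default because each is near-collinear with another character after
#: normalisation by head size.
DEFAULT_CHARACTERS: tuple[str, ...] = (
    "HFL", "ML", "PPW", "PEW", "SPWI", "MtpW", "MW", "CL", "PoOc", "FL",
    "dAN", "RTI", "SLd", "POTCos", "EW", "EL", "PreOc", "PEH", "PEL",
    "PPL", "PPH", "PnHL", "Ppsh", "MPSP", "MPST", "MPPL", "PLST", "PLSP",
    "MC1TG", "CW", "SPST",
)

#: Characters recorded as small non-negative integer counts rather than
#: continuous lengths; they are analysed as numeric like all others.
DISCRETE_CHARACTERS: tuple[str, ...] = ("POTCos", "MC1TG")

#: The 20 climatic (Bio1-Bio19 bioclim surfaces plus the TAS standard air
#: temperature niche variable) and 8 soil variables describing each
#: species-locality combination.
ECO_VARIABLES: tuple[str, ...] = tuple(f"Bio{i}" for i in range(1, 20)) + (
    "TAS", "Bldfie", "Cecsol", "Clyppt", "Crfvol", "Ocstha", "Phihox",
    "Sltppt", "Sndppt",
)

_NEST_META = ("nest_id", "species", "locality_id", "cs")
_LOCALITY_META = ("locality_id", "species", "latitude", "longitude", "altitude")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _check_numeric(df: pd.DataFrame, columns: Iterable[str], what: str) -> pd.DataFrame:
    """Coerce columns to float, raising ParseError naming the first bad cell."""
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric {what} {out[col].iloc[row]!r} in column "
                f"{col!r} at row {row}"
            )
        out[col] = coerced.astype(float)
    return out


def _reject_missing(df: pd.DataFrame, columns: Sequence[str],
                    drop_incomplete: bool) -> pd.DataFrame:
    incomplete = df[list(columns)].isna().any(axis=1)
    if not incomplete.any():
        return df
    if drop_incomplete:
        return df.loc[~incomplete].reset_index(drop=True)
    rows = np.flatnonzero(incomplete.to_numpy()).tolist()
    raise ValidationError(
        f"missing values in analysed columns at rows {rows}; "
        "pass drop_incomplete=True to delete them"
    )


@dataclass(frozen=True)
class NestTable:
    """Nests (or individual workers) x named morphometric characters.

    ``data`` carries the label columns ``nest_id``, ``species``,
    ``locality_id``, the head-size index ``cs`` and one float column per
    character.  A worker-level table additionally carries ``worker_id``;
    :func:`cryptistat.distances.nest_means` collapses it to nest level.
    """

    data: pd.DataFrame
    characters: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [c for c in _NEST_META if c not in self.data.columns]
        if missing:
            raise SchemaError(f"nest table missing required column(s) {missing}")
        absent = [c for c in self.characters if c not in self.data.columns]
        if absent:
            raise SchemaError(f"nest table missing character column(s) {absent}")
        if "worker_id" not in self.data.columns:
            dup = self.data["nest_id"][self.data["nest_id"].duplicated()]
            if len(dup):
                raise ValidationError(f"duplicate nest_id values: {sorted(set(dup))[:5]}")
        vals = self.data[list(self.characters)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite character measurement present")
        if (vals < 0).any():
            raise ValidationError("negative character measurement present")
        cs = self.data["cs"].to_numpy(dtype=float)
        if not np.isfinite(cs).all() or (cs <= 0).any():
            bad = self.data["nest_id"].iloc[int(np.argmin(cs))]
            raise ValidationError(f"cs must be finite and > 0 (offending nest {bad!r})")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def matrix(self) -> np.ndarray:
        """Character measurements as a dense float array (rows as stored)."""
        return self.data[list(self.characters)].to_numpy(dtype=float)

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.data["nest_id"], self.data["species"]))


@dataclass(frozen=True)
class AFLPMatrix:
    """Binary individuals x loci band matrix with species labels."""

    individual_ids: tuple[str, ...]
    species: tuple[str, ...]
    loci: tuple[str, ...]
    values: np.ndarray  # uint8, shape (n_individuals, n_loci)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (len(self.individual_ids), len(self.loci)):
            raise ValidationError(
                f"AFLP matrix shape {vals.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"AFLP entry {vals[i, j]!r} at (row {i}, locus {j}) is not 0/1"
            )
        object.__setattr__(self, "values", vals.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def species_of(self) -> dict[str, str]:
        return dict(zip(self.individual_ids, self.species))


@dataclass(frozen=True)
class LocalityTable:
    """One row per species-locality combination with ecological variables."""

    data: pd.DataFrame
    eco_variables: tuple[str, ...] = ECO_VARIABLES

    def __post_init__(self) -> None:
        missing = [c for c in _LOCALITY_META if c not in self.data.columns]
        if missing:
            raise SchemaError(f"locality table missing required column(s) {missing}")
        absent = [c for c in self.eco_variables if c not in self.data.columns]
        if absent:
            raise SchemaError(f"locality table missing eco column(s) {absent}")
        lat = self.data["latitude"].to_numpy(dtype=float)
        if (np.abs(lat) > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
        eco = self.data[list(self.eco_variables)].to_numpy(dtype=float)
        if not np.isfinite(eco).all():
            raise ValidationError("non-finite ecological value present")
        key = self.data[["species", "locality_id"]]
        if key.duplicated().any():
            raise ValidationError("duplicate species-locality combination")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PipelineConfig:
    """Tunable analysis knobs shared across the pipeline stages."""

    cumulative_variance_threshold: float = 0.80
    correlation_prune_threshold: float = 0.8
    n_permutations: int = 100_000
    alpha: float = 0.05
    tail: str = "two_sided"
    random_seed: int = 0
    pca_scaling_morphology: str = "covariance"
    pca_scaling_aflp: str = "covariance"
    pca_scaling_ecology: str = "correlation"
    exhaustive: bool = False
    lda_mode: str = "resubstitution"
    lda_priors: str = "equal"
    covariate_transform: str = "absolute"

    def __post_init__(self) -> None:
        if not 0 < self.cumulative_variance_threshold <= 1:
            raise ValidationError("cumulative_variance_threshold must be in (0, 1]")
        if not 0 < self.correlation_prune_threshold <= 1:
            raise ValidationError("correlation_prune_threshold must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.tail not in ("two_sided", "greater", "less"):
            raise ValidationError(f"unknown tail {self.tail!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


# ---------------------------------------------------------------------------
# nest tables


def read_nest_table(path: str | Path, sep: str | None = None,
                    characters: Sequence[str] | None = None,
                    drop_incomplete: bool = False) -> NestTable:
    """Read a nest (or worker) table from delimited text.

    Columns ``nest_id, species, locality_id, cs`` are required; every other
    numeric column is taken as a character unless ``characters`` names an
    explicit subset.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _NEST_META if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    meta = [c for c in (*_NEST_META, "worker_id") if c in df.columns]
    chars = tuple(characters) if characters is not None else tuple(
        c for c in df.columns if c not in meta)
    df = _check_numeric(df, [*chars, "cs"], "measurement")
    df = _reject_missing(df, [*chars, "cs"], drop_incomplete)
    return NestTable(df.reset_index(drop=True), chars)


def write_nest_table(table: NestTable, path: str | Path, sep: str = ",") -> None:
    meta = [c for c in ("nest_id", "worker_id", "species", "locality_id", "cs")
            if c in table.data.columns]
    cols = meta + list(table.characters)
    table.data[cols].to_csv(path, sep=sep, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# AFLP matrices


def read_aflp_matrix(path: str | Path, sep: str | None = None) -> AFLPMatrix:
    """Read a binary AFLP table: columns individual_id, species, then loci."""
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if list(df.columns[:2]) != ["individual_id", "species"]:
        raise SchemaError(
            f"{path.name}: first two columns must be individual_id, species "
            f"(got {list(df.columns[:2])})"
        )
    loci = tuple(df.columns[2:])
    raw = df[list(loci)].to_numpy()
    vals = np.zeros(raw.shape, dtype=np.int64)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(raw[:, j], errors="coerce")
        bad = ~np.isin(col, (0.0, 1.0)) | np.isnan(col)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"{path.name}: AFLP entry {raw[i, j]!r} at (row {i}, locus {j}) "
                "is not 0/1"
            )
        vals[:, j] = col.astype(np.int64)
    return AFLPMatrix(tuple(df["individual_id"]), tuple(df["species"]), loci, vals)


def write_aflp_matrix(matrix: AFLPMatrix, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(matrix.values, columns=list(matrix.loci))
    df.insert(0, "species", matrix.species)
    df.insert(0, "individual_id", matrix.individual_ids)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# locality tables


def read_locality_table(path: str | Path, sep: str | None = None,
                        eco_variables: Sequence[str] = ECO_VARIABLES,
                        drop_incomplete: bool = False) -> LocalityTable:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in (*_LOCALITY_META, *eco_variables) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    numeric = ["latitude", "longitude", "altitude", *eco_variables]
    df = _check_numeric(df, numeric, "value")
    df = _reject_missing(df, numeric, drop_incomplete)
    return LocalityTable(df.reset_index(drop=True), tuple(eco_variables))


def write_locality_table(table: LocalityTable, path: str | Path, sep: str = ",") -> None:
    cols = [*_LOCALITY_META, *table.eco_variables]
    table.data[cols].to_csv(path, sep=sep, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# distance matrices


def write_distance_matrix(matrix, path: str | Path, format: str = "labelled",
                          sep: str = ",") -> None:
    """Write a symmetric labelled distance matrix.

    ``format='labelled'`` emits a delimited table with identical header and
    row labels; ``format='phylip'`` emits PHYLIP square format (taxon count
    line, then one whitespace-separated row per taxon).
    """
    n = len(matrix.labels)
    if n == 0:
        raise ValidationError("refusing to write an empty distance matrix")
    vals = np.asarray(matrix.values, dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise ValidationError("distance matrix is not symmetric")
    path = Path(path)
    if format == "labelled":
        df = pd.DataFrame(vals, index=list(matrix.labels), columns=list(matrix.labels))
        df.to_csv(path, sep=sep, index_label="", float_format="%.12g")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{n}\n")
            for label, row in zip(matrix.labels, vals):
                fh.write(label + "  " + "  ".join(f"{x:.12g}" for x in row) + "\n")
    else:
        raise ValidationError(f"unknown distance-matrix format {format!r}")


def read_distance_matrix(path: str | Path, format: str = "labelled",
                         sep: str = ","):
    from .distances import DistanceMatrix

    path = Path(path)
    if format == "labelled":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return DistanceMatrix(tuple(str(x) for x in df.index),
                              df.to_numpy(dtype=float))
    if format == "phylip":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(labels) != n:
            raise ParseError(f"{path.name}: expected {n} taxa, found {len(labels)}")
        return DistanceMatrix(tuple(labels), np.asarray(rows, dtype=float))
    raise ValidationError(f"unknown distance-matrix format {format!r}")
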