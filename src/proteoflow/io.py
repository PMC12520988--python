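"""Tables, gene sets and sample metadata.

The central in-memory object is :class:`IntensityMatrix`, a proteins x
samples table of intensities with explicit missingness (NaN), a scale tag
(``raw`` or ``log2``) and a provenance tag (``tmt``, ``dia``, ``generic`` or
``synthetic``).  Readers exist for the two wide TSV dialects produced by
protein-level reports of multiplexed (TMT) and data-independent (DIA)
acquisition, for tab-separated sample metadata and for GMT gene-set
collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents recognised as "missing" in every dialect.
MISSING_TOKENS = frozenset({"", "NA", "NaN"})

#: Flat key=value defaults shared by the CLI and the library.
DEFAULT_CONFIG: dict[str, float | int] = {
    "min_valid": 3,
    "min_valid_large": 10,
    "downshift": 1.8,
    "width": 0.3,
    "lfc_threshold": 1.0,
    "lfc_threshold_relaxed": 0.5,
    "alpha": 0.05,
    "gsea_permutations": 10000,
    "gsea_min_size": 20,
    "gsea_min_size_loadings": 100,
    "simplify_cutoff": 0.7,
    "marker_z": 2.0,
    "marker_min_fraction": 0.25,
    "grid_spacing_um": 62.25,
}


class FormatError(ValueError):
    """A file violates the expected tabular layout."""


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity table with explicit missingness.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id;
        ``NaN`` encodes a missing (unquantified) cell.
    scale
        ``"raw"`` for linear-scale intensities, ``"log2"`` after log
        transformation.
    provenance
        Where the table came from: ``tmt``, ``dia``, ``generic`` or
        ``synthetic``.
    """

    values: pd.DataFrame
    scale: str = "log2"
    provenance: str = "generic"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise ValueError(f"duplicate protein ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        observed = ~np.isnan(arr)
        if not np.isfinite(arr[observed]).all():
            raise ValueError("observed intensities must be finite")

    # -- convenience -----------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "IntensityMatrix":
        return IntensityMatrix(values, scale or self.scale, self.provenance)


@dataclass
class SampleMetadata:
    """Per-sample annotations: group, blocking individual, covariates, batch.

    ``table`` is indexed by sample id; covariate columns that could not be
    parsed (e.g. a non-numeric age) are kept as NaN and listed in
    ``missing_covariates``.
    """

    table: pd.DataFrame
    missing_covariates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = sorted(set(self.table.index[self.table.index.duplicated()]))
            raise ValueError(f"duplicate sample ids in metadata: {dups}")

    def covers(self, matrix: IntensityMatrix) -> bool:
        return matrix.sample_ids.isin(self.table.index).all()

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"metadata has no column {name!r}")
        return self.table[name]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): id -> (description, members)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def filtered(self, universe, min_size: int = 1, max_size: int | None = None) -> "GeneSetCollection":
        """Intersect every set with *universe* and drop sets outside the size band."""
        uni = set(universe)
        out: dict[str, list[str]] = {}
        for sid, members in self.sets.items():
            inter = [g for g in members if g in uni]
            if len(inter) >= min_size and (max_size is None or len(inter) <= max_size):
                out[sid] = inter
        return GeneSetCollection(out, {s: self.descriptions.get(s, "") for s in out})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_cell(token: str, dialect: str) -> float:
    token = token.strip()
    if token in MISSING_TOKENS:
        return np.nan
    value = float(token)  # caller wraps ValueError with position info
    if dialect == "dia" and value == 0.0:
        # DIA protein reports encode non-detection as literal zero.
        return np.nan
    return value


def read_intensity_table(path: str | Path, dialect: str = "generic") -> IntensityMatrix:
    """Read a wide proteins-x-samples TSV.

    The first column holds the protein identifier.  Empty cells, ``NA`` and
    ``NaN`` are missing in every dialect; in the ``dia`` dialect a literal
    ``0`` additionally maps to missing (intensity zero is a non-detection
    there).  Duplicate protein or sample ids raise an error naming them.
    """
    if dialect not in ("tmt", "dia", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        if len(sample_ids) != len(set(sample_ids)):
            dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"{path}: duplicate sample ids in header: {dups}")
        proteins: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(fields)}"
                )
            proteins.append(fields[0])
            row = []
            for j, token in enumerate(fields[1:]):
                try:
                    row.append(_parse_cell(token, dialect))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {token!r} "
                        f"in column {sample_ids[j]!r}"
                    ) from None
            rows.append(row)
    if len(proteins) != len(set(proteins)):
        dups = sorted({p for p in proteins if proteins.count(p) > 1})
        raise ValueError(f"{path}: duplicate protein ids: {dups}")
    values = pd.DataFrame(rows, index=pd.Index(proteins, name="protein_id"), columns=sample_ids)
    provenance = dialect if dialect in ("tmt", "dia") else "generic"
    # raw reports carry linear intensities; the caller log-transforms
    return IntensityMatrix(values, scale="raw", provenance=provenance)


def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write the matrix as a wide TSV (missing cells become ``NA``)."""
    matrix.values.to_csv(path, sep="\t", na_rep="NA", index_label="protein_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample-metadata TSV with a mandatory ``sample_id`` column.

    ``age`` is coerced to numeric; values that do not parse are recorded as
    missing covariates rather than rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise ValueError(f"{path}: duplicate sample rows: {dups}")
    df = df.set_index("sample_id")
    df = df.replace({tok: np.nan for tok in MISSING_TOKENS})
    missing: dict[str, list[str]] = {}
    if "age" in df.columns:
        age = pd.to_numeric(df["age"], errors="coerce")
        bad = df.index[age.isna()].tolist()
        if bad:
            missing["age"] = bad
        df["age"] = age
    for col in df.columns:
        if df[col].isna().any() and col not in missing:
            missing[col] = df.index[df[col].isna()].tolist()
    absent = [c for c in ("age", "sex") if c not in df.columns]
    if absent:
        logger.info("metadata lacks covariate column(s): %s", ", ".join(absent))
        for col in absent:
            missing[col] = list(df.index)
    return SampleMetadata(df, missing)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: ``set_id<TAB>description<TAB>gene...``.

    Duplicate genes within a line are dropped keeping the first occurrence.
    A line with fewer than three fields is a format error (reported with its
    line number).  An empty file yields an empty collection.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}")
            sid, desc = fields[0], fields[1]
            if sid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set id {sid!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {sid!r} has no genes")
            sets[sid] = members
            descriptions[sid] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sid, members in collection:
            desc = collection.descriptions.get(sid, "")
            fh.write("\t".join([sid, desc, *members]) + "\n")


def read_config(path: str | Path) -> dict[str, float | int | str]:
    """Read a flat ``key = value`` config file on top of the defaults."""
    cfg: dict[str, float | int | str] = dict(DEFAULT_CONFIG)
    for lineno, line in enumerate(Path(path).open(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        try:
            val: float | int | str = int(raw)
        except ValueError:
            try:
                val = float(raw)
            except ValueError:
                val = raw
        cfg[key] = val
    return cfg


def harmonize_ids(ids) -> pd.Index:
    """Uppercase identifiers for exact cross-dataset matching."""
    return pd.Index([str(i).upper() for i in ids])
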