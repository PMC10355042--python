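"""Core data containers and readers/writers for the standard table formats.

Protein identity throughout the package is the combined
``GeneSymbol|UniProtID`` string; enrichment operations match on the gene
symbol prefix (:func:`gene_symbol`).  Abundance matrices are log2 scale
with NaN for missing; the accompanying design table assigns every column a
role (``sample`` / ``gis`` / ``pool``) and a batch.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError

__all__ = [
    "AbundanceMatrix",
    "GeneSetCollection",
    "CellTypeMarkers",
    "gene_symbol",
    "read_abundance",
    "write_abundance",
    "read_gmt",
    "load_config",
    "save_config",
    "CELL_TYPES",
]

log = logging.getLogger("csfnet")

ROLES = ("sample", "gis", "pool")
CELL_TYPES = ("neuron", "oligodendrocyte", "astrocyte", "microglia", "endothelia")
_MISSING_TOKENS = {"", "na", "nan"}


def gene_symbol(protein_id: str) -> str:
    """Gene-symbol prefix of a ``GeneSymbol|UniProtID`` identifier."""
    return protein_id.split("|", 1)[0]


@dataclass
class AbundanceMatrix:
    """Protein x channel log2 abundance matrix with column roles and batches."""

    data: pd.DataFrame                      # proteins x columns, NaN = missing
    roles: pd.Series                        # column -> sample|gis|pool
    batches: pd.Series                      # column -> batch label
    sample_of_column: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate protein id: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate column id: {dup}")
        missing_design = [c for c in self.data.columns if c not in self.roles.index]
        if missing_design:
            raise FormatError(
                f"columns absent from design: {', '.join(map(str, missing_design))}")
        missing_batch = [c for c in self.data.columns if c not in self.batches.index]
        if missing_batch:
            raise FormatError(
                f"columns without a batch: {', '.join(map(str, missing_batch))}")
        bad = set(self.roles.loc[self.data.columns]) - set(ROLES)
        if bad:
            raise FormatError(f"unknown column roles: {sorted(bad)}")
        vals = self.data.to_numpy()
        if np.isinf(vals).any():
            raise FormatError("abundance values must be finite where present")

    # -- column views ------------------------------------------------------
    def _cols(self, role: str) -> list:
        return [c for c in self.data.columns if self.roles[c] == role]

    @property
    def sample_columns(self) -> list:
        return self._cols("sample")

    @property
    def gis_columns(self) -> list:
        return self._cols("gis")

    @property
    def pool_columns(self) -> list:
        return self._cols("pool")

    @property
    def proteins(self) -> pd.Index:
        return self.data.index

    def column_of_sample(self, sample_id: str) -> str:
        hits = self.sample_of_column[self.sample_of_column == sample_id]
        if len(hits) != 1:
            raise KeyError(f"sample {sample_id!r} not uniquely mapped to a column")
        return hits.index[0]

    def sample_frame(self) -> pd.DataFrame:
        """Sample-role columns only, columns renamed to sample ids when mapped."""
        cols = self.sample_columns
        sub = self.data[cols]
        if len(self.sample_of_column):
            rename = {c: self.sample_of_column[c]
                      for c in cols if c in self.sample_of_column.index}
            sub = sub.rename(columns=rename)
        return sub

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            data=self.data.copy(),
            roles=self.roles.copy(),
            batches=self.batches.copy(),
            sample_of_column=self.sample_of_column.copy(),
        )

    def with_data(self, data: pd.DataFrame) -> "AbundanceMatrix":
        """Same design, new values (columns must be a subset of the design)."""
        return AbundanceMatrix(
            data=data,
            roles=self.roles.copy(),
            batches=self.batches.copy(),
            sample_of_column=self.sample_of_column.copy(),
        )

    def drop_columns(self, cols) -> "AbundanceMatrix":
        keep = [c for c in self.data.columns if c not in set(cols)]
        return self.with_data(self.data[keep])


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:12]


def read_abundance(path, design_path) -> AbundanceMatrix:
    """Read a protein x column TSV plus its design CSV.

    The TSV has a header of column ids and protein ids in the first field;
    blank or ``NA`` cells (case-insensitive) are missing.  Rows whose field
    count disagrees with the header are rejected rather than padded.  The
    design CSV needs ``column``, ``role`` and ``batch`` columns and may map
    sample columns to external ids via ``sample_id``.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise FormatError(f"{path}: empty abundance file")
    header = lines[0].split("\t")
    ncol = len(header)
    ids, rows = [], []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != ncol:
            raise FormatError(
                f"{path}: line {i} has {len(fields)} fields, expected {ncol}")
        ids.append(fields[0])
        rows.append([np.nan if f.strip().lower() in _MISSING_TOKENS else float(f)
                     for f in fields[1:]])
    data = pd.DataFrame(rows, index=ids, columns=header[1:], dtype=float)

    design = pd.read_csv(design_path)
    for col in ("column", "role", "batch"):
        if col not in design.columns:
            raise FormatError(f"{design_path}: missing design column {col!r}")
    design = design.set_index("column")
    if design.index.duplicated().any():
        raise FormatError(f"{design_path}: duplicate column entries")
    sample_of = (design["sample_id"].dropna()
                 if "sample_id" in design.columns else pd.Series(dtype=object))
    m = AbundanceMatrix(
        data=data,
        roles=design["role"],
        batches=design["batch"].astype(str),
        sample_of_column=sample_of,
    )
    log.info("read_abundance: %s (%d proteins x %d columns, sha256:%s)",
             path, data.shape[0], data.shape[1], _checksum(path))
    return m


def write_abundance(m: AbundanceMatrix, path, design_path) -> None:
    """Write the matrix TSV (NA for missing) and its design CSV."""
    out = m.data.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    rows = []
    for c in m.data.columns:
        rows.append({
            "column": c, "role": m.roles[c], "batch": m.batches[c],
            "sample_id": m.sample_of_column.get(c, ""),
        })
    pd.DataFrame(rows).to_csv(design_path, index=False)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) for enrichment testing."""

    sets: dict                       # name -> set of gene symbols
    source: str = ""

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if any((not isinstance(s, str)) or s == "" for s in members):
                raise FormatError(f"gene set {name!r} has blank member symbols")

    def __len__(self):
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then tab-separated member symbols.

    Duplicate members within a line are deduplicated; a line with fewer
    than three fields is a format error naming the line.  An empty file
    yields an empty collection with a logged warning.
    """
    sets = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            members = {f for f in fields[2:] if f.strip()}
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        warnings.warn(f"{path}: empty GMT file; returning empty collection",
                      stacklevel=2)
        return _empty_collection(str(path))
    return GeneSetCollection(sets=sets, source=str(path))


def _empty_collection(source: str) -> GeneSetCollection:
    coll = GeneSetCollection.__new__(GeneSetCollection)
    coll.sets = {}
    coll.source = source
    return coll


@dataclass
class CellTypeMarkers:
    """Marker gene symbols for the five brain cell types."""

    markers: dict                    # cell type -> set of gene symbols

    def __post_init__(self):
        missing = [t for t in CELL_TYPES if t not in self.markers]
        if missing:
            raise FormatError(f"missing cell types: {missing}")
        for t in CELL_TYPES:
            if not self.markers[t]:
                raise FormatError(f"cell type {t!r} has no markers")

    def as_collection(self) -> GeneSetCollection:
        return GeneSetCollection(sets={t: set(self.markers[t]) for t in CELL_TYPES},
                                 source="cell-type markers")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    log.info("load_config: %s (sha256:%s)", path, _checksum(path))
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
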