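"""Readers, writers and normalization for intensity matrices and catalogs.

The universal exchange object is :class:`IntensityTensor`: a protein ×
(particle, condition, sample, replicate) matrix of linear-scale, strictly
positive intensities with explicit missing values (``NaN`` in memory, the
string ``NA`` on disk — never zero: a zero intensity is a format error, and
drawing conventions that plot missing values as 0 are never applied to
computation).

On disk a tensor is a tab-separated file whose first column is
``protein_id`` and whose remaining columns are named
``<np_id>__<condition>__<sample>__r<replicate>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError

logger = logging.getLogger(__name__)

#: string used for missing cells on disk
NA_REP = "NA"

COLUMN_LEVELS = ("np_id", "condition", "sample", "replicate")


def _format_column(key: tuple) -> str:
    np_id, condition, sample, replicate = key
    return f"{np_id}__{condition}__{sample}__r{int(replicate)}"


def _parse_column(name: str) -> tuple:
    parts = name.split("__")
    if len(parts) != 4 or not parts[3].startswith("r"):
        raise FormatError(
            f"column {name!r} is not of the form <np>__<condition>__<sample>__r<rep>"
        )
    try:
        rep = int(parts[3][1:])
    except ValueError as exc:
        raise FormatError(f"column {name!r}: replicate index is not an integer") from exc
    return (parts[0], parts[1], parts[2], rep)


@dataclass
class IntensityTensor:
    """Protein × (particle, condition, sample, replicate) intensity matrix.

    ``data`` is indexed by protein ID with a 4-level column MultiIndex
    (``np_id, condition, sample, replicate``). ``scale`` is ``"linear"``
    (strictly positive values) or ``"log10"`` (any real, produced by
    :func:`median_normalize_log`).
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein IDs: {dupes}")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate column keys")
        if not isinstance(self.data.columns, pd.MultiIndex):
            self.data.columns = pd.MultiIndex.from_tuples(
                [tuple(c) for c in self.data.columns], names=COLUMN_LEVELS
            )
        else:
            self.data.columns = self.data.columns.set_names(COLUMN_LEVELS)
        if self.scale == "linear":
            vals = self.data.to_numpy(dtype=float)
            bad = np.asarray(vals <= 0) & ~np.isnan(vals)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(
                    "non-positive intensity at protein "
                    f"{self.data.index[i]!r}, column {self.data.columns[j]} "
                    "(zero is not a valid intensity; use NA for missing)"
                )

    # -- structure -----------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def np_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("np_id")))

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("condition")))

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values("sample")))

    @property
    def n_replicates(self) -> int:
        """Maximum replicate count of any (particle, condition, sample) group."""
        counts = self.data.columns.to_frame(index=False).groupby(
            ["np_id", "condition", "sample"], sort=False
        )["replicate"].count()
        return int(counts.max())

    def select(self, np_id=None, condition=None, sample=None) -> "IntensityTensor":
        """Subset columns by particle / condition / sample (None = keep all)."""
        cols = self.data.columns
        mask = np.ones(len(cols), dtype=bool)
        for level, want in (("np_id", np_id), ("condition", condition), ("sample", sample)):
            if want is not None:
                wanted = {want} if isinstance(want, str) else set(want)
                mask &= cols.get_level_values(level).isin(wanted)
        return IntensityTensor(self.data.loc[:, mask].copy(), scale=self.scale)

    def replicate_groups(self):
        """Yield ((np_id, condition, sample), frame-of-replicates) pairs."""
        for key, frame in self.data.T.groupby(level=["np_id", "condition", "sample"], sort=False):
            yield key, frame.T

    # -- I/O -----------------------------------------------------------
    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out.columns = [_format_column(k) for k in out.columns]
        out.index.name = "protein_id"
        # repr-based float formatting keeps round-trips bit-exact
        out.to_csv(path, sep="\t", na_rep=NA_REP, float_format=lambda v: repr(float(v)))

    @classmethod
    def read_tsv(cls, path, scale: str = "linear") -> "IntensityTensor":
        return read_intensity_tsv(path, scale=scale)


def read_intensity_tsv(path, scale: str = "linear") -> IntensityTensor:
    """Parse an intensity TSV, rejecting rather than coercing invalid cells."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "protein_id":
        raise FormatError(f"{path}: first column must be 'protein_id', got {raw.columns[0]!r}")
    ids = raw["protein_id"]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate protein IDs: {dupes}")
    body = raw.iloc[:, 1:]
    values = np.full(body.shape, np.nan)
    for j, col in enumerate(body.columns):
        cells = body[col]
        is_na = cells == NA_REP
        try:
            parsed = pd.to_numeric(cells.where(~is_na, np.nan))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in column {col!r}") from exc
        if scale == "linear":
            bad = parsed <= 0
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise FormatError(
                    f"{path}: non-positive intensity {cells.iloc[i]!r} at "
                    f"protein {ids.iloc[i]!r}, column {col!r}"
                )
        values[:, j] = parsed
    columns = pd.MultiIndex.from_tuples(
        [_parse_column(c) for c in body.columns], names=COLUMN_LEVELS
    )
    frame = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"), columns=columns)
    return IntensityTensor(frame, scale=scale)


def median_normalize_log(tensor: IntensityTensor) -> IntensityTensor:
    """log10-transform each column and subtract its median of observed values.

    Missing stays missing; every output column has median exactly 0. This is
    the normalization applied before difference-score / rank-enrichment
    analysis (CVs and compression fits work on the linear scale).
    """
    if tensor.scale != "linear":
        raise ValueError("median_normalize_log expects a linear-scale tensor")
    logged = np.log10(tensor.data)
    medians = logged.median(axis=0, skipna=True)
    empty = medians.index[medians.isna()]
    if len(empty):
        raise ValueError(f"all-missing column(s): {[tuple(c) for c in empty]}")
    return IntensityTensor(logged - medians, scale="log10")


# ---------------------------------------------------------------------
# annotation catalogs (GMT)
# ---------------------------------------------------------------------

@dataclass
class AnnotationCatalog:
    """One annotation space (GOCC, GOBP, KEGG, Keywords, Pfam or user label)
    mapping term IDs to non-empty protein-ID member sets."""

    space: str
    terms: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.terms.items():
            if len(members) == 0:
                raise ValueError(f"term {term!r} has no members")
            self.terms[term] = frozenset(members)

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path, space: str | None = None) -> AnnotationCatalog:
    """Read a GMT file (term, description, members; tab-separated).

    Terms with an empty member list are skipped with a logged warning;
    duplicate term IDs are a format error.
    """
    path = Path(path)
    terms: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least term and description")
            term, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if term in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term ID {term!r}")
            if not members:
                logger.warning("%s:%d: term %r has no members; skipped", path, lineno, term)
                continue
            terms[term] = frozenset(members)
            descriptions[term] = desc
    return AnnotationCatalog(space=space or path.stem, terms=terms, descriptions=descriptions)


def write_gmt(catalog: AnnotationCatalog, path) -> None:
    with open(path, "w") as fh:
        for term in catalog.terms:
            desc = catalog.descriptions.get(term, "")
            members = "\t".join(sorted(catalog.terms[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------
# reference abundance table
# ---------------------------------------------------------------------

@dataclass
class ReferenceAbundanceTable:
    """Ranked reference plasma abundances (rank 1 = most intense), optionally
    flagging known biomarkers."""

    table: pd.DataFrame  # index protein_id; columns: intensity, rank, is_biomarker

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise FormatError("duplicate protein IDs in reference table")
        if "is_biomarker" not in t.columns:
            t["is_biomarker"] = False
        ranks = np.sort(t["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(t) + 1)):
            raise FormatError("ranks must be a permutation of 1..n")
        by_rank = t.sort_values("rank")["intensity"].to_numpy()
        if np.any(np.diff(by_rank) > 0):
            raise FormatError("intensities must be non-increasing in rank")

    @classmethod
    def from_intensities(cls, intensities: pd.Series, biomarkers=None) -> "ReferenceAbundanceTable":
        """Build a table from a protein→intensity map; ranks assigned by
        descending intensity (ties broken by protein ID for determinism)."""
        s = pd.Series(intensities, dtype=float)
        order = sorted(s.index, key=lambda p: (-s[p], p))
        table = pd.DataFrame(
            {
                "intensity": s.loc[order].to_numpy(),
                "rank": np.arange(1, len(s) + 1),
                "is_biomarker": [p in (biomarkers or set()) for p in order],
            },
            index=pd.Index(order, name="protein_id"),
        )
        return cls(table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def protein_ids(self) -> pd.Index:
        return self.table.index

    def rank_of(self, protein_id: str) -> int:
        return int(self.table.loc[protein_id, "rank"])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ReferenceAbundanceTable":
        t = pd.read_csv(path, sep="\t", index_col="protein_id")
        if "is_biomarker" in t.columns:
            t["is_biomarker"] = t["is_biomarker"].astype(bool)
        return cls(t)


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    # detection / precision
    "min_replicates_present": 3,
    "cv_threshold": 0.20,
    # enrichment
    "fisher_fdr": 0.01,
    "oned_fdr": 0.02,
    "oned_min_size": 11,
    # classification
    "cv_repeats": 10,
    "cv_folds": 10,
}


def load_config(path=None) -> dict:
    """Merge a flat YAML key-value file over the built-in defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: config must be a flat mapping")
        config.update(user)
    return config
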