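"""Core data containers and TSV readers/writers.

The pipeline's interchange format is plain tab-delimited text: a count table
is features-as-rows x samples-as-columns with a header row of sample ids and
a first column of feature ids; metadata is one row per sample. In the topic
model the samples play the role of documents and the features (ASVs, KEGG
orthologs, metabolites) the role of words, so a :class:`CountTable` is the
"documents x words" input with per-sample totals ``N_d`` given by its column
sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleMetadata",
    "OmicSet",
    "CountTableError",
    "MetadataError",
    "AlignmentError",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "align_omics",
]


class CountTableError(ValueError):
    """Structural or parse problem in a count table."""


class MetadataError(ValueError):
    """Schema or value problem in a sample metadata table."""


class AlignmentError(ValueError):
    """No common samples across omic tables."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise CountTableError(f"duplicate {kind} id {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """One omic's feature-by-sample nonnegative matrix.

    Parameters
    ----------
    omic_name
        Label for the omic layer (e.g. ``"16s"``, ``"mtg"``).
    feature_ids, sample_ids
        Ordered unique identifiers; ``values`` is indexed ``[feature, sample]``.
    values
        V x D nonnegative, finite array.
    is_discrete
        True when every value is an integer (the LDA training representation).
    """

    omic_name: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    is_discrete: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise CountTableError("values must be a 2-D array")
        v, d = self.values.shape
        if v < 1 or d < 1:
            raise CountTableError("count table must have >= 1 feature and >= 1 sample")
        if len(self.feature_ids) != v or len(self.sample_ids) != d:
            raise CountTableError("id lengths do not match value dimensions")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise CountTableError(f"non-finite value in table {self.omic_name!r}")
        if np.any(self.values < 0):
            f, s = np.argwhere(self.values < 0)[0]
            raise CountTableError(
                f"negative value at feature {self.feature_ids[f]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        self.is_discrete = bool(np.allclose(self.values, np.round(self.values)))

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_totals(self) -> np.ndarray:
        """Per-sample totals N_d (column sums)."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """Restrict to ``sample_ids`` in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise CountTableError(f"samples not in table {self.omic_name!r}: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountTable(
            self.omic_name, list(self.feature_ids), list(sample_ids), self.values[:, idx]
        )


# Default phenotype dictionary: the cohort design contrasts a previously
# diagnosed sibling (case) against a typically developing sibling (control).
DEFAULT_PHENOTYPE_MAP: Mapping[str, str] = {
    "asd": "case",
    "case": "case",
    "td": "control",
    "control": "control",
}

REQUIRED_METADATA_COLUMNS = ("sample_id", "individual_id", "family_id", "phenotype")


@dataclass
class SampleMetadata:
    """Collection of per-sample metadata records backed by a DataFrame.

    Required columns: sample_id, individual_id, family_id, phenotype
    (mapped to {case, control}); ``age`` is recognized when present and every
    other column is retained as a numeric/ordinal covariate.
    """

    frame: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in self.frame.columns:
                raise MetadataError(f"missing required metadata column {col!r}")
        if self.frame["sample_id"].duplicated().any():
            dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()].iloc[0]
            raise MetadataError(f"duplicate sample_id {dup!r}")
        bad = set(self.frame["phenotype"]) - {"case", "control"}
        if bad:
            raise MetadataError(f"phenotype values outside {{case, control}}: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def phenotype_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        sub = self.frame.set_index("sample_id").loc[list(sample_ids)]
        return sub["phenotype"].to_numpy()

    def family_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        sub = self.frame.set_index("sample_id").loc[list(sample_ids)]
        return sub["family_id"].to_numpy()

    def covariate_matrix(self, sample_ids: Sequence[str], names: Sequence[str] | None = None) -> pd.DataFrame:
        names = list(names) if names is not None else list(self.covariate_names)
        sub = self.frame.set_index("sample_id").loc[list(sample_ids)]
        return sub[names].apply(pd.to_numeric, errors="coerce")

    def sibling_pairs(self, sample_ids: Sequence[str] | None = None) -> list[tuple[str, str]]:
        """(sample, sample) pairs of distinct individuals sharing a family."""
        frame = self.frame
        if sample_ids is not None:
            frame = frame[frame["sample_id"].isin(set(sample_ids))]
        pairs: list[tuple[str, str]] = []
        for _, grp in frame.groupby("family_id", sort=True):
            individuals = grp.drop_duplicates("individual_id")
            ids = individuals["sample_id"].tolist()
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    pairs.append((ids[i], ids[j]))
        return pairs

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        sub = self.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleMetadata(sub, list(self.covariate_names))


@dataclass
class OmicSet:
    """Omic tables aligned to one shared, lexicographically ordered sample set."""

    tables: dict[str, CountTable]
    shared_samples: list[str]

    def __iter__(self):
        return iter(self.tables.values())

    def __getitem__(self, omic_name: str) -> CountTable:
        return self.tables[omic_name]


def read_count_table(path: str | Path, omic_name: str) -> CountTable:
    """Read a feature-by-sample TSV (header = sample ids, column 1 = feature ids)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # pandas mangles duplicate column names, so check the raw header
    _check_unique(header[1:], "sample")
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise CountTableError(f"empty count table in {path}")
    sample_ids = [str(c) for c in frame.columns]
    feature_ids = [str(i) for i in frame.index]
    _check_unique(sample_ids, "sample")
    _check_unique(feature_ids, "feature")
    raw = frame.to_numpy()
    numeric = frame.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(numeric) | (numeric < 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise CountTableError(
            f"invalid cell {raw[i, j]!r} (non-numeric, negative or non-finite) at "
            f"feature {feature_ids[i]!r}, sample {sample_ids[j]!r} in {path}"
        )
    return CountTable(omic_name, feature_ids, sample_ids, numeric)


def write_count_table(table: CountTable, path: str | Path, precision: int = 10) -> None:
    frame = table.to_frame()
    frame.to_csv(Path(path), sep="\t", float_format=f"%.{precision}g", index_label="feature_id")


def read_metadata(
    path: str | Path,
    phenotype_map: Mapping[str, str] | None = None,
) -> SampleMetadata:
    """Read a sample metadata TSV; unknown columns become covariates.

    Phenotype strings are mapped case-insensitively through ``phenotype_map``
    (default ASD -> case, TD -> control).
    """
    phenotype_map = {k.lower(): v for k, v in (phenotype_map or DEFAULT_PHENOTYPE_MAP).items()}
    frame = pd.read_csv(Path(path), sep="\t", dtype={c: str for c in REQUIRED_METADATA_COLUMNS})
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in frame.columns:
            raise MetadataError(f"metadata file {path} missing required column {col!r}")
    mapped = []
    for raw in frame["phenotype"]:
        key = str(raw).strip().lower()
        if key not in phenotype_map:
            raise MetadataError(f"unmappable phenotype value {raw!r} in {path}")
        mapped.append(phenotype_map[key])
    frame = frame.assign(phenotype=mapped)
    covariates = [
        c for c in frame.columns if c not in REQUIRED_METADATA_COLUMNS and c != "age"
    ]
    return SampleMetadata(frame, covariates)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(Path(path), sep="\t", index=False)


def align_omics(tables: Sequence[CountTable]) -> OmicSet:
    """Restrict every table to the shared samples, in lexicographic order.

    The study design motivates this: each omic was measured on a different
    subset of stool samples and only the intersection supports cross-omic
    work. Raises :class:`AlignmentError` (listing per-table sample counts)
    when the intersection is empty.
    """
    if not tables:
        raise AlignmentError("align_omics requires at least one table")
    shared: set[str] = set(tables[0].sample_ids)
    for t in tables[1:]:
        shared &= set(t.sample_ids)
    if not shared:
        counts = {t.omic_name: t.n_samples for t in tables}
        raise AlignmentError(f"no samples shared across omics (per-table counts: {counts})")
    ordered = sorted(shared)
    aligned = {t.omic_name: t.subset_samples(ordered) for t in tables}
    return OmicSet(aligned, ordered)
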