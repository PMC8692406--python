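"""OTU tables, fraction metadata, and the quality filters applied before qSIP.

Two filters are applied to the OTU table, in this order:

1. Contamination filter: an OTU is considered endemic to the samples (kept)
   only if its total read count across all samples is strictly greater than
   ``ratio`` (default 10) times its read count in the laboratory-contaminant
   profile.
2. Low-abundance filter: within each substrate x H2 comparison, an OTU enters
   the qSIP analysis only if its reads summed across all density fractions
   strictly exceed ``min_reads`` (default 12) in every replicate incubation
   (labeled and control arms alike) of that comparison.  Low-abundance taxa
   otherwise inflate the variance of the density-shift estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "FractionMetadata",
    "ContaminantProfile",
    "FilterReport",
    "read_otu_table",
    "read_fraction_metadata",
    "read_contaminant_profile",
    "filter_contaminants",
    "filter_low_abundance",
    "removal_summary",
]

METADATA_COLUMNS = [
    "sample_id",
    "treatment",
    "substrate",
    "h2",
    "label",
    "replicate",
    "fraction",
    "density_g_ml",
    "qpcr_copies",
]

DENSITY_RANGE = (1.55, 1.85)


class ValidationError(ValueError):
    """Raised when an input table violates its invariants."""


@dataclass
class OTUTable:
    """Read counts per OTU (rows) per density-fraction sample (columns)."""

    otu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_otus, n_samples) non-negative ints
    taxonomy: dict[str, str] | None = None

    def __post_init__(self):
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64).reshape(len(self.otu_ids), len(self.sample_ids))
        if self.counts.size and self.counts.min() < 0:
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for OTU {self.otu_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        for name, ids in (("otu_ids", self.otu_ids), ("sample_ids", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dup = pd.Series(ids).loc[lambda s: s.duplicated()].iloc[0]
                raise ValidationError(f"duplicate {name}: {dup!r}")

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def otu_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.otu_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    def select_otus(self, keep: list[str]) -> "OTUTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        rows = [idx[o] for o in keep]
        tax = {o: self.taxonomy[o] for o in keep if o in self.taxonomy} if self.taxonomy else None
        return OTUTable(list(keep), list(self.sample_ids),
                        self.counts[rows] if rows else np.zeros((0, self.n_samples), int),
                        taxonomy=tax)

    def write_tsv(self, path):
        df = self.to_frame()
        df.index.name = "#OTU ID"
        df.to_csv(path, sep="\t")


@dataclass
class FractionMetadata:
    """Per-sample gradient metadata: incubation identity, density, qPCR total.

    ``treatment`` identifies the incubation fully (substrate x H2 x label);
    ``comparison`` (derived) identifies the substrate x H2 pair shared by a
    13C incubation and its unlabeled control.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame.copy()
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        df["h2"] = df["h2"].map(_parse_bool)
        df["density_g_ml"] = df["density_g_ml"].astype(float)
        df["qpcr_copies"] = df["qpcr_copies"].astype(float)
        lo, hi = DENSITY_RANGE
        bad = df[(df["density_g_ml"] < lo) | (df["density_g_ml"] > hi)]
        if len(bad):
            raise ValidationError(
                f"density outside [{lo}, {hi}] g/ml for sample "
                f"{bad['sample_id'].iloc[0]!r} ({bad['density_g_ml'].iloc[0]})"
            )
        if (df["qpcr_copies"] < 0).any():
            s = df.loc[df["qpcr_copies"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"negative qpcr_copies for sample {s!r}")
        key = df[["treatment", "replicate", "fraction"]]
        if key.duplicated().any():
            raise ValidationError("duplicate (treatment, replicate, fraction) key")
        df["comparison"] = df["substrate"].astype(str) + np.where(df["h2"], "+H2", "")
        self.frame = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def comparisons(self) -> list[str]:
        return sorted(self.frame["comparison"].unique())

    def require_samples(self, sample_ids) -> None:
        unknown = [s for s in sample_ids if s not in self.frame.index]
        if unknown:
            raise ValidationError(f"samples without metadata: {unknown[:5]}")


@dataclass
class ContaminantProfile:
    """Aggregate read counts per OTU over contamination-control samples."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for otu, c in self.counts.items():
            if c < 0:
                raise ValidationError(f"negative contaminant count for {otu!r}")

    def get(self, otu_id: str) -> int:
        return int(self.counts.get(otu_id, 0))


@dataclass
class FilterReport:
    """Outcome of one filtering step (or an aggregate of steps)."""

    name: str
    n_otus_removed_contaminant: int = 0
    n_otus_removed_low_abundance: int = 0
    reads_removed: int = 0
    reads_total: int = 0
    removed_otus: list[str] = field(default_factory=list)
    kept_by_treatment: dict[str, list[str]] | None = None

    @property
    def reads_kept(self) -> int:
        return self.reads_total - self.reads_removed

    @property
    def percent_reads_removed(self) -> float:
        if self.reads_total == 0:
            raise ValidationError("reads_total is zero")
        return 100.0 * self.reads_removed / self.reads_total

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "n_otus_removed_contaminant": self.n_otus_removed_contaminant,
            "n_otus_removed_low_abundance": self.n_otus_removed_low_abundance,
            "reads_removed": self.reads_removed,
            "reads_total": self.reads_total,
            "percent_reads_removed": round(self.percent_reads_removed, 2),
            "removed_otus": self.removed_otus,
        }
        if self.kept_by_treatment is not None:
            d["kept_by_treatment"] = {k: sorted(v) for k, v in self.kept_by_treatment.items()}
        return d

    def to_json(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def log_lines(self) -> list[str]:
        return [
            f"[{self.name}] removed {len(self.removed_otus)} OTUs, "
            f"{self.reads_removed} of {self.reads_total} reads "
            f"({self.percent_reads_removed:.2f}%)"
        ]


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"1", "true", "yes", "+h2", "h2"}:
        return True
    if s in {"0", "false", "no", "-h2", "none", ""}:
        return False
    raise ValidationError(f"cannot parse H2 flag: {v!r}")


# ---------------------------------------------------------------------------
# readers


def read_otu_table(path, format: str | None = None) -> OTUTable:
    """Read an OTU count table from TSV or BIOM 2.1 (HDF5).

    TSV layout: first column OTU ids (header cell ``#OTU ID`` accepted),
    remaining columns one per fraction sample.  An optional trailing
    ``taxonomy`` column is split off into the taxonomy map.
    """
    path = Path(path)
    if format is None:
        format = "biom" if path.suffix == ".biom" else "tsv"
    if format == "tsv":
        return _read_otu_tsv(path)
    if format == "biom":
        return _read_otu_biom(path)
    raise ValidationError(f"unknown OTU table format: {format!r}")


def _read_otu_tsv(path: Path) -> OTUTable:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    taxonomy = None
    tax_cols = [c for c in df.columns if c.lower() in {"taxonomy", "lineage"}]
    if tax_cols:
        taxonomy = df[tax_cols[0]].to_dict()
        df = df.drop(columns=tax_cols)
    if df.index.duplicated().any():
        raise ValidationError(f"duplicate OTU id: {df.index[df.index.duplicated()][0]!r}")
    if df.columns.duplicated().any():
        raise ValidationError(f"duplicate sample id: {df.columns[df.columns.duplicated()][0]!r}")
    counts = np.zeros(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        try:
            vals = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as e:
            raise ValidationError(f"non-numeric count in column {col!r}: {e}") from None
        if (vals < 0).any():
            row = df.index[np.flatnonzero(vals < 0)[0]]
            raise ValidationError(f"negative count at OTU {row!r}, column {col!r}")
        if not np.allclose(vals, np.round(vals)):
            row = df.index[np.flatnonzero(vals != np.round(vals))[0]]
            raise ValidationError(f"non-integer count at OTU {row!r}, column {col!r}")
        counts[:, j] = np.round(vals).astype(np.int64)
    return OTUTable(list(df.index), list(df.columns), counts, taxonomy=taxonomy)


def _read_otu_biom(path: Path) -> OTUTable:
    # BIOM 2.1 stores a CSR matrix over observations in an HDF5 container.
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        try:
            otu_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
            sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
            grp = f["observation/matrix"]
            mat = sparse.csr_matrix(
                (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
                shape=(len(otu_ids), len(sample_ids)),
            )
        except KeyError as e:
            raise ValidationError(f"not a BIOM 2.1 file: missing {e}") from None
        taxonomy = None
        if "observation/metadata/taxonomy" in f:
            raw = f["observation/metadata/taxonomy"][:]
            taxonomy = {}
            for otu, row in zip(otu_ids, raw):
                if isinstance(row, bytes):
                    taxonomy[otu] = row.decode()
                else:
                    taxonomy[otu] = "; ".join(
                        x.decode() if isinstance(x, bytes) else str(x) for x in np.atleast_1d(row)
                    )
    dense = np.asarray(mat.todense())
    if dense.size and dense.min() < 0:
        raise ValidationError("negative count in BIOM matrix")
    return OTUTable(otu_ids, sample_ids, dense, taxonomy=taxonomy)


def read_fraction_metadata(path) -> FractionMetadata:
    return FractionMetadata(pd.read_csv(path))


def read_contaminant_profile(path) -> ContaminantProfile:
    """Two-column TSV ``otu_id<TAB>count``; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("contaminant profile needs two columns: otu_id, count")
    first = str(df.iloc[0, 1])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    counts = {}
    for otu, c in zip(df.iloc[:, 0], df.iloc[:, 1]):
        counts[str(otu)] = counts.get(str(otu), 0) + int(float(c))
    return ContaminantProfile(counts)


# ---------------------------------------------------------------------------
# filters


def filter_contaminants(
    table: OTUTable,
    contaminants: ContaminantProfile,
    ratio: float = 10.0,
) -> tuple[OTUTable, FilterReport]:
    """Keep an OTU iff its total sample reads strictly exceed ratio x its
    contaminant-profile reads.  OTUs absent from the profile count as 0
    contaminant reads and are always kept."""
    if ratio <= 0:
        raise ValidationError("ratio must be positive")
    totals = table.otu_totals()
    keep, removed = [], []
    for otu in table.otu_ids:
        if totals[otu] > ratio * contaminants.get(otu):
            keep.append(otu)
        else:
            removed.append(otu)
    filtered = table.select_otus(keep)
    report = FilterReport(
        name="contaminant_filter",
        n_otus_removed_contaminant=len(removed),
        reads_removed=int(totals[removed].sum()) if removed else 0,
        reads_total=table.total_reads,
        removed_otus=removed,
    )
    return filtered, report


def filter_low_abundance(
    table: OTUTable,
    metadata: FractionMetadata,
    min_reads: int = 12,
) -> tuple[OTUTable, FilterReport]:
    """Keep an OTU for a comparison iff its reads summed over density
    fractions strictly exceed ``min_reads`` in every replicate incubation of
    that comparison.  The returned table keeps OTUs passing in at least one
    comparison; per-comparison keep sets are reported."""
    metadata.require_samples(table.sample_ids)
    md = metadata.frame.loc[table.sample_ids]
    counts = table.to_frame()
    kept_by: dict[str, list[str]] = {}
    for comp, sub in md.groupby("comparison"):
        rep_sums = counts[sub["sample_id"]].T.groupby(
            [sub["label"].values, sub["replicate"].values]
        ).sum()  # (label, replicate) x OTU
        ok = (rep_sums > min_reads).all(axis=0)
        kept_by[comp] = [o for o in table.otu_ids if ok[o]]
    keep_any = set().union(*kept_by.values()) if kept_by else set()
    keep = [o for o in table.otu_ids if o in keep_any]
    removed = [o for o in table.otu_ids if o not in keep_any]
    totals = table.otu_totals()
    filtered = table.select_otus(keep)
    report = FilterReport(
        name="low_abundance_filter",
        n_otus_removed_low_abundance=len(removed),
        reads_removed=int(totals[removed].sum()) if removed else 0,
        reads_total=table.total_reads,
        removed_otus=removed,
        kept_by_treatment=kept_by,
    )
    return filtered, report


def removal_summary(reports: list[FilterReport]) -> FilterReport:
    """Aggregate several filter reports sharing a common reads_total basis.

    reads_total of the aggregate is the basis of the first report (the table
    before any filtering); removed reads and OTU counts are summed.
    """
    if not reports:
        raise ValidationError("no reports to aggregate")
    basis = reports[0].reads_total
    if basis == 0:
        raise ValidationError("reads_total is zero")
    agg = FilterReport(
        name="combined",
        n_otus_removed_contaminant=sum(r.n_otus_removed_contaminant for r in reports),
        n_otus_removed_low_abundance=sum(r.n_otus_removed_low_abundance for r in reports),
        reads_removed=sum(r.reads_removed for r in reports),
        reads_total=basis,
        removed_otus=[o for r in reports for o in r.removed_otus],
    )
    return agg
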