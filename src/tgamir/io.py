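"""Readers, writers and containers for the pipeline's external artifacts.

All tabular artifacts are tab-delimited UTF-8 text with "." as the decimal
mark.  Expression matrices are features x samples with an optional parallel
set of ``<sample>.detected`` boolean columns carrying the array detection
calls; clinical metadata, miRNA->gene binding-site tables, differential
expression tables and correlation-network edge lists each have a fixed
column schema validated on read.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

GROUPS = ("TGA_RV", "TGA_LV", "control")

METADATA_COLUMNS = [
    "sample_id",
    "group",
    "overt_hf",
    "death",
    "ntprobnp",
    "hstnt",
    "egfr",
]


class SchemaError(ValueError):
    """An input file violates the expected schema."""


@dataclass
class ExpressionMatrix:
    """A feature x sample intensity matrix with per-cell detection calls.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.  On the
        ``raw`` scale all values must be finite and non-negative; on the
        ``log2`` scale any finite real is allowed.
    detected
        Boolean DataFrame of identical shape: the platform's detection call
        for each cell.
    scale
        ``"raw"`` or ``"log2"``.
    platform
        ``"miRNA"`` or ``"mRNA"``.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    scale: str = "raw"
    platform: str = "miRNA"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise SchemaError(f"unknown scale {self.scale!r}")
        if self.platform not in ("miRNA", "mRNA"):
            raise SchemaError(f"unknown platform {self.platform!r}")
        if self.values.shape != self.detected.shape:
            raise SchemaError("values and detected must have identical shape")
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise SchemaError("values and detected must share index and columns")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate feature ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if self.scale == "raw":
            if not np.all(np.isfinite(arr)):
                raise SchemaError("raw-scale matrix contains non-finite values")
            if np.any(arr < 0):
                raise SchemaError("raw-scale matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features: Iterable[str]) -> "ExpressionMatrix":
        keep = list(features)
        return ExpressionMatrix(
            self.values.loc[keep].copy(),
            self.detected.loc[keep].copy(),
            scale=self.scale,
            platform=self.platform,
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        keep = list(samples)
        return ExpressionMatrix(
            self.values[keep].copy(),
            self.detected[keep].copy(),
            scale=self.scale,
            platform=self.platform,
        )


@dataclass(frozen=True)
class CorrelationEdge:
    """One retained miRNA-mRNA pair of the inverse-correlation network."""

    mirna_id: str
    mrna_id: str
    rho: float
    p: float
    mirna_direction: str
    mrna_direction: str
    has_site: bool
    n_samples: int


class BindingSiteTable:
    """miRNA -> gene 3'UTR binding sites with O(1) pair membership tests.

    Stands in for the output of a sequence-based target-prediction engine:
    each row records one predicted seed-match site (mirna_id, gene_id,
    region, site_start, site_end).  Only 3'UTR sites are modelled.
    """

    COLUMNS = ["mirna_id", "gene_id", "region", "site_start", "site_end"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"binding-site table missing columns {missing}")
        table = table[self.COLUMNS].reset_index(drop=True)
        if not (table["region"] == "UTR3").all():
            raise SchemaError("only UTR3 binding sites are supported")
        starts = table["site_start"].to_numpy()
        ends = table["site_end"].to_numpy()
        if np.any(starts < 0) or np.any(ends <= starts):
            raise SchemaError("binding sites require 0 <= site_start < site_end")
        self.table = table
        self._pairs = set(zip(table["mirna_id"], table["gene_id"]))

    def __len__(self) -> int:
        return len(self.table)

    def has_site(self, mirna_id: str, gene_id: str) -> bool:
        return (mirna_id, gene_id) in self._pairs

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: str | Path, platform: str = "miRNA") -> ExpressionMatrix:
    """Read a raw-scale expression TSV.

    The first column holds feature ids, remaining columns one sample each;
    optional ``<sample>.detected`` columns carry boolean detection calls and
    default to all-detected when absent.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen, dup_cols = set(), []
    for col in header:
        if col in seen:
            dup_cols.append(col)
        seen.add(col)
    if dup_cols:
        raise SchemaError(f"{path}: duplicated column headers {sorted(set(dup_cols))}")
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    feature_col = df.columns[0]
    df = df.set_index(feature_col)
    det_cols = [c for c in df.columns if c.endswith(".detected")]
    sample_cols = [c for c in df.columns if not c.endswith(".detected")]
    values = df[sample_cols]
    bad = values.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SchemaError(
            f"{path}: non-numeric value at feature {values.index[r]!r}, sample {values.columns[c]!r}"
        )
    values = values.astype(float)
    if det_cols:
        expected = [f"{s}.detected" for s in sample_cols]
        if sorted(det_cols) != sorted(expected):
            raise SchemaError(f"{path}: detection columns do not match sample columns")
        detected = df[expected].astype(bool)
        detected.columns = sample_cols
    else:
        detected = pd.DataFrame(True, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, detected, scale="raw", platform=platform)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, with_detection: bool = True
) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    if with_detection:
        det = matrix.detected.copy()
        det.columns = [f"{c}.detected" for c in det.columns]
        out = pd.concat([out, det], axis=1)
    out.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# sample metadata


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the clinical metadata table (one row per sample).

    Missing clinical markers are empty cells and come back as NaN; they are
    never encoded as 0 (controls legitimately lack heart-failure labs).
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids in metadata")
    bad_groups = set(meta["group"]) - set(GROUPS)
    if bad_groups:
        raise SchemaError(f"{path}: unknown groups {sorted(bad_groups)}")
    for col in ("overt_hf", "death"):
        meta[col] = meta[col].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# binding sites


def read_binding_sites(path: str | Path) -> BindingSiteTable:
    return BindingSiteTable(pd.read_csv(path, sep="\t"))


def write_binding_sites(sites: BindingSiteTable, path: str | Path) -> None:
    sites.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network edges

NETWORK_COLUMNS = [
    "mirna",
    "mrna",
    "rho",
    "p",
    "mirna_direction",
    "mrna_direction",
    "has_site",
    "n_samples",
]


def write_network(edges: Iterable[CorrelationEdge], path: str | Path) -> None:
    rows = [
        (
            e.mirna_id,
            e.mrna_id,
            e.rho,
            e.p,
            e.mirna_direction,
            e.mrna_direction,
            e.has_site,
            e.n_samples,
        )
        for e in edges
    ]
    pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_network(path: str | Path) -> list[CorrelationEdge]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: network table missing columns {missing}")
    return [
        CorrelationEdge(
            mirna_id=str(r.mirna),
            mrna_id=str(r.mrna),
            rho=float(r.rho),
            p=float(r.p),
            mirna_direction=str(r.mirna_direction),
            mrna_direction=str(r.mrna_direction),
            has_site=bool(r.has_site),
            n_samples=int(r.n_samples),
        )
        for r in df.itertuples()
    ]


def write_network_graphml(edges: Iterable[CorrelationEdge], path: str | Path) -> None:
    """Export the bipartite miRNA-mRNA network as GraphML."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.mirna_id, kind="miRNA", direction=e.mirna_direction)
        g.add_node(e.mrna_id, kind="mRNA", direction=e.mrna_direction)
        g.add_edge(e.mirna_id, e.mrna_id, rho=e.rho, p=e.p)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# printed differential-expression fixture tables

FIXTURE_FILES = {
    "T2A": "table2a.tsv",
    "T2B": "table2b.tsv",
    "T2C": "table2c.tsv",
    "T3A": "table3a.tsv",
    "T3B": "table3b.tsv",
}

FIXTURE_COMPARISONS = {
    "T2A": "miRNA: TGA (n=31) vs control (n=15)",
    "T2B": "miRNA: TGA-LV (n=15) vs TGA-RV (n=16)",
    "T2C": "miRNA: TGA-RV (n=16) vs control (n=15)",
    "T3A": "mRNA: TGA (n=32) vs control (n=16)",
    "T3B": "mRNA: TGA-RV (n=16) vs control (n=16)",
}


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load one of the published differential-expression tables.

    Returns a DataFrame with columns feature_id, fold_change (2 decimals, as
    printed), adjusted_p (4 decimals) and regulation (Lower/Higher); the
    comparison label is stored in ``.attrs["comparison"]``.
    """
    if name not in FIXTURE_FILES:
        raise KeyError(f"unknown fixture table {name!r}; choose from {sorted(FIXTURE_FILES)}")
    ref = importlib.resources.files("tgamir.fixtures") / FIXTURE_FILES[name]
    with importlib.resources.as_file(ref) as fp:
        df = pd.read_csv(fp, sep="\t")
    df["fold_change"] = df["fold_change"].astype(float)
    df["adjusted_p"] = df["adjusted_p"].astype(float)
    if (df["fold_change"] <= 0).any():
        raise SchemaError(f"fixture {name}: non-positive fold change")
    lower = df["regulation"] == "Lower"
    if not ((df["fold_change"] < 1) == lower).all():
        raise SchemaError(f"fixture {name}: regulation label inconsistent with fold change")
    df.attrs["comparison"] = FIXTURE_COMPARISONS[name]
    return df
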