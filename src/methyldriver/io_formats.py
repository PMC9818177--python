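"""Readers and writers for every external table the pipeline touches.

All files are plain tab-separated text (GMT for gene sets).  Validation is
strict: duplicate identifiers, missing channels, missing values and samples
absent from the sample sheet are hard errors, never silently repaired.
Downstream modules only ever see the in-memory containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "CASE"
CONTROL = "CONTROL"

#: Gene-annotation classes, promoter-proximal first.
GENE_REGIONS = ("TSS1500", "TSS200", "UTR5", "FIRST_EXON", "BODY", "UTR3")

#: Promoter-window subset of :data:`GENE_REGIONS` (used by integration policies).
PROMOTER_REGIONS = ("TSS1500", "TSS200", "UTR5", "FIRST_EXON")

#: CpG-island annotation classes.  OPEN_SEA is the catch-all for probes
#: outside islands, shores and shelves.
CPG_REGIONS = ("ISLAND", "N_SHORE", "S_SHORE", "N_SHELF", "S_SHELF", "OPEN_SEA")


class FormatError(ValueError):
    """A malformed or internally inconsistent input file."""


@dataclass(frozen=True)
class SampleSheet:
    """Case/control assignment for the samples of one cohort.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, in canonical order.  All matrices are
        reordered to this order on load.
    groups
        Group label per sample, ``"CASE"`` or ``"CONTROL"``.
    """

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise FormatError("sample_ids and groups differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample_id in sample sheet")
        bad = sorted(set(self.groups) - {CASE, CONTROL})
        if bad:
            raise FormatError(f"unknown group label(s): {bad}")
        for grp in (CASE, CONTROL):
            if self.groups.count(grp) < 2:
                raise FormatError(
                    f"group {grp} has {self.groups.count(grp)} samples; "
                    "two-sample tests need at least 2 per group"
                )

    @property
    def case_ids(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.groups) if g == CONTROL]

    def swapped(self) -> "SampleSheet":
        """Return a sheet with CASE and CONTROL labels exchanged."""
        flip = {CASE: CONTROL, CONTROL: CASE}
        return SampleSheet(self.sample_ids, tuple(flip[g] for g in self.groups))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleSheet":
        return cls(tuple(frame["sample_id"].astype(str)), tuple(frame["group"].astype(str)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups})


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe manifest mapping each probe to a gene and two annotation classes.

    ``table`` is indexed by ``probe_id`` with columns ``gene`` (empty string
    for intergenic probes), ``gene_region`` and ``cpg_region``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "gene_region", "cpg_region"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"annotation missing column(s): {sorted(missing)}")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"duplicate probe_id in manifest: {dup!r}")
        bad_gr = set(self.table["gene_region"]) - set(GENE_REGIONS)
        if bad_gr:
            raise FormatError(f"unknown gene_region value(s): {sorted(bad_gr)}")
        bad_cr = set(self.table["cpg_region"]) - set(CPG_REGIONS)
        if bad_cr:
            raise FormatError(f"unknown cpg_region value(s): {sorted(bad_cr)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics).

    ``terms`` maps term_id -> frozenset of gene symbols; ``names`` maps
    term_id -> human-readable description.
    """

    terms: Mapping[str, frozenset]
    names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, genes in self.terms.items():
            if not genes:
                raise FormatError(f"term {tid!r} has no genes")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def universe(self) -> frozenset:
        out: set = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


@dataclass(frozen=True)
class ChannelLayout:
    """Column-naming convention for two-channel signal tables.

    Each sample contributes two columns, ``<sample><methylated_suffix>`` and
    ``<sample><unmethylated_suffix>`` (GenomeStudio-style export).
    """

    methylated_suffix: str = ".Methylated"
    unmethylated_suffix: str = ".Unmethylated"


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a two-column TSV sample sheet (``sample_id``, ``group``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(frame.columns):
        raise FormatError(f"{path}: expected columns sample_id, group")
    return SampleSheet.from_frame(frame)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe manifest TSV (``probe_id``, ``gene``, ``gene_region``, ``cpg_region``)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "probe_id" not in frame.columns:
        raise FormatError(f"{path}: expected a probe_id column")
    return ProbeAnnotation(frame.set_index("probe_id"))


def read_signal_table(
    path: str | Path,
    sheet: SampleSheet,
    layout: ChannelLayout = ChannelLayout(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a two-channel probe intensity table.

    Returns ``(methylated, unmethylated)`` probe x sample matrices with
    identical probe ordering and columns ordered per the sample sheet.
    Negative intensities are preserved: clamping with ``max(., 0)`` belongs
    to the beta-value formula, not to parsing.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe row {dup!r}")
    meth_cols = {}
    unmeth_cols = {}
    for col in frame.columns:
        if col.endswith(layout.methylated_suffix):
            meth_cols[col[: -len(layout.methylated_suffix)]] = col
        elif col.endswith(layout.unmethylated_suffix):
            unmeth_cols[col[: -len(layout.unmethylated_suffix)]] = col
        else:
            raise FormatError(f"{path}: column {col!r} matches neither channel suffix")
    file_samples = set(meth_cols) | set(unmeth_cols)
    unknown = file_samples - set(sheet.sample_ids)
    if unknown:
        raise FormatError(f"{path}: sample(s) absent from sample sheet: {sorted(unknown)}")
    for sid in sheet.sample_ids:
        if sid not in meth_cols:
            raise FormatError(f"{path}: missing methylated channel for sample {sid!r}")
        if sid not in unmeth_cols:
            raise FormatError(f"{path}: missing unmethylated channel for sample {sid!r}")
    meth = frame[[meth_cols[s] for s in sheet.sample_ids]].copy()
    meth.columns = list(sheet.sample_ids)
    unmeth = frame[[unmeth_cols[s] for s in sheet.sample_ids]].copy()
    unmeth.columns = list(sheet.sample_ids)
    for name, mat in (("methylated", meth), ("unmethylated", unmeth)):
        if mat.isna().any().any():
            probe = mat.index[mat.isna().any(axis=1)][0]
            raise FormatError(f"{path}: missing {name} value at probe {probe!r}")
    return meth.astype(float), unmeth.astype(float)


def write_signal_table(
    methylated: pd.DataFrame,
    unmethylated: pd.DataFrame,
    path: str | Path,
    layout: ChannelLayout = ChannelLayout(),
) -> None:
    """Write a two-channel signal table in the layout `read_signal_table` expects."""
    if not methylated.index.equals(unmethylated.index):
        raise FormatError("channel matrices disagree on probe ordering")
    if list(methylated.columns) != list(unmethylated.columns):
        raise FormatError("channel matrices disagree on sample ordering")
    out = pd.DataFrame(index=methylated.index)
    out.index.name = "probe_id"
    for sample in methylated.columns:
        out[f"{sample}{layout.methylated_suffix}"] = methylated[sample]
        out[f"{sample}{layout.unmethylated_suffix}"] = unmethylated[sample]
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_matrix(path: str | Path, sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (e.g. log2 expression).

    If a sample sheet is given, columns are validated against it and put in
    sheet order.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature row {dup!r}")
    if frame.isna().any().any():
        feat = frame.index[frame.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value at feature {feat!r}")
    if sheet is not None:
        unknown = set(frame.columns) - set(sheet.sample_ids)
        if unknown:
            raise FormatError(f"{path}: sample(s) absent from sample sheet: {sorted(unknown)}")
        absent = [s for s in sheet.sample_ids if s not in frame.columns]
        if absent:
            raise FormatError(f"{path}: sample(s) missing from matrix: {absent}")
        frame = frame[list(sheet.sample_ids)]
    return frame.astype(float)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``term_id TAB description TAB gene [TAB gene ...]``.

    Duplicate genes within a line are deduplicated (set semantics); an empty
    file yields an empty collection.
    """
    terms: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, name = fields[0], fields[1]
            if term_id in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
            terms[term_id] = genes
            names[term_id] = name
    return GeneSetCollection(terms, names)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection as GMT with genes sorted for byte-determinism."""
    with open(path, "w") as handle:
        for term_id in collection.terms:
            name = collection.names.get(term_id, term_id)
            genes = "\t".join(sorted(collection.terms[term_id]))
            handle.write(f"{term_id}\t{name}\t{genes}\n")


def read_gene_list(path: str | Path) -> frozenset:
    """Read a plain one-gene-per-line list (e.g. a metabolism pathway list)."""
    with open(path) as handle:
        return frozenset(line.strip() for line in handle if line.strip())


#: Deterministic sort key per result-table kind, applied by `write_results`.
RESULT_SORT_KEYS: dict[str, list[str]] = {
    "dmp": ["p_value", "probe_id"],
    "dmr": ["p_value", "gene", "region_class"],
    "deg": ["p_value", "gene"],
    "driver": ["gene"],
    "enrichment": ["p_value", "term_id"],
    "correlation": ["p_value", "gene"],
    "gene_methylation": ["gene"],
}


def write_results(table: pd.DataFrame, path: str | Path, kind: str | None = None) -> None:
    """Write a result table as TSV with a deterministic row order.

    ``kind`` selects the documented sort key (see :data:`RESULT_SORT_KEYS`);
    unknown kinds are written in current row order.  Floats use 6 significant
    digits, so writing the same table twice is byte-identical.
    """
    out = table
    if kind is not None and kind in RESULT_SORT_KEYS:
        keys = [k for k in RESULT_SORT_KEYS[kind] if k in table.columns]
        if keys:
            out = table.sort_values(keys, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.6g")
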