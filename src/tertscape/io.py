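"""Readers and writers for every external table the pipeline touches.

In-memory conventions
---------------------
* Count matrices are :class:`pandas.DataFrame` objects with gene (or TE
  instance) identifiers as the row index and sample identifiers as columns;
  entries are non-negative integers.
* Sample annotations are a :class:`pandas.DataFrame` indexed by ``sample_id``
  with columns ``tumor_type``, ``role`` (``tumor``/``control``),
  ``tert_stratum`` (``pos``/``neg``/``unset``) and ``mutation_status``
  (``wt``, ``C228T``, ``C228A``, ``C250T``, ``C250A``, ``unknown``).
* Signed pathway libraries are :class:`PathwayLibrary` objects mapping
  pathway -> {gene -> activator/repressor role in {-1, 0, +1}}.

All tables on disk are TSV with a header row, UTF-8, ``.`` decimal separator.
Lines starting with ``#`` are treated as comments/provenance and skipped on
read.  The signed pathway format is a GMT dialect ("signed GMT"): one pathway
per line, ``pathway_id<TAB>description<TAB>gene:role...``, introduced by the
header line ``#signed-gmt v1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataContractError

SIGNED_GMT_HEADER = "#signed-gmt v1"

STAR_SUMMARY_PREFIX = "N_"
STAR_STRAND_COLUMNS = {"unstranded": 1, "fwd": 2, "rev": 3}

ROLES = ("tumor", "control")
STRATA = ("pos", "neg", "unset")
MUTATION_STATUSES = ("wt", "C228T", "C228A", "C250T", "C250A", "unknown")

SAMPLE_TABLE_COLUMNS = ["tumor_type", "role", "tert_stratum", "mutation_status"]


# ---------------------------------------------------------------------------
# Pathway library
# ---------------------------------------------------------------------------


@dataclass
class PathwayLibrary:
    """Signed gene-set library: pathway -> {gene -> role in {-1, 0, +1}}.

    The role encodes the activator/repressor function of the gene product in
    the pathway: +1 activator, -1 inhibitor, 0 ambiguous.
    """

    pathways: dict[str, dict[str, int]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            for gene, role in members.items():
                if role not in (-1, 0, 1):
                    raise DataContractError(
                        f"pathway {pid!r}: gene {gene!r} has role {role!r}, "
                        "expected one of -1, 0, +1"
                    )

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __getitem__(self, pathway_id: str) -> dict[str, int]:
        return self.pathways[pathway_id]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out.update(members)
        return out


# ---------------------------------------------------------------------------
# STAR GeneCounts
# ---------------------------------------------------------------------------


def read_star_gene_counts(path: str | Path, strand_column: str = "unstranded") -> pd.Series:
    """Parse a STAR ``ReadsPerGene.out.tab`` file into a gene -> count Series.

    The file has four tab-separated columns: gene id, unstranded counts,
    forward-strand counts, reverse-strand counts.  Rows whose gene id starts
    with ``N_`` (``N_unmapped``, ``N_multimapping``, ``N_noFeature``,
    ``N_ambiguous``) are summary rows: they are excluded from the returned
    vector but kept in ``series.attrs``.

    Parameters
    ----------
    path
        Path to the 4-column TSV.
    strand_column
        Which count column to use: ``unstranded`` (default), ``fwd`` or
        ``rev``.
    """
    if strand_column not in STAR_STRAND_COLUMNS:
        raise DataContractError(
            f"strand_column must be one of {sorted(STAR_STRAND_COLUMNS)}, got {strand_column!r}"
        )
    col = STAR_STRAND_COLUMNS[strand_column]
    genes: list[str] = []
    counts: list[int] = []
    attrs: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataContractError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            name = fields[0]
            try:
                value = int(fields[col])
            except ValueError as exc:
                raise DataContractError(
                    f"{path}:{lineno}: non-integer count {fields[col]!r}"
                ) from exc
            if value < 0:
                raise DataContractError(f"{path}:{lineno}: negative count {value}")
            if name.startswith(STAR_SUMMARY_PREFIX):
                attrs[name] = value
            else:
                genes.append(name)
                counts.append(value)
    series = pd.Series(counts, index=pd.Index(genes, name="gene_id"), dtype=np.int64)
    if series.index.has_duplicates:
        dup = series.index[series.index.duplicated()][0]
        raise DataContractError(f"{path}: duplicate gene id {dup!r}")
    series.attrs.update(attrs)
    return series


def merge_counts(vectors: Sequence[pd.Series], sample_ids: Sequence[str]) -> pd.DataFrame:
    """Merge per-sample count vectors into a genes x samples count matrix.

    The gene universe is the union across samples, ordered lexicographically
    for deterministic output; absent (gene, sample) pairs are filled with 0.
    """
    if len(vectors) != len(sample_ids):
        raise DataContractError(
            f"{len(vectors)} vectors but {len(sample_ids)} sample ids"
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise DataContractError("duplicate sample ids in merge_counts")
    if not vectors:
        return pd.DataFrame(dtype=np.int64)
    merged = pd.concat(
        {sid: v for sid, v in zip(sample_ids, vectors)}, axis=1
    ).fillna(0).astype(np.int64)
    merged = merged.loc[sorted(merged.index), list(sample_ids)]
    merged.index.name = "gene_id"
    return merged


# ---------------------------------------------------------------------------
# Count matrix TSV
# ---------------------------------------------------------------------------


def _validate_counts(cm: pd.DataFrame, what: str = "count matrix") -> None:
    if cm.index.has_duplicates:
        raise DataContractError(f"{what}: duplicate gene ids")
    if cm.columns.has_duplicates:
        raise DataContractError(f"{what}: duplicate sample ids")
    values = cm.to_numpy()
    if values.size and (values < 0).any():
        raise DataContractError(f"{what}: negative counts")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a merged genes x samples count matrix (first column = gene id)."""
    cm = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    cm.index.name = "gene_id"
    cm = cm.astype(np.int64)
    _validate_counts(cm, str(path))
    return cm


def write_counts_tsv(cm: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cm.to_csv(fh, sep="\t", index_label="gene_id")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a real-valued feature x sample matrix; 'NA' cells become NaN."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#", na_values=["NA"])


def write_matrix_tsv(m: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a real-valued matrix; undefined cells serialize as the token NA."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        m.to_csv(fh, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Signed GMT
# ---------------------------------------------------------------------------


def read_signed_gmt(path: str | Path) -> PathwayLibrary:
    """Read a signed-GMT pathway library (``gene:role`` member tokens)."""
    pathways: dict[str, dict[str, int]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataContractError(
                    f"{path}:{lineno}: expected pathway_id, description and >=1 gene:role token"
                )
            pid, desc = fields[0], fields[1]
            if pid in pathways:
                raise DataContractError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            members: dict[str, int] = {}
            for token in fields[2:]:
                gene, sep, role_str = token.rpartition(":")
                if not sep or not gene:
                    raise DataContractError(
                        f"{path}:{lineno}: malformed member token {token!r}"
                    )
                try:
                    role = int(role_str)
                except ValueError as exc:
                    raise DataContractError(
                        f"{path}:{lineno}: non-integer role in token {token!r}"
                    ) from exc
                if role not in (-1, 0, 1):
                    raise DataContractError(
                        f"{path}:{lineno}: role {role} outside {{-1, 0, 1}} for gene {gene!r}"
                    )
                if gene in members:
                    raise DataContractError(
                        f"{path}:{lineno}: gene {gene!r} listed twice in pathway {pid!r}"
                    )
                members[gene] = role
            pathways[pid] = members
            descriptions[pid] = desc
    return PathwayLibrary(pathways, descriptions)


def write_signed_gmt(lib: PathwayLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SIGNED_GMT_HEADER + "\n")
        for pid, members in lib.pathways.items():
            desc = lib.descriptions.get(pid, "")
            tokens = [f"{gene}:{role}" for gene, role in members.items()]
            fh.write("\t".join([pid, desc, *tokens]) + "\n")


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------


def _check_enum(series: pd.Series, allowed: tuple[str, ...], column: str, path) -> None:
    bad = sorted(set(series) - set(allowed))
    if bad:
        raise DataContractError(
            f"{path}: column {column!r} contains unknown value(s) {bad}; "
            f"allowed: {list(allowed)}"
        )


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation table; enumerations are strict.

    Empty ``tert_stratum`` cells become ``unset`` and empty
    ``mutation_status`` cells become ``unknown``; any other out-of-vocabulary
    string is rejected rather than coerced.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    required = ["sample_id"] + SAMPLE_TABLE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataContractError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DataContractError(f"{path}: duplicate sample id {dup!r}")
    df = df.set_index("sample_id")
    df["tert_stratum"] = df["tert_stratum"].replace("", "unset")
    df["mutation_status"] = df["mutation_status"].replace("", "unknown")
    _check_enum(df["role"], ROLES, "role", path)
    _check_enum(df["tert_stratum"], STRATA, "tert_stratum", path)
    _check_enum(df["mutation_status"], MUTATION_STATUSES, "mutation_status", path)
    return df[SAMPLE_TABLE_COLUMNS]


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def validate_sample_table(samples: pd.DataFrame) -> None:
    """In-memory contract check mirroring :func:`read_sample_table`."""
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in samples.columns]
    if missing:
        raise DataContractError(f"sample table missing column(s) {missing}")
    if samples.index.has_duplicates:
        raise DataContractError("sample table has duplicate sample ids")
    _check_enum(samples["role"], ROLES, "role", "<memory>")
    _check_enum(samples["tert_stratum"], STRATA, "tert_stratum", "<memory>")
    _check_enum(samples["mutation_status"], MUTATION_STATUSES, "mutation_status", "<memory>")


# ---------------------------------------------------------------------------
# Gene id map
# ---------------------------------------------------------------------------


def read_gene_id_map(path: str | Path) -> pd.Series:
    """Read a source_id -> target_symbol mapping (e.g. Ensembl -> HGNC).

    Many-to-one is allowed; one source mapping to two different targets is
    rejected.  Returned as a Series indexed by source id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("source_id", "target_symbol"):
        if col not in df.columns:
            raise DataContractError(f"{path}: missing required column {col!r}")
    conflicts = df.groupby("source_id")["target_symbol"].nunique()
    bad = conflicts[conflicts > 1]
    if len(bad):
        raise DataContractError(
            f"{path}: source id(s) mapped to multiple targets: {list(bad.index[:5])}"
        )
    df = df.drop_duplicates("source_id")
    return pd.Series(df["target_symbol"].values, index=df["source_id"].values, name="target_symbol")


# ---------------------------------------------------------------------------
# Transposable-element instance counts
# ---------------------------------------------------------------------------


def read_te_counts(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read TE instance counts: columns instance_id, subfamily, <samples...>.

    Returns ``(counts, subfamily)`` where counts is instances x samples and
    subfamily maps instance id -> subfamily label (e.g. L1HS, L1PA2).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("instance_id", "subfamily"):
        if col not in df.columns:
            raise DataContractError(f"{path}: missing required column {col!r}")
    if df["instance_id"].duplicated().any():
        raise DataContractError(f"{path}: duplicate TE instance ids")
    df = df.set_index("instance_id")
    subfamily = df["subfamily"].astype(str)
    counts = df.drop(columns="subfamily").astype(np.int64)
    _validate_counts(counts, str(path))
    if (subfamily.str.strip() == "").any():
        raise DataContractError(f"{path}: unlabeled TE instance (empty subfamily)")
    return counts, subfamily


def write_te_counts(counts: pd.DataFrame, subfamily: pd.Series, path: str | Path) -> None:
    out = counts.copy()
    out.insert(0, "subfamily", subfamily.reindex(counts.index))
    out.to_csv(path, sep="\t", index_label="instance_id")


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
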