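"""Readers/writers for expression matrices, GMT signature collections and drug tables.

Gene identifiers are plain symbol strings, uppercased on ingest; all
matching between expression rows, query lists and signature members is
exact string equality after uppercasing.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: default gene-universe size: the number of annotated human RefSeq genes
#: used as N in the hypergeometric overlap model.
DEFAULT_UNIVERSE_SIZE = 20203

VALID_CATEGORIES = ("neural", "immune", "process")

DRUG_TABLE_COLUMNS = ["drug", "similarity", "zscore", "pvalue", "qvalue", "moa"]


def normalize_symbol(symbol: object) -> str:
    """Canonical form of a gene (or probe) identifier: stripped, uppercased."""
    return str(symbol).strip().upper()


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression table with per-sample group labels.

    ``values`` rows are gene (or, before probe collapse, probe) identifiers
    and columns are sample identifiers. Units are whatever the source
    provides (log-intensity, RPKM, ...); the package never rescales on read.
    """

    values: pd.DataFrame
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.group_labels]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        # keep only labels for samples actually present
        self.group_labels = {s: self.group_labels[s] for s in self.values.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.group_labels[s], None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        hits = [s for s in self.values.columns if self.group_labels[s] == group]
        if not hits:
            raise KeyError(f"unknown group: {group!r}")
        return hits

    def subset_group(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in_group(group)]


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set characterising a cell type or biological process."""

    name: str
    category: str
    source_tag: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in VALID_CATEGORIES:
            raise ValueError(
                f"category must be one of {VALID_CATEGORIES}, got {self.category!r}"
            )
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        bad = [g for g in self.genes if not g or g != g.strip().upper()]
        if bad:
            raise ValueError(f"signature {self.name!r}: non-canonical symbols {bad[:5]}")

    @property
    def size(self) -> int:
        """D, the number of unique genes in the signature."""
        return len(self.genes)


@dataclass
class SignatureCollection:
    """An ordered collection of gene signatures sharing one gene universe N."""

    signatures: list[GeneSignature] = field(default_factory=list)
    universe_size: int = DEFAULT_UNIVERSE_SIZE

    def __post_init__(self) -> None:
        names = [s.name for s in self.signatures]
        if len(names) != len(set(names)):
            raise ValueError("duplicate signature names in collection")
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        if self.signatures:
            biggest = max(s.size for s in self.signatures)
            if self.universe_size < biggest:
                raise ValueError(
                    f"universe_size {self.universe_size} smaller than largest "
                    f"signature ({biggest})"
                )

    def __len__(self) -> int:
        return len(self.signatures)

    def __iter__(self):
        return iter(self.signatures)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.signatures]

    def get(self, name: str) -> GeneSignature:
        for s in self.signatures:
            if s.name == name:
                return s
        raise KeyError(f"no signature named {name!r}")


def _read_annotation(annotation: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(annotation, Mapping):
        return {str(k): str(v) for k, v in annotation.items()}
    table = pd.read_csv(annotation, sep="\t", header=None, dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"annotation file {annotation} needs two columns (sample, group)")
    # tolerate an optional header row
    if [c.lower() for c in table.iloc[0, :2]] == ["sample", "group"]:
        table = table.iloc[1:]
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def read_expression(
    path: str | Path, annotation: str | Path | Mapping[str, str]
) -> ExpressionMatrix:
    """Read a tab-separated genes x samples table plus a sample->group map.

    First column holds gene identifiers (uppercased on read), the header row
    holds sample identifiers. Rows with an empty/missing gene identifier are
    dropped and counted in the log. Non-numeric expression cells raise.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    dup = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup:
        raise ValueError(f"duplicate sample identifiers in {path}: {sorted(dup)}")

    raw = pd.read_csv(path, sep="\t", header=0, dtype={header[0]: str})
    raw.columns = header  # defeat pandas' mangling of duplicate names (none here)
    ids = raw.iloc[:, 0]
    keep = ids.notna() & (ids.astype(str).str.strip() != "")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows with empty gene identifier from %s", n_dropped, path)
    body = raw.loc[keep, sample_ids]
    try:
        body = body.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    body.index = [normalize_symbol(g) for g in ids[keep]]

    labels = _read_annotation(annotation)
    unlabeled = [s for s in sample_ids if s not in labels]
    if unlabeled:
        raise ValueError(f"no group annotation for sample(s): {unlabeled}")
    return ExpressionMatrix(values=body, group_labels={s: labels[s] for s in sample_ids})


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     annotation_path: str | Path | None = None) -> None:
    """Write an expression matrix as TSV; optionally the annotation alongside."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    if annotation_path is not None:
        pd.DataFrame(
            {"sample": matrix.samples, "group": [matrix.group_labels[s] for s in matrix.samples]}
        ).to_csv(annotation_path, sep="\t", header=False, index=False)


def read_gmt(
    path: str | Path,
    category: str = "process",
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> SignatureCollection:
    """Parse a GMT file (name, description, genes... per tab-separated line).

    Duplicate genes within a line are deduplicated before the signature size
    is computed; a line that yields an empty gene set is rejected.
    """
    signatures = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, source_tag = fields[0], fields[1]
            genes = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise ValueError(f"{path}:{lineno}: signature {name!r} has no genes")
            signatures.append(
                GeneSignature(name=name, category=category, source_tag=source_tag, genes=genes)
            )
    return SignatureCollection(signatures=signatures, universe_size=universe_size)


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    """Write a collection as GMT, genes sorted lexicographically per line."""
    if not len(collection):
        raise ValueError("refusing to write an empty signature collection")
    with open(path, "w", encoding="utf-8") as fh:
        for sig in collection:
            fh.write("\t".join([sig.name, sig.source_tag, *sorted(sig.genes)]) + "\n")


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a drug-perturbation TSV (drug, similarity, zscore, pvalue, qvalue, moa)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"drug table {path} missing column(s): {missing}")
    return table


def write_drug_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in DRUG_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"drug table missing column(s): {missing}")
    table.to_csv(path, sep="\t", index=False)
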