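"""Readers and writers for the external representations of the pipeline.

Gene tables and homology-hit tables are plain TSV; multiple sequence
alignments come in as aligned FASTA or Clustal. Everything downstream
consumes the in-memory types defined here (:class:`GeneRecord`,
:class:`HitRecord`, :class:`AlignmentBlock`) — no other module re-parses
files.

Gene coordinates are 1-based ordinal ranks within a replicon (gene order,
not base pairs): the neighborhood statistics reason only about consecutive
gene positions. Replicons are linear, so the first and last gene of a
replicon each have a single neighbor, and clusters/neighborhoods never span
replicons. Strand is ignored throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO

DOMAIN_CODES = ("HK", "RR", "HPt")

GENE_TABLE_COLUMNS = [
    "organism_id",
    "replicon_id",
    "position",
    "gene_id",
    "annotation",
    "domains",
]

HIT_TABLE_COLUMNS = ["protein_id", "domain", "e_value", "coverage", "source"]

HIT_SOURCES = ("hmm", "psiblast_msa", "psiblast_consensus", "textmine")


class FormatError(ValueError):
    """A file violates the expected tabular/alignment format."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene: ordinal position on a replicon plus its IST-domain content.

    ``domains`` is the ordered (N→C) list of internal-signal-transduction
    domain codes found in the encoded protein; an empty tuple means the gene
    does not code for a TCS/PR protein.
    """

    organism_id: str
    replicon_id: str
    position: int
    gene_id: str
    annotation: str = ""
    domains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for code in self.domains:
            if code not in DOMAIN_CODES:
                raise FormatError(
                    f"unknown domain code {code!r} for gene {self.gene_id!r}"
                )

    @property
    def is_ist(self) -> bool:
        """True if the gene codes for at least one HK/RR/HPt domain."""
        return len(self.domains) > 0


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit: protein, domain type, e-value, coverage."""

    protein_id: str
    domain: str
    e_value: float
    coverage: float
    source: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_CODES:
            raise FormatError(f"unknown domain code {self.domain!r}")
        if self.e_value < 0:
            raise FormatError("e_value must be non-negative")
        if not 0.0 <= self.coverage <= 1.0:
            raise FormatError("coverage must lie in [0, 1]")
        if self.source not in HIT_SOURCES:
            raise FormatError(f"unknown hit source {self.source!r}")


@dataclass(frozen=True)
class AlignmentBlock:
    """A multiple sequence alignment: equal-length rows over AAs plus '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise FormatError("alignment must contain at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise FormatError("alignment rows have unequal lengths")
        if len(self.ids) != len(self.rows):
            raise FormatError("one id required per alignment row")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)


def _parse_domains(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(tok.strip() for tok in text.split(","))


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV gene table and validate per-replicon position contiguity.

    Positions within each replicon must be unique and cover 1..L exactly.
    Records come back sorted by (organism, replicon, position).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table missing columns: {missing}")
    records: list[GeneRecord] = []
    for row in df.itertuples(index=False):
        try:
            pos = int(row.position)
        except ValueError as exc:
            raise FormatError(f"non-integer position {row.position!r}") from exc
        records.append(
            GeneRecord(
                organism_id=row.organism_id,
                replicon_id=row.replicon_id,
                position=pos,
                gene_id=row.gene_id,
                annotation=row.annotation,
                domains=_parse_domains(row.domains),
            )
        )
    records.sort(key=lambda g: (g.organism_id, g.replicon_id, g.position))
    _validate_contiguity(records)
    return records


def _validate_contiguity(records: Sequence[GeneRecord]) -> None:
    by_replicon: dict[tuple[str, str], list[int]] = {}
    for g in records:
        by_replicon.setdefault((g.organism_id, g.replicon_id), []).append(g.position)
    for (org, rep), positions in by_replicon.items():
        seen = set(positions)
        if len(seen) != len(positions):
            raise FormatError(f"duplicate position on replicon {rep!r} ({org!r})")
        if seen != set(range(1, len(positions) + 1)):
            raise FormatError(
                f"positions on replicon {rep!r} ({org!r}) are not contiguous 1..L"
            )


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords back to the TSV gene-table format."""
    rows = [
        {
            "organism_id": g.organism_id,
            "replicon_id": g.replicon_id,
            "position": g.position,
            "gene_id": g.gene_id,
            "annotation": g.annotation,
            "domains": ",".join(g.domains),
        }
        for g in records
    ]
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a TSV homology-hit table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"hit table missing columns: {missing}")
    hits = []
    for row in df.itertuples(index=False):
        try:
            e_value = float(row.e_value)
            coverage = float(row.coverage)
        except ValueError as exc:
            raise FormatError("non-numeric e_value or coverage") from exc
        hits.append(
            HitRecord(
                protein_id=row.protein_id,
                domain=row.domain,
                e_value=e_value,
                coverage=coverage,
                source=row.source,
            )
        )
    return hits


def read_alignment(path: str | Path, dialect: str = "aligned_fasta") -> AlignmentBlock:
    """Read an alignment file (``aligned_fasta`` or ``clustal``)."""
    fmt = {"aligned_fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    return AlignmentBlock(
        ids=tuple(rec.id for rec in aln),
        rows=tuple(str(rec.seq) for rec in aln),
    )


def write_alignment_fasta(block: AlignmentBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in zip(block.ids, block.rows):
            fh.write(f">{seq_id}\n{row}\n")


def write_report(
    tables: Mapping[str, pd.DataFrame] | pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write census/neighborhood/fusion report tables.

    TSV holds one table per file (a mapping writes ``<path stem>.<name>.tsv``
    siblings); JSON holds all tables in one object keyed by table name.
    Reals are written to 12 significant digits so a round-trip read
    reproduces integers bit-exactly and reals to that precision.
    """
    path = Path(path)
    if isinstance(tables, pd.DataFrame):
        tables = {"table": tables}
    if format == "tsv":
        if len(tables) == 1:
            (name, df), = tables.items()
            df.to_csv(path, sep="\t", index=False, float_format="%.12g")
        else:
            for name, df in tables.items():
                sibling = path.with_name(f"{path.stem}.{name}.tsv")
                df.to_csv(sibling, sep="\t", index=False, float_format="%.12g")
    elif format == "json":
        payload = {
            name: json.loads(df.to_json(orient="records", double_precision=12))
            for name, df in tables.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
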