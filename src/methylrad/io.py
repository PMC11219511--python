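"""Readers and writers for the external formats the pipeline touches.

No science lives here.  Internal coordinates are 0-based half-open
throughout the package; conversion to the 1-based inclusive convention of
GFF3/TSV and the 0-based half-open convention of BED happens only in this
module, at the format boundary.

All readers validate and reject malformed records rather than coercing
them, and every (write, read) pair round-trips losslessly.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "GeneRecord",
    "GeneAnnotation",
    "SampleMetadata",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "write_sites",
]

_DNA_ALPHABET = frozenset("ACGTN")

ORIGINS = ("Helgoland", "Spitsbergen")
CULTIVATIONS = ("lab", "field")
TEMPERATURES = (5.0, 10.0, 15.0)


class FormatError(ValueError):
    """A malformed or inconsistent input file."""


@dataclass(frozen=True)
class Genome:
    """A single DNA sequence, uppercased, over the alphabet {A,C,G,T,N}.

    ``circular`` marks a circular molecule (e.g. an organellar genome);
    digestion treats the sequence as linear unless told otherwise.
    """

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise FormatError("genome sequence is empty")
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise FormatError(
                f"genome {self.id!r} contains illegal characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 0-based half-open span, strand, free-text product."""

    gene_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "gene"
    product: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")


@dataclass
class GeneAnnotation:
    """Gene records of one genome, sorted by start, unique gene_ids."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate gene ids: {dupes}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


class SampleMetadata:
    """Experimental factors per sample.

    The design has two origins (Helgoland, Spitsbergen) and two cultivation
    modes: field samples (no controlled temperature, recorded NA) and
    laboratory samples reared at 5, 10 or 15 degrees C.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sample_id", "origin", "cultivation", "temperature_C"}
        missing = required - set(table.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        table = table.copy()
        table["sample_id"] = table["sample_id"].astype(str)
        if table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        bad_origin = set(table["origin"]) - set(ORIGINS)
        if bad_origin:
            raise FormatError(f"unknown origin level(s): {sorted(bad_origin)}")
        bad_cult = set(table["cultivation"]) - set(CULTIVATIONS)
        if bad_cult:
            raise FormatError(f"unknown cultivation level(s): {sorted(bad_cult)}")
        temp = pd.to_numeric(table["temperature_C"], errors="coerce")
        is_field = table["cultivation"] == "field"
        if temp[is_field].notna().any():
            raise FormatError("field samples must have temperature NA")
        lab_temp = temp[~is_field]
        if lab_temp.isna().any() or not lab_temp.isin(TEMPERATURES).all():
            raise FormatError("lab samples must have temperature in {5, 10, 15}")
        table["temperature_C"] = temp
        self.table = table.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def factor(self, name: str) -> pd.Series:
        """Return one factor column indexed by sample id.

        ``temperature_C`` is returned as a string factor ('5', '10', '15',
        NA for field samples) so it can be used directly as a grouping.
        """
        if name not in self.table.columns:
            raise KeyError(f"unknown factor {name!r}")
        col = self.table[name]
        if name == "temperature_C":
            col = col.map(lambda t: None if pd.isna(t) else str(int(t)))
        return col

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise KeyError(f"samples not in metadata: {missing}")
        return SampleMetadata(self.table.loc[list(sample_ids)].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.table.reset_index(drop=True).equals(
            other.table.reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, single: bool = True) -> Genome:
    """Read a genome FASTA (single record) into a :class:`Genome`.

    The sequence is uppercased; ``N`` is allowed, ``U`` (RNA) is rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no records")
    if single and len(records) > 1:
        raise FormatError(
            f"{path}: expected a single genome record, found {len(records)}"
        )
    rec = records[0]
    return Genome(id=rec.id, sequence=str(rec.seq).upper())


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    del width  # Biopython wraps at 60; kept for signature stability


def write_fragments_fasta(fragments, path) -> None:
    """Write tag fragments (site_id -> sequence) as a multi-FASTA."""
    recs = [
        SeqRecord(Seq(f.sequence), id=f.site_id, description=f"{f.start}-{f.end}")
        for f in fragments
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3

_GFF3_COLS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gff3(path, genome: Genome | None = None,
              feature_types: tuple[str, ...] = ("gene",)) -> GeneAnnotation:
    """Read gene records from a GFF3 file.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    the internal 0-based half-open one, and validated against the genome
    length when a genome is given.
    """
    genes: list[GeneRecord] = []
    genome_id = genome.id if genome is not None else None
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise FormatError(f"{path}: missing ##gff-version header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            row = dict(zip(_GFF3_COLS, fields))
            if row["type"] not in feature_types:
                continue
            try:
                start1 = int(row["start"])
                end1 = int(row["end"])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if start1 < 1:
                raise FormatError(f"{path}:{lineno}: start < 1")
            if genome is not None and end1 > len(genome):
                raise FormatError(
                    f"{path}:{lineno}: end {end1} beyond genome length {len(genome)}"
                )
            attrs = _parse_gff3_attributes(row["attributes"])
            gene_id = attrs.get("ID") or attrs.get("gene")
            if gene_id is None:
                raise FormatError(f"{path}:{lineno}: record has no ID/gene attribute")
            if genome_id is None:
                genome_id = row["seqid"]
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    start=start1 - 1,
                    end=end1,
                    strand=row["strand"] if row["strand"] in "+-" else "+",
                    feature_type=row["type"],
                    product=attrs.get("product"),
                )
            )
    return GeneAnnotation(genome_id=genome_id or "unknown", genes=genes)


def _gff3_escape(text: str) -> str:
    return text.replace(";", "%3B").replace("=", "%3D").replace("\t", "%09")


def write_gff3(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            attrs = f"ID={_gff3_escape(g.gene_id)}"
            if g.product is not None:
                attrs += f";product={_gff3_escape(g.product)}"
            fh.write(
                "\t".join(
                    [
                        annotation.genome_id,
                        "methylrad",
                        g.feature_type,
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Count tables and metadata (TSV, '.' for NA)


def read_count_table(path, site_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a site x sample tag-count table.

    First column holds site ids, header row holds sample ids; counts must
    be non-negative integers.  If ``site_ids`` is given, the table's sites
    must be a subset of it.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if table.index.duplicated().any():
        dupes = sorted(set(table.index[table.index.duplicated()]))
        raise FormatError(f"{path}: duplicated site id(s): {dupes}")
    try:
        counts = table.astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer count") from exc
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative count")
    if site_ids is not None:
        unknown = set(counts.index) - set(site_ids)
        if unknown:
            raise FormatError(f"{path}: unknown site id(s): {sorted(unknown)[:5]}")
    counts.index.name = "site_id"
    return counts


def write_count_table(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=True)
    return SampleMetadata(table)


def write_metadata(metadata: SampleMetadata, path) -> None:
    out = metadata.table.reset_index(drop=True).copy()
    out["temperature_C"] = out["temperature_C"].map(
        lambda t: "." if pd.isna(t) else str(int(t))
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Site lists


def write_sites(sites: Iterable, path, fmt: str = "tsv",
                genome_id: str = "genome") -> None:
    """Write digested (or annotated) sites as BED, GFF3 or TSV.

    BED is 0-based half-open; GFF3 and TSV use 1-based inclusive start.
    """
    sites = list(sites)
    fmt = fmt.lower()
    if fmt == "bed":
        with open(path, "w") as fh:
            for s in sites:
                end = s.start + len(s.motif.pattern)
                fh.write(f"{genome_id}\t{s.start}\t{end}\t{s.site_id}\t0\t{s.strand}\n")
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for s in sites:
                end = s.start + len(s.motif.pattern)
                attrs = (
                    f"ID={_gff3_escape(s.site_id)};motif={s.motif.pattern};"
                    f"context={s.context}"
                )
                fh.write(
                    f"{genome_id}\tmethylrad\tmethylation_site\t{s.start + 1}\t{end}"
                    f"\t.\t{s.strand}\t.\t{attrs}\n"
                )
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("site_id\tstart\tmotif\tcontext\tregion\tgene_id\tproduct\n")
            for s in sites:
                region = getattr(s, "region", ".")
                gene_id = getattr(s, "gene_id", None) or "."
                product = getattr(s, "product", None) or "."
                fh.write(
                    f"{s.site_id}\t{s.start + 1}\t{s.motif.pattern}\t{s.context}"
                    f"\t{region}\t{gene_id}\t{product}\n"
                )
    else:
        raise ValueError(f"unknown site format {fmt!r} (expected bed/gff3/tsv)")


def read_library_totals(path) -> pd.Series:
    """Read a two-column TSV of sample_id -> total mapped reads."""
    table = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "total"],
                        dtype={"sample_id": str})
    totals = pd.to_numeric(table["total"], errors="raise")
    if (totals <= 0).any():
        raise FormatError(f"{path}: library totals must be positive")
    return pd.Series(totals.to_numpy(), index=table["sample_id"].to_numpy())
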