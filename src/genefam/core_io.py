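"""Domain types and I/O shared by every pipeline stage.

Coordinates are 1-based inclusive throughout, matching the convention of
Ensembl gene tables; all arithmetic in this module assumes it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneRecord",
    "SequenceSet",
    "Alignment",
    "UpstreamSequence",
    "read_gene_table",
    "write_gene_table",
    "bundled_gene_table",
    "read_fasta",
    "write_fasta",
    "translate_cds",
    "reverse_complement",
    "extract_upstream",
]

DATA_DIR = Path(__file__).parent / "data"

_NUCLEOTIDE_CHARS = set("ACGTUNRYSWKMBDHV-")
_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*-")

# en dash, em dash and hyphen all appear as range separators in gene tables
_DASHES = "–—-"


class GeneTableError(ValueError):
    """Raised for malformed or inconsistent gene-table rows."""


@dataclass
class GeneRecord:
    """One gene model: identity, location, and basic protein attributes."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    orf_length: int | None = None
    protein_length: int | None = None
    mw: float | None = None
    pi: float | None = None
    exon_count: int = 1
    cds: str | None = None
    protein: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GeneTableError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in "+-":
            raise GeneTableError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.orf_length is not None and self.orf_length % 3:
            raise GeneTableError(
                f"{self.gene_id}: ORF length {self.orf_length} not divisible by 3"
            )
        if self.exon_count < 1:
            raise GeneTableError(f"{self.gene_id}: exon count < 1")


@dataclass
class SequenceSet:
    """Ordered id -> sequence map with a declared alphabet."""

    records: dict[str, str]
    alphabet: Literal["nucleotide", "protein"] = "nucleotide"

    def __post_init__(self) -> None:
        allowed = (
            _NUCLEOTIDE_CHARS if self.alphabet == "nucleotide" else _PROTEIN_CHARS
        )
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            bad = set(seq.upper()) - allowed
            if bad:
                raise ValueError(
                    f"{name!r}: characters {sorted(bad)} outside "
                    f"{self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def items(self):
        return self.records.items()


@dataclass
class Alignment:
    """A multiple alignment: ordered (id, gapped sequence) rows."""

    rows: list[tuple[str, str]]
    alphabet: Literal["nucleotide", "protein"] = "protein"

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def ungapped(self, name: str) -> str:
        for rid, seq in self.rows:
            if rid == name:
                return seq.replace("-", "")
        raise KeyError(name)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

_LOCATION_RE = re.compile(
    rf"^Chr(?P<chrom>\w+?):(?P<start>[\d,]+)[{_DASHES}](?P<end>[\d,]+)$"
)


def _parse_location(text: str, row_label: str) -> tuple[str, int, int]:
    m = _LOCATION_RE.match(text.strip())
    if not m:
        raise GeneTableError(f"row {row_label!r}: malformed location {text!r}")
    return (
        m.group("chrom"),
        int(m.group("start").replace(",", "")),
        int(m.group("end").replace(",", "")),
    )


def _num(text: str) -> float:
    return float(text.replace(",", ""))


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a gene-summary TSV into :class:`GeneRecord` objects.

    Expected header columns (case-insensitive, flexible naming): gene name,
    location ``ChrNA:start–end``, ORF length (bp), size (aa), MW (Da), pI and
    exon count.  Thousands separators in numeric fields are stripped; the
    strand defaults to ``+`` because summary tables usually omit it.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c.strip().lower(): i for i, c in enumerate(header)}

        def col(*names: str) -> int:
            for n in names:
                if n in cols:
                    return cols[n]
            raise GeneTableError(f"{path.name}: missing column {names[0]!r}")

        i_name = col("name", "gene")
        i_loc = col("location")
        i_orf = col("orf_length_bp", "orf length(bp)", "orf length")
        i_aa = col("size_aa", "size (aa)", "size")
        i_mw = col("mw_da", "mw(da)", "mw")
        i_pi = col("pi")
        i_ex = col("exons", "exon_count")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name = parts[i_name].strip()
            if name in seen:
                raise GeneTableError(f"duplicate gene id {name!r}")
            seen.add(name)
            chrom, start, end = _parse_location(parts[i_loc], name)
            records.append(
                GeneRecord(
                    gene_id=name,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    orf_length=int(_num(parts[i_orf])),
                    protein_length=int(_num(parts[i_aa])),
                    mw=_num(parts[i_mw]),
                    pi=_num(parts[i_pi]),
                    exon_count=int(_num(parts[i_ex])),
                )
            )
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write records in the same TSV layout :func:`read_gene_table` reads."""
    with open(path, "w") as fh:
        fh.write("name\tlocation\torf_length_bp\tsize_aa\tmw_da\tpi\texons\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\tChr{r.chromosome}:{r.start}–{r.end}\t"
                f"{r.orf_length}\t{r.protein_length}\t{r.mw}\t{r.pi}\t"
                f"{r.exon_count}\n"
            )


def bundled_gene_table() -> list[GeneRecord]:
    """The bundled 65-gene wheat TaVQ family table."""
    return read_gene_table(DATA_DIR / "wheat_vq_genes.tsv")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path, alphabet: Literal["nucleotide", "protein"] = "nucleotide"
) -> SequenceSet:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return SequenceSet(records, alphabet)


def write_fasta(seqs: SequenceSet | dict[str, str], path: str | Path) -> None:
    """Write sequences wrapped at 60 columns."""
    items = seqs.items() if hasattr(seqs, "items") else seqs
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# translation and coordinates
# ---------------------------------------------------------------------------

def translate_cds(cds: str, permissive: bool = False) -> str:
    """Translate a CDS with the standard code.

    A terminal stop codon is dropped; an internal stop raises unless
    ``permissive`` is set (it is then written as ``*``); codons containing
    N translate to ``X`` when ambiguous.
    """
    if not cds:
        raise ValueError("empty CDS")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    bad = set(cds) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected CDS characters: {sorted(bad)}")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot and not permissive:
        raise ValueError(f"internal stop codon at residue {prot.index('*') + 1}")
    return prot


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UpstreamSequence(NamedTuple):
    """Promoter slice plus a flag marking truncation at a contig edge."""

    sequence: str
    truncated: bool


def extract_upstream(
    genome: SequenceSet, gene: GeneRecord, length: int = 1500
) -> UpstreamSequence:
    """Sequence immediately upstream of the gene start (promoter region).

    For ``+`` strand genes this is bases ``[start-length, start-1]``; for
    ``-`` strand genes, the reverse complement of ``[end+1, end+length]``.
    The slice is truncated at the contig boundary, flagged in the result.
    """
    if gene.chromosome not in genome:
        raise KeyError(f"chromosome {gene.chromosome!r} not in genome")
    contig = genome[gene.chromosome]
    if gene.strand == "+":
        lo = max(1, gene.start - length)
        hi = gene.start - 1
        seq = contig[lo - 1 : hi]
    else:
        lo = gene.end + 1
        hi = min(len(contig), gene.end + length)
        seq = reverse_complement(contig[lo - 1 : hi])
    return UpstreamSequence(seq, truncated=len(seq) < length)
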