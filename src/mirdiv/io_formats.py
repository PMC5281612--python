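"""Readers, writers and core record types for the pipeline's file formats.

Conventions
-----------
* UTR sequences are stored as uppercase DNA in mRNA-sense (5'->3')
  orientation; RNA input (U) is converted to T.  IUPAC ambiguity codes
  are permitted in UTRs (ancient-genome consensus sequences contain N).
* Mature miRNAs are stored as RNA (A/C/G/U), 5'->3'.
* Coordinates are 0-based half-open everywhere in memory.  The on-disk
  SNP table uses 1-based positions (VCF convention); conversion happens
  at the read/write boundary.
* Parsers reject malformed input instead of repairing it; TSV error
  messages carry line numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .divergence_stats import classify_mutation

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS_DNA = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")


class FormatError(ValueError):
    """Malformed input file or record."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtrRecord:
    """One 3' UTR sequence for one gene in one taxon.

    ``source_coords``, when present, is ``(chromosome, start, end, strand)``
    in 0-based half-open genome coordinates; the interval length must equal
    the sequence length.
    """

    gene_id: str
    taxon: str
    sequence: str
    source_coords: tuple[str, int, int, str] | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("UtrRecord requires a non-empty gene_id")
        if not self.sequence:
            raise FormatError(f"empty sequence for gene {self.gene_id!r}")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"non-IUPAC character(s) {sorted(bad)} in UTR of gene {self.gene_id!r}"
            )
        if self.source_coords is not None:
            _, start, end, strand = self.source_coords
            if not (0 <= start < end):
                raise FormatError(f"bad coordinates {start}..{end} for gene {self.gene_id!r}")
            if end - start != len(self.sequence):
                raise FormatError(
                    f"coordinate span {end - start} != sequence length "
                    f"{len(self.sequence)} for gene {self.gene_id!r}"
                )
            if strand not in "+-":
                raise FormatError(f"bad strand {strand!r} for gene {self.gene_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA (RNA, 5'->3') with its derived seed regions.

    The seed is positions 2-7 (1-based) of the mature sequence; position 8
    extends the seed match on the 5' side of the target site; positions
    13-16 form the 3' supplementary pairing region (absent for miRNAs
    shorter than 16 nt).
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("miRNA requires a non-empty name")
        if len(self.sequence) < 8:
            raise FormatError(
                f"miRNA {self.name!r} is {len(self.sequence)} nt; at least 8 nt are "
                "required to define the seed and position 8"
            )
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise FormatError(f"non-RNA character(s) {sorted(bad)} in miRNA {self.name!r}")

    @property
    def seed6(self) -> str:
        """Positions 2-7 (1-based) of the mature sequence."""
        return self.sequence[1:7]

    @property
    def p8(self) -> str:
        """Position 8 of the mature sequence."""
        return self.sequence[7]

    @property
    def three_prime_region(self) -> str | None:
        """Positions 13-16 (1-based), or None for miRNAs shorter than 16 nt."""
        return self.sequence[12:16] if len(self.sequence) >= 16 else None


@dataclass(frozen=True)
class SnpRecord:
    """A single-base substitution between taxon A (ref) and taxon B (alt).

    ``pos`` is a 0-based offset within the UTR; ``mut_class`` is derived
    (transition iff {ref,alt} is {A,G} or {C,T}).
    """

    gene_id: str
    pos: int
    ref: str
    alt: str
    mut_class: str = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise FormatError(f"negative SNP position {self.pos} for gene {self.gene_id!r}")
        if self.ref not in UNAMBIGUOUS_DNA or self.alt not in UNAMBIGUOUS_DNA:
            raise FormatError(
                f"SNP alleles must be single A/C/G/T bases, got "
                f"{self.ref!r}->{self.alt!r} (gene {self.gene_id!r}); substitutions only"
            )
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref!r}) at {self.gene_id}:{self.pos}")
        object.__setattr__(self, "mut_class", classify_mutation(self.ref, self.alt))


class BedInterval(NamedTuple):
    """One BED6 interval; ``name`` carries the gene id."""

    chrom: str
    start: int
    end: int
    name: str
    score: str
    strand: str


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_utr_fasta(path: str | Path, taxon: str = "A") -> list[UtrRecord]:
    """Read UTRs from FASTA; first header token is the gene id.

    Sequences are uppercased and U converted to T.  Duplicate gene ids,
    empty sequences and non-IUPAC characters are rejected.
    """
    records: list[UtrRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        gene_id = rec.id
        if gene_id in seen:
            raise FormatError(f"duplicate gene_id {gene_id!r} (record {i}) in {path}")
        seen.add(gene_id)
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FormatError(f"empty sequence for gene {gene_id!r} (record {i}) in {path}")
        records.append(UtrRecord(gene_id=gene_id, taxon=taxon, sequence=seq))
    return records


def read_mirna_table(path: str | Path) -> list[MatureMiRNA]:
    """Read mature miRNAs from a two-column TSV (name, sequence) or FASTA.

    Sequences are uppercased and T converted to U.  Duplicate names and
    sequences shorter than 8 nt (seed undefined) are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    entries: list[tuple[str, str, int]] = []  # (name, sequence, line number)
    if first.startswith(">"):
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            entries.append((rec.id, str(rec.seq), i))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if lineno == 1 and fields[0].lower() == "name":
                    continue
                if len(fields) < 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
                entries.append((fields[0], fields[1], lineno))
    mirnas: list[MatureMiRNA] = []
    seen: set[str] = set()
    for name, seq, lineno in entries:
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate miRNA name {name!r}")
        seen.add(name)
        try:
            mirnas.append(MatureMiRNA(name=name, sequence=seq.upper().replace("T", "U")))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return mirnas


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    """Read a minimal VCF-like TSV: gene_id, pos (1-based), ref, alt.

    Positions are converted to 0-based; indels (multi-base alleles) are
    rejected with a "substitutions only" message.
    """
    path = Path(path)
    snps: list[SnpRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "gene_id":
                continue  # header
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
            gene_id, pos_s, ref, alt = fields[:4]
            try:
                pos1 = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: position {pos_s!r} is not an integer") from None
            if pos1 < 1:
                raise FormatError(f"{path}:{lineno}: 1-based position must be >= 1, got {pos1}")
            if len(ref) != 1 or len(alt) != 1:
                raise FormatError(
                    f"{path}:{lineno}: multi-base allele {ref!r}->{alt!r}; substitutions only"
                )
            try:
                snps.append(SnpRecord(gene_id=gene_id, pos=pos1 - 1, ref=ref.upper(), alt=alt.upper()))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return snps


def read_bed(path: str | Path) -> list[BedInterval]:
    """Read a BED6 file of UTR coordinates (name field = gene_id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "score": str, "strand": str},
    )
    if df.isnull().any().any():
        raise FormatError(f"{path}: BED6 requires 6 columns in every row")
    intervals = []
    for row in df.itertuples(index=False):
        if row.strand not in "+-":
            raise FormatError(f"{path}: bad strand {row.strand!r} for interval {row.name!r}")
        if not (0 <= int(row.start) < int(row.end)):
            raise FormatError(f"{path}: bad interval {row.start}..{row.end} for {row.name!r}")
        intervals.append(
            BedInterval(row.chrom, int(row.start), int(row.end), row.name, row.score, row.strand)
        )
    return intervals


def read_pathway_map(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column gene_id -> pathway_id TSV (optional header)."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "gene_id":
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            pairs.append((fields[0], fields[1]))
    return pairs


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_utr_fasta(records: Iterable[UtrRecord], path: str | Path) -> None:
    """Write UTR records as FASTA (60-column wrap, header = gene_id)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_mirna_table(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\n")
        for m in mirnas:
            fh.write(f"{m.name}\t{m.sequence}\n")


def write_snp_table(snps: Iterable[SnpRecord], path: str | Path) -> None:
    """Write SNPs with 1-based positions (VCF convention)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tpos\tref\talt\tmut_class\n")
        for s in snps:
            fh.write(f"{s.gene_id}\t{s.pos + 1}\t{s.ref}\t{s.alt}\t{s.mut_class}\n")


#: documented sort keys per output table; rows are sorted on these columns
#: (subset actually present) so repeated runs are byte-identical.
_TABLE_SORT_KEYS: Mapping[str, tuple[str, ...]] = {
    "sites": ("gene_id", "taxon", "mirna", "start"),
    "scored_sites": ("gene_id", "taxon", "mirna", "start"),
    "events": ("gene_id", "mirna"),
    "gene_summary": ("gene_id",),
    "ranking": ("rank",),
    "titv": ("subset_label",),
    "venn": ("region",),
    "pathway_scores": ("summed_ssr", "pathway_id"),
    "snp_summary": (),
}


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write result tables as TSV files with deterministic row order.

    Each table is sorted on its documented key columns and written as
    ``<name>.tsv`` under ``out_dir``.  Running twice on the same input
    yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        keys = [c for c in _TABLE_SORT_KEYS.get(name, tuple(df.columns)) if c in df.columns]
        if keys:
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
        dest = out_dir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False, lineterminator="\n")
        written[name] = dest
    return written


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware, via Biopython)."""
    return str(Seq(seq).reverse_complement())
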