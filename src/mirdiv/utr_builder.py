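"""Construction of orthologous UTR pairs.

A :class:`UtrPair` holds the taxon-A UTR (e.g. the reference assembly),
the taxon-B UTR (e.g. a consensus built by substituting fixed variants
into the reference) and the substitution list relating them.  Pairs can
be built either by applying a SNP table to taxon A, or by diffing two
equal-length sequences back into SNPs.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

from .io_formats import (
    UNAMBIGUOUS_DNA,
    BedInterval,
    SnpRecord,
    UtrRecord,
    reverse_complement_dna,
)


class CoordinateError(ValueError):
    """Interval outside the genome, or chromosome missing."""


class PairError(ValueError):
    """Inconsistent UTR pair or SNP application failure."""


@dataclass(frozen=True)
class UtrPair:
    """Equal-length orthologous UTRs for taxa A and B plus their SNPs.

    Invariants (checked on construction): sequences have equal length;
    every SNP satisfies ``utr_a[pos] == ref`` and ``utr_b[pos] == alt``;
    and the SNP list covers exactly the positions where both taxa carry
    unambiguous, differing bases.
    """

    gene_id: str
    utr_a: UtrRecord
    utr_b: UtrRecord
    snps: tuple[SnpRecord, ...]

    def __post_init__(self) -> None:
        a, b = self.utr_a.sequence, self.utr_b.sequence
        if len(a) != len(b):
            raise PairError(
                f"gene {self.gene_id!r}: taxon A ({len(a)} nt) and taxon B "
                f"({len(b)} nt) UTRs differ in length"
            )
        snp_positions = set()
        for snp in self.snps:
            if snp.gene_id != self.gene_id:
                raise PairError(f"SNP gene {snp.gene_id!r} != pair gene {self.gene_id!r}")
            if snp.pos >= len(a):
                raise PairError(f"gene {self.gene_id!r}: SNP position {snp.pos} beyond UTR")
            if a[snp.pos] != snp.ref or b[snp.pos] != snp.alt:
                raise PairError(
                    f"gene {self.gene_id!r} pos {snp.pos}: SNP {snp.ref}->{snp.alt} "
                    f"inconsistent with sequences ({a[snp.pos]}/{b[snp.pos]})"
                )
            if snp.pos in snp_positions:
                raise PairError(f"gene {self.gene_id!r}: two SNPs at position {snp.pos}")
            snp_positions.add(snp.pos)
        observed = {
            i
            for i, (x, y) in enumerate(zip(a, b))
            if x != y and x in UNAMBIGUOUS_DNA and y in UNAMBIGUOUS_DNA
        }
        if observed != snp_positions:
            raise PairError(
                f"gene {self.gene_id!r}: SNP list does not match sequence differences "
                f"(missing {sorted(observed - snp_positions)}, "
                f"extra {sorted(snp_positions - observed)})"
            )


class DiffResult(NamedTuple):
    """SNPs between two aligned UTRs plus the count of ambiguity-masked positions."""

    snps: list[SnpRecord]
    n_masked: int


def extract_utr(
    genome: Mapping[str, str], interval: BedInterval, taxon: str = "A"
) -> UtrRecord:
    """Extract a UTR from a genome by BED interval, returned mRNA-sense.

    For minus-strand intervals the extracted slice is reverse-complemented
    so that downstream scanning always sees the mRNA sense strand.
    """
    if interval.chrom not in genome:
        raise CoordinateError(f"chromosome {interval.chrom!r} absent from genome")
    chrom_seq = genome[interval.chrom]
    if not (0 <= interval.start < interval.end <= len(chrom_seq)):
        raise CoordinateError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} outside "
            f"chromosome bounds (length {len(chrom_seq)})"
        )
    seq = chrom_seq[interval.start : interval.end].upper().replace("U", "T")
    if interval.strand == "-":
        seq = reverse_complement_dna(seq)
    return UtrRecord(
        gene_id=interval.name,
        taxon=taxon,
        sequence=seq,
        source_coords=(interval.chrom, interval.start, interval.end, interval.strand),
    )


def apply_snps(
    utr_a: UtrRecord, snps: Iterable[SnpRecord], taxon_b: str = "B"
) -> UtrPair:
    """Substitute a SNP list into taxon A to produce the taxon-B consensus."""
    seq = list(utr_a.sequence)
    seen: set[int] = set()
    ordered = sorted(snps, key=lambda s: s.pos)
    for snp in ordered:
        if snp.gene_id != utr_a.gene_id:
            raise PairError(f"SNP gene {snp.gene_id!r} != UTR gene {utr_a.gene_id!r}")
        if snp.pos >= len(seq):
            raise PairError(
                f"gene {utr_a.gene_id!r}: SNP position {snp.pos} beyond UTR length {len(seq)}"
            )
        if snp.pos in seen:
            raise PairError(f"gene {utr_a.gene_id!r}: two SNPs at position {snp.pos}")
        seen.add(snp.pos)
        if seq[snp.pos] != snp.ref:
            raise PairError(
                f"ref mismatch for gene {utr_a.gene_id!r} at pos {snp.pos}: "
                f"expected {snp.ref!r}, found {seq[snp.pos]!r}"
            )
        seq[snp.pos] = snp.alt
    utr_b = UtrRecord(
        gene_id=utr_a.gene_id,
        taxon=taxon_b,
        sequence="".join(seq),
        source_coords=utr_a.source_coords,
    )
    return UtrPair(utr_a.gene_id, utr_a, utr_b, tuple(ordered))


def diff_utrs(utr_a: UtrRecord, utr_b: UtrRecord) -> DiffResult:
    """Diff two equal-length UTRs into SNPs.

    Positions where either base is ambiguous (non-ACGT) are skipped and
    tallied in ``n_masked``; this mirrors the removal of ambiguous
    consensus positions from an ancient-genome comparison.
    """
    if len(utr_a.sequence) != len(utr_b.sequence):
        raise PairError(
            f"gene {utr_a.gene_id!r}: cannot diff UTRs of unequal length "
            f"({len(utr_a.sequence)} vs {len(utr_b.sequence)})"
        )
    snps: list[SnpRecord] = []
    n_masked = 0
    for i, (x, y) in enumerate(zip(utr_a.sequence, utr_b.sequence)):
        if x == y:
            continue
        if x not in UNAMBIGUOUS_DNA or y not in UNAMBIGUOUS_DNA:
            n_masked += 1
            continue
        snps.append(SnpRecord(gene_id=utr_a.gene_id, pos=i, ref=x, alt=y))
    return DiffResult(snps, n_masked)


def build_pair(utr_a: UtrRecord, utr_b: UtrRecord) -> UtrPair:
    """Pair two UTR records, deriving the SNP list by diffing."""
    if utr_a.gene_id != utr_b.gene_id:
        raise PairError(f"gene ids differ: {utr_a.gene_id!r} vs {utr_b.gene_id!r}")
    diff = diff_utrs(utr_a, utr_b)
    return UtrPair(utr_a.gene_id, utr_a, utr_b, tuple(diff.snps))


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def annotation_percentages(
    n_genes_total: int, n_genes_with_utr: int, n_genes_with_snp: int
) -> tuple[int, int]:
    """Integer percentages of genes with an annotated UTR, and of UTR genes
    carrying at least one SNP (rounded to the nearest percent)."""
    pct_utr = int(round(100.0 * n_genes_with_utr / n_genes_total)) if n_genes_total else 0
    pct_snp = int(round(100.0 * n_genes_with_snp / n_genes_with_utr)) if n_genes_with_utr else 0
    return pct_utr, pct_snp


@dataclass(frozen=True)
class SnpSummary:
    n_genes_total: int | None
    n_genes_with_utr: int
    n_genes_with_snp: int
    total_snps: int
    mean_snps_per_utr: float
    median_snps_per_utr: float
    max_snps_per_utr: int
    pct_genes_with_utr: int | None
    pct_utr_genes_with_snp: int


def summarize_snp_stats(
    pairs: Sequence[UtrPair],
    n_genes_total: int | None = None,
    denominator: str = "genes-with-snp",
) -> SnpSummary:
    """Summarize SNP density over a set of UTR pairs.

    ``denominator`` selects what the mean is taken over: SNP-bearing UTRs
    ("genes-with-snp", default) or all UTRs ("genes-with-utr").  The
    median and maximum are always taken over all pairs.
    """
    if not pairs:
        raise PairError("summarize_snp_stats requires at least one pair")
    if denominator not in ("genes-with-snp", "genes-with-utr"):
        raise ValueError(f"unknown denominator {denominator!r}")
    counts = [len(p.snps) for p in pairs]
    total = sum(counts)
    n_with_snp = sum(1 for c in counts if c > 0)
    n_with_utr = len(pairs)
    denom = n_with_snp if denominator == "genes-with-snp" else n_with_utr
    mean = total / denom if denom else 0.0
    pct_utr: int | None = None
    if n_genes_total is not None:
        pct_utr, _ = annotation_percentages(n_genes_total, n_with_utr, n_with_snp)
    _, pct_snp = annotation_percentages(n_genes_total or n_with_utr, n_with_utr, n_with_snp)
    return SnpSummary(
        n_genes_total=n_genes_total,
        n_genes_with_utr=n_with_utr,
        n_genes_with_snp=n_with_snp,
        total_snps=total,
        mean_snps_per_utr=mean,
        median_snps_per_utr=float(statistics.median(counts)),
        max_snps_per_utr=max(counts),
        pct_genes_with_utr=pct_utr,
        pct_utr_genes_with_snp=pct_snp,
    )
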