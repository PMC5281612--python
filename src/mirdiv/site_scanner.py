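"""Canonical miRNA seed-site detection in 3' UTR sequences.

A target site is recognized purely from the seed region of the mature
miRNA: the reverse complement of positions 2-7 (the 6mer core), possibly
extended by a match to position 8 on the 5' side of the target motif
(m8) and/or a literal adenosine opposite position 1 on the 3' side (A1).
The four canonical site types and their target motifs are

======== =============================== ======
type     target motif (5'->3' on UTR)    length
======== =============================== ======
6mer     revcomp(p2-7)                   6
7mer-m8  revcomp(p2-8)                   7
7mer-A1  revcomp(p2-7) + "A"             7
8mer     revcomp(p2-8) + "A"             8
======== =============================== ======

The A1 adenosine is a literal target "A" regardless of the identity of
miRNA position 1.  At each 6mer-core occurrence the single largest
applicable type wins (8mer > 7mer-m8 > 7mer-A1 > 6mer).  Sites whose
motif span contains an ambiguous base are discarded, and a left-to-right
overlap filter keeps only sites disjoint from previously accepted sites
of the same miRNA (5'-most site wins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import UNAMBIGUOUS_DNA, MatureMiRNA, UtrRecord, reverse_complement_dna

#: site types in decreasing priority (largest/strongest first)
SITE_PRIORITY: tuple[str, ...] = ("8mer", "7mer-m8", "7mer-A1", "6mer")

SITE_LENGTH = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


@dataclass(frozen=True)
class SeedSite:
    """One predicted seed-match site in one taxon's UTR.

    ``start``/``end`` are 0-based half-open offsets of the full matched
    motif (including the m8 and/or A1 positions) within the UTR.
    """

    gene_id: str
    mirna_name: str
    site_type: str
    start: int
    end: int
    taxon: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_LENGTH:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != SITE_LENGTH[self.site_type]:
            raise ValueError(
                f"{self.site_type} span [{self.start},{self.end}) has wrong length"
            )

    @property
    def core_start(self) -> int:
        """Start of the 6mer seed core within the UTR."""
        return self.start + 1 if self.site_type in ("8mer", "7mer-m8") else self.start


def target_motifs(mirna: MatureMiRNA) -> dict[str, str]:
    """DNA target motifs (5'->3' on the UTR) for the four site types."""
    core = reverse_complement_dna(mirna.seed6.replace("U", "T"))
    m8 = reverse_complement_dna(mirna.sequence[1:8].replace("U", "T"))
    return {"6mer": core, "7mer-m8": m8, "7mer-A1": core + "A", "8mer": m8 + "A"}


def find_seed_sites(
    utr: UtrRecord,
    mirna: MatureMiRNA,
    overlap_filter: bool = True,
    exclude_first: int = 0,
) -> list[SeedSite]:
    """All canonical seed sites for one miRNA in one UTR.

    Every occurrence of the 6mer core is located (overlapping occurrences
    included); each is assigned its single largest applicable site type by
    testing the base 5' of the core (m8 match) and the base 3' of the core
    (target A).  Sites spanning an ambiguous base are discarded.  With
    ``overlap_filter`` (the default) a left-to-right scan then drops any
    site overlapping a previously accepted site of the same miRNA.

    ``exclude_first`` optionally suppresses sites starting within the
    first N nt of the UTR (off by default; some target predictors exclude
    a short region just downstream of the stop codon).
    """
    seq = utr.sequence
    motifs = target_motifs(mirna)
    core = motifs["6mer"]
    m8_base = motifs["7mer-m8"][0]
    candidates: list[SeedSite] = []
    i = seq.find(core)
    while i != -1:
        has_m8 = i > 0 and seq[i - 1] == m8_base
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, end = "8mer", i - 1, i + 7
        elif has_m8:
            site_type, start, end = "7mer-m8", i - 1, i + 6
        elif has_a1:
            site_type, start, end = "7mer-A1", i, i + 7
        else:
            site_type, start, end = "6mer", i, i + 6
        if start >= exclude_first and set(seq[start:end]) <= UNAMBIGUOUS_DNA:
            candidates.append(
                SeedSite(utr.gene_id, mirna.name, site_type, start, end, utr.taxon)
            )
        i = seq.find(core, i + 1)
    candidates.sort(key=lambda s: (s.start, s.core_start))
    if not overlap_filter:
        return candidates
    accepted: list[SeedSite] = []
    last_end = -1
    for site in candidates:
        if site.start >= last_end:
            accepted.append(site)
            last_end = site.end
    return accepted


def scan_all(
    utrs: Iterable[UtrRecord],
    mirnas: Iterable[MatureMiRNA],
    exclude_first: int = 0,
) -> list[SeedSite]:
    """Seed sites over the full UTR x miRNA cross product.

    Output order is deterministic: (gene_id, miRNA name, start).
    """
    sites: list[SeedSite] = []
    for utr in sorted(utrs, key=lambda u: u.gene_id):
        for mirna in sorted(mirnas, key=lambda m: m.name):
            sites.extend(find_seed_sites(utr, mirna, exclude_first=exclude_first))
    return sites


def sites_to_frame(
    sites: Sequence[SeedSite], utr_lookup: dict[tuple[str, str], UtrRecord] | None = None
) -> pd.DataFrame:
    """Tabulate sites; with ``utr_lookup`` (keyed by (gene_id, taxon)) the
    matched motif substring is included."""
    rows = []
    for s in sites:
        row = {
            "gene_id": s.gene_id,
            "taxon": s.taxon,
            "mirna": s.mirna_name,
            "site_type": s.site_type,
            "start": s.start,
            "end": s.end,
        }
        if utr_lookup is not None:
            row["motif"] = utr_lookup[(s.gene_id, s.taxon)].sequence[s.start : s.end]
        rows.append(row)
    cols = ["gene_id", "taxon", "mirna", "site_type", "start", "end"]
    if utr_lookup is not None:
        cols.append("motif")
    return pd.DataFrame(rows, columns=cols)
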