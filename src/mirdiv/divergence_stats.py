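"""Transition/transversion statistics over SNP sets.

Substitutions are split into the two classical mutational classes:
transitions exchange a purine for a purine or a pyrimidine for a
pyrimidine (A<->G, C<->T); every other exchange is a transversion
(A<->C, A<->T, C<->G, G<->T).  The ti/tv ratio of a SNP set is a cheap
diagnostic: mammalian genomes sit near 2.1-2.2 genome-wide, while
ancient-DNA deamination damage (C->T / G->A) inflates it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .io_formats import SnpRecord

TRANSITION = "transition"
TRANSVERSION = "transversion"

_TRANSITION_PAIRS = (frozenset("AG"), frozenset("CT"))


class MutationClassError(ValueError):
    """Raised for alleles that cannot be classified (non-ACGT or identical)."""


def classify_mutation(ref: str, alt: str) -> str:
    """Classify a single-base substitution as transition or transversion.

    Both alleles must be unambiguous DNA bases and must differ.
    """
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise MutationClassError(f"alleles must be single A/C/G/T bases, got {ref!r}->{alt!r}")
    if ref == alt:
        raise MutationClassError(f"identical alleles {ref!r}->{alt!r} are not a substitution")
    return TRANSITION if frozenset((ref, alt)) in _TRANSITION_PAIRS else TRANSVERSION


@dataclass(frozen=True)
class TitvReport:
    """Counts and ratio of transitions vs transversions for one SNP subset.

    ``ratio`` is ``None`` when no transversions were observed (undefined);
    the counts are still reported.
    """

    n_transitions: int
    n_transversions: int
    ratio: float | None
    subset_label: str


def titv_ratio(
    snps: Iterable["SnpRecord"],
    site_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    subset_label: str = "all_3utr_snps",
) -> TitvReport:
    """Compute the ti/tv ratio for a SNP set, optionally restricted to sites.

    Parameters
    ----------
    snps
        SNP records carrying ``gene_id``, ``pos`` (0-based), ``ref``, ``alt``.
    site_intervals
        Optional per-gene lists of half-open ``(start, end)`` intervals
        (e.g. predicted binding-site spans).  When given, only SNPs whose
        position falls inside an interval of their gene are counted.
    subset_label
        Free-text label carried into the report.

    A SNP is counted once even if it appears in several records or is
    overlapped by binding sites of several miRNAs (position-level set).
    """
    seen: set[tuple[str, int, str, str]] = set()
    n_ti = n_tv = 0
    for snp in snps:
        key = (snp.gene_id, snp.pos, snp.ref, snp.alt)
        if key in seen:
            continue
        seen.add(key)
        if site_intervals is not None:
            intervals = site_intervals.get(snp.gene_id, ())
            if not any(start <= snp.pos < end for start, end in intervals):
                continue
        if classify_mutation(snp.ref, snp.alt) == TRANSITION:
            n_ti += 1
        else:
            n_tv += 1
    ratio = (n_ti / n_tv) if n_tv > 0 else None
    return TitvReport(n_ti, n_tv, ratio, subset_label)


def titv_to_frame(reports: Iterable[TitvReport]) -> pd.DataFrame:
    """Tabulate ti/tv reports; an undefined ratio becomes the string 'NA'."""
    rows = [
        {
            "subset_label": r.subset_label,
            "n_transitions": r.n_transitions,
            "n_transversions": r.n_transversions,
            "titv_ratio": "NA" if r.ratio is None else round(r.ratio, 6),
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=["subset_label", "n_transitions", "n_transversions", "titv_ratio"])
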