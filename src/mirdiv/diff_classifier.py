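"""Cross-taxon matching of binding sites and gain/loss classification.

For each (gene, miRNA) the site sets of the two taxa are matched
one-to-one by identical start coordinate AND site type (orthologous UTRs
have equal length, so coordinates are directly comparable).  The
difference between the two sets is then classified:

* ``gain``     - site(s) present only in taxon A, none shared;
* ``loss``     - site(s) present only in taxon B, none shared;
* ``increase`` - taxon A has extra site(s) on top of a shared one;
* ``decrease`` - taxon B has extra site(s) on top of a shared one.

A (gene, miRNA) with exclusive sites in both taxa and nothing shared
records both gain and loss.  A SNP that changes the site *type* at a
fixed position (e.g. 7mer-A1 -> 8mer) leaves one unmatched site in each
taxon; such pairs are flagged ``type_shift`` so downstream consumers can
distinguish them from genuine independent gains/losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .context_scoring import ScoredSite

GAIN = "gain"
LOSS = "loss"
INCREASE = "increase"
DECREASE = "decrease"
CATEGORIES: tuple[str, ...] = (GAIN, LOSS, INCREASE, DECREASE)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one-to-one site matching between taxa A and B."""

    common: tuple[tuple[ScoredSite, ScoredSite], ...]
    only_a: tuple[ScoredSite, ...]
    only_b: tuple[ScoredSite, ...]
    type_shifts: tuple[tuple[ScoredSite, ScoredSite], ...]


def match_sites(
    sites_a: Sequence[ScoredSite], sites_b: Sequence[ScoredSite]
) -> MatchResult:
    """Match sites between taxa by (start, site_type).

    Both lists must belong to the same (gene, miRNA).  Matching is
    one-to-one by construction: after overlap filtering a taxon cannot
    hold two sites with the same start and type.
    """
    def index(sites: Sequence[ScoredSite]) -> dict[tuple[int, str], ScoredSite]:
        idx: dict[tuple[int, str], ScoredSite] = {}
        for s in sites:
            key = (s.start, s.site_type)
            if key in idx:
                raise ValueError(f"duplicate site {key} in one taxon for {s.gene_id}/{s.mirna_name}")
            idx[key] = s
        return idx

    idx_a, idx_b = index(sites_a), index(sites_b)
    common_keys = sorted(set(idx_a) & set(idx_b))
    common = tuple((idx_a[k], idx_b[k]) for k in common_keys)
    only_a = tuple(idx_a[k] for k in sorted(set(idx_a) - set(idx_b)))
    only_b = tuple(idx_b[k] for k in sorted(set(idx_b) - set(idx_a)))
    starts_b = {s.start: s for s in only_b}
    type_shifts = tuple(
        (s, starts_b[s.start]) for s in only_a if s.start in starts_b
    )
    return MatchResult(common, only_a, only_b, type_shifts)


def classify_mirna_events(match: MatchResult) -> frozenset[str]:
    """Event categories implied by one matched (gene, miRNA) comparison."""
    cats: set[str] = set()
    if match.common:
        if match.only_a:
            cats.add(INCREASE)
        if match.only_b:
            cats.add(DECREASE)
    else:
        if match.only_a:
            cats.add(GAIN)
        if match.only_b:
            cats.add(LOSS)
    return frozenset(cats)


@dataclass(frozen=True)
class GeneMirnaComparison:
    """Matched site sets and event classification for one (gene, miRNA)."""

    gene_id: str
    mirna_name: str
    sites_a: tuple[ScoredSite, ...]
    sites_b: tuple[ScoredSite, ...]
    match: MatchResult
    categories: frozenset[str]

    @property
    def n_common(self) -> int:
        return len(self.match.common)

    @property
    def n_only_a(self) -> int:
        return len(self.match.only_a)

    @property
    def n_only_b(self) -> int:
        return len(self.match.only_b)

    @property
    def type_shift(self) -> bool:
        return bool(self.match.type_shifts)

    @property
    def gain_loss_pair(self) -> bool:
        """Exclusive sites in both taxa with nothing shared (same miRNA)."""
        return GAIN in self.categories and LOSS in self.categories


def compare_gene_mirna(
    gene_id: str,
    mirna_name: str,
    sites_a: Sequence[ScoredSite],
    sites_b: Sequence[ScoredSite],
) -> GeneMirnaComparison:
    for s in (*sites_a, *sites_b):
        if s.gene_id != gene_id or s.mirna_name != mirna_name:
            raise ValueError(
                f"site ({s.gene_id}, {s.mirna_name}) out of place in comparison "
                f"({gene_id}, {mirna_name})"
            )
    match = match_sites(sites_a, sites_b)
    return GeneMirnaComparison(
        gene_id=gene_id,
        mirna_name=mirna_name,
        sites_a=tuple(sites_a),
        sites_b=tuple(sites_b),
        match=match,
        categories=classify_mirna_events(match),
    )


@dataclass(frozen=True)
class GeneEventSummary:
    """Per-gene event tallies across miRNAs.

    Category counts are numbers of miRNAs with that event.  ``psn`` and
    ``csn`` count *distinct site positions* (start coordinates): a
    position shared by several miRNAs is counted once; a matched position
    contributes to ``csn``, an unmatched one to ``psn``.
    """

    gene_id: str
    n_gain: int
    n_loss: int
    n_increase: int
    n_decrease: int
    mirnas_by_category: Mapping[str, tuple[str, ...]]
    psn: int
    csn: int

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(
            c
            for c, n in zip(
                CATEGORIES, (self.n_gain, self.n_loss, self.n_increase, self.n_decrease)
            )
            if n > 0
        )


def summarize_gene_events(comparisons: Sequence[GeneMirnaComparison]) -> GeneEventSummary:
    """Aggregate one gene's comparisons into an event summary."""
    genes = {c.gene_id for c in comparisons}
    if len(genes) != 1:
        raise ValueError(f"comparisons span multiple genes: {sorted(genes)}")
    gene_id = genes.pop()
    mirnas: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    matched_positions: set[int] = set()
    unmatched_positions: set[int] = set()
    for comp in comparisons:
        for cat in comp.categories:
            mirnas[cat].append(comp.mirna_name)
        for a, _ in comp.match.common:
            matched_positions.add(a.start)
        for s in (*comp.match.only_a, *comp.match.only_b):
            unmatched_positions.add(s.start)
    by_cat = {c: tuple(sorted(names)) for c, names in mirnas.items()}
    return GeneEventSummary(
        gene_id=gene_id,
        n_gain=len(by_cat[GAIN]),
        n_loss=len(by_cat[LOSS]),
        n_increase=len(by_cat[INCREASE]),
        n_decrease=len(by_cat[DECREASE]),
        mirnas_by_category=by_cat,
        psn=len(unmatched_positions),
        csn=len(matched_positions),
    )


def venn_counts(summaries: Iterable[GeneEventSummary]) -> dict[str, int]:
    """Gene counts per event category and every category intersection.

    Keys are '&'-joined category names in canonical order (gain, loss,
    increase, decrease); values are intersection cardinalities, suitable
    for populating a 4-set Venn diagram.
    """
    sets: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for s in summaries:
        for c in s.categories:
            sets[c].add(s.gene_id)
    counts: dict[str, int] = {}
    n = len(CATEGORIES)
    for mask in range(1, 2 ** n):
        combo = [CATEGORIES[i] for i in range(n) if mask >> i & 1]
        genes = set.intersection(*(sets[c] for c in combo))
        counts["&".join(combo)] = len(genes)
    return counts


def events_to_frame(comparisons: Sequence[GeneMirnaComparison]) -> pd.DataFrame:
    """One row per (gene, miRNA) with categories and flags."""
    rows = []
    for c in comparisons:
        flags = []
        if c.type_shift:
            flags.append("type_shift")
        if c.gain_loss_pair:
            flags.append("gain_loss_pair")
        rows.append(
            {
                "gene_id": c.gene_id,
                "mirna": c.mirna_name,
                "category": ",".join(sorted(c.categories)) or "shared_only",
                "n_a": len(c.sites_a),
                "n_b": len(c.sites_b),
                "n_common": c.n_common,
                "flags": ",".join(flags),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "mirna", "category", "n_a", "n_b", "n_common", "flags"]
    )


def venn_to_frame(counts: Mapping[str, int]) -> pd.DataFrame:
    rows = [{"region": k, "n_genes": v} for k, v in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["region", "n_genes"])


def gene_summaries_to_frame(summaries: Sequence[GeneEventSummary]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": s.gene_id,
            "n_gain": s.n_gain,
            "n_loss": s.n_loss,
            "n_increase": s.n_increase,
            "n_decrease": s.n_decrease,
            "psn": s.psn,
            "csn": s.csn,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "n_gain", "n_loss", "n_increase", "n_decrease", "psn", "csn"],
    )
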