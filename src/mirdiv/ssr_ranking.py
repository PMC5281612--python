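"""The SSr (Score Site ratio) gene-ranking statistic and pathway sums.

For one gene with n predicted binding sites (union over both taxa,
matched sites counted once),

    SSr = (sum_{i=1..n} score_i) * psn / csn

where psn is the number of binding-site positions polymorphic between
the taxa and csn the number common to both.  Because context scores are
negative, genes with many impactful polymorphic sites and few shared
ones get the most negative SSr and rank first.  Genes whose sites are
all polymorphic (csn = 0) would leave the ratio undefined; they are
scored with csn = 1 and flagged ``csn_pseudo`` so the ranking stays
total and the substitution auditable.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diff_classifier import GeneMirnaComparison, summarize_gene_events


def compute_ssr(sum_score: float, psn: int, csn: int) -> float:
    """SSr = sum_score * psn / csn, with the csn = 0 pseudo-count rule.

    psn = 0 (no polymorphic sites) gives 0; csn = 0 with psn > 0 uses a
    pseudo-count of 1 (see :func:`is_csn_pseudo`).
    """
    if psn < 0 or csn < 0:
        raise ValueError(f"negative site counts psn={psn}, csn={csn}")
    if psn == 0:
        return 0.0
    return sum_score * psn / (csn if csn > 0 else 1)


def is_csn_pseudo(psn: int, csn: int) -> bool:
    """True when the csn = 0 -> 1 substitution was applied."""
    return csn == 0 and psn > 0


@dataclass
class GeneSsrResult:
    """Per-gene SSr with its ingredients; ``rank`` is set by rank_genes."""

    gene_id: str
    n_sites: int
    sum_score: float
    psn: int
    csn: int
    csn_pseudo: bool
    ssr: float
    rank: int | None = None


def gene_ssr_results(
    comparisons: Iterable[GeneMirnaComparison],
) -> list[GeneSsrResult]:
    """Build per-gene SSr results from (gene, miRNA) comparisons.

    The score sum runs over the union of sites in both taxa: matched
    sites are counted once using the taxon-A score; each unmatched site
    contributes the score computed in the taxon where it exists.
    """
    by_gene: dict[str, list[GeneMirnaComparison]] = defaultdict(list)
    for comp in comparisons:
        by_gene[comp.gene_id].append(comp)
    results: list[GeneSsrResult] = []
    for gene_id in sorted(by_gene):
        comps = by_gene[gene_id]
        summary = summarize_gene_events(comps)
        n_sites = 0
        sum_score = 0.0
        for comp in comps:
            n_sites += comp.n_common + comp.n_only_a + comp.n_only_b
            sum_score += sum(a.context_score for a, _ in comp.match.common)
            sum_score += sum(s.context_score for s in comp.match.only_a)
            sum_score += sum(s.context_score for s in comp.match.only_b)
        results.append(
            GeneSsrResult(
                gene_id=gene_id,
                n_sites=n_sites,
                sum_score=sum_score,
                psn=summary.psn,
                csn=summary.csn,
                csn_pseudo=is_csn_pseudo(summary.psn, summary.csn),
                ssr=compute_ssr(sum_score, summary.psn, summary.csn),
            )
        )
    return results


def rank_genes(results: Sequence[GeneSsrResult]) -> list[GeneSsrResult]:
    """Rank ascending by SSr (most negative = rank 1), ties by gene_id."""
    ranked = sorted(results, key=lambda r: (r.ssr, r.gene_id))
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked


@dataclass(frozen=True)
class PathwayScore:
    """Sum of member genes' SSr values for one gene set."""

    pathway_id: str
    member_genes: tuple[str, ...]
    summed_ssr: float
    empty: bool


def pathway_scores(
    results: Sequence[GeneSsrResult],
    gene_pathways: Iterable[tuple[str, str]],
) -> tuple[list[PathwayScore], int]:
    """Sum SSr over supplied gene sets.

    ``gene_pathways`` is (gene_id, pathway_id) pairs; a gene may belong
    to several pathways and contributes to each.  Mapped genes absent
    from the results are skipped; their count is returned for warning.
    Pathways with no present members score 0 and are flagged empty.
    """
    ssr_by_gene = {r.gene_id: r.ssr for r in results}
    members: dict[str, list[str]] = defaultdict(list)
    n_missing = 0
    for gene_id, pathway_id in gene_pathways:
        if gene_id in ssr_by_gene:
            members[pathway_id].append(gene_id)
        else:
            members[pathway_id]  # pathway still reported (empty if nothing maps)
            n_missing += 1
    scores = [
        PathwayScore(
            pathway_id=pid,
            member_genes=tuple(sorted(genes)),
            summed_ssr=sum(ssr_by_gene[g] for g in genes),
            empty=not genes,
        )
        for pid, genes in sorted(members.items())
    ]
    return scores, n_missing


def ranking_to_frame(results: Sequence[GeneSsrResult]) -> pd.DataFrame:
    rows = [
        {
            "rank": r.rank,
            "gene_id": r.gene_id,
            "n_sites": r.n_sites,
            "sum_score": r.sum_score,
            "psn": r.psn,
            "csn": r.csn,
            "csn_pseudo": int(r.csn_pseudo),
            "ssr": r.ssr,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["rank", "gene_id", "n_sites", "sum_score", "psn", "csn", "csn_pseudo", "ssr"],
    )


def pathways_to_frame(scores: Sequence[PathwayScore]) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": p.pathway_id,
            "n_members": len(p.member_genes),
            "member_genes": ",".join(p.member_genes),
            "summed_ssr": p.summed_ssr,
            "empty": int(p.empty),
        }
        for p in scores
    ]
    return pd.DataFrame(
        rows, columns=["pathway_id", "n_members", "member_genes", "summed_ssr", "empty"]
    )
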