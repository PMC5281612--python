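"""End-to-end orchestration: pair -> scan -> score -> classify -> rank -> ti/tv.

:func:`run_pipeline` is the in-memory workhorse operating on UTR pairs
and miRNA objects; :func:`run_all` wraps it with file I/O, stage
logging, TSV outputs and a JSON manifest of input/output digests so a
run can be reproduced and verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .context_scoring import (
    ContextModelConfig,
    ScoredSite,
    harmonize_discards,
    score_sites,
    scored_to_frame,
)
from .diff_classifier import (
    GeneEventSummary,
    GeneMirnaComparison,
    compare_gene_mirna,
    events_to_frame,
    gene_summaries_to_frame,
    summarize_gene_events,
    venn_counts,
    venn_to_frame,
)
from .divergence_stats import TitvReport, titv_ratio, titv_to_frame
from .io_formats import (
    FormatError,
    MatureMiRNA,
    read_mirna_table,
    read_pathway_map,
    read_snp_table,
    read_utr_fasta,
    write_results,
)
from .site_scanner import SeedSite, find_seed_sites, sites_to_frame
from .ssr_ranking import (
    GeneSsrResult,
    PathwayScore,
    gene_ssr_results,
    pathway_scores,
    pathways_to_frame,
    rank_genes,
    ranking_to_frame,
)
from .utr_builder import UtrPair, apply_snps, build_pair, summarize_snp_stats

logger = logging.getLogger("mirdiv")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    """All intermediate and final products of one run."""

    pairs: list[UtrPair]
    mirnas: list[MatureMiRNA]
    sites: dict[str, list[SeedSite]]            # taxon label -> raw sites
    scored: dict[str, list[ScoredSite]]         # taxon label -> scored, harmonized
    discarded_keys: set[tuple[str, str, int, str]]
    comparisons: list[GeneMirnaComparison]
    summaries: list[GeneEventSummary]
    venn: dict[str, int]
    ranking: list[GeneSsrResult]
    pathways: list[PathwayScore] | None
    n_pathway_genes_missing: int
    titv_all: TitvReport
    titv_sites: TitvReport
    snp_summary: Any

    def tables(self) -> dict[str, pd.DataFrame]:
        utr_lookup = {}
        for p in self.pairs:
            utr_lookup[(p.gene_id, p.utr_a.taxon)] = p.utr_a
            utr_lookup[(p.gene_id, p.utr_b.taxon)] = p.utr_b
        all_sites = [s for sites in self.sites.values() for s in sites]
        all_scored = [s for scored in self.scored.values() for s in scored]
        tables = {
            "sites": sites_to_frame(all_sites, utr_lookup),
            "scored_sites": scored_to_frame(all_scored),
            "events": events_to_frame(self.comparisons),
            "gene_summary": gene_summaries_to_frame(self.summaries),
            "ranking": ranking_to_frame(self.ranking),
            "venn": venn_to_frame(self.venn),
            "titv": titv_to_frame([self.titv_all, self.titv_sites]),
            "snp_summary": pd.DataFrame([vars(self.snp_summary)]),
        }
        if self.pathways is not None:
            tables["pathway_scores"] = pathways_to_frame(self.pathways)
        return tables


def run_pipeline(
    pairs: Sequence[UtrPair],
    mirnas: Sequence[MatureMiRNA],
    scoring_config: ContextModelConfig | None = None,
    pathway_map: Sequence[tuple[str, str]] | None = None,
    n_genes_total: int | None = None,
    exclude_first: int = 0,
) -> PipelineResult:
    """Run scan -> score -> classify -> rank -> ti/tv on built UTR pairs."""
    if not pairs:
        raise PipelineError("pipeline requires at least one UTR pair")
    if not mirnas:
        raise PipelineError("pipeline requires a non-empty miRNA table")
    config = scoring_config or ContextModelConfig()
    taxon_a = pairs[0].utr_a.taxon
    taxon_b = pairs[0].utr_b.taxon

    sites: dict[str, list[SeedSite]] = {taxon_a: [], taxon_b: []}
    scored: dict[str, list[ScoredSite]] = {taxon_a: [], taxon_b: []}
    discarded_keys: set[tuple[str, str, int, str]] = set()
    comparisons: list[GeneMirnaComparison] = []
    mirnas_sorted = sorted(mirnas, key=lambda m: m.name)
    for pair in sorted(pairs, key=lambda p: p.gene_id):
        for mirna in mirnas_sorted:
            raw_a = find_seed_sites(pair.utr_a, mirna, exclude_first=exclude_first)
            raw_b = find_seed_sites(pair.utr_b, mirna, exclude_first=exclude_first)
            if not raw_a and not raw_b:
                continue
            sites[taxon_a].extend(raw_a)
            sites[taxon_b].extend(raw_b)
            scored_a, disc_a = score_sites(pair.utr_a, mirna, raw_a, config)
            scored_b, disc_b = score_sites(pair.utr_b, mirna, raw_b, config)
            kept_a, kept_b, keys = harmonize_discards(scored_a, scored_b, disc_a, disc_b)
            discarded_keys |= keys
            scored[taxon_a].extend(kept_a)
            scored[taxon_b].extend(kept_b)
            if kept_a or kept_b:
                comparisons.append(
                    compare_gene_mirna(pair.gene_id, mirna.name, kept_a, kept_b)
                )

    by_gene: dict[str, list[GeneMirnaComparison]] = defaultdict(list)
    for comp in comparisons:
        by_gene[comp.gene_id].append(comp)
    summaries = [summarize_gene_events(by_gene[g]) for g in sorted(by_gene)]
    venn = venn_counts(summaries)
    ranking = rank_genes(gene_ssr_results(comparisons))

    pathways = None
    n_missing = 0
    if pathway_map is not None:
        pathways, n_missing = pathway_scores(ranking, pathway_map)

    all_snps = [s for p in pairs for s in p.snps]
    intervals: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for taxon_sites in scored.values():
        for s in taxon_sites:
            intervals[s.gene_id].append((s.start, s.end))
    titv_all = titv_ratio(all_snps, subset_label="all_3utr_snps")
    titv_sites = titv_ratio(all_snps, site_intervals=intervals, subset_label="binding_site_snps")
    snp_summary = summarize_snp_stats(pairs, n_genes_total=n_genes_total)

    return PipelineResult(
        pairs=list(pairs),
        mirnas=list(mirnas),
        sites=sites,
        scored=scored,
        discarded_keys=discarded_keys,
        comparisons=comparisons,
        summaries=summaries,
        venn=venn,
        ranking=ranking,
        pathways=pathways,
        n_pathway_genes_missing=n_missing,
        titv_all=titv_all,
        titv_sites=titv_sites,
        snp_summary=snp_summary,
    )


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_pairs(
    utrs_a_path: str | Path,
    utrs_b_path: str | Path | None = None,
    snps_path: str | Path | None = None,
) -> list[UtrPair]:
    """Build UTR pairs from taxon-A FASTA plus either a taxon-B FASTA or
    a SNP table applied to taxon A."""
    utrs_a = read_utr_fasta(utrs_a_path, taxon="A")
    if (utrs_b_path is None) == (snps_path is None):
        raise PipelineError("provide exactly one of: taxon-B FASTA, SNP table")
    if utrs_b_path is not None:
        b_by_gene = {u.gene_id: u for u in read_utr_fasta(utrs_b_path, taxon="B")}
        missing = [u.gene_id for u in utrs_a if u.gene_id not in b_by_gene]
        if missing:
            raise PipelineError(f"taxon-B FASTA lacks genes: {missing[:5]}...")
        return [build_pair(u, b_by_gene[u.gene_id]) for u in utrs_a]
    snps_by_gene: dict[str, list] = defaultdict(list)
    for s in read_snp_table(snps_path):
        snps_by_gene[s.gene_id].append(s)
    return [apply_snps(u, snps_by_gene.get(u.gene_id, ())) for u in utrs_a]


def run_all(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Run the whole workflow from a config mapping or YAML path.

    Recognized config keys: ``utrs_a`` (FASTA, required), one of
    ``utrs_b`` (FASTA) or ``snps`` (TSV); ``mirnas`` (TSV/FASTA,
    required); optional ``scoring`` (YAML path or inline mapping),
    ``pathways`` (TSV), ``total_genes`` (int), ``exclude_first`` (int).
    Writes all stage outputs plus ``manifest.json`` under ``out_dir``.
    """
    if isinstance(config, (str, Path)):
        config_path = Path(config)
        with open(config_path) as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    inputs: dict[str, str] = {}

    def stage(name: str):
        logger.info("stage %s", name)

    try:
        stage("read-inputs")
        for key in ("utrs_a", "utrs_b", "snps", "mirnas", "pathways"):
            if config.get(key):
                inputs[key] = _sha256(Path(config[key]))
        mirnas = read_mirna_table(config["mirnas"])
        if not mirnas:
            raise PipelineError("empty miRNA table")
        scoring = config.get("scoring")
        if isinstance(scoring, (str, Path)):
            scoring_config = ContextModelConfig.from_yaml(scoring)
        elif isinstance(scoring, Mapping):
            scoring_config = ContextModelConfig(**scoring)
        else:
            scoring_config = ContextModelConfig()
        pathway_map = read_pathway_map(config["pathways"]) if config.get("pathways") else None

        stage("build-pairs")
        pairs = load_pairs(
            config["utrs_a"], config.get("utrs_b"), config.get("snps")
        )

        stage("scan-score-classify-rank")
        result = run_pipeline(
            pairs,
            mirnas,
            scoring_config=scoring_config,
            pathway_map=pathway_map,
            n_genes_total=config.get("total_genes"),
            exclude_first=int(config.get("exclude_first", 0)),
        )

        stage("write-outputs")
        tables = result.tables()
        written = write_results(tables, out_dir)
    except (FormatError, PipelineError, KeyError) as exc:
        raise PipelineError(f"pipeline failed: {exc}") from exc

    manifest = {
        "tool": "mirdiv",
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": inputs,
        "row_counts": {name: int(len(df)) for name, df in tables.items()},
        "outputs": {name: _sha256(path) for name, path in sorted(written.items())},
        "n_genes_with_sites": len(result.summaries),
        "n_ambiguity_discarded_sites": len(result.discarded_keys),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %d genes with sites", len(result.summaries))
    return out_dir
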