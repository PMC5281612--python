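"""Context-style efficacy scoring of seed sites.

Each accepted site receives a score on a repression log-ratio scale
(more negative = stronger predicted repression) built from four additive
features:

* ``f_type`` - a per-site-type baseline (8mer strongest, 6mer weakest);
* ``f_au``   - local AU content of the flanking sequence (AU-rich
  flanks increase accessibility);
* ``f_3p``   - 3' supplementary pairing of miRNA positions 13-16 with
  the target region opposite them;
* ``f_pos``  - proximity of the site to either UTR end (sites near the
  ends of long UTRs are more effective than sites in the middle).

All coefficients live in :class:`ContextModelConfig`.  The shipped
defaults preserve the canonical ordering and negative scale of published
context scores but are deliberately transparent linear weights, not a
re-fit of any external regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .io_formats import UNAMBIGUOUS_DNA, MatureMiRNA, UtrRecord
from .site_scanner import SeedSite

#: default per-type baselines (score units; repression log-ratio scale)
DEFAULT_BASELINES = {"8mer": -0.310, "7mer-m8": -0.161, "7mer-A1": -0.099, "6mer": -0.015}

#: Watson-Crick partner of a DNA target base on the (RNA) miRNA side
_DNA_TO_RNA_PARTNER = {"A": "U", "C": "G", "G": "C", "T": "A"}


class IntegrityError(ValueError):
    """Site inconsistent with the UTR/miRNA it claims to come from."""


@dataclass(frozen=True)
class ContextModelConfig:
    """Coefficients of the four-feature linear scoring model.

    Attributes
    ----------
    baselines
        Per-site-type intercepts, score units.
    w_au
        Weight on the AU fraction of the flanks (negative: AU-rich flanks
        strengthen repression).
    au_window
        Flank width, nt, taken on each side of the site (truncated at the
        UTR ends; the AU denominator is the actual flank length).
    w_3p
        Weight on the 3' supplementary pairing fraction m/4.
    w_pos
        Weight on the positional term max(0, 1 - d/pos_halfmax), where d
        is the distance from the site's nearest edge to the nearest UTR end.
    pos_halfmax
        Distance, nt, at which the positional effect decays to zero.
    """

    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    w_au: float = -0.10
    au_window: int = 30
    w_3p: float = -0.05
    w_pos: float = -0.05
    pos_halfmax: int = 1500

    def __post_init__(self) -> None:
        if self.au_window <= 0:
            raise ValueError("au_window must be positive")
        if self.pos_halfmax <= 0:
            raise ValueError("pos_halfmax must be positive")
        missing = set(DEFAULT_BASELINES) - set(self.baselines)
        if missing:
            raise ValueError(f"baselines missing site types: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ContextModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "baselines": dict(self.baselines),
            "w_au": self.w_au,
            "au_window": self.au_window,
            "w_3p": self.w_3p,
            "w_pos": self.w_pos,
            "pos_halfmax": self.pos_halfmax,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class ScoredSite:
    """A seed site plus its four feature contributions and total score."""

    gene_id: str
    mirna_name: str
    site_type: str
    start: int
    end: int
    taxon: str
    f_type: float
    f_au: float
    f_3p: float
    f_pos: float
    context_score: float

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Cross-taxon site identity: (gene, miRNA, start, type)."""
        return (self.gene_id, self.mirna_name, self.start, self.site_type)


def _three_prime_pairing(seq: str, core_start: int, mirna: MatureMiRNA) -> int | None:
    """Longest contiguous Watson-Crick run between miRNA positions 13-16
    and the target window opposite them.

    The target window is the 4 nt immediately 5' of the region pairing
    miRNA position 12 — i.e. target indices core_start-9 .. core_start-6,
    with miRNA position 13 opposite index core_start-6 and position 16
    opposite core_start-9.  Truncated windows use whatever target
    sequence exists.  Returns ``None`` when an available target base is
    ambiguous (the caller discards the site), else the run length m in 0..4.
    """
    region = mirna.three_prime_region
    pairs: list[bool] = []
    for k in range(4):  # k=0 -> miRNA position 13
        t = core_start - 6 - k
        if not (0 <= t < len(seq)):
            pairs.append(False)
            continue
        base = seq[t]
        if base not in UNAMBIGUOUS_DNA:
            return None
        if region is None:
            pairs.append(False)
        else:
            pairs.append(region[k] == _DNA_TO_RNA_PARTNER[base])
    best = run = 0
    for hit in pairs:
        run = run + 1 if hit else 0
        best = max(best, run)
    return best


def score_site(
    utr: UtrRecord,
    mirna: MatureMiRNA,
    site: SeedSite,
    config: ContextModelConfig | None = None,
) -> ScoredSite | None:
    """Score one site; returns ``None`` when the site is discarded because
    its 3'-pairing target window contains an ambiguous base."""
    config = config or ContextModelConfig()
    seq = utr.sequence
    if site.gene_id != utr.gene_id or site.mirna_name != mirna.name:
        raise IntegrityError(
            f"site ({site.gene_id}, {site.mirna_name}) does not belong to "
            f"UTR {utr.gene_id!r} / miRNA {mirna.name!r}"
        )
    if not (0 <= site.start < site.end <= len(seq)):
        raise IntegrityError(f"site span [{site.start},{site.end}) outside UTR {utr.gene_id!r}")

    m = _three_prime_pairing(seq, site.core_start, mirna)
    if m is None:
        return None

    f_type = config.baselines[site.site_type]
    upstream = seq[max(0, site.start - config.au_window) : site.start]
    downstream = seq[site.end : site.end + config.au_window]
    flank = upstream + downstream
    au_fraction = (sum(1 for b in flank if b in "AT") / len(flank)) if flank else 0.0
    f_au = config.w_au * au_fraction
    f_3p = config.w_3p * (m / 4.0)
    d = min(site.start, len(seq) - site.end)
    f_pos = config.w_pos * max(0.0, 1.0 - d / config.pos_halfmax)
    return ScoredSite(
        gene_id=site.gene_id,
        mirna_name=site.mirna_name,
        site_type=site.site_type,
        start=site.start,
        end=site.end,
        taxon=site.taxon,
        f_type=f_type,
        f_au=f_au,
        f_3p=f_3p,
        f_pos=f_pos,
        context_score=f_type + f_au + f_3p + f_pos,
    )


def score_sites(
    utr: UtrRecord,
    mirna: MatureMiRNA,
    sites: Iterable[SeedSite],
    config: ContextModelConfig | None = None,
) -> tuple[list[ScoredSite], list[SeedSite]]:
    """Score a site list; returns (scored, discarded-for-ambiguity)."""
    scored: list[ScoredSite] = []
    discarded: list[SeedSite] = []
    for site in sites:
        result = score_site(utr, mirna, site, config)
        if result is None:
            discarded.append(site)
        else:
            scored.append(result)
    return scored, discarded


def harmonize_discards(
    scored_a: Sequence[ScoredSite],
    scored_b: Sequence[ScoredSite],
    discarded_a: Sequence[SeedSite],
    discarded_b: Sequence[SeedSite],
) -> tuple[list[ScoredSite], list[ScoredSite], set[tuple[str, str, int, str]]]:
    """Remove ambiguity-discarded sites from *both* taxa's site sets.

    A site dropped in one taxon (typically an N in the ancient consensus)
    is also dropped at the same (gene, miRNA, start, type) in the other,
    so cross-taxon comparisons stay well-defined.  Returns the filtered
    lists and the set of removed keys for reporting.
    """
    keys = {
        (s.gene_id, s.mirna_name, s.start, s.site_type)
        for s in (*discarded_a, *discarded_b)
    }
    kept_a = [s for s in scored_a if s.key not in keys]
    kept_b = [s for s in scored_b if s.key not in keys]
    return kept_a, kept_b, keys


def sum_gene_mirna_scores(scored: Sequence[ScoredSite]) -> float:
    """Sum of context scores over one (gene, miRNA, taxon) site set."""
    if scored:
        heads = {(s.gene_id, s.mirna_name, s.taxon) for s in scored}
        if len(heads) > 1:
            raise IntegrityError(f"sites span multiple (gene, miRNA, taxon) groups: {sorted(heads)}")
    return sum(s.context_score for s in scored)


def scored_to_frame(scored: Sequence[ScoredSite]):
    """Tabulate scored sites (one row per site)."""
    import pandas as pd

    rows = [
        {
            "gene_id": s.gene_id,
            "taxon": s.taxon,
            "mirna": s.mirna_name,
            "site_type": s.site_type,
            "start": s.start,
            "end": s.end,
            "f_type": s.f_type,
            "f_au": s.f_au,
            "f_3p": s.f_3p,
            "f_pos": s.f_pos,
            "context_score": s.context_score,
        }
        for s in scored
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "taxon", "mirna", "site_type", "start", "end",
            "f_type", "f_au", "f_3p", "f_pos", "context_score",
        ],
    )
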