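"""Synthetic orthologous-UTR datasets with planted sites and known truth.

The generator emulates the structure of a two-taxon UTR comparison:
pairs of equal-length UTRs that differ only by substitutions, a set of
mature miRNAs, planted binding-site events of known category, and
background SNPs drawn with a tunable transition/transversion bias.

Planted events per (gene, miRNA):

* ``gain``     - an 8mer site in taxon A only; a single seed-region SNP
                 breaks it in taxon B;
* ``loss``     - the mirror image (site in B only);
* ``increase`` - one shared site plus one A-only site;
* ``decrease`` - one shared site plus one B-only site;
* ``shared``   - an identical site in both taxa, no SNP inside.

Background sequence is *motif-scrubbed*: any accidental occurrence of a
miRNA seed core outside the planted slots is destroyed by resampling a
background base (bounded rejection), so the scanner/classifier truth is
exactly the planted truth.  Background SNPs are placed outside all slot
spans; transitions are drawn with probability w/(1+w) for ti/tv weight w.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    MatureMiRNA,
    SnpRecord,
    UtrRecord,
    read_mirna_table,
    read_snp_table,
    read_utr_fasta,
    write_mirna_table,
    write_snp_table,
    write_utr_fasta,
)
from .site_scanner import target_motifs
from .utr_builder import UtrPair

GAIN, LOSS, INCREASE, DECREASE, SHARED = "gain", "loss", "increase", "decrease", "shared"
PLANTABLE = (GAIN, LOSS, INCREASE, DECREASE, SHARED)

_DNA = "ACGT"
_RNA = "ACGU"
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_PARTNERS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}

#: slot geometry: planted 8mer motifs, kept clear of each other and the ends
_MOTIF_LEN = 8
_SLOT_GAP = 12
_END_MARGIN = 10


class SimulationError(RuntimeError):
    """Generation failed under the given configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a mammalian two-taxon 3' UTR comparison: ~45% GC
    background, 22-nt miRNAs, a substitution rate of 0.0055 per nt
    (about 1.9 background SNPs on a mean 350-nt UTR) and a ti/tv weight
    of 1.93 (the ratio observed for binding-site SNPs in a modern-vs-
    ancient bovine comparison; genome-wide mammalian values sit near 2.2).
    """

    n_genes: int = 100
    utr_length_range: tuple[int, int] = (200, 500)
    gc_content: float = 0.45
    n_mirnas: int = 20
    mirna_length: int = 22
    snp_rate: float = 0.0055
    titv_weight: float = 1.93
    planted_events: tuple[tuple[str, int], ...] = (
        (GAIN, 30), (LOSS, 30), (INCREASE, 15), (DECREASE, 15), (SHARED, 30),
    )
    snps_per_event: int = 1
    rng_seed: int = 0
    max_scrub_iterations: int = 2000

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_mirnas <= 0:
            raise ValueError("n_genes and n_mirnas must be positive")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        if not (0.0 <= self.snp_rate <= 1.0):
            raise ValueError("snp_rate must be in [0, 1]")
        if self.titv_weight <= 0:
            raise ValueError("titv_weight must be positive")
        if self.mirna_length < 8:
            raise ValueError("mirna_length must be at least 8")
        lo, hi = self.utr_length_range
        if not (0 < lo <= hi):
            raise ValueError("utr_length_range must satisfy 0 < lo <= hi")
        for cat, count in self.planted_events:
            if cat not in PLANTABLE:
                raise ValueError(f"unknown planted category {cat!r}")
            if count < 0:
                raise ValueError("planted event counts must be non-negative")
        if not (1 <= self.snps_per_event <= 6):
            raise ValueError("snps_per_event must be in 1..6 (seed core width)")


@dataclass(frozen=True)
class TruthRecord:
    """Planted truth for one (gene, miRNA) event."""

    gene_id: str
    mirna_name: str
    category: str
    sites_a: tuple[int, ...]  # motif start offsets, taxon A
    sites_b: tuple[int, ...]
    snps: tuple[SnpRecord, ...]  # event-realizing SNPs (inside the motif)


@dataclass
class TruthTable:
    """All planted events plus the miRNA set used to generate them."""

    records: list[TruthRecord]
    mirnas: list[MatureMiRNA] = field(default_factory=list)

    def by_gene_mirna(self) -> dict[tuple[str, str], TruthRecord]:
        return {(r.gene_id, r.mirna_name): r for r in self.records}

    def expected_psn_csn(self) -> dict[str, tuple[int, int]]:
        """Planted (psn, csn) per gene, over distinct site positions."""
        poly: dict[str, set[int]] = defaultdict(set)
        common: dict[str, set[int]] = defaultdict(set)
        for r in self.records:
            shared = set(r.sites_a) & set(r.sites_b)
            common[r.gene_id] |= shared
            poly[r.gene_id] |= (set(r.sites_a) | set(r.sites_b)) - shared
        genes = set(poly) | set(common)
        return {g: (len(poly[g]), len(common[g])) for g in sorted(genes)}


# ---------------------------------------------------------------------------
# miRNA generation
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(_RNA[i] for i in rng.integers(0, 4, size=length))

def _core_overlaps(core: str, motif8: str, self_motif: bool) -> bool:
    """Does ``core`` occur in ``motif8`` anywhere it must not?

    For a miRNA's own motif the core is expected exactly at offset 1;
    any other occurrence (self-overlap) or any occurrence of a foreign
    core makes planted slots ambiguous.
    """
    start = 0
    while (i := motif8.find(core, start)) != -1:
        if not (self_motif and i == 1):
            return True
        start = i + 1
    return False


def generate_mirnas(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[MatureMiRNA]:
    """Random mature miRNAs with pairwise-distinct, non-interfering seeds.

    Seeds (positions 2-7) are pairwise distinct, and no miRNA's seed core
    may occur inside another miRNA's 8mer target motif (or shifted inside
    its own), so that planted motifs belong to exactly one miRNA.
    """
    if config.n_mirnas > 4 ** 6:
        raise SimulationError(
            f"n_mirnas={config.n_mirnas} exceeds the number of distinct 6-nt seeds"
        )
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    mirnas: list[MatureMiRNA] = []
    motifs: list[str] = []
    cores: list[str] = []
    for i in range(config.n_mirnas):
        for _ in range(1000):
            seq = _random_rna(rng, config.mirna_length)
            cand = MatureMiRNA(name=f"sim-miR-{i + 1}", sequence=seq)
            tm = target_motifs(cand)
            core, motif8 = tm["6mer"], tm["8mer"]
            if core in cores:
                continue
            if _core_overlaps(core, motif8, self_motif=True):
                continue
            if any(_core_overlaps(core, m, self_motif=False) for m in motifs):
                continue
            if any(_core_overlaps(c, motif8, self_motif=False) for c in cores):
                continue
            mirnas.append(cand)
            motifs.append(motif8)
            cores.append(core)
            break
        else:
            raise SimulationError(f"could not draw a non-interfering seed for miRNA {i + 1}")
    return mirnas


# ---------------------------------------------------------------------------
# per-gene construction
# ---------------------------------------------------------------------------

def _place_slots(L: int, n_slots: int, rng: np.random.Generator) -> list[int]:
    """Start offsets for n_slots 8-nt motif slots, mutually separated and
    kept away from the UTR ends; leftover length is spread randomly."""
    if n_slots == 0:
        return []
    needed = 2 * _END_MARGIN + n_slots * _MOTIF_LEN + (n_slots - 1) * _SLOT_GAP
    if L < needed:
        raise SimulationError(
            f"UTR of length {L} too short to host {n_slots} motif slots (needs {needed})"
        )
    slack = L - needed
    extra = rng.multinomial(slack, [1.0 / (n_slots + 1)] * (n_slots + 1))
    starts: list[int] = []
    pos = _END_MARGIN + int(extra[0])
    for k in range(n_slots):
        starts.append(pos)
        pos += _MOTIF_LEN + _SLOT_GAP + int(extra[k + 1])
    return starts


def _random_background(rng: np.random.Generator, L: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return [_DNA[i] for i in rng.choice(4, size=L, p=probs)]


def _substitute_base(ref: str, titv_weight: float, rng: np.random.Generator) -> str:
    """Draw a substituted base: the transition partner with probability
    w/(1+w), else one of the two transversion partners uniformly."""
    if rng.random() < titv_weight / (titv_weight + 1.0):
        return _TRANSITION_PARTNER[ref]
    return _TRANSVERSION_PARTNERS[ref][int(rng.integers(0, 2))]


def _broken_motif(
    motif8: str,
    cores: Sequence[str],
    rng: np.random.Generator,
    n_breaks: int,
    titv_weight: float,
) -> tuple[str, list[int]]:
    """Mutate ``n_breaks`` seed-core bases of an 8mer motif so that the
    result contains no seed core of any miRNA; returns (string, offsets).

    Replacement bases follow the same ti/tv bias as background SNPs, so
    binding-site SNPs inherit the configured ratio (up to the rare
    rejection of substitutions that would recreate a seed core).
    """
    for _ in range(200):
        offsets = sorted(rng.choice(np.arange(1, 7), size=n_breaks, replace=False).tolist())
        chars = list(motif8)
        for j in offsets:
            chars[j] = _substitute_base(motif8[j], titv_weight, rng)
        broken = "".join(chars)
        if not any(c in broken for c in cores):
            return broken, offsets
    raise SimulationError("could not break a planted motif without creating a new seed core")


def _unwanted_occurrence(
    seq: str, cores: Sequence[str], expected: set[tuple[str, int]]
) -> tuple[str, int] | None:
    """First (core, position) occurrence not in the expected set, or None."""
    for core in cores:
        start = 0
        while (i := seq.find(core, start)) != -1:
            if (core, i) not in expected:
                return core, i
            start = i + 1
    return None


@dataclass
class _GeneBuild:
    seq_a: list[str]
    seq_b: list[str]
    slot_spans: list[tuple[int, int]]
    expected_a: set[tuple[str, int]]  # (core string, core offset)
    expected_b: set[tuple[str, int]]
    event_snps: list[SnpRecord]
    truth: list[TruthRecord]


def _build_gene(
    gene_id: str,
    L: int,
    events: Sequence[tuple[MatureMiRNA, str]],
    cores_by_name: dict[str, str],
    motifs_by_name: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> _GeneBuild:
    cores = list(cores_by_name.values())
    n_slots = sum(2 if cat in (INCREASE, DECREASE) else 1 for _, cat in events)
    starts = _place_slots(L, n_slots, rng)
    seq_a = _random_background(rng, L, config.gc_content)
    seq_b = list(seq_a)
    build = _GeneBuild(seq_a, seq_b, [], set(), set(), [], [])

    def plant(slot: int, mirna: MatureMiRNA, in_a: bool, in_b: bool) -> list[SnpRecord]:
        """Write the motif into the taxa where the site exists and a
        seed-broken copy into the other; returns the realizing SNPs."""
        motif = motifs_by_name[mirna.name]
        core = cores_by_name[mirna.name]
        build.slot_spans.append((slot, slot + _MOTIF_LEN))
        snps: list[SnpRecord] = []
        if in_a and in_b:
            variants = {"a": motif, "b": motif}
        else:
            broken, offsets = _broken_motif(
                motif, cores, rng, config.snps_per_event, config.titv_weight
            )
            variants = {"a": motif if in_a else broken, "b": motif if in_b else broken}
            for j in offsets:
                snps.append(
                    SnpRecord(
                        gene_id=gene_id,
                        pos=slot + j,
                        ref=variants["a"][j],
                        alt=variants["b"][j],
                    )
                )
        seq_a[slot : slot + _MOTIF_LEN] = list(variants["a"])
        seq_b[slot : slot + _MOTIF_LEN] = list(variants["b"])
        if in_a:
            build.expected_a.add((core, slot + 1))
        if in_b:
            build.expected_b.add((core, slot + 1))
        return snps

    slot_iter = iter(starts)
    for mirna, category in events:
        sites_a: list[int] = []
        sites_b: list[int] = []
        snps: list[SnpRecord] = []
        if category in (INCREASE, DECREASE):
            shared_slot = next(slot_iter)
            plant(shared_slot, mirna, in_a=True, in_b=True)
            sites_a.append(shared_slot)
            sites_b.append(shared_slot)
        slot = next(slot_iter)
        in_a = category in (GAIN, INCREASE, SHARED)
        in_b = category in (LOSS, DECREASE, SHARED)
        snps.extend(plant(slot, mirna, in_a=in_a, in_b=in_b))
        if in_a:
            sites_a.append(slot)
        if in_b:
            sites_b.append(slot)
        build.event_snps.extend(snps)
        build.truth.append(
            TruthRecord(
                gene_id=gene_id,
                mirna_name=mirna.name,
                category=category,
                sites_a=tuple(sorted(sites_a)),
                sites_b=tuple(sorted(sites_b)),
                snps=tuple(snps),
            )
        )

    _scrub(build, cores, config, rng)
    return build


def _scrub(
    build: _GeneBuild,
    cores: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Destroy accidental seed cores by resampling background bases.

    Only positions outside planted slots are touched (background is
    shared between the taxa before SNPs, so both copies are updated).
    """
    in_slot = set()
    for s, e in build.slot_spans:
        in_slot.update(range(s, e))
    for _ in range(config.max_scrub_iterations):
        hit = _unwanted_occurrence("".join(build.seq_a), cores, build.expected_a)
        which = "a"
        if hit is None:
            hit = _unwanted_occurrence("".join(build.seq_b), cores, build.expected_b)
            which = "b"
        if hit is None:
            return
        core, pos = hit
        candidates = [p for p in range(pos, pos + len(core)) if p not in in_slot]
        if not candidates:
            raise SimulationError(
                "accidental seed core confined to planted slots; cannot scrub "
                f"(core {core} at {pos}, taxon {which})"
            )
        p = candidates[int(rng.integers(0, len(candidates)))]
        current = build.seq_a[p]
        alternatives = [b for b in _DNA if b != current]
        new = alternatives[int(rng.integers(0, 3))]
        build.seq_a[p] = new
        build.seq_b[p] = new
    raise SimulationError("motif scrubbing did not converge; raise max_scrub_iterations")


def _draw_background_snps(
    build: _GeneBuild,
    gene_id: str,
    cores: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SnpRecord]:
    """Bernoulli(snp_rate) substitutions outside slot spans, transition
    with probability w/(1+w).  A draw that would create a spurious seed
    core in taxon B is dropped (rare; see docs)."""
    in_slot = set()
    for s, e in build.slot_spans:
        in_slot.update(range(s, e))
    snps: list[SnpRecord] = []
    L = len(build.seq_a)
    draws = rng.random(L)
    for pos in range(L):
        if pos in in_slot or draws[pos] >= config.snp_rate:
            continue
        ref = build.seq_b[pos]
        alt = _substitute_base(ref, config.titv_weight, rng)
        old = build.seq_b[pos]
        build.seq_b[pos] = alt
        window = "".join(build.seq_b[max(0, pos - 5) : pos + 6])
        if any(c in window for c in cores):
            build.seq_b[pos] = old  # would fake a binding site; skip this draw
            continue
        snps.append(SnpRecord(gene_id=gene_id, pos=pos, ref=ref, alt=alt))
    return snps


# ---------------------------------------------------------------------------
# dataset-level API
# ---------------------------------------------------------------------------

def _expand_events(
    config: SimulationConfig, mirnas: Sequence[MatureMiRNA], rng: np.random.Generator
) -> dict[int, list[tuple[MatureMiRNA, str]]]:
    """Assign planted events to (gene, miRNA) pairs, round-robin over genes
    so no gene hosts the same miRNA twice."""
    flat: list[str] = []
    for cat, count in config.planted_events:
        flat.extend([cat] * count)
    order = rng.permutation(len(flat))
    assignments: dict[int, list[tuple[MatureMiRNA, str]]] = defaultdict(list)
    for k, idx in enumerate(order):
        g = k % config.n_genes
        m = k // config.n_genes  # distinct per gene, so a gene never repeats a miRNA
        if m >= config.n_mirnas:
            raise SimulationError(
                f"{len(flat)} planted events exceed n_genes * n_mirnas capacity"
            )
        assignments[g].append((mirnas[(g + m) % config.n_mirnas], flat[idx]))
    return assignments


def generate_pair_with_truth(
    config: SimulationConfig,
) -> tuple[list[UtrPair], TruthTable]:
    """Generate the full dataset: UTR pairs plus the planted truth table.

    Deterministic for a fixed config (including ``rng_seed``).
    """
    rng = np.random.default_rng(config.rng_seed)
    mirnas = generate_mirnas(config, rng)
    cores_by_name = {m.name: target_motifs(m)["6mer"] for m in mirnas}
    motifs_by_name = {m.name: target_motifs(m)["8mer"] for m in mirnas}
    cores = list(cores_by_name.values())
    assignments = _expand_events(config, mirnas, rng)
    lo, hi = config.utr_length_range

    pairs: list[UtrPair] = []
    truth = TruthTable(records=[], mirnas=mirnas)
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:0{width}d}"
        L = int(rng.integers(lo, hi + 1))
        build = _build_gene(
            gene_id, L, assignments.get(g, []), cores_by_name, motifs_by_name, config, rng
        )
        bg_snps = _draw_background_snps(build, gene_id, cores, config, rng)
        all_snps = sorted(build.event_snps + bg_snps, key=lambda s: s.pos)
        utr_a = UtrRecord(gene_id=gene_id, taxon="A", sequence="".join(build.seq_a))
        utr_b = UtrRecord(gene_id=gene_id, taxon="B", sequence="".join(build.seq_b))
        pairs.append(UtrPair(gene_id, utr_a, utr_b, tuple(all_snps)))
        truth.records.extend(build.truth)
    return pairs, truth


def simulate_snps(
    n: int, titv_weight: float, rng: np.random.Generator | int = 0
) -> list[SnpRecord]:
    """n standalone substitutions with transition probability w/(1+w).

    Useful for calibration checks of the ti/tv machinery at large n
    without building full UTR datasets.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    snps = []
    for i in range(n):
        ref = _DNA[int(rng.integers(0, 4))]
        snps.append(
            SnpRecord(gene_id="sim", pos=i, ref=ref, alt=_substitute_base(ref, titv_weight, rng))
        )
    return snps


# ---------------------------------------------------------------------------
# emission / read-back
# ---------------------------------------------------------------------------

def emit_dataset(
    pairs: Sequence[UtrPair], truth: TruthTable, out_dir: str | Path
) -> dict[str, Path]:
    """Write utrs_a.fa, utrs_b.fa, snps.tsv, mirnas.tsv and truth.tsv.

    Formats are exactly those the readers consume; truth.tsv positions
    are 0-based motif start offsets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "utrs_a": out_dir / "utrs_a.fa",
        "utrs_b": out_dir / "utrs_b.fa",
        "snps": out_dir / "snps.tsv",
        "mirnas": out_dir / "mirnas.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_utr_fasta((p.utr_a for p in pairs), paths["utrs_a"])
    write_utr_fasta((p.utr_b for p in pairs), paths["utrs_b"])
    write_snp_table((s for p in pairs for s in p.snps), paths["snps"])
    write_mirna_table(truth.mirnas, paths["mirnas"])
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tmirna\tcategory\tsites_a\tsites_b\tsnp_pos\n")
        for r in truth.records:
            fh.write(
                f"{r.gene_id}\t{r.mirna_name}\t{r.category}\t"
                f"{','.join(map(str, r.sites_a))}\t{','.join(map(str, r.sites_b))}\t"
                f"{','.join(str(s.pos) for s in r.snps)}\n"
            )
    return paths


def read_dataset(data_dir: str | Path) -> tuple[list[UtrPair], TruthTable]:
    """Read back an emitted dataset directory into in-memory objects."""
    data_dir = Path(data_dir)
    utrs_a = read_utr_fasta(data_dir / "utrs_a.fa", taxon="A")
    utrs_b = {u.gene_id: u for u in read_utr_fasta(data_dir / "utrs_b.fa", taxon="B")}
    snps_by_gene: dict[str, list[SnpRecord]] = defaultdict(list)
    for s in read_snp_table(data_dir / "snps.tsv"):
        snps_by_gene[s.gene_id].append(s)
    pairs = [
        UtrPair(u.gene_id, u, utrs_b[u.gene_id], tuple(snps_by_gene.get(u.gene_id, ())))
        for u in utrs_a
    ]
    mirnas = read_mirna_table(data_dir / "mirnas.tsv")
    records: list[TruthRecord] = []
    with open(data_dir / "truth.tsv") as fh:
        header = fh.readline()
        snp_lookup = {
            (s.gene_id, s.pos): s for gene in snps_by_gene.values() for s in gene
        }
        for line in fh:
            gene_id, mirna, category, sa, sb, sp = line.rstrip("\n").split("\t")
            positions = tuple(int(x) for x in sp.split(",") if x != "")
            records.append(
                TruthRecord(
                    gene_id=gene_id,
                    mirna_name=mirna,
                    category=category,
                    sites_a=tuple(int(x) for x in sa.split(",") if x != ""),
                    sites_b=tuple(int(x) for x in sb.split(",") if x != ""),
                    snps=tuple(snp_lookup[(gene_id, p)] for p in positions),
                )
            )
    return pairs, TruthTable(records=records, mirnas=mirnas)
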