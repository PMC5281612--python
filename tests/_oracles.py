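"""Independent brute-force oracles used to cross-check the scanner.

Deliberately naive: motifs are rebuilt with a local complement table and
every substring of the UTR is compared against every motif, so nothing
is shared with the implementation under test beyond the definitions.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _revcomp(dna: str) -> str:
    return "".join(_COMP[b] for b in reversed(dna))


def oracle_motifs(mirna_rna: str) -> dict[str, str]:
    dna = mirna_rna.replace("U", "T")
    core = _revcomp(dna[1:7])       # positions 2-7
    m8 = _revcomp(dna[1:8])         # positions 2-8
    return {"6mer": core, "7mer-m8": m8, "7mer-A1": core + "A", "8mer": m8 + "A"}


def brute_force_sites(seq: str, mirna_rna: str) -> list[tuple[str, int, int]]:
    """All (site_type, start, end) matches, largest type per seed core.

    Every substring is compared against the four motifs in priority
    order; of the types matching at a given 6mer-core position only the
    largest is kept.  No overlap filtering (matches the scanner's
    pre-filter output).
    """
    motifs = oracle_motifs(mirna_rna)
    by_core: dict[int, tuple[str, int, int]] = {}
    for site_type in _PRIORITY:
        motif = motifs[site_type]
        for i in range(len(seq) - len(motif) + 1):
            if seq[i : i + len(motif)] != motif:
                continue
            core_pos = i + 1 if site_type in ("8mer", "7mer-m8") else i
            if core_pos not in by_core:
                by_core[core_pos] = (site_type, i, i + len(motif))
    return [by_core[k] for k in sorted(by_core, key=lambda c: (by_core[c][1], c))]
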