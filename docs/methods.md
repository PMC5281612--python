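# Methods

This note documents the models and procedures implemented in `mirdiv`,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical conventions.

## Coordinates and sequence conventions

All in-memory coordinates are 0-based, half-open.  The on-disk SNP table
is 1-based (VCF convention); conversion happens only at the read/write
boundary.  UTRs are stored as uppercase DNA in mRNA-sense orientation
(minus-strand extraction reverse-complements at the source), so every
downstream stage scans a single alphabet; mature miRNAs stay RNA.
Indels are rejected everywhere: the comparison model assumes
equal-length orthologous UTRs differing only by substitutions, which
makes positions directly comparable across taxa.

## Seed-site model

A site is recognized from the seed alone.  With `core` the DNA reverse
complement of miRNA positions 2–7 and `m8` the complement of position 8,
the four canonical types are `6mer = core`, `7mer-m8 = m8 + core`,
`7mer-A1 = core + "A"`, `8mer = m8 + core + "A"`.  The A1 adenosine is a
literal target `A` regardless of miRNA position 1 (target adenosines
opposite position 1 are recognized by Argonaute directly, not by
pairing).  Decisions at each core occurrence:

* **largest type wins** (8mer > 7mer-m8 > 7mer-A1 > 6mer), the standard
  convention when one locus satisfies several definitions;
* sites whose motif span contains a non-ACGT base are discarded
  (ambiguity in an ancient-genome consensus must not produce calls);
* after a left-to-right scan, any site overlapping a previously
  accepted site of the same miRNA is discarded.  The original rule is
  order-dependent; we fix the order as ascending start coordinate so the
  5′-most site deterministically wins ties.  The rule is applied within
  (gene, miRNA) regardless of site type.

No positional exclusion zone is applied near the UTR start by default;
an `exclude_first` option exists for users who want a stop-codon-
proximal dead zone.

## Context-style scoring

Site efficacy is scored with a transparent four-feature linear model on
the repression log-ratio scale (more negative = stronger repression):

```
score = baseline[type] + w_au * AU + w_3p * m/4 + w_pos * max(0, 1 - d/pos_halfmax)
```

* `baseline`: per-type intercepts, defaults −0.310 (8mer), −0.161
  (7mer-m8), −0.099 (7mer-A1), −0.015 (6mer).  These preserve the
  canonical efficacy ordering and realistic magnitudes of published
  context-score baselines; they are *not* a re-fit of any external
  regression, and no conservation term is included.
* `AU`: fraction of A/T in up to `au_window` (default 30) nt on each
  side of the site, site excluded; truncated flanks use the sequence
  that exists and the actual flank length as denominator.
* `m`: longest contiguous Watson–Crick run between miRNA positions
  13–16 and the 4 target nt immediately 5′ of the region pairing
  position 12 (zero offset; the offset search of full context models is
  deliberately simplified away).  If any base in that target window is
  ambiguous the site is removed — from **both** taxa's site sets, so
  cross-taxon comparisons stay well-defined; removals are counted in
  the run manifest.  A window lying entirely outside the UTR simply
  contributes m = 0.
* `d`: distance from the site's nearest edge to the nearest UTR end;
  the positional bonus decays linearly to zero at `pos_halfmax`
  (default 1500 nt), reflecting that sites near UTR ends outperform
  mid-UTR sites in long UTRs.

Default weights `w_au = −0.10`, `w_3p = −0.05`, `w_pos = −0.05` keep
each modifier small relative to the type baselines.  All coefficients
live in a YAML-serializable config; setting every weight and baseline
to zero yields exactly zero scores (null-model check, under test).
Per-(gene, miRNA) scores are plain sums of site scores.

## Classification and SSr

Sites are matched across taxa by identical start **and** site type,
one-to-one.  A substitution that merely changes the type at a fixed
position (e.g. 7mer-A1 → 8mer) therefore appears as one unmatched site
in each taxon; such pairs are flagged `type_shift` in the events table
so users preferring position-only matching can recover it.  Categories
per (gene, miRNA): gain / loss when one taxon has exclusive sites and
nothing is shared (both recorded if both taxa have exclusive sites and
none shared — flagged `gain_loss_pair`); increase / decrease when
exclusive sites coexist with a shared site.  Swapping the taxa swaps
gain↔loss and increase↔decrease exactly (under test).

Per gene, `psn` and `csn` count *distinct site positions* (start
coordinates) that are polymorphic respectively common, so a position
targeted by several miRNAs is counted once.  The ranking statistic is

```
SSr = (sum of site scores over the union of both taxa's sites) * psn / csn
```

with matched sites counted once using the taxon-A score and each
exclusive site contributing the score computed in the taxon where it
exists (the score of a site that exists in only one taxon is only
defined there).  `psn = 0` gives SSr = 0.  `csn = 0` with `psn > 0`
(pure gain/loss genes, which necessarily exist) would be undefined; we
substitute `csn = 1` and set a `csn_pseudo` flag, keeping the ranking
total and the substitution auditable.  Ranking is ascending — the most
negative SSr (strongest predicted regulatory divergence) is rank 1 —
with ties broken lexicographically by gene id.  Pathway scores are sums
of member genes' SSr over user-supplied gene sets; genes absent from
the results are skipped and counted.

## ti/tv

Substitutions are classified as transitions (A↔G, C↔T) or transversions
(all others).  Ratios are reported for all UTR SNPs and for the subset
inside predicted binding-site spans (union over taxa and miRNAs); a SNP
overlapped by several sites counts once.  Zero transversions yield an
explicit undefined marker rather than a division error.  This is a
diagnostic for post-mortem deamination in ancient consensus sequences,
which inflates C→T transitions; no significance test between the two
ratios is provided.

## Synthetic data

The generator produces the study conditions the pipeline is validated
under: `n_genes = 100` UTR pairs of 200–500 nt at 45% GC (typical of
mammalian 3′ UTRs), `n_mirnas = 20` random 22-nt miRNAs, a background
substitution rate of 0.0055 per nt (≈1.9 SNPs on a mean 350-nt UTR,
matching the per-UTR SNP density scale of a modern-vs-ancient bovine
comparison), and a ti/tv weight of 1.93 — the value observed for
binding-site SNPs in that setting; 2.19 is the corresponding
genome-wide value and is used as a second calibration point in the
tests.  Planted events default to 30 gains, 30 losses, 15 increases,
15 decreases and 30 shared sites assigned round-robin to distinct
(gene, miRNA) pairs.

Construction per gene: motif slots (8 nt, ≥12 nt apart, ≥10 nt from the
ends) are placed with randomized spacing; planted events write the 8mer
motif into the taxa where the site must exist and a seed-broken copy
(default one substitution in the core, `snps_per_event` configurable)
into the other, recording the realizing SNP.  miRNA seeds are drawn so
that no seed core occurs inside another miRNA's 8mer motif (or shifted
inside its own), which makes slot ownership unambiguous.  Background
sequence is then *motif-scrubbed*: any accidental seed-core occurrence
outside the expected set is destroyed by resampling a background base,
iterating to a fixed point (bounded; failure raises).  Background SNPs
are Bernoulli per background position with transition probability
w/(1+w); a draw that would create a spurious seed core in taxon B is
dropped (≈3% of draws at 20 miRNAs — a small downward density bias well
inside the tested 3-standard-error band).  Scrub-resampled bases are
drawn uniformly over the three alternatives, ignoring the GC weight;
seed-breaking substitutions follow the same ti/tv weight as background
SNPs, so binding-site SNPs inherit the configured ratio.

What the generator does **not** emulate: indels, rate heterogeneity and
substitution-rate matrices beyond the single ti/tv weight, linkage
between SNPs, ancient-DNA damage profiles (position-dependent C→T), UTR
annotation errors, and non-canonical (bulged, centered, 3′-compensatory)
sites.  Passing the truth-recovery tests therefore demonstrates that the
detection → scoring → classification → ranking chain is internally
correct on substitution-only divergence with unambiguous site ownership;
it does not validate site predictions against measured repression, nor
robustness to alignment or annotation error in real data.

## Problem sizes and determinism

Test and acceptance runs use 100 genes × 20 miRNAs for the end-to-end
truth-recovery study, 1,000 random pairs (UTRs ≤ 500 nt) for the
scanner/oracle cross-check and 10,000 draws for ti/tv calibration —
sizes at which every stochastic check sits comfortably inside its
3-standard-error band while the whole suite runs in seconds.  All
randomness flows through seeded NumPy generators; a fixed config and
seed reproduce datasets byte-for-byte, and the pipeline driver writes a
manifest with SHA-256 digests of inputs and outputs so reruns can be
verified byte-identically.

## Known limitations

* The scoring model shares its feature set with published context
  models but not their fitted coefficients; absolute scores are not
  comparable to TargetScan output, and no conservation (PCT) term
  exists.  Rankings driven by site counts and types are robust to this;
  fine score differences are not.
* Genome-scale figures (thousands of genes) require a reference
  annotation and, for an ancient taxon, a consensus genome; nothing in
  this package attempts to produce those inputs.
* The mean-SNPs-per-UTR denominator is ambiguous in published summaries
  of this kind; both "per SNP-bearing UTR" (default) and "per annotated
  UTR" are exposed as a config switch in `summarize_snp_stats`.
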