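# Methods

This note records the models, parameter choices, and numerical decisions
behind each module, in enough detail to reproduce or deliberately change
them.

## Coordinates and sequences

All coordinates are 1-based and inclusive at both ends internally —
length = end − start + 1 — matching GenBank-style printed tables; the BED
writer converts to 0-based half-open at the boundary and the GFF3 writer
stays 1-based. Printed descending coordinate pairs (the convention for
minus-strand elements listed 5'→3') are normalized to (min, max) with
strand "−" at ingest. Lowercase residues are uppercased and carry no
masking semantics: in the promoter literature this package serves,
lowercase marks consensus deviations, not repeats. `N` in a *subject*
sequence matches nothing (every non-`N` pattern code counts it as a
mismatch) so masked input cannot generate spurious hits; `N` in a
*pattern* matches everything.

Interval union merges intervals that overlap **or touch** (end + 1 =
next start), because adjacent annotation blocks form one functional
region; strand is ignored for union.

## Motif scanning

A window matches a degenerate IUPAC pattern with Hamming accounting: a
position costs one mismatch iff the subject base is outside the pattern
code's allowed set; ambiguity codes are satisfied at zero cost by any
allowed base. Exclusion patterns are tested at zero mismatches regardless
of the main budget — they encode absolute "excluding:" clauses of
compound elements such as TATA-532 (`HWHWWWWR` excluding `HTYTTTWR`,
`CAYTTTWR`, `MAMAAAAR`, `CTYAAAAR`). Minus-strand search scans the
reverse complement and maps hits back to forward-strand intervals, so
hit sets satisfy strand symmetry exactly.

The built-in catalog carries the core-promoter and response-element
consensus strings used throughout (TATA variants, INR, DTIE, CCAAT and
inverted CCAAT, BRE, DPE, ARE, E-box, GAF `GAGAG`/`GAGAGA`, the 19-nt
CTCF site). SP1 (`GGGCGG`), AP1 (`TGACTCA`), GRE (`AGAACANNNTGTTCT`) and
ERE (`GGTCANNNTGACC`) have no locus-specific printed string, so canonical
consensus defaults are shipped; every entry is overridable through a YAML
catalog file. Overlap-aware counting (`merge_overlapping`) collapses
mutually overlapping same-strand windows into one site, so a `GAGAGA`
match and its internal `GAGAG` windows count once.

## CpG islands

Fixed-interval statistics are exact counts: %GC = 100·(#C+#G)/N and
Obs/Exp CpG = #CpG / ((#C·#G)/N), defined as 0 when the region lacks C or
G; U counts as T so the statistics are alphabet- and case-invariant.
Ambiguity codes count as non-C/non-G and break CpG dinucleotides
(conservative).

Detection defaults to the published parameter set — Obs/Exp > 0.60,
%GC > 55.0, length > 200 bp, 100-nt window — with strict inequalities on
the two ratio thresholds. Window statistics are computed at every
position and **averaged per position** over all windows covering it;
maximal runs of positions whose averaged values clear both thresholds
become islands, and runs shorter than the minimum length are dropped.
The averaging was chosen over the simpler alternative (merging the full
spans of passing windows) because span-merging systematically smears
island boundaries up to nearly a window length into non-CpG flanks —
for a 100-nt window and a ~95%-GC core, ~42 bp per side — whereas
per-position averaging places boundaries within ~10 bp of a strong
block's edges. Reported islands carry whole-island statistics re-measured
over the final interval, so every island is self-consistent under
re-measurement.

Boundary recovery degrades gracefully as a region's Obs/Exp approaches
the 0.60 threshold: with 100-nt windows, a block at Obs/Exp ≈ 0.85 has
per-window Obs/Exp noise of roughly ±0.26, so edge windows dip below
threshold and the reported island may cover only the strongest core.
The detection guarantee is therefore zero false negatives (an island of
at least minimum length inside the block), not exact boundary
reproduction — the same behavior any windowed threshold detector,
including the classical plotting tool this scheme follows, exhibits.

## p53 response elements

The element model is two `RRRCWWGYYY` decamer half-sites separated by a
0–13-nt spacer of arbitrary bases. Search enumerates every (strand,
offset, spacer) placement and scores per-half IUPAC mismatches; results
sort by (total mismatches, start, spacer). `best_match` clips the spacer
range to what the sequence length permits, so a short printed element
string — too short to hold two decamers plus the nominal spacer — still
yields its optimal decomposition; ties break deterministically toward
smaller spacer, then smaller start, then the + strand. Because the
half-site class is reverse-complement symmetric, the minimum mismatch
count of any sequence equals that of its reverse complement, which the
tests assert both on the printed intron-1 elements and on random
sequences.

## miRNA recognition elements

**Duplex model.** The hybridization dynamic program finds the
minimum-energy *intermolecular* duplex between a miR (m nt) and a target
window: pairs are Watson–Crick (GC, AU) or wobble (GU), strands are
antiparallel so pairs are non-crossing (miR index ascending ↔ target
index descending), bulges and internal loops are allowed up to a
per-side cap, intramolecular pairs are forbidden, and dangling ends are
free. Energies are a deliberately simple per-pair scheme — defaults
GC −3.0, AU −2.0, GU −1.0 kcal/mol; bulge open +3.0 / extend +0.5;
internal-loop open +2.0 / extend +0.5; maximum bulge 15 nt — not the
full nearest-neighbor stacking tables. This keeps the model transparent
and exactly checkable by exhaustive structure enumeration (the tests
verify DP = enumeration for miR ≤ 8 nt against windows ≤ 12 nt); all
parameters are overridable via `EnergyModel`. The DP kernel is
JIT-compiled (numba), O(m·n·b²) for window length n and bulge cap b.

**Site enumeration.** Candidate windows are anchored at seed matches
(miR positions 2–8 by default, reverse-complement match on the target;
6mer and GU-tolerant classes optional), falling back to overlapping
exhaustive tiles when no seed exists or when `exhaustive=True` — the
anchoring is an optimization only. Sites are selected greedily by
ascending MFE subject to pairwise non-overlap of their target spans, up
to `max_sites`; positions are reported 1-based with the site's leftmost
transcript position first, matching the convention of published MRE
tables.

**Significance.** The best-site score is length-normalized as
x = −MFE / ln(m·n). The null is generated by Altschul–Erikson
dinucleotide-preserving shuffles of the target (preserving CpG/stacking
composition, which dominates hybridization energy), and a Gumbel
location/scale is fitted by the method of moments
(scale = std·√6/π, location = mean − γ·scale). Site p-values are the
Gumbel upper tail 1 − exp(−exp(−(x−μ)/β)), strictly decreasing in −MFE.
Calibration is deterministic given its seed and requires ≥100 shuffles;
degenerate (zero-variance) backgrounds are rejected with a relative
1e-9 tolerance on the score standard deviation. Multiple-site
significance uses the Poisson upper tail P(K ≥ k) at a user-supplied
expected rate. The energy grid is discrete (multiples of 0.5 kcal/mol
under the defaults), so null p-values are approximately, not perfectly,
uniform; at the tested scale (22-nt miR, 400-nt target) the
Kolmogorov–Smirnov distance from uniform is below 0.1.

**Feature mapping.** Each site is labeled by the transcript feature
(5'UTR, exon/CDS, 3'UTR) containing its leftmost position; positions
outside the annotation are labeled `unannotated` with a warning, and
per-feature counts are emitted in the layout of published MRE tables.

## Synthetic data

Background sequence is i.i.d. with a specified GC fraction. Planted
features are realized deterministically from the seed: motif instances
match their IUPAC pattern at exactly (length − k) positions for a
requested mismatch count k; dimer sites are two independently realized
half-sites around a random spacer; miRNA sites are the reverse
complement of the miR degraded to a requested fidelity; CpG blocks are
sampled from an order-1 model whose post-C G-probability is scaled by
the target Obs/Exp, then rejection-sampled until block-level %GC is
within ±2 points and Obs/Exp within ±0.05 of target (bounded tries,
error on failure). Plants are bounds- and overlap-checked before any
output; identical specs produce byte-identical FASTA/BED/TSV outputs.
The generator emulates composition and planted signals only — no
chromatin, methylation, conservation, or repeat structure — so
closed-loop tests demonstrate detector correctness, not performance on
real genomes.

## Problem sizes in the test suite

The suite exercises: motif-scan oracle equivalence on 10-kb seeded
sequences; dimer oracle equivalence on 200-nt sequences at budget 3;
DP-vs-enumeration on ~12 random miR/window instances; planted-MRE
recovery on 2-kb transcripts over 20 seeds; EVD calibration with 500
shuffles and 1000 fresh null draws on a 400-nt target; and 100-kb
composition checks. These sizes make the full suite complete in well
under a minute on one CPU while leaving every statistical check
comfortably powered.

## Known limitations

* The duplex energy model omits stacking context, terminal AU penalties
  and loop-sequence effects; MFE values are comparable within this model
  only, not against nearest-neighbor folding engines.
* Island boundaries inherit windowing bias near thresholds (see above).
* The motif scanner is exhaustive (no index); intended scale is
  promoter/locus scans, not whole genomes.
* Position-weight-matrix scoring and database-specific E-values are out
  of scope; consensus strings with mismatch budgets are the supported
  motif model.
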