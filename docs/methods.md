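# Methods

## Coordinate model

A `TranscriptModel` is a coding-region exon structure: genomic intervals are
0-based half-open internally, HGVS rendering is 1-based inclusive, and c.1
is the first modeled base. Intronic positions carry offsets (`c.1408+743`,
`c.5763-1056`); mapping a genomic base back to c. space uses the HGVS
half-intron convention (5' half anchored to the donor with `+`, 3' half to
the acceptor with `-`, ties to the donor). UTR-anchored positions (`c.-k`,
`c.*k`) are rejected outright: the workflow never needs them and silently
mis-anchoring one would corrupt every downstream breakpoint. Minus-strand
transcripts are fully supported; junction keys are always stored in genomic
orientation (the STAR `SJ.out.tab` convention, 1-based intron start/end)
and converted at the HGVS boundary. Models carry an explicit first-exon
number so LRG-style numbering (a first coding exon that is not "exon 1")
reproduces clinical event labels without renumbering exon records.

Variant sites classify into four groups using the common clinical consensus
windows — donor (5'ss): last 3 exonic + first 8 intronic nt; acceptor
(3'ss): last 12 intronic + first 2 exonic nt; everything else is deep
intronic (DI) or deep exonic (DE).

## Events and nomenclature

An aberrant transcript species is a deletion (Δ family: whole-exon skip,
acceptor-/donor-shift partial deletion, multi-exon/compound deletion) or an
intronic insertion (▼ family: pseudoexon, donor-/acceptor-side partial
intron retention). Deletions store a removed c.-range — contiguous in c.
space even when it crosses an exon boundary; insertions store the inserted
intronic interval. Letters (A, B, …) disambiguate multiple events sharing
one exon/intron and side, ordered by descending read support with ties
broken 5'-first; the ordering is total, so naming is invariant to input
order.

r. descriptions render deletions as `r.<start>_<end>del` (single bases
collapse to `r.<pos>del`) and insertions as
`r.<exonL>_<exonR>ins<from>_<to>`. Pseudoexon intervals are written in
transcript order; partial intron retentions are written boundary-proximal
base first (`ins1237-1_1237-10` for a 10-nt acceptor-side retention),
matching how such events are conventionally reported in clinical summaries.
The parser accepts either order, and parse→render→parse is the identity on
complete events.

Junction interpretation: a non-canonical junction with two exonic flanks is
a deletion; with one intronic flank it is a retention candidate. An
intronic breakpoint within 50 nt of its exon boundary is read as a
determined partial retention (a cryptic-site shift near the boundary);
deeper breakpoints are pseudoexon flanks — a matching acceptor/donor flank
pair in the same intron merges into one pseudoexon event, and an unpaired
deep flank stays flagged *incomplete* (its retained extent cannot be told
apart from a pseudoexon whose partner junction went unobserved). Note that
positions derived from junctions are half-intron normalized, so a detected
pseudoexon deep in a long intron may render with acceptor-anchored (`-`)
offsets where a curator wrote donor-anchored (`+`) ones; the two forms name
the same bases.

Frame effects follow the mod-3 rule exactly: in-frame iff the net length
change is divisible by 3. An in-frame inclusion can still truncate the
protein through an internal stop codon; that distinction belongs to protein
prediction, not frame arithmetic. `predict_protein_effect` recomposes the
mutant CDS, translates to the first stop and emits HGVS-style p. strings
(`del`, `fs*k`, `*`); it needs the CDS (and, for insertions, the inserted
sequence) and is exercised on synthetic sequences — no genome FASTA is
required anywhere else.

## Quantification

Events are expressed as per-junction percentages: `100·a/(a+n)` where `a`
is the aberrant junction's unique-read count (the mean of the two flanking
junctions for a pseudoexon — they measure the same molecule twice) and `n`
the mean count of the annotated junction(s) the event competes with (every
annotated intron its novel junction genomically overlaps). The denominator
makes the three per-variant quantities (aberrant %, alt full-length %, ref
full-length %) live on a common scale; the literal `a/n` ratio is available
as `mode="literal"`. Only uniquely-mapped counts are used by default.
Quantification is scale-invariant in the counts. With several co-occurring
events the per-junction ratio slightly overstates each event's molecular
fraction (reads of *other* aberrant species are absent from its
denominator); this is a property of the junction-ratio method itself and is
left uncorrected.

Intron retentions lacking any junction signature (full-intron retention)
are not quantifiable from a junction table and are reported as such;
per-read records are the supported route for them.

An event is **variant-associated** when the carrier percentage clears an
absolute floor (0.1%), exceeds every control sample, and is at least 3×
the control mean. Both thresholds are configurable; the fold rule encodes
the judgment that a carrier signal a few-fold above a nonzero background
(e.g. 3% vs a 0.7% control mean) is still attributable to the variant,
while a naturally occurring alternative event at comparable levels in
controls is not. It is a heuristic, not a significance test — junction
counts at these depths would support a binomial test, but the clinical
decision in the source workflow is threshold-based and we mirror that.

Allele-resolved full-length fractions need an exonic tag: among reads whose
junction chain is fully canonical, the alt:ref split at the variant
position is scaled by the canonical fraction of all reads, so
aberrant + alt-full-length + ref-full-length ≈ 100%.

## Splicing classes and ACMG evidence

* **1S** — no variant-associated event.
* **3S** — variant-associated events, an exonic tag is available, and the
  alt-allele full-length share is below the noise threshold
  (`noise_alt_percent`, default 1.0%): the variant allele makes no
  full-length transcript. Intronic variants can never reach 3S.
* **2S** — everything between.

Functional evidence derives accordingly: 3S → PS3 (strong); 2S with total
aberrant expression above the insignificance threshold (default 2.0%) →
PS3-m (moderate); no significant impairment in a silent or intronic variant
→ BS3-SA (stand-alone benign). A missense with normal splicing earns no
functional item — its protein effect is untested. The derivation is a
*suggestion* reported alongside curator-supplied evidence strings, never an
override: curators legitimately depart from it (e.g. preferring PM4 for a
modest in-frame skip), and gene-specific guidance may set strengths such as
PM2-supp that the engine takes as given.

Combination implements the standard five-tier combining rules on resolved
strengths (including the very-strong and stand-alone paths unused by the
bundled cohort), with two extensions: BS3-SA forces 2-LB — not 1-B, and
deliberately weaker than BA1 — absorbing co-occurring supporting-level
pathogenic evidence (the computational prediction the assay just
disproved), while a pathogenic side independently reaching LP/P is a
genuine conflict and yields 3-VUS.

## Triage rule

A variant qualifies for RNA analysis when SpliceAI Δ > 0.2 (strict) **and**
(≥ 2 tools predict a novel splice site, or the natural site is weakened:
one tool calls complete loss, or MaxEntScan drops ≥ 15% and SSF ≥ 5% of
wild type). Whether the SpliceAI gate is conjunctive or an independent
OR-clause is genuinely ambiguous in threshold-based triage practice; the
default is conjunctive, a config flag flips it, and the triggered clauses
are reported either way. The rule is monotone in every score, and missing
scores never trigger a clause. SPICE output is carried through as an extra
column but does not enter the default rule.

## Synthetic data

`simulate_sample` draws reads as whole transcript-species observations:
a multinomial over {each aberrant species, full-length alt, full-length
ref} with probabilities proportional to fraction × NMD factor,
renormalized. Each aberrant read carries the annotated junction chain with
its replaced junction(s) swapped for the event's novel ones; canonical
reads carry the annotated chain and their allele. NMD is a per-event
multiplicative detection factor in (0, 1], default 1.0 (off) — an
observation model, not a decay mechanism. Controls share the model, express
events only at their background fractions, and derive per-sample seeds from
the spec seed; everything is bitwise reproducible per seed.

This emulates exactly the information the pipeline consumes and nothing
more. It does **not** model positional short-read coverage, sequencing
error, mapping bias, overdispersion between library preparations, or
partial junction overhangs — so passing recovery tests demonstrate
estimator correctness under multinomial sampling, not robustness to real
library artifacts.

## Bundled reference cohort

`splicework.cohort` encodes a published 12-variant clinical series (eight
hereditary-cancer genes) as the package's standing fixture: per-event r.
descriptions, carrier percentages, control levels, tag-SNP observations
and curated evidence strings. Transcript models are synthetic but
constrained — exon boundaries forced by the printed c. coordinates are
exact (the ATM model's intron 38 is 2175 nt so that its two pseudoexons
measure 137 and 120 nt); filler exon/intron sizes are interpolated.
Control lists are chosen to match the reported mean, range and
carrier-count facts (e.g. mean 0.7% ranging 0.3–1.3%; a background event
in 2 of 5 controls averaging 0.16%). Where a variant was observed in two
patients, the first patient's percentages are the carrier record and the
second's are kept as an auxiliary field.

One internal inconsistency in the source data is preserved rather than
corrected: the ▼38B pseudoexon's r. description forces a 120-nt inclusion,
which is in-frame under the mod-3 rule, while its reported protein change
is a frameshift. The frame classifier follows the arithmetic; the
corresponding acceptance test documents the discrepancy by failing for
exactly that event.

## Problem sizes and numerical choices

The recovery grid runs true fractions {0.003, 0.02, 0.07, 0.2, 0.4} ×
depths {500, 5000, 50000} × 200 seeded replicates and requires the
junction-ratio estimate within 3 binomial SD of truth in ≥ 99% of runs;
end-to-end class recovery uses 10 seeds × 3 scenarios at depth 10⁴.
Coordinate-map equivalence is checked by exhaustive enumeration on random
sub-kilobase models (both strands). These sizes keep the full suite in a
few seconds while leaving the binomial bands well-resolved at the smallest
fraction × depth cell. Tie-breaks and degenerate inputs: naming ties go
5'-first; a junction removing nothing is rejected as canonical adjacency;
`a + n = 0` reports "no coverage" rather than 0; single-base deletions
render `r.<pos>del`; SJ counts are bounded by the format's 32-bit field.

## Known limitations

* No NMD correction: attenuated aberrant fractions are interpreted
  downstream (e.g. a 3S call rests on the tag SNP, not on the fraction).
* No population-frequency automation (PM2/BS1 assignment), no phenotype
  logic (PP4), no predictor-score computation — scores and evidence
  strings are inputs.
* Junction evidence cannot distinguish full-intron retention from
  background without per-read records; such events surface as flagged
  candidates.
* p.-string prediction is validated on synthetic CDS only; real-gene
  protein annotation requires the actual CDS sequence.
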