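# Methods

## Scope and model

The package models the desk analysis of a CRISPR adaptation assay in a
three-replicon system — a linear host chromosome and circular plasmid and
virus replicons — for a subtype I-A-like acquisition machinery whose PAM is
5′-CCN. The unit of observation is one Sanger-sequenced clone of a
leader-proximal PCR product; the unit of inference is one acquisition
event (a new repeat–spacer unit joined to its protospacer of origin).

An amplicon is assumed to have the structure

```
leader · R · (new spacer · R)^m · parental₁ · R · … · parentalₖ · R [· primer tail]
```

with all new units leader-proximal and the parental order intact. Reads
are assumed oriented leader-first (fixed primer pair); if fewer than two
repeats are found, the reverse complement is tried before declaring a
clone unparseable. Indels, chimeras and quality values are out of scope:
the only error process modelled is per-base substitution.

## Array parsing

Repeat matching is a greedy left-to-right scan accepting any window within
Hamming distance `max_mismatch` (default 2 for a 24-nt repeat — tolerant of
Sanger miscalls yet far below the ~8-mismatch random background) and
consuming its span, which makes the interval set unique and deterministic.
The scan is a numpy-vectorised position-by-position comparison and is
required (and property-tested) to be identical to the naive O(n·m) scan.

Inter-repeat segments shorter than 10 nt or longer than 80 nt are flagged
and excluded. The new/parental split anchors on the first observed spacer
matching parental spacer 1 within `anchor_mismatch` (default 2); the
remaining spacers must then follow parental order (truncated tails are
accepted — the amplicon may simply end). Clones violating this are
reported as `unanchored` / `rearranged` and excluded rather than guessed
at; a clone whose anchor is detectable is always parsed, however many new
units it carries.

## Protospacer mapping

Mapping enumerates all Hamming matches ≤ `max_mismatch` (default 2; at
34–44 nt a random match within 2 mismatches of a ~200 kb search space has
negligible probability) on both strands of every replicon. Coordinates
are 0-based half-open on the plus strand; strand `+` means the stored
spacer equals the plus-strand slice. Best-hit selection takes fewest
mismatches, then replicon-kind priority virus > plasmid > host
(configurable — a declared convention, since multi-replicon ties have no
published resolution rule), and reports any residual tie as `ambiguous`
rather than picking arbitrarily.

## PAM classification

Flanks (6 nt each side, the minimum that covers slip offsets up to ±3) are
extracted in stored-spacer orientation: for a minus-strand hit the
upstream flank is the reverse complement of the plus-strand downstream
sequence. Plasmid and virus replicons wrap across the origin; host flanks
that cross a linear boundary flag the event `edge`, which classifies as
`other`.

Classification is first-match-wins in the order canonical → flip → slip →
mismatch → other, which makes the five classes exclusive and exhaustive
(reported class percentages therefore sum to 100% up to rounding):

1. canonical: C at upstream positions −3 and −2;
2. flip: G at downstream positions +2 and +3 (the reverse-complement image
   of an upstream CCN for the inverted insertion);
3. slip: CC at upstream (−3+δ, −2+δ) or GG at downstream (+2+δ, +3+δ) for
   some δ ∈ {±1, ±2, ±3}, δ ≠ 0, both positions inside the flank; the
   first δ in (|δ|, positive-first) order is reported. "Slip" has no
   published formal definition; this shifted-PAM reading is the standard
   usage for slipped integration, and the window is configurable.
   Within a 6-nt flank the upstream side covers δ ∈ {−3…−1, +1} and the
   downstream side δ ∈ {−1, +1…+3}, so every offset is checkable on at
   least one side.
4. mismatch: upstream −3..−1 is CDN or DCN with D ∈ {A, T, G} — exactly
   one of the two PAM Cs retained;
5. other: residual (also the fallback for `edge` events).

`N` never matches C or G, so ambiguous base calls cannot inflate
canonical/flip/slip counts. The NGG re-analysis counts downstream NGG among
events whose upstream has no C at either −3 or −2 (i.e. lacking CCN, CNN
and NCN), with the percentage taken over all classified events.

## Summary report

Percentages are rounded half-away-from-zero to one decimal — the rule that
reproduces every percentage of the published protospacer report from its
integer counts, which bankers' rounding would not. Undefined cells
(zero denominators, absent locations) render as `/`. Multiplicity is
binned 1/2/3/4+ per clone; all other sections are per spacer.

## Synthetic data generator

The generator's defaults are the virus-infection study condition: mode
weights 0.565/0.364/0.043/0.007/0.021 (canonical/flip/slip/mismatch/other)
and multiplicity weights 0.63/0.22/0.14/0.01 over 1–4 insertions, taken
from the published class frequencies and clone counts; source = virus
only; replicon sizes 50 kb / 8 kb / 20 kb (host/plasmid/virus) at GC 0.38;
spacer length uniform on [34, 44] nt (a genus-typical range — the assay
itself does not fix one); substitution error rate 0 (Sanger consensus
reads are near-clean; 0.002 is used as the stress condition in tests).

One RNG stream seeded once drives every draw, in documented order
(replicons sorted by kind, locus, then clones/events in order), making all
outputs byte-reproducible. Event planting samples a site uniformly with a
6-nt margin, rejects overlaps with previously planted windows, picks a
strand, and rewrites both flanks (in stored-spacer orientation) with
random sequence constrained to the requested class — constructive motif
placement followed by rejection against the full rule priority, so the
planted label is exactly what the classifier must return. For `flip` the
stored spacer is the inverse of the CCN-adjacent orientation, so its truth
strand is the opposite of the orientation the PAM sits on; strand
frequencies stay ~50/50 in every mode. A placement is also rejected if
the spacer would contain a near-copy of the repeat, collide with the
anchor spacer, or fail to map uniquely (≤ 2 mismatches, both strands, all
replicons); a bounded number of failures raises a generation error naming
the mode. After all edits, every planted spacer is re-verified to map
uniquely.

What the generator does **not** emulate: indels and chimeric PCR products,
read-quality structure, PCR duplicates, biased protospacer sampling along
the replicon (real acquisition hotspots), and spacers whose flanks satisfy
several classes at once (real data contain genuinely ambiguous events; the
generator deliberately excludes them so that truth labels are exact).
Passing round-trip tests therefore demonstrates correctness of the
detection/classification chain, not robustness to every artefact of real
amplicon data.

Capacity note: events occupy disjoint ~50–56 nt windows, so the event
count must stay well below (total replicon length)/56; the large
validation runs (500 clones, ~800 events) use 100 kb / 30 kb / 76 kb
replicons — the virus sized like a fusiform *Sulfolobus* virus genome —
while routine use keeps the smaller defaults.

## Differential expression

RPKM = count / ((length/1000)·(total/10⁶)). Replicates are summed into
one pooled count per sample before testing, because the 2×2 chi-square
admits no replicate structure; a per-replicate log-RPKM correlation table
is emitted as a diagnostic instead. The test is the closed-form Pearson
statistic N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with 1 df, upper tail, no
continuity correction by default (counts are large; the correction is a
flag), cross-checked in tests against an independent contingency-table
implementation. A zero margin yields p = 1 with a warning. BH adjustment
uses the statsmodels step-up implementation. Fold-changes are
log₂(RPKM₁/RPKM₂) with 0.5 added to both RPKMs only when either is zero —
keeping fold-changes finite while leaving the raw RPKMs reported
untouched. FDR is applied to all tested genes, without pre-filtering.
The DEG flag is the conjunction p < 0.01 ∧ |log₂FC| > 1 ∧ q < 0.05 (all
thresholds configurable).

Note the BH step-up map is not idempotent (re-adjusting q-values inflates
them); the tested invariants are q ≥ p, q ≤ 1, and monotonicity in p-order.

## Numerical and validation choices

Percent rounding uses `decimal` half-up on exact rationals, not binary
floats. Validation sizes were chosen to keep the default suite and the
reproduction script to a few tens of seconds: 500-clone error-free and
400-clone noisy recovery runs, 100 oracle-equivalence instances (sizes
0.5–6 kb plus three at 20 kb), a 10,000-gene null calibration at ~10⁶
depth, and a 50-planted/950-null four-fold power simulation. Null
calibration of the chi-square at these depths sits within Monte-Carlo
error of the nominal 1% (the test band is [0.007, 0.013]).

## Known limitations

* No gapped alignment: an indel inside a spacer or repeat defeats the
  Hamming matchers (by design — substitution-only error model).
* Best-hit kind priority is a convention; cross-replicon exact duplicates
  are reported `ambiguous` and excluded from classification.
* The DEG caller inherits the chi-square's anticonservative behaviour at
  very low counts; it is faithful to the published procedure rather than
  to modern negative-binomial practice.
* De novo repeat discovery, read alignment/counting, and enrichment
  statistics on PAMs are out of scope.
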