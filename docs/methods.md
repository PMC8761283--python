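# Methods

## Coordinate frame

Every promoter is a window of `window_up` bases upstream and `window_down`
bases downstream of the TSS (defaults 120/120, configurable per run).
Relative coordinates follow the promoter-literature convention: the TSS
base is +1, the base immediately upstream is −1, and position 0 does not
exist. Sequences are stored in transcribed-strand orientation — for a
"−"-strand gene the window sequence is the reverse complement of the
reference slice — so motif and repeat analysis is strand-free downstream.
BED input/output is 0-based half-open, VCF is 1-based; all internal genomic
positions are 1-based and conversions happen only at I/O boundaries. A
window that would run past a contig end is an error, never a silent clip:
truncated windows would corrupt the relative frame.

The 120/120 default was chosen to cover, with margin, the span of
TSS-relative positions at which functional core promoter lesions are
typically reported (roughly −70 to +101 for the motifs and published
examples this package targets).

## The filtering cascade

Calls are ingested per (case, compartment) VCF with pysam; multi-allelic
records are split and alleles reduced to minimal representation (shared
suffix then prefix trimming, keeping one base per allele). Full
left-alignment against the reference is not performed: trimming suffices
for identity matching of already-normalized promoter-window calls, and the
synthetic generator emits minimal representations. Distinct-mutation
identity is (gene, relative position, ref, alt) after normalization —
operationally keyed by the equivalent genomic tuple.

Stages, in order, each logging input/removed/surviving counts:

1. **Origin.** A variant in a case's tumor but not its blood is somatic for
   that case; any blood presence makes it germline (blood-only variants are
   germline by definition — germline status *is* blood presence). A case
   counts as paired when both compartment files exist, even if one has no
   calls. Cross-case origin conflicts resolve by carrier majority, ties to
   germline (the conservative call).
2. **Polymorphism removal.** A population-panel entry carrying a MAF
   removes the matching mutation iff MAF > 0.01 (strict, so exactly 0.01
   survives); an entry without a MAF removes on presence alone.
3. **Novelty.** A mutation absent from every known-variant catalog
   (recognized tags: dbsnp, 1000genome, esp6500, exac, gnomad, cosmic,
   clinvar; plain site+allele TSVs) is novel; the cosmic-tagged catalog
   additionally drives the COSMIC-presence flag.
4. **Recurrence.** Mutations carried by ≥ 2 cases survive; carrier
   multiplicity is preserved so occurrence totals can be reported.
5. **Type and repeat context.** Equal allele lengths → substitution;
   longer alt → insertion; longer ref → deletion. The repeat flag is true
   iff the reference footprint ±1 bp overlaps a perfect tandem repeat (unit
   1–6 bp, ≥ 3 full copies, total length ≥ 6 bp) in the window. The ±1
   slack captures insertions adjacent to a run (e.g. a CT dinucleotide
   inserted at the edge of a CT track).

No genotype-quality or depth filtering is applied by default; the cascade
assumes upstream best-practice calling.

Summary percentages are 100·part/distinct rounded half-up to one decimal;
the per-case average is occurrences/cases rounded half-up to an integer.
Half-up (not banker's) rounding reproduces conventional table arithmetic.

## Motif catalog and gain/loss

Motifs are IUPAC consensus strings with an optional TSS-relative window
constraining where a match may start, and a strand policy. The shipped
defaults use standard literature consensi where they exist — BREu
`SSRCGCC` (−38..−32), TATA `TATAWAAR` (−31..−24), Inr `YYANWYY` (−2..+3),
TCT `YYCTTTYY` (−2..+2), MTE boxes `CSARC` (+18..+22) and `SSAACGS`
(+23..+27), DPE `RGWYVT` (+28..+32), DCE boxes `CTTC`/`CTGT`/`AGC`
(+6..+11, +16..+21, +30..+34) — plus a provisional DTIE placeholder
`RGGGA` (+20..+40) and the position-free, double-stranded Ets core `GGAW`.
Positional elements are sense-only because core promoter elements are
orientation-dependent; transcription-factor sites are scanned both ways.
DTIE and the MTE box split have no consensus definition in the element
literature; both are flagged provisional and the whole catalog is a flat
YAML file users can replace.

Mutation impact is called by full re-scan: apply the variant in the
relative frame (the frame re-anchors so the TSS stays +1; an indel wholly
upstream shifts `window_up` by the length difference), scan both sequences,
and diff hit sets by (name, start, strand). No attempt is made to "track"
motifs through an indel — downstream offsets legitimately shift, and the
re-scan comparison is the ground truth the tests also enforce. `located_in`
uses the defined window for positional motifs and actual hit footprints for
position-free ones.

Enrichment uses a uniform-placement null: drawing the observed number of
mutation positions without replacement from the frame's positions, the
count falling in a motif's window is hypergeometric; the reported p is the
upper cumulative tail, and a motif is enriched iff p < 0.05, overlap ≥ 1
and enrichment factor (observed/expected) > 1.5. The tail is validated
against full subset enumeration on small frames.

## Expression and luciferase statistics

The t-test is Welch's (unequal variance), two-sided, run on log2(x+1) by
default; `equal_var=True` restores pooled Student's and `log_transform`
exposes the raw scale, since neither choice is canonical for this analysis.
Fold change is computed on raw-scale group means with a pseudo-count of 1
(so genes silent in one group stay finite) and signed so magnitudes are
≥ 1: up is cancer/normal, down is −(normal/cancer). Significance is the
dual rule p < 0.05 ∧ |fold| ≥ 1.5. No multiple-testing correction is
applied — the dual rule is deliberately the raw-p convention of the
analysis this package reproduces; this is a known liberal choice and is
stated here prominently rather than silently corrected.

Luciferase replicates normalize as E_l = E_f/E_r (Renilla must be strictly
positive); arms need ≥ 3 replicates; the mutant/wild-type comparison uses
the same signed fold (pseudo-count 0 — activities are bounded away from
zero) and dual rule.

## Synthetic cohort: what it emulates and what it does not

The default generator mirrors the targeted study design: 77 cases with
matched blood, 30 promoters of 240 bp on alternating strands, planted
recurrent somatic mutations (2–5 carriers, including a substitution
engineered to create an Ets site from `GGCA` and a CT-dinucleotide
insertion into a planted CT track), recurrent germline mutations (including
an A>C at −60 converting a planted `CCCACC` to `CCCCCC`), singleton decoys
for the recurrence filter, polymorphisms with MAFs straddling 0.01 (0.05
and 0.02 filtered, 0.008 retained, one presence-only panel entry), and
catalog memberships exercising the novelty flags. Polymorphism carriers
are drawn binomially at probability 2·MAF per case (diploid presence
approximation — only presence matters to the cascade). Background
composition is uniform A/C/G/T; truth tables record realized carriers,
expected cascade outcome, and a repeat flag computed with an independent
substring-enumeration detector so the pipeline's run-based detector is
cross-checked, not self-confirmed.

Variant presence is exact by default — no dropout, depth or purity noise —
because the cascade consumes *called* VCFs and its correctness is a set
logic question. Consequently the planted-truth tests demonstrate the logic
is right, not that the method is robust to caller noise; real cohorts add
caller false negatives/positives this generator does not model.

Expression is log-normal per gene (natural-log σ = 0.15, a moderate
between-sample variability at which a multiplicative effect at n = 19 per
group is identifiable to ~±10%), with the cancer-group scale multiplied by
the planted factor; effect genes get a high baseline (log-mean 8) so the
pseudo-count does not bias the recovered ratio, which is the regime the
large published effects (7.5× up, 25.7× down) live in. Null genes share
one distribution across groups. Luciferase arms are triplicate with ~8%
multiplicative noise around a per-construct baseline, the mutant arm scaled
by the planted factor; ten constructs ship by default, five with real
effects (including a 4.8× decrease) and five null.

All generation flows from one `numpy` Generator seeded by the spec, and
same-seed regeneration is byte-identical.

## Problem sizes

Tests and the acceptance script run the full default cohort (77 cases ×
2 compartments × 30 promoters), 100 random 240-mers for scanner/oracle
equivalence, full subset enumeration up to C(30,8) for the hypergeometric
check, and a 600-gene null matrix for the type-I rate — sizes at which
every stochastic check is stable under reseeding.

## Known limitations

- Allele normalization trims but does not left-align against the
  reference; pathological redundant representations from external callers
  could evade identity matching.
- One promoter per gene: the "promoters affected" and "genes affected"
  summary rows coincide; bidirectional promoters serving two genes are not
  modelled.
- Enrichment treats mutation positions as independent uniform draws;
  mutational signatures and sequence-context biases are outside the null.
- The DTIE and MTE box definitions are provisional placeholders, and
  position-weight-matrix scoring is out of scope — the scanner is
  consensus-exact by design.
- The paired design assumes one tumor and one blood sample per case;
  multi-region or longitudinal sampling is unsupported.
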