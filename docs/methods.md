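# Methods

## Scope and coordinates

`cutfuse` analyses engineered chromosomal rearrangements produced by two
CRISPR/Cas9 double-strand breaks on one molecule: deletion of the
intervening segment or its inversion. All internal coordinates are 0-based,
half-open, on the plus strand; cut positions are *gap* coordinates (gap *k*
precedes base *k*). 1-based positions appear only in reports, matching the
convention of published indel tables. Circular molecules (plasmid
reporters) are supported throughout: site scanning doubles the sequence and
deduplicates modulo length, and window extraction wraps the origin.

## Cut-site model

A `CutModel(t, p)` cuts the sgRNA-complementary (target) strand `t` nt
upstream of the PAM and the PAM-bearing (non-complementary) strand `p` nt
upstream. `t` is fixed at 3 — complementary-strand cleavage at the third
nucleotide is the best-supported invariant of Cas9 biochemistry — while
`p` ranges over 3–8, the span reported for non-complementary-strand
cleavage. Since `p ≥ t`, every staggered break carries a 5′ overhang of
`p − 3` nt (0–5 nt); 3′-overhang geometries are rejected at model
construction. The overhang sequence is read 5′→3′ on the PAM-bearing
strand.

PAM classes are restricted to NGG (canonical) and NAG (weak), the two
classes relevant for these reporters — including sgRNAs that target LoxP
sites through an internal NAG PAM. `N` matches any base in the PAM
pattern; ambiguity codes in the reference never match a protospacer.

## Junction construction and repair enumeration

The canonical fusion junction assumes blunt `(3,3)` cuts and precise
ligation: deletion joins the two flanks directly (one junction), inversion
reverse-complements the segment (two junctions, 5′ and 3′, quantified
independently because each amplicon spans one fusion). The canonical
junction is the alignment reference; staggered geometries enter only
through repair enumeration.

Each break end is modelled by its blunt extent after end processing:

- **fill-in** — the recessed 3′ strand is extended across the 5′ overhang,
  so the fragment retains the overhang (extent at the overhang's outer
  gap). Because the complementary copy of the overhang also remains on the
  partner fragment, ligation duplicates it: a templated insertion equal to
  the overhang sequence (tandem duplication).
- **resection** — the overhang is trimmed (extent at the inner gap). Only
  the overhang itself is trimmed; longer deletions are attributed to
  generic NHEJ rather than modelled as progressive chew-back, keeping the
  mechanism space finite.
- **blunt ligation** — valid only for blunt cuts; reproduces the canonical
  junction.

A geometric consequence worth stating explicitly: the canonical gap always
coincides with the target-strand cut, so at any given junction an end whose
PAM faces the fusion shows insertions under fill-in and is neutral under
resection, while an end whose PAM faces away shows deletions under
resection and is neutral under fill-in. Per filled-in end the insertion is
at most 5 nt; a junction ligating two filled-in staggered ends can show up
to 10.

Variant junctions are represented as windows anchored at the canonical
outer boundaries, so each variant differs from the canonical window by one
contiguous indel; the indel token is derived by direct sequence comparison
with left-normalisation (shifted to the smallest anchor preserving the
alternate sequence, as variant callers do). `explain_indel` inverts the
enumeration and always appends a generic NHEJ-error explanation for 1–2 nt
events, because junction sequence alone cannot distinguish NHEJ errors from
alternative cleavage; the tool reports all consistent mechanisms and never
picks one.

## Read alignment and spectrum reports

Reads are aligned glocally (read global, reference local) with affine gap
scoring (defaults: match +2, mismatch −4, gap open −6, gap extend −1),
implemented over Biopython's `PairwiseAligner` with free reference end
gaps and an exact-substring fast path for error-free reads. Reads below
80 % identity (matches over read length) are unmapped. A read must overlap
the fusion by ≥ 10 nt on each side to count as junction-spanning.

Indels within ± 20 nt (configurable) of the fusion are left-normalised and
aggregated by (anchor, token). `VarFreq = var_reads / (ref_reads +
var_reads)` with `ref_reads` the spanning reads covering the anchor
without that indel; this two-allele definition is used because full pileup
depths across all alleles are not meaningful for an indel-centric junction
assay, and raw counts are always emitted so alternative denominators can
be recomputed. Mismatch-only reads count as reference at indel anchors.
Significance is a one-sided binomial tail P(X ≥ var_reads) at a
configurable per-base error rate (default 0.01) — a deliberate,
documented replacement for heuristic caller-internal tests; reported
p-values are not comparable to other callers'.

Two summary statistics follow the field's reporting style: the
*perfect-fusion fraction* (spanning reads with neither mismatch nor indel
inside the window — the precise-ligation estimate) and *indel
representation* (each token's share of all indel-supporting reads).
`recovered_spectrum` additionally gives the read-level outcome mixture
(indel-free / per-token / multiple), which is robust to substitution
errors and is what the simulation-recovery tests compare against.

## Synthetic data generator

The generator emulates the *structure* of three reporter designs — element
layout, PAM classes, site multiplicities, primer logic — not any real
plasmid or sgRNA sequence (those live in supplementary materials not
reproduced here, so fixtures are labelled synthetic):

- `igfp_like`: circular; promoter, reporter cassette in inverted
  orientation, flanking NGG guide sites, and two head-to-head LoxP-like
  34-nt sites (13-bp inverted-repeat arms, asymmetric 8-bp spacer) each
  carrying an internal NAG PAM hit by one guide.
- `lsl_like`: circular promoter–STOP–reporter with two *identical*
  same-orientation LoxP-like sites, so a single guide cuts twice and
  deletion removes the STOP cassette.
- `two_cut_locus`: linear, two NGG guide sites ~scale/2 apart. A
  multi-kilobase genomic region is emulated at 2–5 kb (default 3 kb):
  cut distance is a parameter and no modelled property depends on the
  literal size. Both guides sit on the minus strand so the deletion
  junction can display both indel classes (fill-in insertions from the A
  side, resection deletions from the B side), and four sgB protospacer
  bases are fixed to `GTAC` so every seed's canonical junctions read
  `…|AC…` at the fusion, making the standard demo spectrum (with `-A` and
  `-AC` tokens) applicable to any seed.

Read simulation draws single-end reads centred on the fusion with uniform
offset (the fusion stays ≥ 15 nt inside the read), applies the sampled
outcome token to the junction template, then per-base substitution errors.
The error model is substitution-only by default — isolating repair-derived
indels, which are the signal of interest — with an optional 1-nt
indel-error mode for stress tests. Read length 150 nt and error rate 0.001
are defaults in the range of Illumina amplicon data; paired-end data are
handled as independent mates. Editing pools sample event labels
(unedited/deletion/inversion) and repair mechanisms from configured
mixtures; a ligase-deficient condition is emulated purely as an inversion
rate of zero, not as a mechanistic model of NHEJ enzymology.

What passing tests show — and do not show — about real data: the
simulations demonstrate that the pipeline recovers a known outcome mixture
under its own error model (total-variation distance < 0.03 at n = 10,000)
and calls no spurious indels above 1 % from substitution error alone at
n = 100,000. They do not address PCR amplification bias (short products
amplify better), chimeric reads, context-dependent sequencing error, or
mapping competition against a whole genome, all of which affect real
amplicon data.

## Numerical and design choices

- Exact primer matching in in-silico PCR: the assay reproduces detection
  logic (which bands can exist and their sizes), not hybridisation
  thermodynamics or efficiency.
- Alignment tie-breaks: the aligner's first-reported optimum is used;
  indel placement is made deterministic downstream by left-normalisation,
  so ties never affect reported tokens or anchors.
- Off-target enumeration is an exhaustive Hamming scan with a PAM filter —
  a transparent stand-in, not a reproduction of any published off-target
  predictor, and deliberately unscored (no CFD/MIT weights).
- Deterministic outputs: all randomness flows through explicit integer
  seeds (`numpy.random.default_rng`); two runs with identical config and
  seed are byte-identical except the run-log timestamp.
- Degenerate inputs: empty PAM-class sets, overhang-incompatible repair
  modes, deletion tokens absent from the junction, windows that exceed
  linear sequence ends, and zero-read pileups are all rejected or reported
  empty with explicit semantics rather than silently coerced.
- Problem sizes in the test and acceptance runs (3 kb locus, 10,000 reads
  for spectrum recovery, 100,000 for the error-only null, 500 alignment
  oracle cases) were chosen as the smallest scales at which the binomial
  tolerances are meaningful.

## Known limitations

- The mechanism space is deliberately small: no microhomology-mediated end
  joining, no HDR, no probabilistic weighting across mechanisms (the data
  cannot identify weights), and resection limited to the overhang.
- Indel calling is junction-centric: substitutions are not called as
  variants, multi-allelic interactions are ignored, and reads carrying
  multiple indels count once as non-precise.
- In-silico PCR requires exact matches, so primer-design errors that would
  merely weaken a band in practice abolish it here.
- The LoxP-like sites are structural emulations; analyses requiring the
  true LoxP sequence must supply it.
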