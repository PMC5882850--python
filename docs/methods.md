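# Methods

This note documents the models and procedures implemented in `optoxr`, the
parameters that matter and why their defaults are what they are, what the
synthetic-data generators do and do not emulate, and the numerical choices
made where the design was genuinely open.

## 7TM topology model

A seven-transmembrane protein is modeled as an ordered 15-segment partition
— Nt, TM1, IL1, TM2, EL1, TM3, IL2, TM4, EL2, TM5, IL3, TM6, EL3, TM7, Ct —
with the N-terminal side of the membrane declared by the caller (default
extracellular, true of both channelrhodopsins and GPCRs). Loop labels follow
by alternation: with an extracellular N-terminus the loop after TM1 is
intracellular. Orientation is an input, not an inference; no positive-inside
rule is applied.

Transmembrane helices are detected on a windowed-mean Kyte–Doolittle
hydropathy profile. Windows are truncated at the sequence ends (means over
the residues actually present) rather than padded, so no hydropathy is
fabricated at the termini. Candidate helices are the maximal runs of the
profile at or above a threshold; runs separated by fewer than `min_loop_len`
positions are merged, runs shorter than `min_tm_len` are dropped, and runs
longer than `max_tm_len` are split at their interior profile minimum. A
candidate count other than seven is a loud failure carrying the candidate
list — segment identity decides what gets spliced, so silently keeping the
"best 7" would be dangerous.

Defaults and rationale:

| parameter      | default | unit     | rationale |
|----------------|---------|----------|-----------|
| `window`       | 9       | residues | must resolve the shortest GPCR loops (~8 aa). A window wider than roughly twice the loop length can never dip below threshold inside the loop, fusing adjacent helices; at width 9 the profile tracks helix edges to within about one residue. |
| `threshold`    | 0.2     | KD units | near the midpoint of the hydropathy contrast between helix and loop residues. The windowed profile crosses the midpoint at the true helix edge; a threshold deep inside the hydrophobic range (e.g. the classical 1.6 used with 19-residue windows for coarse scans) shifts every detected edge several residues into the helix. |
| `min_tm_len`   | 15      | residues | shorter runs cannot span a bilayer |
| `max_tm_len`   | 30      | residues | longer runs are two fused helices |
| `min_loop_len` | 4       | residues | below this, adjacent runs are one helix interrupted by noise |

The classical wide-window settings remain available for exploratory scans of
long-loop proteins; they are not suitable for boundary-accurate calls.

### Family consensus

Boundary calls can be refined over a homolog family. Each homolog is aligned
to the reference by a star multiple alignment (below), its 14 internal
boundaries are projected into reference coordinates, and each reference
boundary is replaced by the median of all votes (reference included). The
median, not the mean, keeps boundaries integral and shrugs off one divergent
homolog; ties on even vote counts round toward the reference's own call,
which avoids a systematic half-residue drift. Votes landing on a reference
gap are skipped with a logged notice. The result is clipped to preserve
segment order and minimum TM lengths.

## Alignment

Pairwise alignment is global (Needleman–Wunsch) with affine gap costs in a
three-state dynamic program; a gap of length L costs
`gap_open + (L−1)·gap_extend`. Defaults BLOSUM62 / 10 / 1 are conventional
and configurable; nothing downstream is sensitive to them for the close
homolog families this workflow aligns. Terminal gaps are penalized like any
others — domain boundaries near the termini (the C-terminal splice) matter,
so end gaps must compete on cost. Traceback ties break deterministically
(diagonal > up > left) so outputs are bit-reproducible.

The multiple alignment is a star around the reference: every homolog is
aligned pairwise to the reference and reference-row gap structures are merged
("once a gap, always a gap", taking the per-slot maximum). A guide-tree
progressive MSA would give prettier columns between homologs, but the only
consumer is homolog→reference coordinate transfer, which the star
construction makes exact by design.

## Chimera assembly

A swap specification names which of {IL1, IL2, IL3, Ct} to take from the
target (default: all four — the full intracellular signaling surface). Splice
junctions sit exactly at the backbone's TM boundaries: the backbone's helices
carry the light-sensing function and are never cut. Unequal loop lengths are
expected and unpadded; the chimera simply changes length. An optional
per-junction offset can retain backbone anchor residues at a splice edge
(default 0); whether real constructs keep such anchors varies, so the tool
exposes the choice instead of asserting one. The retinal-binding lysine of
channelrhodopsin backbones lies in TM7, which is never swapped; a warning is
emitted if an offset touches a TM. Every part records its source and original
coordinates, so a design can be re-spliced idempotently and rendered as a
per-residue provenance track.

## Cassette compilation

Back-translation uses per-amino-acid relative codon-usage tables. The default
host is Mus musculus, the usual expression animal for AAV-delivered opto-XR
constructs; the table is data (two-column text: codon, frequency) and any
host can be substituted, with the host recorded in output metadata.
Deterministic mode takes each residue's highest-frequency codon (ties broken
alphabetically — byte-reproducible); sampled mode draws codons proportionally
to usage under a seed, for sequence diversity across synthesis orders.

Restriction-site removal is iterative and leftmost-first: one codon
overlapping the offending site is replaced by its next-most-frequent synonym,
translation unchanged by construction, until no hits remain on either strand
(or a forced Met/Trp codon makes a site unresolvable, which is an error
naming the position). Protected intervals are exempt: the default
direct-fusion linker `GCGGCCGCC` (Ala-Ala-Ala) deliberately contains a NotI
core useful for cloning and must survive the audit.

Reporter fusion has two styles. Direct fusion appends the in-frame linker and
the reporter with its initiator codon deleted, then exactly one terminal stop
(default TAA, configurable): one uninterrupted reading frame, enforced by
translation after assembly. The bicistronic style joins the receptor ORF, a
self-cleaving 2A peptide, and the reporter with its initiator retained — the
layout of hSyn-MCS-T2A-reporter AAV vectors. No particular 2A sequence ships
as a default; it is an explicit input. A terminal stop on the incoming ORF is
stripped with a logged notice (a fusion cannot read through a stop). Kozak
insertion is available as an element role but off by default. The final
cassette is flanked by cloning sites (KpnI upstream, BamHI downstream by
default), carries the promoter as annotation (vector backbones are named,
not reconstructed), and round-trips through GenBank with one feature per
element. GenBank LOCUS dates are pinned to a constant so identical designs
serialize identically.

## Primer design and qPCR

In-silico PCR finds every convergent primer-pair match on either strand:
each primer may carry at most `max_mismatch` (default 2) mismatches but its
3'-terminal `three_prime_exact` (default 5) bases must match exactly —
polymerase extension is launched from the 3' end, so terminal mismatches
kill amplification; products are capped at `max_product` (default 2000 nt).
These conservative screen settings stand in for the melting-curve
confirmation a wet lab would run.

The junction designer places the forward primer across the splice point with
at least `junction_anchor` (default 6) bases on each side, so neither parent
alone can template it, and the reverse primer downstream within the amplicon
bounds (80–300 nt default, standard for SYBR qPCR). Candidates are ranked by
forward/reverse Tm balance, then combined GC distance from 50%, and screened
in rank order; the first pair with ≥1 junction-covering product on the
chimera and 0 products on every parent is emitted. The designer can never
disagree with the screener — the screen is the acceptance condition.
Melting temperatures use the Wallace rule (2(A+T)+4(G+C)) below 14 nt and
the simple GC formula (64.9 + 41(GC−16.4)/N) otherwise; this ranks
candidates adequately, and nearest-neighbor thermodynamics is a listed
extension. Primer-dimer/hairpin screening and transcriptome-scale off-target
search are out of scope.

Relative quantification is the uncorrected 2^(−ΔΔCt) method: Ct replicates
are aggregated by arithmetic mean (the standard for this method), ΔCt is
target minus reference within a sample, ΔΔCt subtracts the calibrator, and
the fold change is 2^(−ΔΔCt). No amplification-efficiency correction is
applied.

## Synthetic data

The generators produce what the real workflow consumes, with ground truth
attached. 7TM proteins are built segment by segment: TM residues from the
hydrophobic alphabet {A,I,L,V,F,M,W,C} with helix-like weights (I/L/V/F
dominant, W and C rare), loops and termini from the hydrophilic alphabet
{D,E,K,R,S,T,N,Q,G,P,H,Y} weighted toward charged residues. With these
compositions the windowed TM hydropathy clears the calling threshold with a
wide margin — the margin is asserted by a test on generated fixtures, not
assumed. Default segment sizes: TM 18–25 aa, loops 8–40 aa, Nt 30, Ct 60,
spanning the short-loop regime that makes topology calling hard.

Homolog families apply i.i.d. point substitutions only (no indels), by
default class-preserving (substitutions stay within the segment's alphabet).
This keeps homolog→reference coordinate transfer exact and isolates the
consensus logic from alignment quality; an indel mode is a listed extension.
qPCR tables place the reference gene at a constant Ct and the target at the
calibrator's Ct minus log2(fold), plus Gaussian noise, so noise-free tables
invert exactly under 2^(−ΔΔCt).

What passing tests on these fixtures do **not** show: recovery on real
sequences, where loops contain hydrophobic residues, helices contain polar
ones, families have indels, and published boundary calls come from curated
alignments. The tool therefore exposes every boundary as data (BED-like
text) so users can override calls with published cut points. No attempt is
made to mimic real channelrhodopsin/GPCR composition statistics, and the
synthetic reporter CDS is a shape stand-in (initiator, open frame, one stop),
not a real fluorophore sequence.

Derived seeds come from `numpy.random.SeedSequence(seed).generate_state(k)`
masked to 31 bits, so one top-level seed reproduces an entire scenario.

## Problem sizes and determinism

The test suite and the acceptance script run at the sizes the properties
need and no more: 100 synthetic proteins for topology recovery, exhaustive
length-≤2 pairs plus 200 sampled length-≤6 pairs against the enumeration
oracle, 500 codon round-trips, 100 planted-site ORFs, 20 parent/chimera
primer scaffolds, 50 in-silico PCR oracle instances, 200 noisy qPCR tables.
Everything is seeded; two pipeline runs from the same manifest inputs are
byte-identical, which the suite checks by hashing output trees.

## Known limitations

- Topology calling is hydropathy-only; no machine-learned predictors, no
  signal-peptide handling, and no re-derivation of any published construct's
  exact cut points.
- Local alignment and nucleotide alignment are out of scope; the star MSA is
  reference-centric by design.
- No structural modeling, expression or trafficking prediction for the
  chimera; loop-length compatibility is the user's judgment.
- No mRNA secondary-structure or GC-window optimization, and no
  synthesis-vendor constraint screening.
- The qPCR module assumes equal amplification efficiency between target and
  reference assays.
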