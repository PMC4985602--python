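# Methods

## Study design being emulated

A bacteriocin-sensitive wild-type strain and a panel of ten
independently selected resistant mutants are whole-genome sequenced
(250-nt paired-end reads). Because no finished reference exists for the
target strain, reads are compared against a crude draft assembly built
from the wild type's own reads. Differences are then screened: those
the wild type shares with the mutants are assembly errors by
self-comparison; those shared by several mutants in low-coverage
assembly regions are unreliable consensus; the survivors are verified
site-by-site and attributed to genes. The gene that accumulates
independent mutations across all resistant isolates is the candidate
bacteriocin target — here an APC-superfamily amino
acid–polyamine–organocation transporter with 12 transmembrane helices
and a 610-residue product.

All inputs are synthetic and carry a machine-readable truth manifest,
so the pipeline's sensitivity and precision can be scored exactly.

## The synthetic genome and mutant panel

`synthdata.build_genome` produces a 50 kb, 5-contig genome by default
(a "large" profile scales the same generator to 1.59 Mb / 243 contigs;
it is not the test default — test and acceptance runs use the desk
scale so the whole suite completes in well under a minute of mapping
time per strain). Coordinates are 1-based inclusive everywhere.

The focal gene is engineered codon-by-codon, not random:

- 1,833 nt (610-aa product) placed at contig positions 2209–4041 of the
  middle contig, so its printed-style coordinates match the analysis
  convention used in reports;
- reference codons fixed at the seven mutation sites
  (104 CGA, 177 TTC, 377 GCG, 387 TCT, 395 TGG, 425 ATG, 428 CAT), so
  the study's mutation archetypes hold exactly: C→T at codon 104 gives
  TGA (truncation after 103), G→A in codon 395 gives TGA (truncation
  after 394), and a T inserted in the TT run of codon 177 gives TTTC
  (frameshift);
- codons 190/191 fixed (GCT, AAA) so the +1 frame entered at codon 177
  reads through to its first stop exactly after residue 190; all other
  codons end in C or G, which keeps both the coding frame and the
  +1 frame between codons 177 and 190 stop-free by construction. The
  downstream sequence after a real frameshift is not publishable from
  the study, so the 190-residue truncation is a property of this
  engineered fixture, validated on it.

Background genes are stop-free random ORFs (300–1,503 nt) with an
in-frame stop placed immediately 5′ of each start codon, which makes
every placed gene a maximal ORF recoverable with exact bounds by the
ORF finder. Repeats are two 800-bp copies at ≥ 95 % identity
(default 97 %), the classic cause of assembly consensus errors.

The canonical mutation panel (`study_mutation_specs`) assigns the seven
focal mutations to strains as in the study design (JK4/5/6 and JK8/9
behave as clonal groups; JK3 carries only its focal mutation) plus 18
background substitutions scattered over well-assembled unique sequence.
Background sites deliberately avoid repeats and low-coverage assembly
patches: a true mutation shared by several strains inside a
low-coverage region is *by design* indistinguishable from an assembly
error under this filtering scheme (that is the method's blind spot),
and the emulated scenario mirrors the study outcome in which the causal
gene lay in well-covered sequence (13–45×).

## Read simulation and crude-assembly emulation

Reads: 250 nt paired-end, 50× default coverage, insert 550 ± 40 nt,
uniform i.i.d. substitution errors at rate 0.005. Indel sequencing
errors are not simulated — length-changing alleles in this model come
from the genome, not the sequencer — so indel evidence in pileups is
attributable to true variants. Each fragment contributes one forward
and one reverse read, making per-site strand sampling binomial(0.5).

The crude assembly copies the truth genome and then corrupts it the way
draft assemblies are corrupted: scattered patches (3 % of positions by
default) have their reported coverage collapsed to 1–5× (against a
Normal(50, 50/8) background track), and consensus errors
(substitutions, rate 0.01 within eligible positions) are injected only
inside those patches or inside repeat-derived sequence. The focal gene
is kept clear of low-coverage patches, emulating the study situation
above. The coverage track and error positions are exported for the
filter stage and for truth scoring.

## Mapping and calling

The mapper indexes all contig k-mers (k = 21) and seeds each read with
non-overlapping k-mers; seed hits voting for the same diagonal (± 1, to
tolerate a 1-bp indel) form candidate loci, which are scored by
edit-distance alignment (edlib) constrained to ≤ 5 mismatches and at
most one 1-bp indel per 250-nt read — sufficient because the variant
model is SNVs and 1-bp indels. Ties between equal-scoring loci are
broken by lowest (contig, position) for reproducibility and recorded in
a `unique` flag; pileups drop non-unique alignments by default,
mirroring the exclusion of repeat-confounded evidence. Reads whose
alignment would overhang a contig edge are discarded rather than
clipped. Note the mismatch budget is a per-read cap: at error rates
approaching 0.01 a few percent of reads exceed it, so the ≥ 99 %
mapping-rate property is stated at the default error rate.

Indels are left-normalized to the start of their homopolymer run: an
insertion is reported at the first base of the run with
alt = ref + inserted base (so a TTC→TTTC event reports at the first T),
a deletion at the first deleted-run base with an empty alt.

Calling scans only pileup positions carrying non-reference events: the
majority non-reference allele is emitted when its fraction is ≥ 0.8 at
depth ≥ 10. Calling is deliberately looser than verification (0.9) so
the filter stage — the decision point of the method — does the
excluding. Mixed sites below the calling fraction are treated as
absence: the organisms are haploid and sub-clonal signal is noise here.
Merging across strains unifies records identical in (contig, position,
ref, alt); headline metrics come from the deepest strain, with
per-strain detail retained.

## Filtering policy

Defaults, all swappable through `FilterPolicy`:

| parameter | default | meaning |
|---|---|---|
| `low_coverage_max` | 5× | assembly coverage at/below which consensus is unreliable |
| `shared_strain_min` | 2 | mutants sharing a low-coverage hit to trigger exclusion |
| `verify_min_depth` | 20 reads | minimum site depth (scaled to desk coverage; a declared choice) |
| `verify_min_alt_fraction` | 0.9 | alternate allele in ≥ 90 % of reads |
| `strand_balance_alpha` | 0.01 | two-sided binomial(0.5) level for strand balance |

Exclusion reasons are evaluated in a fixed order (wild-type-shared,
then low-coverage, then verification) and a record is attributed to the
first reason that fires, which makes the 11/11/36-style accounting well
defined even when a record satisfies several rules. "Both strands
equally represented" is operationalized as a binomial test — the
underlying study verified this by inspection, so the test choice is a
policy decision. Its per-site false-rejection probability (< α = 0.01)
means that across a panel of ~25 true sites one occasionally loses a
genuine mutation to a chance strand skew; this is a faithful property
of the verification scheme, visible at some seeds and scales.

The 58-record difference fixture reproduces the published accounting
exactly: 11 records present in the wild type at coverage 1–5×, 11
shared among mutants in low-coverage positions, and 36 retained records
carrying the printed contig labels, positions, assembly coverages,
strain-presence matrix, and annotation strings. The 22 excluded records
are not individually published, so their positions and alleles are
synthesized; only their counts and flag structure are faithful, and the
two excluded groups are disjoint (the publication does not say whether
they overlap). Read-level metrics for all 58 (depth 154–484×, balanced
strands, alt fraction ≥ 0.92) are synthesized deterministically from a
fixed internal seed — the fixture is a constant dataset, not a
simulation. One printed record lacks an assembly-coverage value; the
low-coverage rule therefore checks the sharing condition first and only
demands coverage for records shared widely enough to be excludable.

## Consequence annotation

Codon arithmetic: forward strand codon = ⌊(pos − start)/3⌋ + 1, reverse
strand ⌊(end − pos)/3⌋ + 1; protein length = span/3 − 1. Substitutions
are classified by translating the reference and alternate codons
(table 11); nonsense sets truncation_after = codon − 1. Insertions are
assigned to the codon containing the first inserted base, with
homopolymer-run awareness so that the caller's left-normalized anchor
and a printed-table anchor inside the run resolve to the same codon.
Frameshift truncation points come from translating the actual mutant
sequence from the gene start to the first stop (continuing past the
nominal gene end if needed; running off the contig is flagged); a
combination of records that restores the frame before any shifted stop
is flagged `in_frame_restored` instead. Variants outside genes are
intergenic, or `downstream_proximal` when within 50 nt past a gene's 3′
end (covering "just downstream" annotations such as 6-nt offsets).
Annotation strings follow the report grammar
`REF-ALT = <codon><refAA>-<altAA|stop|frameshift> in <gene>`.

ORF discovery uses starts ATG/GTG/TTG and stops TAA/TAG/TGA on both
strands, reporting maximal ORFs (first start per stop frame,
≥ 300 nt default); supplied GFF gene models bypass it.

## Topology

Kyte–Doolittle hydropathy with a centered window of 19 (ends shrink the
window), threshold 1.6, minimum run 15, maximum helix 30 (longer runs
split recursively at the internal minimum, with both halves kept
≥ 15) — the classical sliding-window parameters, declared here because
the original prediction tool is proprietary. The N-terminus defaults to
cytoplasmic, the usual orientation drawn for APC-family transporters,
and loop sides alternate from there. Helix intervals may also be
supplied directly (TSV), decoupling localization from the predictor.

The engineered 12-helix fixture protein (610 aa) interleaves strongly
hydrophobic stretches (I/V/I/L) with a mildly polar background at
designed intervals chosen to match the transporter's architecture: the
truncation points 103, 190, and 394 fall between helices 2–3, inside
helix 5, and just after helix 10 (removing 10, 7, and 2 helices), the
helix-10 interval contains residues 377 and 387, and the loop between
helices 11 and 12 — extracellular under the alternation — contains 425
and 428. Truncation points in the first half of a loop are described as
"after TM helix N" (the chain has just cleared that helix), in the
second half as "between TM helix N and N+1"; both phrasings appear in
practice and the midpoint rule makes the choice deterministic. The real
protein's helix boundaries are not machine-readable from the
publication figure, so localization claims are validated on this
fixture, not on the biological sequence.

## MIC assay

Inhibition is control-relative:
1 − (OD − blank)/(OD_control − blank), clamped to [0, 1]; the 50 %
threshold is applied to this control-relative growth (the alternative —
endpoint OD — is not used). MIC interpolates the crossing linearly in
log2 concentration, natural for a two-fold ladder; reported values are
"about" values, so half-step accuracy is the contract. Curves are
expected monotone; wobble beyond 0.1 flags the result and the first
downward crossing from the top concentration is used. No crossing means
a censored MIC (above top / below bottom), and censored values never
enter fold ratios silently — they yield directional bounds
("> top/wildtype"). The replicate spread is the half-range of replicate
ratios rounded to one significant figure (the publication's ± is not
defined; this is a declared choice). The simulated plates use a sharp
Hill response (slope 6) crossing 0.5 at the true MIC with Gaussian OD
noise (σ = 0.02); the fold scenario (wild-type MIC 0.5 nmol/L; mutants
100–600×) supplies the true MICs — measured plate data are wet-lab
quantities and exist here only as scenario parameters.

## What the synthetic data do and do not show

The generators reproduce the *statistical structure* of the study —
coverage, error regime, the geography of assembly errors, the mutation
archetypes, the filtering accounting — not its biology. Passing tests
demonstrate that the pipeline's logic is correct under these
conditions: that self-comparison plus coverage filtering separates
injected truth from injected artifacts perfectly at desk scale, that
codon/truncation arithmetic matches the printed values, and that MIC
recovery is accurate to within an interpolation step. They do not
demonstrate performance on real MiSeq error profiles (non-uniform,
indel-containing), real assembler behavior, structural variants,
plasmids, or the biological identity of any receptor. The full-scale
run (1.59 Mb, 243 contigs) is exposed as a profile but not exercised in
tests; results at that scale would additionally stress repeat content
that the two-repeat default does not represent.

## Numerical and degenerate-input choices

- All randomness flows through `numpy` Generators seeded from a single
  run seed via `SeedSequence`; identical seeds give byte-identical
  outputs (the run report records the seed and a hash of the scientific
  configuration, excluding output paths).
- Score ties in mapping break to the lowest (contig, position); the
  ambiguity survives in the `unique` flag rather than being hidden.
- Empty inputs: empty record lists filter to empty results with zero
  counts; a contig shorter than k is skipped from the index with a
  warning; unmapped is a valid mapper return, not an error.
- Failed assays (growth control ≤ blank) raise rather than return
  fractions; alignment past a contig end is rejected and logged.
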