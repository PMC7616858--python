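# Methods

## Setting

A base-editing saturation-mutagenesis screen tiles one gene with sgRNAs
for NGN-PAM adenine and cytosine base editors. Each guide, once the
editor is induced, installs one or more single-nucleotide changes inside
its editing window; cells carrying deleterious variants of a gene that
is required for growth (here, a WRN-like gene in an MSI background)
drop out of the pool between the baseline (T0) and the endpoint. The
package turns (a) a gene model plus guide library into predicted edits
and protein consequences, and (b) count tables into per-guide depletion
scores and per-residue essentiality maps.

## Gene model

Internally all genomic intervals are 0-based half-open; GFF3 I/O uses
1-based inclusive coordinates, and protein residues are 1-based.
Validation enforces sorted non-overlapping exons, CDS containment, frame
(length divisible by 3), absence of internal stops, a terminal stop, and
canonical GT..AG intron cores on the coding strand. Non-canonical splice
dinucleotides are an error for synthetic fixtures (which guarantee them)
but only a warning for user-supplied annotations, where they legitimately
occur. The reference is treated as wild type: no sample-specific variants
are applied before edit prediction.

## Edit prediction and consequences

An editor is a conversion (A→G or C→T on the protospacer strand), an
inclusive window over protospacer positions counted 1..20 from the
PAM-distal 5′ end, and a PAM pattern. The window defaults to **4–8**:
the editors being emulated are high-activity NGN variants and 4–8 is the
conventional high-activity window; because results depend on it, it is a
visible configuration parameter recorded in every run manifest, not a
constant.

*Combined* predictions convert every editable window base at once — the
pessimistic bystander assumption, and the annotation used for scoring.
*Individual* predictions enumerate single-base outcomes for reporting.

Consequences are resolved by applying the edits to the contig,
re-translating the affected coding sequence, and assigning the single
most disruptive class, with priority

```
splice_donor = splice_acceptor > nonsense > start_loss > stop_loss
    > missense > synonymous > promoter > intronic > no_edit
```

Splice calls are restricted to the canonical 2-nt GT/AG cores; extended
splice-region annotation is deliberately out of scope. Disrupting both a
donor and an acceptor reports the donor. A synonymous call lists the
affected codons with unchanged amino acids so that "which residues the
guide touched" is never lost. `installs_proline` flags any change whose
new residue is proline, since proline introduction is a plausible
misfolding mechanism even inside otherwise tolerant domains. Promoter
edits are classified `promoter` with no protein change — the library
tiles promoters, but promoter-variant effects are not modelled further.

Correctness is not argued but measured: a brute-force oracle in the test
suite mutates the whole contig, re-extracts and re-translates the entire
CDS and diffs the proteins, and the implementation must agree exactly on
1000+ random guide/contig/editor triples, including minus-strand genes
(strand symmetry is tested separately).

## Scoring

Per sample, `RPM = (count + ψ) / Σ(count + ψ) × 1e6` with pseudocount
ψ = 1 applied to **raw counts before normalisation** (the emulated
protocol states a pseudocount without value or placement; raw-count
placement keeps RPM sums exactly 1e6 and is the common convention).
RPM values are averaged across replicates within each timepoint;
`L2FC = log2(RPM_end / RPM_T0)`; z standardises L2FC against its
standard deviation over the passing guides of one screen (one screen =
one cell line × one editor; sample sd, n−1). Mean-centering is on by
default; `center_z=false` reproduces the literal divide-by-sd reading.
The read floor discards guides with **mean** raw T0 reads strictly below
100 ("fewer than": 100 passes, 99 fails); the mean-of-replicates choice
is configurable in spirit via the params object but fixed here as the
default because the emulated protocol says only "initial samples".

Control QC reports median z per control category and the rank AUROC
(Mann–Whitney) separating essential-stop from non-essential-stop
controls — the probability that a random essential control is more
depleted.

## Residue maps and enrichment

Passing guides with protein-altering consequences contribute their z to
every residue they change; splice guides contribute to the exonic
residue flanking the disrupted boundary (a display convention — splice
hits remain identifiable by consequence); edits of the terminal stop
codon are displayed on the last residue. Synonymous, intronic, promoter
and no-edit guides contribute nothing. The default aggregate is the
**minimum** contributing z: one strongly depleted guide suffices to mark
a residue intolerant (mean aggregation is available). A residue is a hit
when its aggregate is ≤ −2; uncovered residues carry a null call,
distinct from "not a hit", because absence of guides is not evidence of
tolerance.

Domain enrichment is the one-sided hypergeometric tail P(X ≥ hits_in)
over the universe of guide-covered residues only, applied identically to
domain tracks and pathogenicity-class tracks (e.g. AlphaMissense
classes, supplied as input). Exactness is verified against exhaustive
enumeration of all 2×2 tables with universe ≤ 12.

Cross-screen concordance is Pearson r and r² over guides passing filters
in both screens; the sign is reported alongside r².

## Synthetic data generator

The generator emulates the screen design it is meant to test: a
WRN-sized gene (8 exons × 540 bp → 1439 residues) with promoter and
canonical introns; every NGN guide overlapping exons or promoter
(~2400); control categories at the emulated library's sizes (57
non-targeting, 168 intergenic, 307 essential-stop, 87
non-essential-stop); two editors, two cell lines, two replicates; and
1000× expected T0 coverage per guide.

**Effect model.** A set of essential residues — by default 10% of the
protein, placed uniformly over the interior — defines the truth. A
guide is deleterious in an editor's screen iff its combined edit changes
at least one essential residue (splice guides via the flanking residue),
with true L2FC = −2 × efficiency, where per-guide efficiency ~
Beta(5, 2) models variable editing activity and is a property of the
guide (shared across cell lines). Essential-stop controls deplete at
−3 × efficiency; all other categories and consequence classes are
exactly neutral. Effects are step functions of residue essentiality; no
per-residue dose gradation by default. Uniform placement of the
essential set matters: it keeps two independently drawn truths actually
independent, which the concordance specificity check relies on. A
narrowed `essential_domain_span` (e.g. a helicase-like core) is available
to emulate domain-concentrated intolerance for enrichment demonstrations.

**Noise model.** Per screen, T0 abundances are lognormal around the
coverage (σ = 0.3, mean preserved); endpoint means are
`T0_share × 2^true_L2FC × depth`; counts are negative binomial with
`var = μ + αμ²`, independent per replicate. The default dispersion is
**α = 0.01** (count CV ≈ 10% at 1000× coverage), typical of well-powered
pooled screens; the parameter-recovery verification deliberately runs at
the harsher α = 0.1 with only 20 essential residues to show recovery
survives heavy overdispersion and sparse signal. All draws flow from one
seeded generator: a config is its own replay instruction.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: editing-efficiency structure learned from
sequence, position-dependent within-window editing rates, off-target
effects, infection/selection population dynamics (absorbed into T0
abundance), guide-level PCR jackpotting beyond NB overdispersion, and
any genome beyond a single wild-type gene. Real screens also violate the
step-function effect model (partial-function alleles).

## Verification quantities and problem sizes

`scripts/acceptance.py` recomputes, at the sizes given: oracle agreement
(≥1000 triples on 3-exon genes), scoring max relative error (100
matrices of 50 guides × 4 samples), the read-floor boundary (6
constructed guides), ground-truth recovery (default-scale study, ~3000
guides, 20 essential residues, dispersion 0.1, both editors of one cell
line), concordance medians (10 seeds, single-editor studies on targeting
guides), enrichment exactness (all 1635 tables with universe ≤ 12), and
pipeline determinism (a reduced 3-exon study re-run from its emitted
manifest). The 10-seed concordance block uses single-editor simulations
because the property is per-editor and the second editor would double
runtime without adding information. Concordance is computed on targeting
guides: control guides deplete by category in *any* screen, so including
them would manufacture correlation even between screens with unrelated
truths.

## Numerical and degenerate-input choices

Pseudocount > 0 is required (a zero pseudocount with an all-zero sample
would divide by zero). Fewer than 3 passing guides, an empty control
category, an empty enrichment universe, fewer than 3 shared guides in a
concordance, dispersion < 0, and non-frame CDS lengths are all hard
errors that name the offending object. Ranking ties in control-guide
selection break lexicographically by guide id; AUROC ties count 1/2.
Scoring keeps L2FC for filtered guides but leaves z undefined (NaN)
for them. Pipeline outputs carry a commented header with package version
and a config hash (paths excluded), and re-running any stage from the
emitted run manifest is byte-identical — this is asserted in the tests,
not merely intended.

## Known limitations

Single-transcript gene models only; no isoform resolution. Splice
annotation ignores non-canonical sites and splice-region (non-core)
variants. The consequence classifier assumes substitutions only (base
editing makes no indels). SpliceR-style disruption scores and
AlphaMissense pathogenicity are inputs, never recomputed. No
MAGeCK-style gene-level tests: the unit of inference here is the residue,
via minimum-z aggregation, which is deliberately sensitive (one strong
guide calls a hit) and correspondingly exposed to single-guide artifacts
— the per-residue guide count and raw contributions are always reported
so downstream users can require deeper support.
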