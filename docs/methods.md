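# Methods

This note records the models behind each stage, the tunable parameters
and their defaults, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## XYLP membership rule

A protein is accepted as a xylogen-like protein when three conditions
hold simultaneously.

**PAST-rich regions.** "Region" is made precise as the union of all
qualifying windows: a window of length ≥ `l_min` (default 20 residues)
qualifies when its Pro/Ala/Ser/Thr fraction is ≥ `theta` (default 0.35,
inclusive; `X` counts in the denominator only).  Positions covered by any
qualifying window are merged into maximal runs and each run is reported
with its own PAST fraction.  Two consequences are worth knowing. First,
because long diluted windows can still clear the threshold, a merged
region may extend well beyond the dense core and its *overall* fraction
may fall below `theta` even though every contributing window was above
it; the fraction is therefore reported as data, not enforced as an
invariant.  Second, the definition is directly checkable against a
brute-force oracle (enumerate every window, take the union), which the
test suite does on hundreds of random sequences.

**AG glycomodules.** Every occurrence of the six dipeptides AP, PA, SP,
PS, TP, PT whose first residue lies inside a PAST-rich region.
Overlapping occurrences are all counted; no de-duplication rule is
applied because none is biologically motivated.

**nsLTP scaffold.** Eight cysteines in order with hard constraints —
C3 and C4 adjacent, exactly one residue between C5 and C6, at least one
proline strictly between C2 and C3 — and soft constraints on the
remaining spacers, configurable with defaults C1–C2 ∈ [5, 15],
C2–C3 ∈ [8, 20], C4–C5 ∈ [5, 30], C6–C7 ∈ [10, 30], C7–C8 ∈ [3, 20]
residues, chosen to span canonical plant nsLTP domains.  The matcher
returns the lexicographically smallest (leftmost) assignment via
depth-first search; the tests verify it against exhaustive enumeration of
all 8-subsets of cysteines.  The residue between C5 and C6 is annotated
as hydrophobic or not ({L, I, V, A, F, M}) but never used as a filter,
because natural family members with other residues there exist.

Accepted candidates are named `prefix`1..n in input order.  Ordering by
homology-search score is deliberately not attempted: homolog discovery
(BLAST, Pfam/InterPro validation) is outside this package, which takes a
candidate set as given.

## Physicochemical profiling

MW (average residue masses + one water), GRAVY and the Guruprasad
instability index use Biopython's ProtParam tables (ExPASy conventions);
inputs are validated first so errors name the offending residue and
position.  The theoretical pI uses the Bjellqvist pKa set (including the
residue-specific terminal pKa refinements) with a plain bisection on
pH ∈ [0, 14] down to |net charge| < 1e-4 — the net charge is strictly
decreasing in pH, so the zero crossing is unique.  Bisection is used
rather than a library root finder because the common implementations
restrict the search interval and can clamp strongly acidic peptides.
Hydropathy profiles are unweighted Kyte–Doolittle window means
(default window 9, odd windows only); the aliphatic index is
X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent.  Sequences with
`X` are rejected by default since the report columns require exact
values.  Labels: alkaline ⇔ pI > 7.0; unstable ⇔ instability > 40;
hydrophobic ⇔ GRAVY > 0.

A note on edge behavior: appending a residue changes which residue-specific
C-terminal pKa applies, so pI monotonicity under single-residue appends
holds only up to a few hundredths of a pH unit.

## Phylogeny

Distances are Poisson-corrected amino-acid distances d = −ln(1 − p) with
p the mismatch fraction over columns where both rows are ungapped
(pairwise deletion).  A pair with p = 1 cannot be corrected; it receives
a configurable cap (default 10) and a saturation flag.  Trees are built
by Saitou–Nei neighbor joining with the standard Q criterion; ties are
broken by the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest member leaf), making the topology a
deterministic function of the input.  Negative branch lengths are clamped
to zero and counted on the returned tree.  Bootstrap support resamples
alignment columns with replacement at equal width, rebuilds the NJ tree
per replicate, and reports the percentage of replicates containing each
internal bipartition of the full-data tree; the generator is seeded and
the seed recorded on the tree.  The default replicate count is 1000; the
test suite and the acceptance script run at B = 100 and B = 25–100 with
alignments of 600–2000 columns, which is ample for the 4–5-taxon
fixtures they use.  Clade labels (A–E style groupings) are a post-hoc
annotation by the user, not computed.

## Ka/Ks (NG86)

Nei–Gojobori (1986) counting on an aligned codon pair: per-codon
synonymous site fractions averaged over both sequences; difference counts
pathway-averaged over all orderings of the changed positions, excluding
pathways that pass through a stop codon (all pathways are used, with
stop-creating steps scored nonsynonymous, only in the degenerate case
where every pathway is blocked).  Single-nucleotide changes that would
create a stop codon count as nonsynonymous in site counting, which keeps
S + N = 3 × codons exactly.  Codons containing gaps or ambiguity codes in
either sequence are skipped.  pS and pN are Jukes–Cantor corrected
(d = −(3/4)·ln(1 − 4p/3)); the ratio is reported as N/A with a reason
when pS ≥ 0.75 (the saturation rule used for family reports), when
pN ≥ 0.75 (the same mathematical singularity), or when Ks = 0.  The
universal genetic code is assumed.  Codon alignments are produced by
back-translating a protein alignment with each taxon's CDS, after
verifying the CDS translates to its row (one terminal stop is stripped).

## Duplication modes

Homologous gene pairs are inputs (from classification hits or the
generator).  A pair is **tandem** when both genes share a chromosome and
their rank distance is ≤ `tandem_window` (default 2; ranks are 1-based
positions by genomic start, strand ignored).  Remaining pairs are grouped
by chromosome pair and chained by longest-chain dynamic programming over
anchors with strictly increasing ranks on both axes (both orientations
tried), where consecutive anchors may skip at most `max_gaps` (default
25) ranks on either axis.  Chains are extracted greedily from longest to
shortest; pairs in chains of ≥ `match_size` (default 5) anchors are
**segmental**, everything else **dispersed**.  These thresholds mirror
collinearity-tool conventions; the score/E-value filters of full synteny
pipelines are out of scope because they presuppose the external homology
search.  Both pair-level labels and chain ids/lengths are reported, so
event counts can be read either per pair or per chain.

## Promoters

The promoter is the 2000 bp immediately upstream of the annotated CDS
start: for a plus-strand gene the bases ending just before the gene
start, for a minus-strand gene the reverse complement of the bases just
after the gene end; windows truncated at a chromosome boundary are
flagged and empty windows warn.  Scanning matches IUPAC patterns at every
position (overlaps all counted); an `N` in the promoter matches only a
pattern `N`.  The default is plus-strand-only scanning because
PlantCARE-style dictionaries list reverse-complement element pairs (e.g.
TGACG-motif / CGTCA-motif) as separate entries; a both-strand mode
reports minus-strand hits at the leftmost original coordinate.  The
bundled dictionary is a small curated set covering commonly reported
plant elements with their categories and is in no way a substitute for
the full PlantCARE collection — user dictionaries are a first-class
input (TSV: name, pattern, category, subcategory).  Percentages are per
category over the grand total; an empty scan is flagged rather than
dividing by zero.

## Expression

TPM from counts divides each count by its effective length and scales
columns to 1e6 (all-zero columns warn and stay zero).  Heatmap row
ordering is agglomerative average-linkage clustering on Euclidean
distances of log2(TPM+1) rows (raw values optional); rows are pre-sorted
by gene name so distance ties resolve deterministically, and the leaf
order is the recursive subtree listing.  2^−ΔΔCt: per replicate,
ΔCt = Ct_target − Ct_reference within the same sample and replicate;
ΔΔCt subtracts the mean control-sample ΔCt; RQ = 2^−ΔΔCt, reported as
mean ± SD over replicates.  The SD is computed on the RQ values, not
error-propagated from Ct, matching how biological-replicate bars are
reported.  With noisy Ct values the control mean RQ exceeds 1 slightly
(Jensen's inequality); it equals 1 exactly only in the noise-free case.
The control sample is a required user parameter — time-course designs
can reasonably use either time zero or a mock at each time point, and
that choice belongs to the analyst.  Significance testing (ANOVA/Tukey)
is deliberately left to standard statistics packages.

## Synthetic data

All generators draw from one `numpy.random.default_rng(seed)`;
regeneration with the same seed is byte-identical, and every generator
returns the planted truth.

* **Proteome**: backgrounds are uniform over a PAST-free, cysteine-free
  alphabet, so they cannot form a PAST window or a cysteine scaffold by
  construction.  Planted XYLPs carry a 30–60-residue all-PAST block tiled
  from glycomodule dipeptides plus a scaffold with mid-range spacers
  (so the default bounds accept it; the bounds themselves are tested at
  their edges separately).  Decoys violate exactly one rule.  Default
  composition: 50 backgrounds, 8 XYLPs, 5 + 5 decoys.
* **Codon pairs**: ancestors are drawn from codons that admit both a
  synonymous and a nonsynonymous single-nucleotide change; each requested
  substitution hits a distinct codon, so planted (syn, nonsyn) equal the
  NG86 difference counts exactly.
* **Alignments on trees**: Poisson(b) substitution events per site per
  branch with uniform replacement among the other 19 residues.
* **Genome layouts**: 5 chromosomes × 40 genes by default, with planted
  collinear blocks (order-preserving anchor runs across chromosome
  pairs), rank-adjacent tandem pairs and isolated dispersed pairs on
  chromosome pairs no block uses; rank ranges are kept disjoint so the
  planted labels are unambiguous.
* **Promoters**: uniform A/C/G/T background with non-overlapping planted
  motif instances; accidental occurrences of planted patterns are
  scrubbed by point mutations outside the planted intervals until a scan
  finds exactly the planted counts.
* **Ct tables**: reference Ct 20 + noise; target Ct = baseline −
  log2(fold) + noise, Gaussian noise SD 0.1 by default, 3 replicates —
  the scale of well-run qRT-PCR triplicates.

What the generators do **not** emulate: realistic residue/codon-usage
composition, length and GC heterogeneity, overlapping or nested gene
models, alignment errors, rate variation across sites, or biological
correlation between stages.  Passing the recovery suites therefore shows
the algorithms are correct against their definitions and robust at
realistic noise scales — not that real-proteome false-positive rates are
zero, which depends on genome composition.

## Numerical choices and limitations

* Threshold comparisons on the PAST fraction are inclusive with a 1e-12
  float guard so that exactly 35 % qualifies.
* NJ is exact (path lengths reproduced to 1e-9) for additive matrices;
  for non-additive inputs negative branch estimates are clamped.
* The duplication chain extraction is greedy longest-first; for planted,
  non-interleaved layouts this is exact, but heavily interleaved chains
  sharing anchors could in principle be split differently by other
  collinearity tools.
* The classifier treats the candidate list as given; it performs no
  homology search, HMM validation, signal-peptide or GPI prediction.
  External predictor outputs can be merged into reports through the
  annotation sidecar but are never computed.
* Problem sizes in the test and acceptance suites (proteomes of ~70
  sequences, 5-taxon trees, 2000-site alignments, B = 100 bootstraps,
  5×40-gene layouts) were chosen as the smallest sizes at which each
  recovery question is unambiguous.
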