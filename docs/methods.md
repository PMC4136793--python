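# Methods

This note records the models, conventions and parameter choices behind
`b3locus`, and what the synthetic benchmark does and does not establish
about real data.

## ORF model

Candidate genes are ATG-initiated, first-in-frame-stop-terminated spans
on all six frames. No nested- or overlapping-ORF suppression is applied
at scan time: pheromone precursors are short enough that recall matters
more than parsimony, and the downstream grammar does the selecting. The
pipeline collapses candidates that share a termination site — for
pheromones it keeps the best-scoring, then shortest precursor (the
ATG closest to the grammar); for receptors the longest translation (the
maximal ORF). Coordinates are 1-based inclusive on the forward strand
and include the stop codon, so `(end − start + 1)/3 = peptide length + 1`.
The peptide size filter (default 10–100 aa) counts the initiator Met and
excludes the stop.

Translation follows the standard genetic code; codons containing N give
`X` unless every resolution agrees (GCN → A), a trailing partial codon is
dropped silently, and symbols outside {A,C,G,T,N} are rejected. ORFs
running off a contig end without a stop are not reported.

## Pheromone maturation grammar

Precursors end in a CaaX prenylation motif. Only the Cys at the 4th
position from the C-terminus is constrained — the "a" positions are left
free because documented motifs in related fungi (CVCH, CVRG, CVVA)
violate the aliphatic reading. Maturation removes the three terminal
residues (the farnesylated Cys becomes the new C-terminus) and cuts
upstream at an ER/TR doublet. Offsets count the C-terminal residue as 1,
so the mature length is `offset(R) − 4`. Context residues are counted
from the doublet's Arg: Pro at R−4 and Asp/Asn at R−2. A site's score is
1 (doublet) + 1 per context residue satisfied; sites are ranked by score,
ties toward the smaller offset (the shortest mature peptide, which keeps
the chosen segment adjacent to the doublet).

Two windows are configurable rather than hard-coded because the source
conventions conflict: the doublet-offset window defaults to [13, 19]
(so mature lengths span the literature's 9–15 aa) and the accepted mature
length to [9, 15]; the default generator emits 12–13 aa matures, the
range typical of this locus.

Strict classification requires a chosen site with score ≥ `min_site_score`
(default 3, the full consensus). The default is deliberately the full
grammar: in ~60 kb of background sequence a six-frame scan yields on the
order of a thousand small ORFs, and the doublet-only rule (score ≥ 1)
would admit roughly two spurious precursors per locus by chance
(P(Cys at −4) ≈ 0.03 × P(in-window doublet) ≈ 0.07), whereas the full
consensus admits ~10⁻⁵ per ORF. `min_site_score=1` reproduces the
doublet-only reading; permissive mode reports CaaX-only candidates.

## Receptor topology

TM calling is a single-sequence hydropathy method, not an HMM: a
Kyte–Doolittle profile (centered window 19, truncated at the edges;
unknown residues contribute 0 with a warning), candidate cores where the
profile reaches the canonical 1.6 cutoff, and each core expanded outward
over residues with positive raw hydropathy. The expansion step matters:
a 19-residue window erodes a ~21-residue helix to a ~13-position
supra-threshold run, so thresholding alone would under-call genuine
helices at any sensible minimum length. Expanded segments are unioned,
merged when separated by fewer than 3 residues, and dropped below 15
residues. Topology alternates from an extracellular N-terminus (the
STE3 convention, no signal-peptide modelling), so a 7-TM protein has a
cytoplasmic C-tail; `receptor_like` requires exactly 7 segments and a
C-tail below the threshold (default 50 aa — chosen so the short tails
reported in this family, ~26–35 aa, fall below it and the long ones,
hundreds of residues, far above; a ~54-aa tail sits at the boundary,
which is why the threshold is a knob).

Pairwise identity is Needleman–Wunsch under BLOSUM62 with affine gaps
(open 10, extend 0.5 — conventional protein defaults, stated so the
numbers are reproducible), and identity = 100 × matches / aligned
columns with gapped columns in the denominator. Because co-optimal
alignments can differ in match count, the pair is aligned in a canonical
(sorted) order, making the result symmetric by construction. The
truncated mode cuts the longer sequence (default: to the shorter one's
length) before aligning — the convention for paralogs whose C-terminal
extensions do not correspond.

## Physical map

Contig merging is exact suffix/prefix matching (both orientations of the
second contig), appropriate for clones drawn from a single genome;
mismatch-tolerant assembly is out of scope. The mating-gene span is the
inclusive distance from the first to the last pheromone/receptor
feature, ignoring flanking homologs. In-silico PCR is exact-match on
primers ≥ 15 nt, both orientations; multiple products are all reported
and flagged, with the outermost interval as the headline product. GFF3
and CSV carry 1-based inclusive coordinates verbatim; the BED writer
alone converts to 0-based half-open, and round trips are bit-exact.

## Expression model

Each record carries a target and a duplexed reference Ct.
Per replicate, ΔCt = Ct_target − Ct_reference; per condition,
fold = efficiency^(mean ΔCt_calibrator − mean ΔCt_condition), so the
calibrator condition is exactly 1 for every gene and folds are invariant
to any constant shift applied to all Ct values. Efficiency defaults to
2.0 per cycle (the ΔΔCt assumption) with an override because
standard-curve efficiencies are assay-specific and only Ct values are
typically deposited. The per-condition sd is the spread of
per-replicate folds. The reported comparison is the
calibrator/comparison ratio (e.g. monokaryon over dikaryon). Group
separation is one-way ANOVA then Tukey HSD at α = 0.05 with a greedy
compact-letter display; all-zero within-group variance is flagged as
degenerate rather than tested.

## Synthetic locus

The generator emulates the study conditions: a 60-kb locus split into
40.4-kb and 32.7-kb contigs sharing a 13.1-kb exact overlap; four
pheromone genes of 57–61 codons (full grammar, mature 12–13 aa) and four
receptor genes (328/420/558/470 aa; C-tails 34/100/150/120 aa; seven
21-aa hydrophobic stretches from {I,L,V,F,A,M} separated by hydrophilic
loops from {R,K,D,E,S,T,N,Q,G,P}, loop lengths absorbing the length
budget with a 20-aa N-tail) placed at the printed physical-map start
coordinates on mixed strands; six grammar-ablated decoy small ORFs
(CaaX-without-doublet, doublet-without-CaaX, oversized) in the flanks; a
1,001-nt marker amplicon mid-overlap with its exact 20-nt primer pair;
and triplicate Ct tables (reference Ct 15, baseline ΔCt 8, noise sd 0.1
cycles) with injected monokaryon/dikaryon folds — receptors 3.8, 1.0
(a null gene), 9.0, 12.2 and pheromones 1.5, 31.4, 5.0, 8.0, matching
the fold ranges this locus exhibits with one non-responding receptor.

Background sequence is i.i.d. at GC 0.50. Two compositional constraints
keep truth recovery well-posed: precursor peptides contain no internal
Met (one candidate per termination site) and no Arg in the mature body
or at in-window positions (the truth doublet is the unique in-window
site). A single seeded generator drives everything, so identical spec +
seed gives byte-identical FASTA/GFF3/CSV outputs (the seed is echoed in
every header).

What passing on this benchmark does *not* show: tolerance to introns
(real receptor genes here have them — receptor annotation from genomic
DNA only works on intron-free CDS; use cDNA/protein input otherwise),
repeats, sequencing error, non-uniform codon usage, TM helices of
atypical hydrophobicity, or qPCR efficiency drift. The decoy set
measures specificity only against grammar ablations, not against real
non-pheromone small proteins.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the generator's native
scale: one 60-kb locus, 100-precursor and 100-receptor recovery cohorts,
1,000-peptide specificity draws, 200 expression simulations — sizes at
which every check completes in seconds while the binomial/χ² tolerances
remain meaningful. Ties in site selection break toward smaller offsets;
TM segments are reported in N→C order; degenerate inputs (empty
sequences, missing calibrators, infeasible generator ranges) raise with
explicit messages rather than producing silent partial output.

## Known limitations

Single-reference normalisation only; no amplification-curve fitting; no
intron-aware gene prediction; no homology search (precomputed hits can be
carried in feature notes but are never fetched); hydropathy topology is
deliberately simpler than HMM/neural predictors and its boundaries on
real proteins are approximate even when the segment count is right.
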