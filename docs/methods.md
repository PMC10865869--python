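# Methods

This note documents the models, rules and numerical choices behind
`hicascan`, and what its synthetic benchmarks do and do not demonstrate.

## Coordinates, translation and I/O

All in-memory intervals are 0-based half-open; GenBank and GFF3 (1-based
inclusive) are converted at the I/O boundary, so the conversion is its own
inverse and round trips preserve the feature table exactly. Translation
uses the bacterial/archaeal code (table 11); ATG/GTG/TTG starts all yield
M at position 1; stored proteins exclude the stop codon (an intact CDS has
`end − start = 3·(len(protein)+1)`); internal stops render as `*` because
the pseudogene screen needs to translate through them. Features marked
pseudo are parsed and kept as neighbors but are never focal genes.

## Domain detection

Each domain family is represented by a position-specific log-odds profile
built from a seed alignment: columns with ≥ 50% non-gap occupancy are
kept, and the score of residue *a* in column *j* is
`log2(((n_aj + λ/20) / (N_j + λ)) / (1/20))` bits, with pseudocount
λ = 0.5 and a uniform background. The uniform background keeps the scores
exactly recomputable by hand, which the tests exploit; small seed sets
need the smoothing.

Proteins are scanned by local (Smith–Waterman) alignment of the residue
string against the profile columns with affine gaps (default open 11,
extend 1 — the standard protein-search convention; the first gapped
position costs the open penalty). The dynamic programming runs on
Biopython's pairwise aligner by giving every profile column its own
symbol in a custom substitution matrix; the tests verify the resulting
scores against an independent brute-force recursion on small instances.
Multiple hits per protein are recovered best-first by masking each hit
and rescanning; retained hits may overlap by at most 10 residues
(domain boundaries in this family are approximate to about that scale),
resolved greedily by descending score with ties broken by (start, label).

**Threshold calibration.** No universal bit-score cutoff is assumed.
Each profile's threshold is mean + 5 SD of the best local score of the
profile against shuffled copies of its own consensus (default 100
shuffles, seeded). This is reproducible, seed-stable, and separates true
domains from composition-matched noise by a wide margin: at 30% per-site
divergence from the ancestor, detection sensitivity is ≥ 95% while
shuffled decoys score above threshold < 5% of the time (tested).

SMC recognition additionally requires the protein to be ≥ 600 aa or to
contain a 100-aa window with ≥ 85% hydrophobic residues at heptad a/d
positions (a coiled-coil proxy), because SMC-family proteins are large
coiled-coil ATPases and a bare profile hit on a short protein should not
trigger the SMC–HicA fusion class.

Users with HMMER results can bypass the built-in scanner entirely via
`ingest_domtblout` (envelope coordinates, i-Evalue filter, name→label
map).

## Neighborhood model

Upstream/downstream are defined relative to the focal gene's strand, so
classification is invariant under reverse-complementing a contig (tested).
The context window is 5 genes per side by default. Intergenic gap is
`b.start − a.end` (negative = overlap length). "Closely linked" means
0 ≤ gap ≤ 10 nt; overlap is flagged separately. The 10-nt bound is
configurable (`closely_linked_max_gap`): short gaps and overlaps are the
accepted signature of translational coupling in these operons, and the
literature on this family prints conflicting signs for the criterion, so
the package treats it as an explicit parameter rather than a constant.

## The 14-class rule engine

Rules fire in fixed precedence; each locus gets exactly one class or
`unclassified` (never dropped). More specific evidence outranks
permissive size-only rules:

1. **14** single CDS, valid SMC hit with a HicA dsRBD hit C-terminal to it.
2. **11** single CDS, N→C order HicA dsRBD, HicB core, HTH-or-RHH DBD.
3. **12** single CDS, HicB core before HicA dsRBD, total ≤ 250 aa.
4. **13** single CDS, C-terminal HicA dsRBD, total length 340–440 aa.
5. **9 / 10** the adjacent co-oriented neighbor (gap ≤ 300 nt) downstream /
   upstream has a pVip architecture. A pVip-adjacent hicA that also has a
   cognate hicB partner is assigned 9/10 (adjacency is the defining
   context); the partner stays visible in the evidence.
6. **6 / 5** upstream co-oriented partner has a HicB core plus N-terminal
   Phd/YefM DBD; 6 when the focal HicA also carries a Shared Domain hit
   C-terminal to the dsRBD (within 10 residues of its end), else 5.
   Conserved junction prolines ("domain breakers") are an observation,
   not a requirement.
7. **3 / 4** downstream partner has a HicB core plus C-terminal HTH (3) or
   RHH (4).
8. **7 / 8** upstream partner lacks any DBD and its length falls in
   216–233 aa (7) or 331–356 aa (8). DUF1902 or other middle-domain hits
   are recorded as supporting evidence only, since these classes are
   defined by length and DBD absence.
9. **1 / 2** downstream / upstream partner lacks any DBD with length
   60–97 aa (1) or 63–103 aa (2). Within this tier, a partner carrying a
   detectable HicB core outranks a size-only match, so an unrelated small
   neighbor (a vapB, say) cannot shadow the true antitoxin on the other
   side. All length ranges are closed intervals and configurable; the
   Class 1 and Class 8 defaults are the unions of the two ranges reported
   for those classes (60–97, 331–356), since the reported bounds disagree
   internally.

Every satisfied predicate is stored as `(name, observation)` evidence;
`replay_evidence` re-evaluates the named predicates against the context
and re-derives the class, which the tests use as an audit.

An auxiliary per-locus flag (`rele_pvip_nearby`) marks context windows
containing an adjacent co-oriented RelE–pVip gene pair — an association
worth surfacing, not a class.

**Pseudogene screen.** A candidate Class 1/2 HicB may be a decayed
DBD-bearing HicB truncated by a premature stop. The screen flags it if
(a) translating in frame past the stop codon for up to 300 nt yields a
segment scoring above threshold against the HTH or RHH profile, or
(b) a supplied reference HicB known to carry a DBD matches the candidate
at ≥ 95% identity over the candidate's full length. Flagged loci stay in
the output (with `pseudogene_candidate`) but are excluded from class
counts and tallied separately in summaries.

## Summaries

Per class: locus count, HicA/HicB length ranges, closely-linked and
overlapping counts (disjoint), and the closely-linked percentage at full
precision (displayed rounded to integer percent, the convention of
published surveys). The optional redundancy filter greedily keeps loci in
locus-id order whose HicA is < 95% identical (global-alignment matches
over the shorter sequence) to every kept HicA; greedy order is a
documented determinism choice.

## Phylogeny

Distances are `1 − identity` from global Needleman–Wunsch alignments
(BLOSUM62, affine gaps open 11 / extend 1), identity counted over
alignment columns excluding terminal gaps. Trees are built by
Saitou–Nei neighbor joining rather than approximate maximum likelihood:
NJ is deterministic, exactly checkable against additive matrices, and
sufficient for the clustering statistic; the alignment can be exported
for external ML tools. Q-criterion ties break on the lexicographically
smallest pair of cluster representative ids; negative branch-length
estimates are clamped to zero with the deficit moved to the sister branch
so path lengths are preserved. On additive matrices NJ recovers the
generating tree's path metric exactly (tested on 100 random trees, n ≤ 8,
and cross-checked against scikit-bio's NJ). Full progressive multiple
alignment is deliberately out of scope — the clustering statistic needs
only pairwise distances.

**Class purity** is the fraction of sequences whose nearest neighbor in
the distance matrix (ties lexicographic) shares their class label;
singleton classes are excluded from the denominator with a warning.

## Superposition

Kabsch least-squares superposition via SVD with reflection exclusion
(det +1); degenerate (collinear) inputs warn but return the best proper
rotation. `prune_superpose` repeats {fit on kept pairs; drop pairs with
residual > cutoff} to convergence (default cutoff 2.0 Å, the common
matchmaker-style convention; it is a flagged parameter since published
figures rarely state theirs), never pruning below 3 pairs. Pairing is by
index: inputs are assumed pre-aligned, as structure-alignment-based
residue pairing is out of scope. Note that when outliers are large
relative to the point spread, the first fit can be distorted enough that
good pairs are discarded along with the outlier — with ≥ ~20 points a
single outlier is pruned cleanly.

## Synthetic genomes

The generator is the package's ground-truth instrument. Each domain
family gets a random ancestor protein of family-typical length (HicA 55
aa, HicB core 50, DBDs 45, Shared Domain 55, DUF1902 55, NERD 80, RelE
90, pVip 280, SMC 700); profiles are built from 8 copies of the ancestor
at 15% per-site divergence and calibrated as above. Loci are assembled by
concatenating mutated domain copies per class architecture, padding to
class-typical lengths (defaults sit inside each class's documented size
range, e.g. Class 1 HicB 80 aa, Class 7 HicB 225 aa, Class 13 fusion 380
aa), back-translating with uniform synonymous codons, and embedding in
random DNA with the requested gap. The mutation model is substitution-only
(uniform to a different residue) — no indels by default — which keeps
detection-sensitivity analyses interpretable.

**Overlaps** (negative gaps, down to −20 nt) are realized by genuinely
sharing nucleotides between the two reading frames: the shared region
starts the downstream gene's ATG and ends with the upstream gene's stop
codon, and the junction codons on both sides are chosen to keep both
frames free of internal stops (the one or two junction residues may
therefore differ from the requested proteins; truth tables record the
realized proteins). In-frame overlaps (k ≡ 0 mod 3) and k ∈ {2, 5} admit
no consistent stop/start arrangement and raise an error suggesting the
nearest feasible gap. Every generated CDS translates cleanly from its DNA
— stored proteins equal `translate_cds` output — so GenBank and GFF3
round trips are exact (tested).

Confounder decoys: a pseudogenized Class-3-like locus (engineered stop
before the HTH, annotated as a truncated DBD-less HicB with the DBD DNA
still in frame downstream — built to be caught by the read-through
screen), solitary *hicB* genes, neighboring vapBC/relBE-like modules,
transposase-sized random genes, and RelE–pVip pairs. Island mode packs
many TA loci with short spacers so that eight loci fall within a 7-kb
window, emulating defense-island clustering.

The class-clustering benchmark (`hica_class_benchmark`) draws one HicA
sub-ancestor per class at 45% divergence from a family ancestor and 10
members per class at 5–25% divergence from their sub-ancestor. This
emulates class-wise sequence clusters directly; it demonstrates that the
distance/purity machinery detects such structure, not that real HicA
classes are this cleanly separated.

**What passing synthetic tests shows.** The generator uses the same
profile families the scanner searches with, uniform residue composition,
no indels, and no annotation errors. Round-trip accuracy (100% at ≤ 20%
divergence on 140 loci here) therefore bounds pipeline correctness — rule
logic, coordinates, strand handling, I/O — not real-genome performance,
where domain divergence, indels, unusual compositions and mis-annotation
all reduce sensitivity. Class statistics from real surveys (linkage
fractions, observed length ranges) can be recomputed by running
`classify` + `summarize` on the corresponding annotated genomes; they are
not derivable from synthetic data.

## Problem sizes and determinism

Default analysis sizes were chosen so that every stage runs in seconds on
a laptop: 14–140-locus fixture genomes, 100-sequence phylogenies,
100-shuffle calibrations. Every stochastic step takes an explicit integer
seed; per-locus and per-profile seeds are derived arithmetically from the
run seed (kept below 2^31), and identical seeds produce byte-identical
GenBank output.

## Known limitations

- Profile scanning has no insert/delete states or E-value theory; the
  calibrated-null threshold is a practical surrogate for the unstated
  inclusion thresholds of database searches.
- Classes 7/8 and 13 are length-defined; proteins outside the configured
  (closed) ranges fall through to `unclassified` rather than a nearest
  class.
- Operon membership is purely structural (adjacency + co-orientation +
  gap); no transcriptomic evidence is used.
- NJ trees carry no support values; users wanting ML trees with
  bootstraps should export the sequences.
- The superposition utility pairs residues by index and does not compute
  structure alignments.
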