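# Methods

This note documents the models and procedures slc6kit implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices a maintainer would want spelled out.

## Coordinates

Every position reported anywhere in the package is 1-based and inclusive
on both ends, matching the residue-numbering convention of the structural
and transporter literature (A47, T309, "position 173–176"). Conversion to
0-based indexing is private to each function. Minus-strand intervals are
reported in forward-strand coordinates with a `-` strand flag.

## Hydropathy and membrane topology (`features`)

The Kyte–Doolittle profile is the unweighted sliding mean of the 1982
per-residue hydropathy values; X scores 0. Defaults: window 19,
threshold 1.6, minimum segment length 10 (on the profile), merge gap 5 —
the classic KD setting for membrane proteins, exposed in `PipelineConfig`
because TM counts are sensitive to them. A segment is a maximal run of
window centres at or above threshold; runs separated by fewer than
`merge_gap` centres are merged, then short runs are dropped. Segment
intervals are window-centre spans, so a called segment is expected to be
slightly narrower or wider than the physical helix depending on the
flanking contrast; this is inherent to windowed hydropathy calling.

One caution: the number of *segments* is not monotone in the threshold.
Raising the threshold can split one run into two that both survive the
length filter, so the count can increase even though the set of
above-threshold positions (and hence total covered length) strictly
shrinks. The test suite checks the true monotone quantities.

Topology labelling alternates loop sides starting from `n_term_side`
(default "in", as inferred for this family; positive-inside prediction is
out of scope, so the side is an input, not an inference). With an even
number of crossings the C terminus lands back on the N-terminal side. The
largest "out" loop strictly between two segments is reported as the EL2
analogue. Sequons are N-X-[S/T] with X ≠ P, reported as 3-residue
intervals (some papers print 4-residue spans that include the residue
after the motif; the motif interval is what we report). Masses are
average (not monoisotopic) residue masses plus one water, via Biopython;
sequences containing X have no defined mass and raise.

## Alignment (`align`)

Pairwise alignment is Needleman–Wunsch–Gotoh with affine gaps: a gap of
length k costs `gap_open + (k − 1)·gap_extend` (defaults 10 / 0.5,
BLOSUM62 — ClustalW-style protein defaults). Traceback ties break
diagonal > up > left, fixed for bit-reproducibility; scores are
cross-checked in the tests against an exhaustive enumeration oracle and
against Biopython's independent `PairwiseAligner`.

Percent identity is identical-residue columns over a configurable
denominator (both-non-gap columns by default; shorter-sequence and
all-columns variants exist because published percent-ID conventions
differ). Percent similarity additionally counts residue pairs with a
positive BLOSUM62 score. Gap columns never count as matches. Note that
BLOSUM62 > 0 is a strict notion of "similar": some chemically
conservative pairs (e.g. Ala↔Leu, both small/aliphatic, BLOSUM62 −1) are
classified divergent under it. This matters when comparing against
narrative conservation claims made by eye.

The progressive MSA builds a guide tree by UPGMA (scipy average linkage)
on fractional-common-k-mer distances (k = 3; d = 1 − |shared k-mers| /
min distinct count) — simple, deterministic, and adequate at the ~80-taxon
scale this pipeline targets — then aligns profiles at internal nodes with
the same Gotoh recursion, scoring column pairs by sum-of-pairs BLOSUM62
with gaps contributing 0. Two sequences reduce exactly to the pairwise
aligner. No position-specific gap penalties are attempted; this is not a
ClustalW re-implementation and will not reproduce its columns, only the
same qualitative alignment structure. Terminus trimming removes leading
and trailing columns below a non-gap occupancy fraction (default 0.5), up
to the first/last passing column, leaving the interior untouched.

## Binding-site projection and ion dependence (`siteproj`)

The bundled site fixtures are: LeuT Na1 {A22, G24, N27, T254}, LeuT Na2
{G20, V23, A351, T354, S355} (PDB 2A65 chain numbering) and SERT Cl
{Y121, S336, N368, S372} (NP_001036.1 numbering). Fixtures store the
expected residue so that a mis-numbered template sequence is caught at
load time (`validate_against`). A provisional substrate-pocket set for
LeuT is shipped for the pocket-conservation report; it is a transcription
of the canonical occluded-state leucine-pocket residues and is marked
provisional in the fixture file — users with a curated list should
supply their own TSV.

Projection walks the alignment columns once, maintaining both residue
counters; template positions opposite a gap are "unaligned". Statuses:
identical; similar (BLOSUM62 > 0, the same definition as the alignment
module); divergent; unaligned. The primary path is pairwise
template-vs-query projection; the MSA-column path exists only for the
pocket report.

The ion-dependence call is a pure function of statuses: Na⁺ "dependent"
iff every Na1 residue is identical or similar (Na1 is the indispensable
site; Na2 is reported as a count but does not gate the call, since its
partial conservation is the common state in neurotransmitter-branch
transporters); Cl⁻ "dependent" iff all four chloride-site residues are
identical (the SLC6A18/A20 pattern), "independent_candidate" if any is
non-identical (the SLC6A15/17/19 pattern), "undetermined" if any is
unaligned (conservative: unaligned sites degrade the call rather than
being skipped). When the SERT-S336-equivalent position carries a
threonine the rationale flags it explicitly — that is the LeuT-like
(T254) configuration believed to exclude chloride binding in the
prokaryotic, chloride-independent transporters.

## Phylogenetic placement (`phylo`)

Distances are computed over both-non-gap columns: p-distance or the
Poisson correction −ln(1 − p) (default). Saturated pairs (p = 1) are an
error under the correction rather than an infinity. Neighbor joining is
the standard Saitou–Nei Q-criterion; ties break on the smallest node-index
pair in creation order, and a negative branch length is clamped to zero
with the deficit moved to the sibling edge, so all output lengths are
non-negative. Bootstrap support is the fraction of column-resampled
replicate NJ trees containing the same bipartition; bipartitions are
canonicalized (the side not containing the lexicographically smallest
taxon), which makes supports invariant to rooting and taxon input order.
A saturated bootstrap replicate is counted as supporting no split.

Approximate-maximum-likelihood inference and Shimodaira–Hasegawa local
supports are deliberately **not** implemented. NJ + nonparametric
bootstrap is the documented stand-in: the deliverable of this stage is
the qualitative subfamily cluster structure (is the query inside the NAT
cluster, who are its sisters), not support values comparable to an ML
tool's. Cluster assignment finds the smallest clade containing the query
and at least one labelled leaf, labels it by majority (ties
alphabetical), and reports whether the query is nested inside a
single-label clade.

## In-silico PCR (`insilico_pcr`)

A primer base matches a template base iff the template base is inside the
IUPAC expansion of the primer code; degenerate template bases are covered
only when their whole expansion is allowed by the primer code (an N in
the template never satisfies an A in the primer — conservative).
Defaults: 0 mismatches and an exact 3-nt 3′ anchor, a standard PCR
specificity heuristic; annealing thermodynamics are out of scope. Hits
are reported at the forward-template coordinate of the primer's 5′ base
on either strand, so the length of a forward/reverse product is
`rev − fwd + 1` — which is why primer names that encode their 5′
coordinates (For_293/Rev_684) determine the 392 bp product size by
arithmetic alone. The bundled primer fixture carries the published
cloning and RT-PCR primers; the source methods text prints the name
"PA144" twice where the narrative expects two phage-arm primers, and the
fixture ships the printed sequence once with the discrepancy flagged in a
comment rather than silently resolved.

## Synthetic data (`synthetic`)

The generators exist to give every stage a ground truth; they are pure
functions of their seed.

*Families.* Sequences evolve along a supplied or random tree under a
Poisson process: substitutions per site per branch ~ Poisson(branch
length), each replacing the residue uniformly among the other 19
(a Jukes–Cantor-style protein model — controllable divergence, not
realism; no empirical exchangeabilities, no rate heterogeneity beyond
planted invariant columns, and no indels). Planted invariant columns are
never substituted. Because there are no indels, the true alignment of any
two family members is the identity, which is what makes exact recovery
tests possible.

*Membrane proteins.* Loops and TM segments tile the sequence. TM cores
draw from {I, V, L} and loops from {S, T}: both sets sit inside the
hydrophobic (KD ≥ 1.8) / hydrophilic (KD ≤ −0.4) envelopes, and the
narrow alphabets were chosen by boundary-geometry analysis so that the
window-19 caller's threshold crossing lands within ±1–2 residues of the
planted boundary (low within-set variance keeps boundary windows ~5σ from
the threshold), giving per-segment Jaccard ≥ 0.9 recovery. Sequons are
spliced as N-G-[S/T] and cysteines as C; decorations must sit ≥ 10
residues from any TM boundary (enforced) so they cannot perturb boundary
windows, and loops otherwise contain no N, so sequon recovery is exact by
construction. The default 12-TM spec mirrors the study architecture: an
enlarged loop between TM3 and TM4 carrying two sequons and a
three-cysteine cluster, total length 661 aa. What passing these tests
shows is that the caller recovers clean planted architecture; real
membrane proteins have noisier hydropathy contrast, so real TM counts
remain parameter-sensitive.

*PCR templates.* Uniform ACGT background with primer footprints spliced
at requested 5′ coordinates; degeneracies are resolved uniformly at
random at planting time and the concrete realization is recorded in the
truth, so downstream mismatch counts are exact.

*Study conditions for the planted-site projection check.* The family used
to verify that planted invariant sites project as identical uses a fixed
balanced 8-leaf tree with root-to-leaf path ≈ 0.18 substitutions/site
(the 60–75% similarity regime of the real homolog comparisons) on a
200-aa root. At much higher divergence the check stops measuring
projection correctness: a ~90-aa random-composition pair at p ≈ 0.75 is
past alignment saturation, where the leaf still carries the planted
residue but no aligner can place it — a known limitation of any
alignment-based site projection, not of the projection bookkeeping.

## Pipeline and reports (`pipeline`, `cli`)

`run_characterization` executes annotate → align → project → tree → pcr;
stages with missing optional inputs are skipped with a logged warning, a
stage failure is recorded in the manifest while the others still run, and
the process exit code is 0 iff no stage errored. Every TSV/JSON report
embeds schema version 1 and the effective configuration, and reruns with
the same inputs, config and seed are byte-identical (no timestamps).
Fewer than three family sequences skips the tree stage (NJ needs ≥ 3
taxa).

## Problem sizes

The self-contained test suite and the acceptance script run at desk
scale: 100 generator seeds for membrane-feature recovery, 50 random
additive matrices (5–10 leaves) for NJ, 100 bootstrap replicates on an
8-taxon/500-column family, 2-kb templates for degenerate-primer
verification, and a 10-taxon/400-column family for the cluster-placement
reconstruction. These sizes were chosen as the smallest at which the
checked statistics are stable.

## Known limitations

- Windowed KD calling cannot resolve helices shorter than ~min_tm_len
  window centres or marginally hydrophobic helices; the "12 TM" outcome
  on real sequences depends on the (exposed) parameter set.
- The MSA is a plain progressive aligner; low-identity regions can
  misalign, and site projection inherits any pairwise-alignment error
  (see the saturation note above).
- NJ topology quality degrades on strongly non-additive distance
  matrices; bootstrap supports are not comparable to SH/aLRT values.
- The ion-dependence rules are deterministic sequence heuristics; they
  predict candidacy, not physiology, and were designed around the
  LeuT/SERT template numbering shipped in the fixtures.
- The LeuT substrate-pocket fixture is provisional (see above).
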