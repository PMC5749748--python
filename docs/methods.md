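# Methods

This note documents the models, algorithms and design choices behind
`dwdkit`, the defaults that matter, and what the synthetic-data tests do and
do not demonstrate about real proteomes.

## Motif model

The DWD motif is treated as a hard position-class pattern over 16 positions
(hydrophobic I/F/V/L at 1, 2, 10, 12, 15; small A/G/S/T at 3–5; D/E at 7 and
14; W/Y at 13; R/K at 16; the remaining four positions free). There is no
PSSM, score or threshold: a window matches iff all 16 positions are in
class. This makes the scanner exactly checkable against a per-window
brute-force oracle, and gives a closed-form chance-match probability of
(4/20)⁸ · (2/20)⁴ = 2.56·10⁻¹⁰ per uniform-random window (the background in
the simulator is uniform over the 20 standard amino acids precisely so this
number is exact). The unknown residue `X` matches no position: detection is
conservative on low-quality sequence. Overlapping matches are all reported
and ordinals D1, D2, … are assigned in start order. No partial-motif rescue
(e.g. 4-residue WDxR-only searches) is attempted.

By default the scanner runs over the full sequence of WD40-confirmed
proteins; a `region_only` flag restricts it to the repeat-region hull. Both
behaviours are provided because it is genuinely ambiguous whether motif
occurrences outside annotated repeats should count; full-sequence scanning
is the default since the motif definition itself carries the specificity.

## WD40 detection

The built-in detector is a deliberate simplification of profile-based
homology search (DELTA-BLAST/WDSP-style pipelines): it anchors on the WD
dipeptides that terminate canonical repeats and finds the longest chain of
anchors whose successive spacing lies in `[min_len, max_len]`
(default [40, 60]) using an O(A²) dynamic program over the A anchors —
equivalent to exhaustive enumeration over anchor subsets, and robust to
spurious interior WD dipeptides (a pure greedy left-to-right chain is not).
A chain with ≥ `min_repeats` units (default 4, not 7: annotated repeats of
seven-bladed propellers are often partial) is reported; ties go to the
leftmost chain. The first unit is the `min_len` residues ending at its
anchor, clipped at zero. The detector carries no statistical score and no
e-values; users with real annotations (WDSP, InterPro) can inject them as a
TSV and select `annotation` or `annotation_else_naive` mode.

## Classification rules

The A–K typing uses three features: motif position, motif count, and
other-domain arrangement. The published scheme is schematic, so the default
rule table is an explicit reconstruction, evaluated in a fixed order to
guarantee a total, deterministic mapping:

1. partial proteins (config predicate; default: none, optionally "sequence
   lacks initial Met") → PP;
2. other domains present and ≥ 2 motifs → K;
3. other domains present: H if domains flank the hull on both sides, J if
   ≥ 2 distinct domain names sit on one side, I if a domain nests inside
   the hull, else F (N-terminal) or G (C-terminal). A domain's side is its
   midpoint relative to the hull — total even for domains straddling a hull
   edge;
4. no other domains and ≥ 2 motifs → E;
5. else A/B/C/D by quartile of motif start ÷ protein length.

The quartile boundaries and label names are JSON-overridable so an
alternative convention can be matched exactly. Type fractions are reported
over non-PP records, with PP counted separately.

## Pairwise characterization

BLASTp is replaced by an exact affine-gap global alignment (Gotoh DP) under
BLOSUM62 with gap costs 11 + L (open 11, extend 1 per residue) — the BLAST
defaults — because an exact DP is deterministic and dependency-free, and it
makes "percent similarity" well defined as the positives percentage:
100 × (aligned columns with positive substitution score) / alignment length.
Among co-optimal alignments the DP maximizes (score, identities, positives,
aligned columns) lexicographically, propagated through the recursion as a
packed integer, so reported percentages are unique — this is what allows
exact equality tests against exhaustive alignment enumeration. The kernel is
numba-compiled; sequences up to 4,000 residues are supported (packed-field
widths bound the length).

Group assignment takes the best-hit reference subject to
`min_similarity = 40` (percent) and `min_coverage = 0.5` (aligned columns
over the shorter sequence). The similarity threshold deserves a note: the
empirical null of global-alignment positives for unrelated random proteins
of equal length is ≈ 28% (max ≈ 32% over 60 pairs), because BLOSUM62 has
many positive off-diagonal entries and global alignment is forced to align
most residues. A cutoff of 30 — natural for local-alignment tools — would
therefore accept roughly half of all random queries; 40 sits ≥ 4σ above the
null while true homologs at 20% sequence divergence score ≈ 82%. Ties on
similarity break by higher identity, then lexicographic reference id.
Per-group orthology coverage is 100 × (reference members with ≥ 1 assigned
homolog) / (group size).

When no external reference database is supplied, the pipeline derives one
from a designated reference species (default: lexicographically first): its
DWDs become the references and their D1-motif NJ tree, cut at k, provides
the group labels — mirroring the use of an annotated model species as the
characterization reference.

## Phylogenetics

Motifs are fixed-length 16-mers, so the multiple alignment is the identity
mapping of columns; no gapped MSA is computed anywhere (the one deliberate
deviation from ClustalW-based workflows, which this package does not
reimplement). Distances are p-distances with X-sites excluded pairwise.

Neighbor joining follows Saitou–Nei: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), standard branch-length
formulas, closed-form resolution of the final three nodes. All ties break
lexicographically on cluster labels (a cluster is labelled by its smallest
leaf), making trees a pure function of the input. Negative branch lengths
are clamped to zero with the deficit transferred to the sister branch.
Because Q is computed with vectorized left-to-right float sums it can be
asymmetric at the last ulp; candidate pairs are orientation-normalized
before tie-breaking. On additive matrices the implementation recovers the
generating topology exactly and reproduces path lengths to ≈ 1e-15
(tested on 100 random 8–16-taxon trees); an independent NJ implementation
(scikit-bio) is used as a cross-check in the test suite only.

Bootstrap supports resample the 16 columns with replacement (default 1,000
replicates, seeded). An internal edge's support is the percentage of
replicates whose NJ tree contains the same bipartition. Zero-length internal
edges are treated as polytomies — they contribute no bipartition to a
replicate — so edges without signal get support 0 rather than inheriting
the support of an arbitrary tie-break (an all-identical alignment yields
support 0 everywhere). Multi-motif proteins are represented in trees by
their D1 motif (config-overridable).

Tree cutting removes the k−1 longest internal edges (ties: higher support,
then smallest leaf below), yielding k leaf groups labelled G1…Gk by
smallest leaf label; leaf edges are used only when internal edges run out,
and a cut that would strand a leafless component is skipped. The cutting
rule is this package's documented choice — distance-based group counts are
otherwise underdetermined.

## Synthetic data

The generator emulates a multi-species DWD survey: per homolog family it
builds a WD40 backbone (4–8 repeats of 40–60 residues ending in WD,
uniform-background interior), optionally attaches one named other-domain
segment (60–120 residues from a 6-name synthetic library including
stand-ins for the prokaryote-derived GrpE/FliJ/GYD domains), draws DWD
status once per family (Bernoulli, default 0.55 — the observed DWD/WD40
ratio is ~53–57%), plants 1–3 motifs with probabilities (0.76, 0.21, 0.03)
— midpoints of the observed 72–80% / 17–24% / 0.5–4.7% ranges — at
non-overlapping in-repeat positions clear of the WD anchors, and evolves
the ancestral protein along a known species tree (default: one angiosperm
+ one moss at 0.06 substitutions/site, one microalga at 0.11 — divergences
typical of conserved plant protein families).

Evolution is Jukes–Cantor-style for amino acids: independent sites, uniform
replacement among the 19 alternatives, per-branch substitution probability
1 − exp(−branch length). Motif windows and the repeat-terminal WD
dipeptides evolve at `motif_noise_rate` (default 0) instead — a stand-in
for purifying selection on the functional signature. Without this, branch
substitutions would erode the WD anchors and no detector could achieve
recall 1.0 on "noise-free" data; with it, zero-noise datasets give exact
planted-truth recovery while the rest of the sequence diverges. An
additional `noise_rate` applies per-emitted-protein substitution outside
motif windows after evolution (annotation/sequencing error stand-in;
default 0).

Other-domain placement defaults to prepend/append with equal probability;
nested insertion at a repeat boundary is supported but weighted 0 by
default because it breaks the anchor spacing the naive detector relies on
(Type I then arises only via annotation-mode regions). No indels, no gene
duplication/loss, and no codon-level processes are simulated: coordinates
stay comparable across species and p-distances are well defined without
alignment.

Because DWD status and motif counts are family traits inherited by all
species copies, the independent sample size for ratio and motif-count
checks is the number of families, not the number of proteins; tests use
binomial/multinomial intervals on that basis.

**What passing tests show — and don't.** Exact recovery on noise-free
synthetic data validates the algorithms and their wiring, not performance
on real proteomes: real WD40 repeats are irregular (the naive detector
will miss non-canonical repeats that profile methods find), real motifs
degenerate beyond the hard pattern, and real domain content is far richer
than the 6-name library. The simulator's role is planted ground truth with
known statistics, not realism.

## Numerical and reproducibility choices

- All randomness flows through `numpy.random.default_rng` seeded per run;
  identical configs give byte-identical FASTA/TSV outputs.
- Coordinates are 0-based half-open internally; reports print 1-based
  positions.
- Newick output carries branch lengths to 6 decimals and integer bootstrap
  supports as internal node labels.
- Problem sizes in the acceptance script (3 species × 200 proteins, 100
  bootstrap replicates for the survey-scale tree, 1,000 replicates for the
  dedicated bootstrap checks, 100 additive trees, 10⁷ scanner windows) are
  chosen so the whole recomputation runs in about a minute on one CPU while
  keeping every statistical check at ≥ 3σ resolution.

## Known limitations

- No e-value or profile-based homology statistics anywhere; identity and
  coverage thresholds substitute.
- The A–K rule table is a reconstruction; per-species type percentages from
  external genomes are not reproduced.
- Global (not local) alignment percent similarity; multi-HSP semantics of
  BLAST reports are not emulated (a local-alignment mode is a natural
  extension but is not implemented).
- Trees are unrooted; no rooting is performed (viewers can midpoint-root the
  Newick output for display).
- The simulator does not model gene duplication dynamics or lineage-specific
  family expansion, so evolutionary-rate claims cannot be tested against it.
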