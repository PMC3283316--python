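# Methods

## Representation and the capped adjacency graph

A genome is an ordered, signed arrangement of marker identifiers into
linear chromosomes; marker `m` has two extremities (tail/head) and an
adjacency is an unordered pair of extremities that are neighbours.  For a
pair of genomes on identical marker sets the adjacency graph decomposes
into alternating cycles and open paths ending at telomeres.  We close
every path: each telomeric extremity is paired with an anonymous cap; a
path whose two endpoints are telomeric in the *same* genome is closed by
a cap–cap "null chromosome" added to the *opposite* genome; a path with
endpoints in different genomes has its two capped ends identified.  Each
path then becomes exactly one cycle, which maximizes the cycle count over
cap pairings, and the two genomes end up with equal chromosome counts
(real plus null) automatically.

Cycle lengths use the one-genome convention: a *j-cycle* contains `j`
adjacencies of one genome (elsewhere often called a `2j`-cycle).
1-cycles are conserved adjacencies and never contribute to distances.
Breakpoints are counted two ways: `b_internal` excludes every adjacency
containing a cap; `b_total` counts all adjacencies (cap-bearing and
null-chromosome ones included) lying in cycles of length ≥ 2.  Both
conventions are carried through every downstream statistic because the
published reuse-rate curves differ mainly by this choice.

## Distances

`d_DCJ = b_total − c` with `c` the number of cycles of length ≥ 2; each
cycle resolves independently in `j − 1` double-cut-and-join steps.

`d_HP = d_DCJ + h + f` restricts the repertoire to inversions,
translocations, fissions and fusions.  The correction is computed by two
engines:

* **Exact (small genomes, ≤ 10 markers, ≤ 2 chromosomes per genome).**
  Every sequence of generalized inversions corresponds to a reversal
  scenario on a capped concatenate of the two genomes, so the distance is
  the minimum, over all cappings and concatenations, of the classical
  unichromosomal signed reversal distance (breakpoint-graph cycles plus
  hurdle/fortress analysis of unoriented components).  The search
  enumerates chromosome orders and orientations on *both* sides (the
  junction structure between concatenated chromosomes depends on them —
  fixing one side demonstrably loses optimality), all cap placements and
  cap signs, pads both genomes with one null chromosome beyond the larger
  chromosome count so that scenarios transiently exceeding it (a fission
  before a fusion) stay representable, and iterates candidates round-robin
  across arrangement blocks with an early exit at the DCJ lower bound (for
  unichromosomal pairs sharpened by the count of minimal unoriented real
  components, each of which forces one extra inversion; with more
  chromosomes a translocation can dissolve such a component for free, so
  there the bound stays at `d_DCJ`).  Exactness is not argued from a
  particular formula but enforced by test: the engine agrees with
  breadth-first search over genome space on every single-chromosome pair
  with ≤ 5 markers and on hundreds of random multichromosomal pairs with
  ≤ 8 markers.  Worst-case cost is minutes for a pathological
  two-chromosome instance; typical instances resolve in milliseconds.

* **Component heuristic (large genomes).**  `h + f` is read off the
  unoriented *real* components of the capped graph: cycles confined to a
  single chromosome, free of caps, all of whose arcs connect extremities
  an odd number of positions apart.  Components interleave when arcs
  cross; a component is a hurdle when the remaining unoriented components
  lie entirely inside or entirely outside its span; a hurdle whose removal
  creates a new hurdle is a superhurdle, and an odd number of hurdles, all
  super, adds the fortress +1.  Obstructions entangled with chromosome
  ends (the semi-knot analysis of the full multichromosomal theory) are
  not detected, so `d_HP` can in principle be underestimated by a unit in
  contrived telomere-heavy configurations; at the scales where this
  engine runs (hundreds to thousands of blocks) such configurations are
  vanishingly rare and the published difference `d_HP − d_DCJ` is itself
  at the percent level.

The breadth-first-search oracle (`bpreuse.oracle`) is deliberately
independent of all of the above: it canonicalizes whole genomes
(chromosomes modulo flips, circular chromosomes for the DCJ set) and
searches genome space bidirectionally.  It refuses more than 9 markers.

## Reuse statistics

`r = 2d/b` is computed as an exact rational: `r_GRIMM = 2 d_HP /
b_internal` and `r_DCJ = 2 d_DCJ / b_total`, mirroring the two published
conventions.  A single j-cycle has `r_j = 2(j−1)/j`, and the global rate
is exactly the breakpoint-weighted mixture `Σ n_k·k·r_k / Σ n_k·k` over
cycle classes — an algebraic identity the tests enforce on random
spectra.  `r_DCJ ∈ (0, 2]`; `r_GRIMM` can exceed 2 in telomere-heavy
cases and is reported unclamped.  Cycle fractions `f_2, f_3, f_{>3}`
(of cycles with j ≥ 2) accompany every profile.

## Random-permutation theory

For unsigned permutations, `⟨q_j⟩ = 1/j`, `⟨c⟩ = H_N`,
`⟨c₃⟩ = H_N − H₃`.  For signed genomes the null model is the uniform
random *bipairing*: 2N extremities paired into N adjacencies in
(2N−1)!! ways and compared against a fixed pairing.  The closed form

    ⟨q_j⟩ = C(N,j) (j−1)! 2^(j−1) (2N−2j−1)!! / (2N−1)!!

is admitted only because it reproduces exhaustive enumeration exactly for
every N ≤ 6 (and the odd harmonic series `⟨c⟩ = Σ 1/(2i−1)`, with
`⟨c₃⟩ = ⟨c⟩ − ⟨q₁⟩ − ⟨q₂⟩ − ⟨q₃⟩`); a Monte-Carlo pairing sampler
validates it at large N.  For large N, `⟨c⟩ ≈ ½ ln N + ln 2 + γ/2`.

**Capping offset.**  A *linear* genome pair with k chromosomes per genome
is not a uniform bipairing: path closure forces exactly 2k cap-containing
cycles, so its total cycle count exceeds the series by an O(k) amount
that does not vanish with N (measured: ≈ 0.6 cycles at N = 500, k = 1).
Comparisons against observed or simulated genomes therefore use the
matched random-*genome* model — a uniform signed permutation with the
same block and chromosome counts (`sample_random_pair`), estimated by
Monte-Carlo — while the sweep pipeline's "expected >3-cycles" column
keeps the series-at-(blocks + chromosomes) convention of the published
analysis, which is why observed and expected curves approach but do not
merge even for fully randomized genomes.

## Block filtering

Greedy breakpoint elimination removes the single lowest-weight block
(ties to the lowest id) while any block sits below the weight threshold,
re-coalescing after every removal; a coalesced composite's weight is the
sum of its members and may lift it over the threshold.  Stepwise
smallest-first removal is the same procedure keyed on chromosomal span in
a chosen reference genome.  Coalescing merges maximal runs of blocks
whose oriented adjacency is conserved in *every* genome of the set
(a run read reversed with flipped strands is collinear); it is idempotent
and never changes either distance, because merged runs contain no
breakpoints.  Filtering begins from the coalesced set — runs that are
collinear everywhere carry no signal and count as single blocks from the
outset.  Both procedures are path-independent: filtering at w₁ and then
w₂ ≥ w₁ equals filtering at w₂ directly, which is what makes cumulative
resolution sweeps well defined.

## Simulator

The generator starts from an identity ancestor of N blocks on k linear
chromosomes and applies a shuffled mixture of inversions, translocations,
fissions, fusions, transpositions and block interchanges.  Cut sites are
uniform over gaps (chromosome-end gaps included) unless a fragile-site
model is enabled: a fixed set of hotspot extremities receives probability
mass ρ per cut, the remainder staying uniform.  The history log records
every cut and whether it struck a site that was not an intact ancestral
adjacency — the exact breakpoint-graph notion of reuse — so "no reuse
logged ⇒ d_DCJ equals the operation count and r = 1" is a testable
ground truth.  Block spans are exponential (the distribution implied by
uniformly scattered breakpoints), weights proportional to span
(default factor 1/300, the published span-to-weight regime) with
log-normal noise.  Defaults (1143 blocks, 20 chromosomes, 300 inversions
+ 30 translocations, 2.5 Mb mean span) put the simulator in the regime of
a fine-scale human–mouse comparison; they are plausibility choices, not
fitted values.  `degrade_resolution` drops blocks with probability
logistic in log-weight and re-coalesces (exact identity when nothing is
dropped); `scramble` applies uniform random DCJs restricted to
linearity-preserving, chromosome-count-preserving moves — the gap count
N + k is invariant under composition changes, making the walk's kernel
symmetric and its stationary distribution uniform over the matched
random-genome space.

What the simulator does *not* emulate: sequence-level alignment noise,
indels and duplications, lineage-specific block loss, or three-way
(ancestral) structure.  Passing tests therefore demonstrate correctness
of the graph/distance/filtering machinery and the qualitative
resolution-dependence of the reuse rate, not that real alignments are
free of other artefacts.

## Numerical and design choices

* Rates and expectations are exact `Fraction`s internally; decimals only
  at output.
* Deterministic tie-breaks throughout: traversal starts at the smallest
  extremity, equal-minimal blocks are removed lowest-id first, block
  renumbering ties break by (end, id), `closest_resolution` ties go to
  the lower threshold.
* Every stochastic routine takes a mandatory seed or Generator and is
  reproducible byte-for-byte.
* Test problem sizes: exhaustive oracle comparisons run at ≤ 5 markers
  (the full single-chromosome space), randomized comparisons at ≤ 8
  markers, convergence studies at 100–500 blocks with 100–200 replicates;
  these sizes make every suite deterministic and give comfortable Monte-
  Carlo resolution for 3-standard-error checks.

## Known limitations

* The component-heuristic HP engine can miss telomere-entangled
  obstructions (underestimate by ~1) on large genomes; exact behaviour is
  guaranteed only within the small-genome engine's bounds.
* The exact HP engine's worst case (an obstructed two-chromosome
  instance) costs minutes; it is intended for validation-scale inputs.
* Reuse rates for generalized transpositions are model-dependent by
  construction; both conventions are reported rather than adjudicated.
* The block-table dialect is a simplified stand-in for native alignment
  exports; only coordinates, strands and weights are modelled.
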