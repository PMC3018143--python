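# Methods

## Synteny typing

Each clone end that survives parsing and filtering keeps exactly one
placement: maximal bit score, ties broken by minimal e-value, then
lexicographically by (chromosome, start), so selection is invariant under
input order.  The e-value filter is strict (`e < 1e-10`): a hit exactly at
the threshold is removed.  Coordinates are 0-based half-open internally;
the 12-column tabular input is read as 1-based inclusive, with reversed
subject coordinates normalised and recorded as minus-strand.

A clone with one placed end is type 1.  With two placed ends, different
chromosomes give type 4; on the same chromosome the clone is type 2 when
the *leftmost* placement (ordered by start, then end, then strand) is on
`+`, the rightmost on `-` — the inward-facing mate-pair geometry — and the
outermost-coordinate span is at most `max_span`, else type 3.  The span is
the clone's footprint (outermost coordinates), not the gap between ends,
because the 300 kb rule bounds the clone's extent on the target: 300 kb is
about twice the largest expected insert.  `max_span` is exposed as
`--max-span`, default 300,000 bp.  Same-chromosome pairs inside 300 kb but
with non-opposing strands are type 3: the type-3 definition is
distance-and-orientation-agnostic, type 2 alone requires the opposing
orientation.  A clone whose second-best end fails the e-value filter
contributes as type 1.  Ends re-sequenced more than once collapse to a
single entry before pairing.

## Rate estimators

With insert length L (default 150 kb), the estimators are pure arithmetic
on the type tallies:

* `r = n3/(n2+n3)` — intra-chromosomal discordance.  Type-4 clones are
  excluded from the denominator because a large share of them are
  explained by duplicate-gene loss rather than rearrangement.
* `f = (n3+n4)/(n2+n3+n4)` — total discordance, an upper bound.
* spacing `= L / ratio`; a zero ratio reports missing (infinite spacing)
  rather than a sentinel number.
* breakpoints per chromosome `= C / spacing` with C defaulting to 48 Mb,
  and genome-wide `= G / spacing` with G defaulting to 1.0 Gbp; inversions
  are breakpoints/2, since an inversion has two edges (translocation edges
  are not halved).
* both-end expectation `p**2` under independent per-end detection, and
  expected per-chromosome paralog loss `g * d`.

Ratios are printed at 3 decimals with standard rounding.  The published
table this package reproduces mixes rounding and truncation in its last
printed digit; the shipped copy of those counts
(`besmap.published`) flags the three truncated cells and the two rows
whose printed ratios do not follow from their own printed counts at all,
and the tests assert exact agreement only where the table is
self-consistent.

## Breakpoint clustering

Type-3 clones on one chromosome are clustered by single linkage: clones
co-cluster when both their leftmost-placement midpoints and both their
rightmost-placement midpoints lie within a window W of each other
(default W = 150 kb, one insert length).  Clustering is deterministic and
permutation-invariant (members and clusters are sorted), computed per
chromosome from a dense adjacency over the type-3 clones — adequate
because type-3 clones are a few percent of the library.  `min_support`
defaults to 1 for reporting and 2 for confident calls.  Because the two
edges of an inversion produce overlapping mate-pair signatures on the
target (a clone spanning either edge places one end near each edge), a
cluster typically represents one inversion rather than one edge; truth
matching therefore credits a cluster with every true breakpoint that at
least `min_support` of its members straddle, and calls a cluster spurious
only when no member straddles any true breakpoint.

## The simulator

The generator models the study conditions as a query genome (the library
species) and a target genome derived from it:

* **Genome** — `n_chromosomes` (default 20) equal chromosomes of
  `chrom_length` (default 48 Mb), each with `genes_per_chrom` (default
  1,250) non-overlapping gene intervals of `gene_length` (default 15 kb,
  a typical teleost gene footprint) placed uniformly by the
  sorted-uniform-plus-offset construction.
* **Rearrangements** — `n_inversions` (default 160, i.e. eight per
  chromosome) and `n_translocations` (default 0: the excess of
  inter-chromosomal signal is modelled through paralogs instead) applied
  sequentially to a segment list per target chromosome; an inversion
  reverses a block in place, a translocation reciprocally swaps two
  chromosome tails.  The query→target map is piecewise linear and exactly
  invertible.  Breakpoints are recorded in query coordinates and sampled
  with a minimum separation of one insert length (and the same margin
  from chromosome ends), so a clone straddles at most one breakpoint —
  the accounting the ratio estimators assume.  Placement is by rejection
  sampling; an infeasible request (too many breakpoints for the
  separation constraint) raises a configuration error.
* **Paralogs** — each gene gains a paralog on a uniformly chosen other
  target chromosome with probability `dup_fraction` (default 1.0, the
  whole-genome-duplication remnant); among duplicated genes the syntenic
  copy is lost with probability `loss_prob` (default 0.05).  A detected
  end whose midpoint falls in a lost-syntenic gene is redirected to the
  paralog with random strand — the simplest model of a paralog winning
  the best-hit contest.
* **Library** — `n_clones` (default 73,728) with inserts drawn from a
  normal distribution (mean 150 kb, SD 15 kb — the survey reports only
  means, so a ~10% CV was chosen once as typical BAC-library spread)
  truncated to [2 × end_length, chromosome length]; two inward-facing
  `end_length` (600 bp) reads per clone.
* **Detection** — each end independently yields a hit with probability
  `detect_prob` (default 0.17, the observed per-end hit rate).  Synthetic
  bit scores are drawn high for orthologous placements
  (N(480, 60) clipped to [150, 900]) and low for paralog redirects
  (N(220, 35) clipped to [120, 350]), with `e = 10^(-bit/10)`, so all
  emitted hits pass the 1e-10 filter and the type-4 score distribution
  sits below type 2, as in the real survey.

One seeded `numpy` generator is threaded through every stage; the same
seed yields byte-identical FASTA and hit tables.  The truth table stores
each detected clone's type, derived geometrically from its true
placements, plus the set of breakpoints it straddles — an independent
restatement of the typing rule, so the end-to-end comparison exercises
the full write/parse/select/pair/classify path.

What the simulator does *not* model: nucleotide-level divergence (reads
are random sequence; hits are emitted from coordinates), fissions and
fusions, gene-restricted detectability (detection is uniform along the
insert, so the simulated type-4 fraction at the default paralog
parameters is a few percent of double-hit clones, smaller than the
24–37% seen in real data where hits are concentrated in genic sequence),
repeat content, or chimeric clones.  Passing tests therefore validate
the estimators' arithmetic and the pipeline's bookkeeping under the
stated generative model, not the biological completeness of that model.

## Microsatellite scanner

Perfect tandem repeats only, periods 2–4, with minimum run lengths
12/12/16 bp (di/tri/tetra) — configurable; these thresholds select runs
long enough to be polymorphic genotyping markers.  The published survey
used an external tandem-repeat finder with unstated parameters, so its
absolute repeat counts are not reproduction targets.  Runs are maximal;
`N` breaks runs; mononucleotide runs and units that are themselves
periodic (e.g. `ACAC` as a tetramer) are excluded.  Adjacent maximal runs
of the same period can share up to period−1 bases; the longer run keeps
the contested bases (equal lengths trim both), a strand-symmetric rule
chosen so that calls are invariant under reverse complementation with
mirrored coordinates.  Motifs are canonicalised to the lexicographic
minimum over all rotations of the unit and of its reverse complement.

## Library statistics

Mean read length is `total_bp / n_sequences`; clone coverage is
`n_clones x mean_insert / G` and sequence coverage `total_bp / G`, with
G defaulting to 1.0 Gbp (consistent with the survey's coverage
arithmetic).  The published per-centre totals are shipped as inputs and
reproduce the printed means (562.6 bp and 527.3 bp), 3.8% sequence
coverage and 6.8× clone coverage.

## Numerical and format choices

BED output is 0-based half-open, GFF3 1-based inclusive, Circos links use
the two-anchor single-line dialect with a trailing `id=` parameter.
Placements are clipped to chromosome ends; a placement starting beyond
its chromosome is a validation error naming the record.  Score
histograms bin e-values by decade (`floor(log10 e)`), truncated at the
significance cutoff.  Degenerate estimator inputs (zero denominators,
zero ratios) report missing values rather than raising.

## Problem sizes

The test suite simulates at reduced scale (2–5 Mb chromosomes, hundreds
to thousands of clones) — sufficient for the binomial and recovery bounds
it asserts — while the analysis scripts run the full survey scale
(20 × 48 Mb, 73,728 clones), which completes in a few seconds; the
parameter-recovery check uses 5 × 5 Mb with 10 inversions and 2,000
clones at full detection, about 12× clone coverage.
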