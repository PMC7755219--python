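# Methods

`polyscape` models how the sequence specificity of a hairpin
pyrrole–imidazole polyamide, measured in vitro by iterative selection
from a randomized DNA library, predicts where the ligand binds across a
genome, and how those predictions compare with crosslink-capture data.
Every stage runs on synthetic data with planted ground truth, so the
whole chain is testable end to end without external downloads.  This
note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Affinity model

An eight-ring hairpin reads six base pairs.  Ring-pair chemistry
(Im/Py → G·C, Py/Im → C·G, Py/Py → A·T or T·A, written W) defines a
degenerate 6-bp target — here `WGWWCW` (ligand 1) and `WGGWCW`
(ligand 2), differing at one position.  Relative affinity of a concrete
duplex hexamer is

    a(site) = a0 · θ^d,

with `d` the mismatch count of the better-matching strand against the
target's IUPAC sets.  θ (default **0.1**, dimensionless, per mismatch)
is an invented parameter: no binding constants are available for these
conjugates.  0.1 reproduces two qualitative features of the measured
specificity at once — a steep drop-off away from the cognate site, and
visible enrichment of one-mismatch sites in early selection rounds that
is then competed away in later rounds (the round-wise "selection
effect").  Much smaller θ erases the second feature; much larger θ
erases the first.  A read's occupancy is the sum of `a` over its
fifteen 6-bp windows — additive, saturation-free, the simplest form
that produces round-wise enrichment.

## Synthetic SELEX

The selection pool holds `pool_factor × n_reads` molecules of a
randomized 20-bp library (sequence space 4²⁰ ≈ 10¹²); each round
resamples the pool with probability ∝ `1 + λ·occupancy` and `n_reads`
molecules are sequenced.  λ (default **50**) is the selection-strength
analog of ligand concentration; λ = 0 yields the matched mock
("processed library") series used for background normalization.  The
defaults are `n_reads` = 200 000 (a deliberate scale-down of the
~10⁶ reads per barcode of a real run; chosen so the whole study fits
comfortably in a test session), three rounds, uniform base composition.

The enriched series uses `pool_factor` = 1 — selection plus
amplification collapses library complexity to the order of the captured
molecules, so sequenced reads carry duplication structure.  The mock
series uses `pool_factor` = 10: without selection the library retains
its complexity and mock reads are essentially duplicate-free.  The mock
depth is a free design choice; a clean mock matters because background
model noise propagates *coherently* into the expected counts of every
word sharing a core context, and that family-level noise is what top-50
rankings are most sensitive to.

## Enrichment scores

Every 8-mer is counted with a sliding window over each read **and its
reverse complement** (the ligand binds duplex DNA), making the count
table exactly strand-symmetric.  Expected counts come from a
fifth-order Markov model fitted on the mock pool processed the same
number of rounds: conditional probabilities use Laplace pseudocount
α = 1 and context counts obtained by marginalizing the 6-mer counts —
the marginal, not the raw 5-mer counts, is what makes every conditional
distribution sum to one (read-final 5-mers have no extension).  The
score is the standardized ratio

    r(x) = observed(x) / max(expected(x), ε),   ε = 0.5
    z(x) = (r(x) − mean r) / sd r               (population sd, per round)

computed on raw ratios (a `log2` variant exists but is off by default).
z is the "binding intensity" used by every downstream stage.

## Motif recovery (stand-in for an EM motif finder)

PWMs are built from the 50 most-enriched 8-mers by a deterministic
anchored multiple ungapped alignment rather than an EM/Gibbs motif
finder, which is out of scope.  The procedure is two-pass:

1. Greedy: the rank-1 word anchors the frame; each next word takes the
   (offset ∈ ±2, strand) maximizing positional agreement with the
   running profile.  Ties break by smaller |offset|, then forward
   strand, then smaller offset.
2. Class refinement: columns of the provisional profile that are ≥ 50 %
   covered and ≥ 75 % pure in one complementary base class (W = A/T,
   S = C/G) define a strand-invariant class pattern; every word is then
   re-placed scoring agreement on classified columns only, with
   profile agreement on S columns as tie-breaker.

The refinement exists because naive greedy placement decides each
word's *orientation* by flank and A-vs-T agreement: for a
reverse-complement-palindromic target such as `WGWWCW` both
orientations of a word place the core identically, so hard assignment
collapses the degenerate W columns toward the anchor's bases and
inflates flank information.  Under the class pattern the two
orientations tie exactly and the forward-strand rule preserves the
natural A/T mixture; for a non-palindromic target (`WGGWCW`) the S
columns still force the correct strand flips.  Refinement only applies
when the classified columns contain a contiguous core of ≥ 4 columns:
agreement-seeking alignment invents coherence even in pure-noise input,
and with no evidence of a core the words are left unaligned — the
correct null.

Column probabilities use pseudocount 0.25; information content is
computed from the **raw** column frequencies with the
Schneider–Stephens small-sample correction `3/(2·ln2·n)` per column
(the pseudocount only regularizes the emitted matrix).  The apparent
binding-site width is the longest run of columns with ic ≥ 0.3 bits —
a mean-ic criterion degenerately favors 1–2 columns, while the run
criterion matches the ≈1-bit W / ≈2-bit G/C / ≈0-bit flank structure.
The recovered motif is the run's consensus (single base at p ≥ 0.65,
two-base code at pooled p ≥ 0.8, else N) with uninformative N edges
trimmed, reported in the lexicographically smaller of its two
orientations, since strand-symmetric data cannot fix the orientation.

What passing does not show: the generator gives all concrete cores of a
target identical affinity, so the top-50 ranking among them is driven
by sampling noise with an irreducible family-coherent component; at
some RNG seeds the list concentrates on one core family and the
recovered W columns sharpen toward that family's bases, and genuine
flanking-context preferences (overlapping partial sites under the
additive occupancy model) can lift one flank column just over the
0.3-bit threshold, widening the run to 7.  Real selections spread
families by true flanking-affinity differences.  The bundled tests
assert recovery at the canonical seeds; the reproduction script reports
whatever the chosen seed yields.

## Specificity landscapes (SELs)

All 4⁸ 8-mers are organized in concentric rings by minimal mismatch
distance to the 6-bp seed, minimized over the three alignments of the
seed within the 8-mer and both strands — the only reading under which
an "exact match" ring is well defined for 8-mers against a 6-mer seed.
Among equal-distance alignments the forward strand wins, then the
smaller offset; this affects only the mismatch-position labels, never
the distance.  Within a ring, entries are ordered by mismatch-position
tuple then alphabetically, so ring 1 begins with position-1 mismatches;
each entry gets angle 2πi/ring-size and carries its z as height.  A
mismatch at a W position costs 1 like any other.  Each 8-mer appears
exactly once.

## Genomescapes and Summation-of-Sites

A genomescape assigns `max(z(w), z(revcomp(w)))` to every genomic
position's 8-mer so a site scores identically on either reference
strand; non-ACGT windows carry no value.  SOS tiles the contig with
420-bp windows stepped by 210 bp (full windows only, 0-based half-open
coordinates), summing (default; mean behind a flag) the z of every
8-mer *fully contained* in the window; windows more than 50 % N are
flagged and excluded from ranking.  Top-ranked windows (ties by
coordinate) are the predicted binding loci.

A practical observation from the synthetic study: summing ~413 noisy z
values per window gives the background a standard deviation of ~10–15
z-units, and the more degenerate `WGWWCW` target (four W positions)
sits closer to an AT-rich background than `WGGWCW`, so its
cluster-versus-background contrast is weaker.  At the default depth the
planted-cluster recovery check (≥ 27 of the top 30 windows on truth)
holds for the `WGGWCW` dataset and is not reliable for `WGWWCW`; the
cross-ligand separation holds for both.

## Synthetic genome and crosslink tags

The genome generator plants non-overlapping 420-bp clusters (30 per
ligand on a 2-Mb contig, GC 0.41) each containing exactly 3 exact,
4 one-mismatch and 6 two-mismatch sites at ≥ 6-bp spacing.  For the
emitted truth to be *exact* under rescanning, the background is
scrubbed: any window within mismatch distance 1 of either seed
genome-wide, or distance 2 of the cluster's own seed inside a cluster,
is repaired by mutating non-site bases (a vectorized bulk phase, then a
sequential phase escalating to multi-base edits with bases that
mismatch every seed on both strands).  Planted mismatch sites are
rejection-sampled so their strand-minimal distance is exactly as
intended, they are not exact sites of the other ligand, and their
shifted frames are repairable; the rare cluster whose layout still
cannot be scrubbed is redrawn.  Scrubbing shifts background composition
slightly toward G/C; an i.i.d. background would otherwise contain ~1 %
near-cognate windows and no exact truth could be stated.

Crosslink tags draw fragment midpoints proportional to
`a(site)^w` smoothed by a Gaussian kernel of scale `frag_mean/2`
(midpoints sit up to about half a fragment from the crosslinked site),
with fragment lengths Normal(200, 50) floored at 50 bp (sonication
scale) and a uniform noise floor (`noise_frac` = 0.1).  The capture
exponent `w` (default **3**) models the protocol's sequential stringent
washes — survival of a bound complex is a power of its affinity; with
plain occupancy-proportional capture (`w` = 1) the summed weight of the
~4·10⁵ two-mismatch background windows would exceed the planted
clusters 40:1 and no peak structure would exist.  Sites with a T within
12 bp of either edge (the extended-linker scale of the
photo-crosslinker, which prefers thymines) get weight × 1.5.  PCR and
sequencing-error models are deliberately absent.

## Stand-in peak caller and comparisons

The bundled caller is for synthetic end-to-end tests only: window
midpoint counts against a global Poisson rate, tail probability
< 10⁻⁵, overlapping keepers merged, merged peaks scored by best fold
enrichment.  Real peak sets can be supplied as BED.  Tag densities
around peaks use 25-bp bins over a 10-kbp window centred on each peak,
normalized to a 10⁷-tag library (the fragment midpoint is the reference
point; no strand-shift estimation).  Peak sets are compared by
interval-level overlap fractions and base-pair Jaccard.  Display
scaling (×10 tag density, ×100 genomescape/SOS) is applied only at
export.

## Numerical and interface conventions

All coordinates are 0-based half-open; BED6/bedGraph round-trip
bit-exactly at six significant digits.  Every generator is a pure
function of its config and seed (NumPy PCG64); the pipeline runner
stamps outputs with a config hash and is byte-identical under reruns.
Ranking ties anywhere break deterministically (alphabetical for words,
coordinate order for windows).  Problem sizes of the bundled study —
200k reads × 3 rounds, 2-Mb genome, 10⁵ tags per capture — were chosen
as the package's desk-scale defaults; a laptop reproduces the full
study in a few minutes.

## Known limitations

- Affinity is a single-parameter geometric penalty; no
  position-specific or flanking energetics, so equal-affinity core
  families are distinguishable only by noise (see motif section).
- The selection model is linear in occupancy and saturates quickly at
  λ = 50; concentration series are not calibrated to molarity.
- The scrubbed background makes truth exact but is not an i.i.d.
  genome; incidental-site statistics of real genomes are not modelled,
  and no chromatin-accessibility model exists.
- The apparent site width can read 7 at some seeds (flank columns at
  the information threshold); the recovered core after N-trimming is
  6 bp.
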