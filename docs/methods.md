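# Methods

`gbskaryo` infers the karyotype of allopolyploid plants — here wheat x rye
amphidiploids, genome constitution AABBDDRR — from the genome-wide coverage
profile of genotyping-by-sequencing (GBS) reads. GBS coverage is sparse and
very uneven along the genome (restriction-site targets cluster), but the
unevenness is shared across samples sequenced with the same protocol, so
the *ratio* of a sample's coverage to that of euploid control samples is an
informative dosage signal: a chromosome present in one copy instead of two
runs at half the control rate, an eliminated chromosome drops to the
cross-mapping background, a trisomic one runs at 1.5x.

## Model

Reads are counted per sample in non-overlapping fixed-width bins (default
1 Mb) over a combined genome model (chromosome names, subgenome labels
A/B/D/R, lengths, centromere positions; BED-style 0-based half-open
coordinates throughout). For sample *s* with per-bin counts
*x<sub>sb</sub>*:

1. **CPM scaling** — *c<sub>sb</sub>* = *x<sub>sb</sub>* / Σ<sub>b</sub>
   *x<sub>sb</sub>* x 10⁶, removing library-size differences.
2. **Control reference** — the per-bin arithmetic mean *m<sub>b</sub>* of the
   CPM values of the designated euploid controls. Bins with
   *m<sub>b</sub>* < `min_control_cpm` (default 1 CPM) are GBS target
   deserts carrying no dosage information; they are masked explicitly and
   excluded from all downstream statistics, never silently zeroed.
3. **log2 ratio** — *r<sub>sb</sub>* = log2((*c<sub>sb</sub>* + p) /
   (*m<sub>b</sub>* + p)) with pseudocount p = 0.5 CPM, floored at −5.
   The pseudocount bounds deleted regions (which would otherwise be −∞);
   the floor keeps profiles plot-friendly. Both are configurable. For a
   cohort of identical control vectors the pseudocount cancels and control
   ratios are exactly zero.

Under balanced dosage E[*r*] ≈ 0; a copy-number state *k* sits near
log2(*k*/2). Profiles are computed at the counting resolution (1 Mb) and
conventionally displayed in 5 Mb bins (mean of unmasked fine bins; sums for
raw counts, conserving totals).

### Compositional re-centering

CPM scaling is compositional: the reads a sample "loses" with an eliminated
chromosome are redistributed over the remaining bins. A plant that lost the
whole rye subgenome (~25% of bins) has every remaining wheat bin elevated
by +log2(4/3) ≈ 0.415 — past the trisomy decision boundary (0.322). The
caller therefore re-centers each sample's log2 profile on its own euploid
baseline before segmentation, using a two-pass trimmed median: the median
of all unmasked bins, then the median of bins within ±0.75 log2 of that
first pass (excluding floored/deleted and strongly aberrant bins, which
otherwise drag the plain median off the baseline). This assumes the
majority of unmasked bins are euploid, which holds for every event class in
scope; it would fail for a genome-wide polyploidization, which coverage
ratios cannot detect anyway. Re-centering can be disabled
(`recenter=False`).

## Segmentation

Each chromosome's (masked-compacted) log2 series is segmented by exact
penalized least squares: minimize Σ within-segment squared deviations +
λ·(number of segments − 1) subject to a minimum segment length
(`min_seg_bins`, default 3 bins — events below ~3 Mb are beneath the
method's resolution and outside the "major rearrangement" scope). An
O(n²) dynamic program finds the global optimum; ties are broken toward
fewer segments, then leftmost breakpoints, so results are fully
deterministic. The test suite verifies the DP against exhaustive
enumeration on hundreds of short series.

The penalty default is λ = 20 x the per-bin noise variance estimated from
the controls' own log2 ratios. Rationale: a spurious k-bin segment at mean
deviation d buys an objective gain of ~k·d², and segmentation scans every
position (a heavy multiple-testing burden), so λ must sit above what noise
runs achieve; it must stay below the gain of the smallest real event in
scope, 5 bins at half dosage (gain 5·1² = 5 versus 2λ ≈ 4 at the default
noise level of ~0.1). At 10x, simulated cohorts showed tens of spurious
sub-arm calls; at 20x about one per 30-genotype cohort, with all planted
events still recovered. The penalty is exposed as a parameter.

## Copy number and event classification

A segment with mean log2 ratio *r* is assigned copy number
CN = round(2·2^*r*), clipped to [0, 4] (tetrasomy is the largest state
handled); exact half-integer boundaries round down, toward fewer copies.
The class boundaries fall at *r* = −2.0, −0.415, +0.322, +0.807.

Arm copy number is the *length-weighted mode* of segment copy numbers over
the arm (ties toward fewer copies) — a mode, not a mean, so a terminal
deletion does not shift its arm's baseline. The bin containing the
centromere coordinate belongs to the short (S) arm; the arm boundary is
that bin's end. Chromosome-level labels from the arm pair (CN_S, CN_L):

| arm pattern | label |
|---|---|
| (2,2) | disomic — no event emitted |
| (0,0) / (1,1) / (3,3) / (4,4) | nullisomic / monosomic / trisomic / tetrasomic |
| unequal arms | telosomic for the retained (higher) arm: ditelosomic if the arms differ by ≥2 copies, monotelosomic if by 1; both arm CNs recorded as context |

Segments whose copy number falls below the copy number of the arm holding
the majority of the segment are deletion events: **terminal** if the
segment touches a chromosome end, **pericentric** if it spans or abuts the
centromere bin (the abut rule is a convention), else **interstitial**.
Comparing against the majority arm prevents a breakpoint that lands one
bin past the centromere from misfiring against the other arm's dosage.
Segments *above* their arm's dosage are not classified (sub-arm
duplications are out of scope).

Locus dosage (e.g. the incompatibility alleles on 6AL and 6RL) is the
minimum copy number over segments overlapping the locus interval; the
locus is "present" while at least one copy remains. If no segment overlaps
(a masked desert), the arm's copy number is used.

## Chromosome-number accounting

The somatic chromosome number is 2n = Σ over chromosomes of
max(CN_S, CN_L): a telocentric chromosome (one arm lost) still contributes
each remaining homolog as one chromosome body, so a ditelosomic plant keeps
the euploid count (56 for AABBDDRR), while whole-genome rye elimination
gives 42 and the parental forms give 42 (wheat) and 14 (rye). Mixed states
such as (2,1) contribute max = 2 bodies; this is a declared convention —
such configurations are cytologically ambiguous from coverage alone.

## Synthetic data generator

The simulator emulates exactly the structure the method assumes. Expected
count for bin *b* of sample *s*:

    mu_sb = L_s · d_b · (w_b / w) · max(k_b / 2, f)

with library size L_s (log-normal around 2x10⁶ reads, sigma 0.2), shared
per-bin target density d_b (log-normal, sigma 0.7, normalized so a euploid
sample's expected total is L_s), bin-length fraction w_b/w (the truncated
final bin of each chromosome has proportionally fewer targets), planted
per-bin copy number k_b, and cross-mapping floor f = 0.02 (deleted regions
still attract ~2% of the baseline rate through homoeologous mis-mapping —
fully deleted bins rarely read exactly zero in allopolyploids). Counts are
negative binomial with dispersion 0.05 (variance mu + 0.05·mu²); Poisson
is the dispersion-0 limit, used for analytic checks. Events (copy number
0–4 over a whole chromosome, one arm, or a bp segment; non-overlapping
within a genotype) are expanded to per-bin dosage with overlap weighting at
bin edges. Per-genotype RNG substreams are keyed by (seed, crc32(genotype
name)), so reordering or extending a cohort never changes an existing
genotype's counts.

The default synthetic genome has 28 chromosomes (21 wheat + 7 rye) of
36–60 Mb — deliberately ~2 orders of magnitude below real Triticeae
assemblies so the full pipeline runs in a couple of seconds; real
assembly-scale genome models are read from TSV. The default demo cohort
(30 genotypes: 6 controls + 24 aneuploids) covers every event class:
nullisomy, monosomy, trisomy, tetrasomy, arm losses, terminal/
interstitial/pericentric deletions, and whole-subgenome elimination.
Library-depth defaults are chosen for desk-scale statistical power (mean
bin count well above 100), not taken from any particular sequencing run.

**What the simulator does not model** — and what passing tests therefore do
not demonstrate about real data: GC- or mappability-driven coverage bias
that differs *between* samples (batch effects), restriction-site
polymorphism between genotypes (a real wheat x rye cohort has
genotype-specific target loss), translocations (balanced exchanges are
invisible to coverage), sub-bin events, and mosaicism (all cells of a
simulated plant share one karyotype).

## Numerical and degenerate-input choices

* Exact-constant control columns are kept bit-exact in the control mean so
  identical controls give exactly zero log2 ratios.
* A series shorter than `min_seg_bins` forms a single segment (whole short
  chromosome); an all-masked chromosome is reported as assumed-disomic with
  no events.
* Segment edges are snapped to chromosome ends across leading/trailing
  masked bins, so a masked telomeric desert does not turn an interior
  deletion into a terminal one.
* Copy numbers are capped at 4; log2 ratios floored at −5.
* All file formats are plain TSV; genome, count, and call tables round-trip
  bit-exactly (segment means are serialized via `repr`).

## Known limitations

Coverage ratios measure *relative* dosage: a uniform whole-genome change
(e.g. unreduced gametes) is undetectable. Events smaller than
`min_seg_bins` bins are out of scope by design. Arm classification near
the centromere depends on the declared centromere coordinate; a mis-placed
centromere converts arm events into large segmental ones. The 2n rule
cannot distinguish a (2,1) mixed whole/telosome state from alternatives
with equal body count.
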