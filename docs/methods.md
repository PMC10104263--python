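# Methods

## The screen model

A pooled knockout resistance screen is, statistically, a selection
experiment on a barcoded population: each cell carries one sgRNA, drug
selection multiplies each lineage's expected mass by a survival factor, and
sequencing samples the surviving barcode pool. The simulator implements
exactly that chain:

1. **Library.** `n_genes × guides_per_gene` distinct random 20-mers (default
   120 × 6). Six guides per gene mirrors genome-scale knockout libraries.
2. **Initial representation.** Per-guide abundance ~ lognormal(0, σ),
   normalized; σ defaults to 0.5, a typical plasmid-pool skew (~1.6-fold
   interquartile spread). σ = 0 gives the exactly uniform pool.
3. **MOI bottleneck** (optional, on by default). At MOI *m* (default 0.35,
   within the usual 0.3–0.4 transduction window) a Poisson fraction
   1 − e^−m of cells is infected and survives antibiotic selection;
   the infected pool of `n_guides × cells_per_guide × (1 − e^−m)` cells
   (default coverage 300×) is assigned to guides multinomially.
   Multiply-infected cells are not modeled.
4. **Drug selection.** One multiplicative survival step per dose arm:
   every guide's mass is multiplied by the arm's baseline survival
   (defaults 0.05 at the low dose, 0.01 at the high dose, for a
   two-week selection that kills ≥ 95% of non-resistant cells), and guides
   of *planted* resistance genes additionally by their selection advantage
   s ≥ 1 (capped at survival 1). This is deliberately not a birth–death
   process over the treatment window: a single multiplier per arm is the
   minimal model that produces the enrichment structure the analysis must
   detect, and no kinetic parameters are available to constrain anything
   richer.
5. **Sequencing.** Counts ~ negative binomial with mean `depth × abundance`
   and variance `m + αm²` (α default 0.1, a mid-range estimate of
   PCR/sequencing overdispersion in screen data; α = 0 degenerates to
   Poisson; an exact-multinomial mode conserves total depth). Default depth
   10⁷ reads/sample.
6. **Reads.** FASTQ emission writes one read per count unit as
   `flank_5p + guide + flank_3p` (flanks default to the U6-promoter end and
   scaffold start of lentiviral guide constructs) with i.i.d. per-base
   substitutions at `read_error_rate` (default 0.001); no indels. Read
   titles carry the originating guide so assignment can be audited.

All stages draw from child streams of a single seed; identical configs give
byte-identical libraries, counts, FASTQ and reports.

**What the generator does not emulate:** PCR jackpotting and chimeras,
guide-specific cutting efficiency and Cas9 fitness costs, copy-number
confounders, multi-guide cells, indel sequencing errors. Passing tests
therefore demonstrate that the analysis recovers enrichment structure under
realistic representation skew, bottlenecks and counting noise — not that it
is robust to every artifact of real screen libraries.

## Counting

Guide extraction is anchored (first exact occurrence of a 5′ flank
substring, optionally verified 3′) or fixed-offset for constant-layout or
pre-trimmed reads. Assignment is exact dictionary lookup by default; the
1-mismatch mode precomputes all Hamming-1 neighbors of every guide and
assigns a candidate iff exactly one guide sits at distance 1 (collisions are
recorded as ambiguous, never counted). Per sample,
`assigned + no_anchor + no_match + ambiguous = total_reads` is enforced as a
class invariant. At a 0.001/base error rate the exact matcher is expected to
assign (1 − 0.001)²⁰ ≈ 98.0% of constant-layout reads and the 1-mismatch
matcher ≈ 99.98%, which is what the tests observe.

Abundance is expressed as reads per million assigned reads (RPM):
`(count + pc) / (assigned + pc·n_guides) × 10⁶`, pseudocount default 0. RPM
makes the score's abundance term depth-independent; multiplying a sample's
counts by any constant leaves every score unchanged (tested).

## Scoring and hit calling

`score = (n_detected / n_library) × log2(max(mean RPM of detected guides, 1))`.

Choices a user can move, with defaults and rationale:

- **detection_threshold = 1 raw read.** Any recovered guide counts as
  evidence; deeper screens may raise it.
- **Mean over detected guides** (not all guides): the selected sample is the
  only sample sequenced, and averaging zeros from lost guides into the
  abundance term would double-count dropout, which the detection fraction
  already measures. A mean over all guides is available
  (`detected_only=False`).
- **abundance_floor = 1 RPM** keeps log2 ≥ 0, so the score cannot go
  negative on sub-1-RPM noise and its sign always reads as "enrichment".
- **Variant.** The division form `(n_det/n_lib) / log2(Ā)` exists as
  `variant="division"`; it is not the default because dividing by the
  log-abundance of a strongly enriched gene penalizes exactly the signal a
  resistance screen selects for.
- **top_k = 10** per arm for the two-dose intersection; small enough that
  intersection is selective at genome scale, large enough to tolerate
  rank jitter between arms.
- **min_detected = 1** pre-filter before ranking (genes failing it sink to
  the bottom rather than vanishing, keeping the gene universe identical
  across arms — required by the intersection).

Ranking ties break by detected-guide count, then gene symbol, making ranks
fully deterministic.

## Off-target scan

Plain Hamming scan of every window on both strands (the reverse strand is
scanned as the reverse-complement guide against the forward subject), `N`
never matches, positions are leftmost forward-strand coordinates. The
default tolerance of 3 mismatches reflects common practice for nominating
candidate off-target sites; subjects are expected at amplicon scale
(~500 bp contexts around predicted sites), so no genome index is built.
PAM context is deliberately not modeled — the scan answers "how close is
this sequence anywhere in the subject", and PAM filtering would silently
drop sites a nuclease variant might still cut.

## Dose-response and assay math

Viability is modeled as a four-parameter logistic in log10 concentration,
`v(c) = bottom + (top − bottom) / (1 + (c/IC50)^hill)`; the reported IC50 is
the curve's inflection (relative IC50). Fitting is least squares,
multi-started over a deterministic 7 × 4 grid of log-IC50 × Hill-slope
initial values (bounds: asymptotes in [−0.5, 1.6], hill in [0.01, 10],
log-IC50 within ±3 decades of the dose range), so identical input always
returns the identical fit; a curve whose fitted dynamic range is below 0.1
viability units is flagged `converged=False` instead of raising.
`fix_bottom`/`fix_top` pin the asymptotes — with viability normalized to
untreated control, `fix_top=1` (plus `fix_bottom=0` for fully cytotoxic
drugs) is the standard normalized-response model, and it roughly halves the
IC50 sampling error at bench-typical noise: at 5% Gaussian noise with 3
replicates over 8 two-fold dilutions bracketing the IC50, the constrained
fit's relative error distribution (Cramér–Rao SD ≈ 6%) supports the
within-10% recovery the tests assert, whereas the free 4-parameter fit's
does not (SD ≈ 13–19% depending on dose design).

The remaining assay functions are deliberately thin, exact formulas —
tail-DNA % of an intensity profile with an externally supplied head/tail
boundary (image segmentation is upstream and out of scope), GFP/transfected
repair efficiency, IdU/CldU tract ratio (unit-free), caliper volume
`L·W²/2` with `L ≥ W` enforced, and treatment percent change — wrapped in
typed containers that enforce domain invariants at construction. Group
comparisons delegate to scipy: Mann-Whitney (exact null when both n ≤ 20
and the pooled sample is tie-free, tie-corrected normal approximation
otherwise) for per-cell and per-fiber distributions, Welch's *t* for
summary-level comparisons.

## Test-size choices

Simulated fixtures are desk-scale: 10–120 genes, 5k–100k reads per FASTQ,
20-replicate seed studies. These sizes put every property (round trips,
oracle equivalences, recovery rates) well inside statistical resolution
while keeping the full suite in a few seconds; the generator itself scales
to genome-size libraries by configuration.

## Known limitations

- The enrichment score is a heuristic rank statistic: no p-values, FDR, or
  guide-level variance modeling (no RRA/Bayesian essentiality machinery),
  and no depletion (dropout) analysis.
- 1-mismatch assignment is the maximum supported stringency; indel-bearing
  reads are unassignable by design.
- The simulator's selection step is expectation-level; stochastic lineage
  extinction during drug selection is represented only through the MOI
  bottleneck and sequencing sampling, not through per-cell survival draws.
- `converged` on flat dose-response data is a heuristic (dynamic-range
  cutoff), not a statistical test for lack of fit.
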