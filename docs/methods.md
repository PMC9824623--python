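# Methods

## Model

The predictor decides, for every `TGTC`-core candidate window, between two
hypotheses: H1 — the window is a functional auxin response element (AuxRE) —
and H2 — it is not.  Evidence is represented as basic probability
assignments (BPAs) over the frame {H1, H2, H1∪H2}; the third focal element
is the ignorance set, which lets a weak source abstain instead of guessing.
Sources are assumed independent and are combined with Dempster's orthogonal
sum; the pignistic probability BetP(H1) = m(H1) + m(Θ)/2 is the ranking
score.  Total conflict between two certain, opposed sources leaves the
orthogonal sum undefined; at the engine level this is an error, while the
scanning pipeline resolves such (rare, boundary-coincidence) candidates to
total ignorance with a warning, since a flat contradiction between sources
carries no usable direction.

### Evidence sources

Three learning graphs plus one rule-based source supply the BPAs:

* **(Sc, P)** — significance z-score vs. position relative to the start
  codon.  Sc is a Poisson z-score (observed − E)/√E of the candidate's motif
  word against an order-2 Markov background fitted to the input promoters,
  with an expectation floor of 0.5; the scorer sits behind a small interface
  so an external over-representation score can be substituted.  The motif
  word is the core-oriented hexamer starting at the core (distinct `TGTCNN`
  variants carry distinct statistics).  P is negative upstream of the ATG;
  for minus-strand genes the sign convention mirrors at the candidate
  window's lowest genomic coordinate.
* **(O, D)** — the word's genome-wide occurrence on both strands, and its
  density: the fraction of auxin-responsive promoters (|log₂FC| ≥ 1, i.e.
  two-fold up *or* down, since ARFs both activate and repress) containing
  the word on either strand.
* **(f₁, f₂)** — Fisher discriminant projections of (x₁, y₁, z₁, GC%).
  The Z-curve triple separates purine/pyrimidine, amino/keto and weak/strong
  bond content and, with GC%, summarizes window composition.  The
  discriminant is fitted on three classes — site (candidates in
  summit-window positives), other-regulatory (candidates inside a peak but
  outside the summit window) and background (candidates in control
  intervals) — because two discriminant axes require at least three classes.
  Features are standardized; the within-class scatter is ridge-regularized
  by 1e-6·tr(S_w)/d·I only when singular; axes are oriented so the site
  class mean is non-negative, and offsets are chosen so the pooled grand
  mean projects to (0, 0).
* **Site context** — composite-site geometry.  ARFs preferentially bind
  multiple closely spaced cores, so two or more cores in the window with
  ≤ 50 intervening nucleotides contribute (0.67, 0, 0.33), a distant pair
  (0.33, 0, 0.67), and a lone core abstains (vacuous mass).  The rule table
  is configurable and accepts orientation-conditional entries (DR/ER/IR =
  direct/everted/inverted repeat of adjacent cores), though the default
  ladder does not weight orientation.

### Fuzzy confidence regions

Each graph is covered by a grid of confidence regions — 3×3 for (Sc, P),
3×4 for (O, D), 3×3 for (f₁, f₂).  Axis partitions are trapezoidal fuzzy
sets forming a partition of unity: interior boundaries sit at the k/n
training quantiles, each widened into a ramp of 20% of the smaller adjacent
inter-quantile gap (tied quantiles are nudged apart by a scale-relative
epsilon so the region count is preserved); the outer sets are shoulders, so
every real value is covered and memberships always sum to 1.  Fuzzification
makes the assigned mass continuous in the features — a candidate near a
boundary blends the adjacent regions' masses instead of jumping.

Each region's proposition is learned from labelled training candidates:
positives are candidates inside gold-standard summit windows, negatives are
candidates inside matched random controls.  This balanced design follows the
positive/negative training-set construction of the underlying method; it
also keeps the proposition bands meaningful — with genome-wide candidates
(positive prevalence ≈ 0.1) every non-discriminative region would fall into
the total-confidence-H2 band, whose (0, 1, 0) mass annihilates all other
evidence under Dempster's rule.  A point contributes to region (i, j) with
weight μₓ(i)·μ_y(j); the membership-weighted positive fraction p̂ maps to a
proposition via bands that are exactly mirror-symmetric under label flip:
p̂ ≥ 0.90 → P4, ≥ 0.70 → P3, ≥ 0.55 → P2, else P1, preferring H1 for
p̂ ≥ 0.5 and H2 otherwise (evaluated on max(p̂, 1−p̂)).  Regions with
effective support below 5 points default to ignorance.  Mass values are
stored exactly as the ladder prints them (0.33/0.67), which sum to 1
without renormalization.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| core word | `TGTC` | the AuxRE consensus core |
| window | 100 bp | matches the gold-standard sequence length |
| motif word length | 6 | canonical AuxRE hexamer resolution |
| fold-change threshold | 2.0 (|log₂FC| ≥ 1) | two-fold responsiveness, both directions |
| background order | 2 | captures local dinucleotide context without sparsity |
| proposition bands | 0.90 / 0.70 / 0.55 | gradual-doubt calibration of the region learner |
| min region support | 5 effective points | avoids confident propositions from empty corners |
| context spacing cut | 50 intervening nt | the spacing envelope typical of composite AuxREs |

## Synthetic benchmark

The generator emulates the data shapes of an ARF ChIP-Seq study.  Defaults
(the study conditions used throughout the tests): 400 promoters of 1.5 kb
drawn i.i.d. from an AT-rich composition (A/C/G/T = 0.3/0.2/0.2/0.3, typical
of plant promoters); half receive one planted element of two `TGTCTC` cores
with 5–50 nt spacing (uniform) and uniformly mixed DR/ER/IR orientation at a
uniform-random position; expression draws log₂FC ~ ±N(2.0, 0.5) for planted
genes and N(0, 0.5) otherwise; one peak per element (width 150–300 bp,
summit at the element centre ± ≤ 10 bp jitter) plus 25% decoy peaks placed
on element-free ground, emulating false-positive peak calls.  All randomness
flows from a single seed; every artifact is byte-reproducible.  The
background is order-0 by construction — higher-order background synthesis
would not change what the tests exercise, since the significance scorer
fits its own Markov background from the data.

What the benchmark does *not* emulate: read-level ChIP signal, chromatin
accessibility, sequence conservation, genuine promoter composition
heterogeneity, and motif variants beyond the planted hexamer.  Passing
tests therefore demonstrate that the machinery recovers planted structure
under controlled conditions, not field performance on real genomes.

A known property of these conditions: because half the promoters carry the
same planted hexamer, its over-representation statistics are extreme, and
candidate windows on planted elements already reach the top of the mass
ladder with one or two cores.  AUC consequently saturates (bounded by the
decoy-peak fraction) and does not increase further with more cores per
element; the multi-core advantage shows in the unsaturated part of the score
distribution rather than in AUC.

## Evaluation

Positives are the exact 100 bp summit windows (summit − 50 to summit + 50;
interval midpoint when no summit is called; windows crossing a sequence edge
are skipped with a warning).  Controls are rejection-sampled non-overlapping
intervals with the peaks' rounded mean width; they keep their full width,
which if anything favours the null class (more chances to contain a core)
and is therefore conservative.  A sequence's score is the maximum candidate
decision score inside it; sequences with no core score 0.49, just below
pure ignorance.  The scalar AUC is the Mann–Whitney concordance probability
(ties count one half); the plotted curve is integrated by the trapezoid rule
and agrees with the rank statistic to numerical precision (tested).  AUPR is
the step-wise (interpolation-free) precision–recall area.  Train/test
splitting is by peak, 70/30, seeded.

## Numerical and degenerate-input choices

* Intervals are 0-based half-open throughout; GFF3 is converted on read.
* `N` bases are allowed in input sequences but windows containing `N` are
  skipped (with a log message) rather than imputing frequencies.
* A palindromic word is counted once per strand (twice per forward hit).
* For a palindromic core, only forward-strand candidates are emitted (the
  two strands coincide).
* Candidate words clipped by a window edge fall back to the available
  stretch; words never seen in training score as absent (occurrence 0,
  density 0, Sc from the stored background).
* Dempster combination renormalizes by 1 − K (classical rule); alternatives
  that redistribute conflict are out of scope.
* The 0.33/0.67 ladder masses are used verbatim; their float sum equals 1
  to well within the 1e-9 BPA validation tolerance.

## Limitations

* The significance score is a Poisson z-score stand-in with the same
  over-representation semantics as dedicated motif-discovery scores; swap in
  an external scorer through the interface if exact parity with a specific
  tool is needed.
* The pipeline anchors positions by treating each input record as the
  promoter of the identically named gene (ATG just past its 3' end) unless
  explicit gene models are supplied; genome-scale scanning with nearest-gene
  assignment is not implemented.
* Proposition thresholds are fixed, not learned; frames with more than two
  singleton hypotheses are unsupported.
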