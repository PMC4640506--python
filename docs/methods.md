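# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the `mirstarve` pipeline.  It describes what the code
computes and why the defaults are what they are; every empirical number
quoted here is produced by the test suite or by `scripts/acceptance.py`.

## Reference model

The mapping target is a transcript-space catalog of five sequence classes —
extended mature miRNAs, miRNA hairpins, non-coding transcripts, coding
transcripts, and the genome — concatenated into one index.  Reads map to
feature sequences directly rather than to the genome with projection; the
genome is itself one target class and backs the "intergenic" call.  This
matches the concatenated-FASTA design the pipeline reimplements and keeps
the class-preference logic purely set-theoretic.

Mature annotations live on their hairpin in 0-based half-open coordinates
(1-based only at the GFF3 boundary) and are extended by **3 nt at the 5'
end and 5 nt at the 3' end**, clipped at the hairpin boundaries.  The
extension absorbs templated isomiR ends so slightly shifted reads still map
end-to-end *inside* the mature feature.  Hairpin features record their
extended-mature intervals; where two extended matures on one hairpin would
overlap, their union defines the "mature territory" (an open design point —
the strict complement of that union is the hairpin-proper region).

Strand convention: transcript-class features (mature, hairpin, ncRNA,
coding) are matched sense-only; the reverse complement of a read is searched
against genome-class features only, since an intergenic fragment has no
defined orientation.  `both_strands=True` (CLI `--both-strands`) widens
reverse-complement search to every class.

## Read cleanup

Fixed stage order: hexamer → adapter → length filter → collapse.

* **Hexamer** `ACATCG`: removed once, only at the 5' terminus
  (`--hexamer-max-trims` raises the limit).  A single leading trim is the
  conservative reading of "trim these occurrences"; in the simulated data
  ~7% of reads carry it, matching the artifact rate the pipeline targets.
* **Adapter** `ATCTCGTATGCCGTCTTCTGCTTGC`: best ungapped alignment of an
  adapter *prefix* to the read's 3' portion — minimum overlap 8 nt,
  mismatch allowance `floor(0.1 × overlap)`, no indels; the leftmost
  qualifying start wins (equivalently, the longest adapter match, including
  a full internal one).  An 8-nt exact spurious match arises in ~4 of 10⁴
  reads — the usual cost of greedy adapter trimming.  Reads with no
  qualifying match are *kept*; the length filter is the only discard gate.
* **Length filter**: 16–28 nt inclusive.  Reads containing `N` are dropped
  before collapsing (the mismatch-counting aligner cannot score them) and
  logged separately; empty-after-trim reads are logged too, so
  `raw = kept + length-filtered + empty + N` holds exactly.
* **Collapse**: identical sequences merge into one record carrying the
  total count, ordered by descending count then sequence — deterministic,
  byte-identical across runs.

Base qualities are carried but never used; the pipeline has no quality
trimming by design.

## Alignment

End-to-end, substitutions only, ≤ 2 mismatches, every qualifying location
reported and then capped at 100 in the canonical order (mismatches,
feature, offset, strand) with an overflow flag — capped reads are kept, not
discarded.  The implementation uses pigeonhole seeding (a read with ≤ k
mismatches contains one of k+1 exact segments; exact occurrences of the
segments nominate candidates, which are verified by direct counting).  This
is exhaustive by construction, and the tests assert set-equality with a
brute-force sliding-window scan on mixed-class toy indices, plus
monotonicity in `max_mm` and invariance to feature order.

## Class assignment and fractional counting

Each read is assigned to the single highest-preference class present among
its hits:

```
mature > hairpin > ncRNA > coding > intergenic (genome)
```

Before the preference is applied, a hairpin hit **fully contained** in an
extended-mature interval is re-classified as a hit on that mature feature
(partial overlap stays hairpin; `--mature-containment any` relaxes this).
Hairpin-class reads are therefore the loop/flank byproducts of miRNA
biogenesis.  The read's count is divided equally over its retained
locations *within* the winning class — distinct (feature, offset) pairs are
distinct locations, so two placements on one feature each receive a share
and the feature sums them.  If the per-location share is below 1, the whole
read is ignored (the "< 1 rule": every read→feature contribution is either
0 or ≥ 1).  Counts are exact `Fraction`s internally and are only rounded
(4 d.p.) on export, which is why the conservation identity

```
Σ table + Σ sub-unit-dropped + Σ unmapped = Σ collapsed counts
```

is asserted with equality, not a tolerance.

## Differential expression

The tested matrix is the mature+hairpin rows; its column sums are the CPM
denominators (a deliberate, visible convention — total cleaned reads would
be an equally defensible denominator, and the class-composition report
provides both views).

* **TMM** (`tmm_factors`): for each library against a reference column,
  M = log2 relative-proportion ratio and A = mean log2 proportion over
  features nonzero in both libraries; 30% of M and 5% of A are trimmed from
  *each* tail; the factor is 2^(Σ wM / Σ w) with inverse delta-method
  variance weights, and factors are rescaled to geometric mean 1.  The
  implementation is checked against a direct-formula transcription and
  against Bioconductor edgeR's `calcNormFactors` to 10⁻⁶.  A caveat worth
  knowing: with few features and one feature holding ~50% of the reads, the
  inverse-variance weighting concentrates on the heavy features, so the
  factor inherits their biological noise — visible in the synthetic
  scenario as residual null log2FC offsets of ~0.1–0.4.
* **Exact NB test** (`exact_test_nb`): counts are rescaled to the common
  effective size √(N_A N_B) and rounded to integer pseudo-counts.  Two iid
  NB(μ, φ) variables conditioned on their sum s give a mean-free
  conditional law (beta-binomial form, r = 1/φ); the two-sided p-value is
  the probability-mass method — the sum of conditional probabilities of all
  splits no more likely than the observed one.  At φ = 0 the law is
  binomial(s, ½) and the test reduces to the exact conditional binomial
  test (asserted against `scipy.stats.binomtest`).  This is a documented
  simplification of edgeR's qCML machinery: the contract is oracle
  equivalence of the conditional enumeration, not bitwise equality with
  edgeR.  φ is always user-fixed (default **0.1**; Var = μ + φμ²) because
  the two-library design cannot estimate it.
* **log2FC**: log2 ratio of prior-adjusted proportions with a proportional
  prior of 0.125 per library-size-scaled unit (edgeR-like), which tames
  zero counts; the same prior-derived CPM substitutes a zero when forming
  the signed fold change FC = ±(higher CPM / lower CPM).
* **Filter**: CPM ≥ 1 (inclusive) in at least one library, applied to
  TMM-scaled CPMs.
* **BH FDR** (`bh_adjust`): step-up q(i) = min_{j≥i} p(j)·m/j, capped at 1;
  `m` may exceed the list length to model untested hypotheses at p = 1.
  m defaults to the number of features passing the CPM filter.  The
  published table this pipeline re-derives is consistent with m = 250
  (solved from early ranks: e.g. 2.4×10⁻⁸ × 250/3 = 2.0×10⁻⁶ exactly);
  re-deriving the printed FDR column from the printed (2-significant-figure)
  p-values necessarily inherits their rounding, so the test propagates the
  half-ULP interval of each printed p through the step-up minimization
  instead of demanding digit-exact agreement beyond the anchor rows.
* **Display rounding** mirrors the published table: CPM/log2FC/FC at
  1 d.p., p/FDR in 2-significant-figure scientific notation.

One published log2FC row (miR-36-3p, printed 3.4) differs by 0.053 from the
log2 of its printed CPM ratio (3.347) — the printed value reflects the
original tool's internal pseudo-count ratio; the corresponding check allows
0.055 and says so.  Low-count rows whose printed FC cannot be re-derived
from rounded CPMs at all (zero or near-zero CPMs) are reported but excluded
from exact checks.

## qPCR relative quantification

Efficiency convention: E is the per-cycle amplification factor (2 = perfect
doubling); ratios are E_t^(ΔCt_t) / E_r^(ΔCt_r) with
ΔCt = Ct(control) − Ct(treated).  No efficiencies were measured in the
validation experiments this module mirrors, so E defaults to 2 per assay
and is overridable.  Replicates aggregate as: one ratio per biological
replicate from technical-replicate-mean Cts, then mean ± SEM over the
(three) biological replicates.  Useful identities (all asserted): with
E = 2 the ratio equals 2^(−ΔΔCt); swapping conditions inverts it exactly;
adding a constant to all four Cts leaves it unchanged.

## Synthetic data: what it emulates, and what it does not

`paper_shaped_scenario(seed)` builds 60 random hairpins (55–90 nt, one or
two embedded 20–23 nt matures), 8 ncRNAs, 8 coding genes, and one genome
contig embedding everything between 80–200 nt intergenic spacers.  Read
class mix: 90% mature, 1% hairpin loop, 4% ncRNA, 3% coding, 2% intergenic
— shaped after the observed composition of the libraries being emulated
(~90% of cleaned reads on matures).  One mature is expected at 50% of the
miRNA pool and a second at 19% (the dominant-miRNA structure of the real
libraries); seven clustered matures are truly up by the published family
fold changes (8.6, 10.2, 15.4, 15.4, 17.6, 20.1, 20.2) and two are down
(−7.9, −13). Their baselines (0.3–1.6% of the mature pool) are desk-scale
choices: the published baseline CPMs at ~22M reads would leave several
features with expected counts below 1 at 150,000 reads per library, the
depth used here so the whole pipeline (including the acceptance run) stays
in tens of seconds.

Counts per feature and library are NB draws with Var = μ + 0.1μ² — the same
dispersion the test assumes, so the end-to-end recovery experiment is
self-consistent.  Perturbed weights are renormalized within the mature
class, which dilutes null matures by a common factor (~1.3× here); TMM is
expected to absorb exactly this, and the null-median-|log2FC| < 0.5 check
verifies that it does.  Reads are: mature sequence with ±1 nt end wobble
(kept inside the extended-mature interval — extension exists precisely to
catch these), loop fragments from outside the extended intervals, random
16–28 nt transcript/intergenic fragments; each read gets ≤ 2 substitutions
(Poisson mean 0.05, capped), the hexamer with probability 0.07, the full
adapter appended, and truncation to 36 cycles.  Qualities are constant
`I`; all randomness flows from per-purpose integer-seeded numpy streams,
so a seed reproduces the bundle byte-for-byte.

What the generator does **not** emulate — hence what passing tests do not
show about real data: realistic quality profiles and position-dependent
error spectra; untemplated 3' additions and true isomiR biology; sequence
families with cross-mapping homology (features are random, so multi-mapping
within the mature class is rarer than in a real miRNA family); ligation
bias; and the stability of highly expressed miRNAs across conditions
(applying the full φ = 0.1 dispersion to a 50%-share feature moves its
realized share by ±8 pp, far more than real dominant miRNAs move — the
tests therefore score the dominant share against a model-consistent band
rather than the tight range a real library would show).  A consequence of
the honest noise model is that recovery is stochastic: at the default seed,
8 of the 9 perturbed miRNAs are found at FDR < 5% with one null
false positive; the miss is a feature whose starved-library draw landed in
the 0.1% left tail.

## Numerical choices and degenerate inputs

* Fractional counts: exact rationals until export (4 d.p.).
* Tie-breaks are lexicographic everywhere (hit ordering, collapse order,
  interval choice for a hit inside overlapping extended matures: largest
  overlap, then start, then mature id) — runs are deterministic.
* Probability-mass p-value ties use a 10⁻¹⁰ log-scale tolerance so exact
  mirror splits (k, s−k) are always both included.
* Zero library totals, dangling mature→hairpin references, duplicate
  feature ids, p-values outside (0, 1], efficiencies outside [1, 2.2] are
  errors, not warnings; unmapped reads and empty hit sets are valid data.
* `bh_adjust` is written here (statsmodels' BH does not support m larger
  than the list); it is cross-checked against statsmodels at m = len.

## Limitations

* The exact test reproduces the *shape* of the original analysis (fixed
  common dispersion, TMM, BH) but not any given edgeR version bit-for-bit;
  pseudo-count construction in particular is a simplification.
* Scaling: the seeded aligner is designed for desk-scale references
  (≲ 1 Mb); it is exact but not an FM-index, and full-genome use would need
  a real short-read mapper.
* Two libraries only; replicated designs, GLMs and dispersion estimation
  are out of scope.
* The hairpin-vs-mature boundary depends on the containment convention;
  both conventions are implemented, and the default (full containment) is
  the strict complement of "outside the mature regions".
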