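# Methods

## Problem and model

`snpdesign` addresses the optimal design of low-density SNP genotyping
arrays: choose N markers from a dense candidate map (tens of thousands
of SNPs with known chromosome, base-pair position and minor allele
frequency) so that the panel imputes well to the dense assay.  The
design objective combines three ingredients:

1. **Coverage.**  The budget is spread across chromosomes in proportion
   to *non-gap* map length.  Under the implied multinomial model the
   per-chromosome count is taken to be its expectation
   n_k = N·(1−g_k)L_k / Σ_i (1−g_i)L_i, realized as integers by
   floor-then-largest-remainder rounding (which conserves N exactly).
   A *gap* is an adjacent-candidate interval longer than twice the
   reference mean spacing Δ̄_k = L_k/(n_k−1).  Because gaps depend on
   n_k and n_k on gaps, allocation runs two passes: a gap-free pass
   fixes the reference spacing, a second pass re-allocates with the
   detected gap fractions, and iteration stops there (a single
   adjustment, matching the definition of the adjusted weights).
2. **Information.**  Locus entropy H(p) = −p log₂ p − (1−p) log₂(1−p);
   panel criteria are LASE (mean per-SNP H) or HASE (joint entropy of
   the 2^m haplotype frequencies of an m-SNP window).  HASE is
   normalized per SNP (divide by m) by default so its claimed [0, 1]
   range has an attainable maximum; division by the haplotype count
   2^m is available as a mode and only rescales rankings at fixed m.
   Haplotype frequencies come from a phased panel when one is
   supplied, else from the independence product of the marginal
   frequencies (in which case HASE per SNP equals LASE exactly).
3. **Uniformity.**  Any entropy mean is multiplied by
   1 − (1/(m−1))·Σ|δ_j − δ̄|/(c·δ̄) over the panel's neighbor spacings.
   The factor is floored at 0, since extreme clustering can drive it
   negative at c = 1.  c ≥ 1 damps the penalty; c → ∞ recovers pure
   entropy maximization (equivalently pure MAF maximization per SNP).

## The local search

Virtual-frame (VF) positions — idealized real-valued targets — are
placed per gap-free segment, either uniformly (endpoints included, so
the first and last candidate of every segment are always selected) or
with terminal enrichment: the chromosome is cut into 20 equal segments;
the outer two at each end form terminal groups; frame quotas
(29 %, 42 %, 29 %) for "more" enrichment or (22 %, 56 %, 22 %) for
"less" are assigned to (left, middle, right) groups by largest
remainder, then spread within each group in proportion to non-gap
length.  This quota scheme is the operational rendering of a smoothed
Beta(0.5, 0.5) location density; no continuous density is sampled, as
the quotas are the only quantitative specification available and they
make the placement exactly reproducible.

Each VF position w_j owns the bin [w_j − γΔ̄, w_j + γΔ̄].  Bins are
disjoint for γ ≤ 0.5 and overlap beyond; γ is accepted on [0, 1] with a
logged warning above 0.5.  The sweep runs chromosomes in ascending
order and bins left to right.  Obligatory SNPs consume their nearest
bins before any optimization; remaining bins take the candidate
maximizing the *anchored* adjusted entropy: the score of candidate x in
bin j is H(maf_x) times the uniformity factor of the triple
(left anchor, x, right anchor).

**Anchoring is frame-based.**  A bin's anchors are the flanking *fixed*
positions — segment-boundary SNP, obligatory SNP, or the neighbouring
VF position — never another optimizer pick.  This was a genuinely open
design point; the frame-anchored form was chosen because it makes the
per-bin scores separable, so the left-to-right sweep provably attains
the global arg-max of the summed objective over all one-per-bin
selections (verified against exhaustive enumeration in the test
suite), and it reproduces the canonical single-bin worked example,
whose candidate is anchored on the two fixed segment boundaries.
Tie-breaking everywhere: higher adjusted score, then nearer the VF
position, then lower position, then lexicographic id.

With γ = 0 every bin degenerates to its VF point and the algorithm
selects the nearest candidate — exactly the evenly-spaced (UD)
baseline.  Empty bins fall back to the nearest remaining candidate;
exhausted segments record a shortfall rather than failing, and leftover
budget is spent by gap filling: repeatedly insert into the largest
selected-SNP gap exceeding twice the panel's per-chromosome mean
spacing the interior candidate with the best anchored score (gaps with
no interior candidates remain unfilled).

For the HASE criterion, w ∈ {3, 5} consecutive open bins form a window
scored by exhaustive one-per-bin enumeration (anchored on the window's
flanking fixed positions); windows slide by w, the remainder of a run
falls back to locus scoring, and combination counts above 10⁶ are
truncated to the top-MAF candidates per bin.

Conditional design subtracts reserved slots (manufacturing bead bins,
Y-chromosome and bacterial assays) and unmapped obligatory SNPs from
the selectable budget before allocation; they carry no positions.
Layered multi-panel composition runs the optimizer once per layer with
all previously accumulated SNPs treated as obligatory, supports
per-layer frequency tables (breed-specific MAFs) and MAF thresholds,
and finishes with a gap-fill pass on the union.

## Parameters

| parameter | default | meaning |
|---|---|---|
| γ (gamma) | 0.5 | local search radius as a fraction of mean VF spacing; 0.5 covers the chromosome once without overlap |
| c | 1 | uniformity-penalty damping, ≥ 1; large values revert to pure entropy/MAF maximization |
| criterion | lase | `lase` or `hase`; `hase` needs (or assumes independence of) haplotype frequencies |
| window | 3 | bins per HASE window (1, 3 or 5); cost grows as the product of bin sizes |
| enrichment | uniform | `uniform`, `more` (29/42/29) or `less` (22/56/22) terminal enrichment |
| maf_threshold | none | drop candidates at or below this MAF inside bins (falls back to the unfiltered bin when it would empty it) |
| reserved | 0 | slots held without positions |

Coordinates are 1-based base pairs (PLINK convention); lengths are
plain position differences.  Chromosome labels map to ordinals with X
as 30.  Chromosome length defaults to the candidate span (first to
last SNP), matching the evenly-spaced baseline's convention of pinning
the terminal SNPs; a user table overrides.  Duplicate positions keep
the higher-MAF record (ties: lexicographic id) because the search needs
strict ordering.

## Synthetic data

The generator (`snpdesign.simulate`) emulates the structures the
optimizer consumes, not population-genetic history:

* **Positions** uniform within non-gap intervals, with optional planted
  gaps of controlled total fraction; terminal candidates pin the span.
* **MAF** drawn from 0.5·Beta(a, b) truncated below at 0.001, with
  (a, b) solved so the delivered (truncated) distribution has exactly
  the requested mean and SD — default 0.2264 / 0.1584, the summary
  statistics of a bovine 50K assay in a beef reference population.
  Sampling is by inverse CDF, so fixed seeds give identical maps.
  A plain clipped Beta was rejected: clipping at 0.5 biases the
  delivered mean well below its target.
* **Haplotypes** from a first-order Markov Gaussian-copula: a latent
  AR(1) chain per haplotype with neighbour autocorrelation
  0.5^(d/half-distance), thresholded at Φ⁻¹(MAF).  Marginals match the
  map exactly in expectation while association decays with distance;
  half-distance 0 gives independent loci, very large values near-
  perfect linkage.  A literal allele-copy chain was rejected because it
  biases marginals whenever neighbouring MAFs differ.  The model has no
  mutation, drift, or breed structure; passing tests therefore
  demonstrate algorithmic correctness and direction (local search
  raises LASE, obligatory content dilutes it), not population-genetic
  realism or real-data imputation accuracy, which additionally depend
  on reference-panel relatedness and true LD structure.

Test and documentation examples use desk-scale problems (hundreds of
candidates, tens of picks, ≤ 2 chromosomes), which exercise every code
path; problem size only scales the allocation and sweep linearly.

## Numerical choices and degenerate inputs

* 0·log₂0 := 0 throughout; entropies are exact at p ∈ {0, 1}.
* Largest-remainder rounding breaks remainder ties toward the lower
  index; per-cell minima (obligatory counts) and capacities (available
  candidates) are enforced by iteratively pinning violated cells —
  minima first — and re-apportioning the remainder.
* Unassigned SNPs in segment allocation go to the largest fractional
  remainders deterministically rather than by a probabilistic draw
  proportional to length; reproducibility is worth more than literal
  stochastic assignment, and the expectation is identical.
* Coincident positions (zero mean spacing) raise an error rather than
  returning NaN.
* A budget exceeding the candidate pool, or an exhausted segment,
  records a shortfall; only a budget below the obligatory count is
  fatal.
* HASE tables cap at 2¹⁰ cells; the frequency table must sum to 1
  within 1e−9.

## Known limitations

* The search is local by construction; global optimality is only
  guaranteed for the separable (frame-anchored) objective it defines,
  and only within one-candidate-per-bin feasibility.
* Entropy calculations take allele frequencies as given; no
  phasing, frequency re-estimation, or cross-population pooling is
  performed.
* Imputation itself, and prediction-model training on imputed
  genotypes, are out of scope; panel quality is reported through
  entropy, spacing and gap statistics only.
* With γ > 0.5 overlapping bins are resolved greedily (earlier bins
  win); no conflict-aware re-optimization is attempted.
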