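# snpdesign

Multi-objective local optimization of **low-density SNP genotyping
arrays**.

Low-density (LD) SNP chips are a cost-effective route to genomic
prediction in livestock: a few thousand markers are genotyped and the
remainder imputed up to a medium- or high-density assay.  How those few
thousand markers are chosen matters — imputation accuracy depends on
the markers being both *informative* (high minor allele frequency,
high entropy) and *well spread* along every chromosome, and commercial
designs must also carry obligatory content (parentage, breed and
causal-variant SNPs, prior-panel markers) and reserved manufacturing
slots.  `snpdesign` selects a fixed budget of N SNPs from a dense
candidate map so that non-gap map coverage and spacing-adjusted Shannon
entropy are jointly maximized, conditional on that obligatory content.

## The objective

For a bi-allelic locus with minor allele frequency *p*,

    H(p) = −p log₂ p − (1−p) log₂ (1−p)          (bits)

The panel-level criterion is either the locus-average Shannon entropy
(LASE, the mean of per-SNP *H*) or the haplotype-average Shannon
entropy (HASE, the joint entropy of multi-SNP haplotype frequencies,
normalized per SNP).  Either is adjusted for spacing uniformity: with
*m* SNPs spanning *m−1* neighbor distances δ_j of mean δ̄,

    H_adj = H̄ × ( 1 − (1/(m−1)) Σ_j |δ_j − δ̄| / (c·δ̄) )

where *c* ≥ 1 damps the penalty.  The search is heuristic and local:
the budget is apportioned to chromosomes and gap-free segments in
proportion to non-gap map length (largest-remainder rounding of the
multinomial expectation), virtual-frame (VF) positions are placed
uniformly or with Beta-guided terminal enrichment, and each VF position
owns a bin of radius γ·Δ̄ (Δ̄ the mean VF spacing, 0 ≤ γ ≤ 1) in which
the candidate maximizing the anchored adjusted entropy is taken.
Obligatory SNPs consume their bins first; boundary SNPs are always
kept; leftover budget fills oversized gaps.  γ = 0 reduces to the
classical evenly-spaced (UD) design, and a max-MAF-per-bin (OMM)
baseline is provided for comparison.

## Worked example

```python
from snpdesign import (SimulationConfig, simulate_candidate_map,
                       optimize_chip, increment_over_control, summarize_chip)

cfg = SimulationConfig(n_chromosomes=2, lengths=(2_000_000.0, 1_000_000.0),
                       n_candidates=(300, 150), seed=42)
cmap = simulate_candidate_map(cfg)

control = optimize_chip(cmap, 60, gamma=0.0)   # map positions only
chip = optimize_chip(cmap, 60, gamma=0.5, c=1.0)

print(f"LASE  gamma=0.0: {control.diagnostics['lase']:.4f}")
print(f"LASE  gamma=0.5: {chip.diagnostics['lase']:.4f}")
print(f"increment: {increment_over_control(chip.diagnostics['lase'], control.diagnostics['lase']):.2f}%")
```

prints

```
LASE  gamma=0.0: 0.6703
LASE  gamma=0.5: 0.9211
increment: 37.42%
```

With γ = 0 the design snaps each frame position to the nearest
candidate regardless of its frequency, so panel LASE simply mirrors the
candidate pool's average entropy (0.67 here).  Opening a local search
radius of half the frame spacing (γ = 0.5) lets the optimizer trade a
little positional regularity for far more informative markers, lifting
LASE to 0.92 — a 37 % gain at identical panel size, while
`summarize_chip(chip)` confirms the spacing stays tight (RMS spacing
≈ 52 kb on the 2 Mb chromosome, maximum gap ≈ 76 kb).

The same pipeline is scriptable from the shell:

```bash
snpdesign simulate --chromosomes 2 --candidates 300 --seed 42 --out fixture
snpdesign design --map fixture.map.tsv --panel-size 60 --gamma 0.5 --out chip
snpdesign evaluate --selection chip.tsv --out chip.summary.json
```

Inputs can be candidate-map TSVs or PLINK `.bim`/`.frq` pairs; phased
haplotypes (VCF or 0/1 matrix TSV) enable the HASE criterion;
`snpdesign rank` provides trait-variance (2pqα²) marker ranking for
association-guided panels.

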