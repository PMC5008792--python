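"""Shannon-entropy information measures for SNP panels.

For a bi-allelic locus with minor allele frequency p the entropy is

    H(p) = -p log2 p - (1-p) log2 (1-p)        (bits, in [0, 1])

The locus-average Shannon entropy (LASE) of a panel is the arithmetic
mean of per-SNP H.  The haplotype-average Shannon entropy (HASE) of m
SNPs is the joint entropy of their haplotype frequency table; two
normalizations are offered: per SNP (divide by m; range [0, 1] with
attainable maximum, the default) or per haplotype (divide by l = 2^m).
SNP rankings at fixed m are invariant to the choice.

Either average may be *adjusted* for the uniformity of the SNP spacing:

    H_adj = H * (1 - (1/(m-1)) * sum_j |d_j - dbar| / (c * dbar))

where d_j are the m-1 neighbor distances, dbar their mean, and c >= 1 a
constant damping the penalty (larger c, less adjustment).  The factor
is floored at zero, since extreme clustering can drive it negative at
c = 1.  Equidistant SNPs are never penalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

HAPLOTYPE_CAP = 10  # max SNPs per joint-frequency table (size 2^m)


class EntropyError(ValueError):
    pass


@dataclass
class EntropyResult:
    """Per-locus entropies and panel-level summaries."""

    per_locus_H: np.ndarray
    lase: float
    adjusted: float | None = None
    hase: float | None = None
    hase_normalization: str | None = None
    c: float = 1.0
    m: int = 0


def locus_entropy(p) -> float | np.ndarray:
    """Bi-allelic Shannon entropy at allele frequency p (0*log 0 := 0)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise EntropyError(f"allele frequency outside [0, 1]: {p}")
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(arr * np.log2(arr) + (1 - arr) * np.log2(1 - arr))
    h = np.where((arr == 0) | (arr == 1), 0.0, h)
    return float(h) if np.isscalar(p) or arr.ndim == 0 else h


def lase(frequencies: Sequence[float]) -> float:
    """Locus-average Shannon entropy of a panel of allele frequencies."""
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise EntropyError("LASE of an empty panel is undefined")
    return float(np.mean(locus_entropy(freqs)))


def haplotype_frequencies(panel, snp_indices: Sequence[int]) -> np.ndarray:
    """Relative frequencies of the 2^m haplotypes over the given SNP columns.

    Haplotype index packs alleles most-significant-first:
    haplotype (a_1, ..., a_m) -> sum_i a_i * 2^(m-i).  Unobserved
    haplotypes get frequency 0; the table sums to 1.
    """
    idx = list(snp_indices)
    m = len(idx)
    if m < 1:
        raise EntropyError("need at least one SNP")
    if m > HAPLOTYPE_CAP:
        raise EntropyError(
            f"haplotype table for m={m} SNPs exceeds cap {HAPLOTYPE_CAP} (2^m cells)"
        )
    mat = panel.allele_matrix[:, idx]
    weights = 1 << np.arange(m - 1, -1, -1)
    codes = mat @ weights
    table = np.bincount(codes, minlength=1 << m).astype(float)
    return table / table.sum()


def independent_haplotype_frequencies(freqs: Sequence[float]) -> np.ndarray:
    """Haplotype table under independence: products of per-SNP marginals.

    Fallback used when no haplotype panel is available.
    """
    freqs = np.asarray(freqs, dtype=float)
    m = len(freqs)
    if m < 1:
        raise EntropyError("need at least one SNP")
    if m > HAPLOTYPE_CAP:
        raise EntropyError(f"m={m} exceeds haplotype cap {HAPLOTYPE_CAP}")
    table = np.ones(1)
    for p in freqs:  # MSB-first, matching haplotype_frequencies' packing
        table = np.kron(table, np.array([1 - p, p]))
    return table


def joint_entropy(frequencies: Sequence[float]) -> float:
    """Joint Shannon entropy -sum p log2 p of a frequency table (bits)."""
    f = np.asarray(frequencies, dtype=float)
    nz = f[f > 0]
    return float(-(nz * np.log2(nz)).sum())


def hase(frequency_table: Sequence[float], m: int,
         normalization: str = "per_snp") -> float:
    """Haplotype-average Shannon entropy of an m-SNP haplotype table."""
    f = np.asarray(frequency_table, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise EntropyError(f"haplotype table sums to {f.sum()}, not 1")
    h = joint_entropy(f)
    if normalization == "per_snp":
        return h / m
    if normalization == "per_haplotype":
        return h / (1 << m)
    raise EntropyError(f"unknown normalization {normalization!r}")


def uniformity_factor(positions: Sequence[float], c: float = 1.0) -> float:
    """Spacing-uniformity multiplier in [0, 1] for sorted positions."""
    if c < 1.0:
        raise EntropyError(f"adjustment constant c must be >= 1, got {c}")
    pos = np.asarray(positions, dtype=float)
    m = len(pos)
    if m < 2:
        raise EntropyError("need at least 2 positions")
    d = np.diff(pos)
    dbar = d.mean()
    if dbar <= 0:
        raise EntropyError("coincident positions: mean spacing is zero")
    factor = 1.0 - np.abs(d - dbar).sum() / ((m - 1) * c * dbar)
    return float(max(factor, 0.0))


def adjusted_entropy(H_mean: float, positions: Sequence[float],
                     c: float = 1.0) -> float:
    """Entropy down-weighted by spacing unevenness (floored at 0)."""
    return H_mean * uniformity_factor(positions, c)
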