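"""Synthetic candidate maps and haplotype panels.

The generator emulates the inputs of a real array-design run with no
download: candidate SNPs scattered along chromosomes (optionally with
planted gaps), MAFs drawn from a uniform or Beta-shaped distribution
(the Beta fitted so the *delivered*, truncated-to-[0.001, 0.5] sample
matches the requested mean and standard deviation — the default
targets, mean 0.2264 and SD 0.1584, mimic a bovine 50K assay), and
phased haplotypes whose allele correlation decays along the chromosome
with a configurable half-distance (first-order Markov Gaussian-copula
threshold model, so marginal frequencies match the map exactly in
expectation).  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy import special
from scipy.stats import norm

from .maps import CandidateMap, SnpRecord

MAF_LO, MAF_HI = 0.001, 0.5
DEFAULT_MAF_MEAN, DEFAULT_MAF_SD = 0.2264, 0.1584


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Controls for the synthetic candidate-map generator."""

    n_chromosomes: int = 1
    lengths: tuple[float, ...] = (1_000_000.0,)
    n_candidates: tuple[int, ...] = (500,)
    maf_distribution: str = "beta"  # "beta" or "uniform"
    maf_mean: float = DEFAULT_MAF_MEAN
    maf_sd: float = DEFAULT_MAF_SD
    maf_range: tuple[float, float] = (0.05, 0.5)  # for "uniform"
    gap_count: int = 0
    gap_length_fraction: float = 0.0  # total planted-gap share of each length
    obligatory_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.lengths) != self.n_chromosomes:
            raise SimulationError("lengths must match n_chromosomes")
        if len(self.n_candidates) != self.n_chromosomes:
            raise SimulationError("n_candidates must match n_chromosomes")
        if self.gap_count and not (0 < self.gap_length_fraction < 1):
            raise SimulationError("gap_length_fraction must be in (0, 1)")
        if self.gap_count == 0 and self.gap_length_fraction:
            raise SimulationError("gap fraction given without gap count")


def fit_truncated_beta(mean: float, sd: float,
                       lo: float = MAF_LO, hi: float = MAF_HI
                       ) -> tuple[float, float]:
    """Shape parameters of the MAF model ``hi * Beta(a, b)`` with the
    given delivered moments.

    MAF lives on [0, hi] (hi = 0.5 by definition of a minor allele), so
    the model is a Beta rescaled to that support and truncated below at
    ``lo`` to exclude monomorphic loci.  (a, b) are solved so that the
    *truncated* distribution has exactly the requested mean and SD,
    using closed-form truncated moments (regularized incomplete beta
    ratios) and least squares over (log a, log b).
    """
    zlo = lo / hi
    tm, tv = mean / hi, (sd / hi) ** 2
    target = np.array([tm, tm ** 2 + tv])

    def trunc_moments(a, b):
        z0 = 1.0 - special.betainc(a, b, zlo)
        m1 = (a / (a + b)) * (1.0 - special.betainc(a + 1, b, zlo)) / z0
        m2 = (a * (a + 1) / ((a + b) * (a + b + 1))) * (
            1.0 - special.betainc(a + 2, b, zlo)) / z0
        return np.array([m1, m2])

    def residual(logab):
        a, b = np.exp(logab)
        return trunc_moments(a, b) - target

    common = tm * (1 - tm) / tv - 1
    if common <= 0:
        raise SimulationError(
            f"infeasible MAF moments: mean {mean}, sd {sd}")
    x0 = np.log([max(tm * common, 0.02), max((1 - tm) * common, 0.02)])
    sol = sciopt.least_squares(residual, x0, xtol=1e-14, ftol=1e-14)
    a, b = np.exp(sol.x)
    if sol.cost > 1e-8:
        raise SimulationError(
            f"MAF moments (mean {mean}, sd {sd}) not attainable by the "
            "scaled-beta model")
    return float(a), float(b)


def _draw_maf(rng: np.random.Generator, n: int, config: SimulationConfig
              ) -> np.ndarray:
    if config.maf_distribution == "uniform":
        lo, hi = config.maf_range
        return rng.uniform(lo, hi, size=n)
    if config.maf_distribution != "beta":
        raise SimulationError(f"unknown MAF distribution {config.maf_distribution!r}")
    a, b = fit_truncated_beta(config.maf_mean, config.maf_sd)
    # exact inverse-CDF sampling of the truncated, rescaled beta
    u = rng.uniform(special.betainc(a, b, MAF_LO / MAF_HI), 1.0, size=n)
    return MAF_HI * special.betaincinv(a, b, u)


def simulate_candidate_map(config: SimulationConfig) -> CandidateMap:
    """Draw a candidate map: positions uniform within non-gap intervals."""
    rng = np.random.default_rng(config.seed)
    records: list[SnpRecord] = []
    for k in range(config.n_chromosomes):
        chrom = k + 1
        length = float(config.lengths[k])
        n = int(config.n_candidates[k])
        intervals = _nongap_intervals(rng, length, config)
        weights = np.array([b - a for a, b in intervals])
        counts = rng.multinomial(max(n - 2, 0), weights / weights.sum())
        pos = [1.0, length]  # terminal candidates pin the map span
        for (a, b), cnt in zip(intervals, counts):
            lo = max(a, 1.0)
            pos.extend(rng.uniform(lo, b, size=cnt))
        pos = np.unique(np.round(np.sort(np.asarray(pos))).astype(np.int64))
        mafs = _draw_maf(rng, len(pos), config)
        oblig = rng.random(len(pos)) < config.obligatory_fraction
        for i, (p, f, o) in enumerate(zip(pos, mafs, oblig)):
            records.append(SnpRecord(
                snp_id=f"c{chrom}s{i:05d}", chromosome=chrom,
                position=int(p), maf=float(np.clip(f, MAF_LO, MAF_HI)),
                obligatory=bool(o),
            ))
    return CandidateMap(records)


def _nongap_intervals(rng, length, config) -> list[tuple[float, float]]:
    if config.gap_count == 0:
        return [(1.0, length)]
    total_gap = config.gap_length_fraction * length
    gap_len = total_gap / config.gap_count
    nongap_total = length - total_gap
    if nongap_total <= 0:
        raise SimulationError("infeasible gap specification")
    # split the non-gap length into gap_count+1 parts, gaps in between
    parts = rng.dirichlet(np.full(config.gap_count + 1, 5.0)) * nongap_total
    intervals = []
    cursor = 1.0
    for i, p in enumerate(parts):
        intervals.append((cursor, cursor + p))
        cursor += p
        if i < config.gap_count:
            cursor += gap_len
    return intervals


def simulate_haplotypes(cmap: CandidateMap, n_haplotypes: int,
                        ld_half_distance: float, seed: int = 0):
    """Phased haplotypes with distance-decaying allele association.

    For each haplotype a latent first-order Gaussian chain runs along
    each chromosome with autocorrelation 0.5**(d / half-distance)
    between neighbours d base pairs apart; alleles are the threshold
    indicators at the normal quantile of each SNP's MAF.  Marginal
    frequencies therefore match the map exactly in expectation;
    ``ld_half_distance = 0`` gives independent loci and very large
    values give near-perfect linkage.
    """
    from .maps import HaplotypePanel

    if n_haplotypes % 2:
        raise SimulationError("n_haplotypes must be even (diploid phasing)")
    rng = np.random.default_rng(seed)
    columns = []
    ids = []
    for chrom in cmap.chromosomes:
        grp = cmap.chromosome(chrom)
        pos = grp["pos"].to_numpy(dtype=float)
        maf = grp["maf"].to_numpy(dtype=float)
        n_snp = len(pos)
        d = np.diff(pos)
        if ld_half_distance > 0:
            phi = np.power(0.5, d / ld_half_distance)
        else:
            phi = np.zeros_like(d)
        z = np.empty((n_haplotypes, n_snp))
        z[:, 0] = rng.standard_normal(n_haplotypes)
        for j in range(1, n_snp):
            innov = rng.standard_normal(n_haplotypes)
            z[:, j] = phi[j - 1] * z[:, j - 1] + np.sqrt(
                1.0 - phi[j - 1] ** 2) * innov
        thresholds = norm.ppf(maf)
        columns.append((z < thresholds).astype(np.int8))
        ids.extend(grp["snp_id"])
    return HaplotypePanel(np.hstack(columns), ids)


# ---------------------------------------------------------------------------
# file emission (same formats the readers consume)
# ---------------------------------------------------------------------------

def write_map_tsv(cmap: CandidateMap, path) -> None:
    df = cmap.df.copy()
    df["obligatory"] = df["obligatory"].astype(int)
    df.loc[df["no_map"], ["chrom", "pos"]] = np.nan
    df[["snp_id", "chrom", "pos", "maf", "obligatory"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def write_haplotypes_tsv(panel, path) -> None:
    pd.DataFrame(panel.allele_matrix, columns=panel.snp_ids).to_csv(
        path, sep="\t", index=False)


def write_haplotypes_vcf(panel, cmap: CandidateMap, path) -> None:
    """Emit a minimal phased VCF for the panel (samples = hap pairs)."""
    if panel.n_haplotypes % 2:
        raise SimulationError("need an even number of haplotypes")
    n_samples = panel.n_haplotypes // 2
    lookup = dict(zip(cmap.df["snp_id"], zip(cmap.df["chrom"], cmap.df["pos"])))
    lines = ["##fileformat=VCFv4.2"]
    for chrom in cmap.chromosomes:
        length = int(cmap.chromosome(chrom)["pos"].max()) + 1
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
              "FORMAT"] + [f"S{i:04d}" for i in range(n_samples)]
    lines.append("\t".join(header))
    for col, sid in enumerate(panel.snp_ids):
        chrom, pos = lookup[sid]
        alleles = panel.allele_matrix[:, col]
        gts = [f"{alleles[2 * i]}|{alleles[2 * i + 1]}" for i in range(n_samples)]
        lines.append("\t".join(
            [str(int(chrom)), str(int(pos)), sid, "A", "G", ".", "PASS", ".",
             "GT"] + gts))
    Path(path).write_text("\n".join(lines) + "\n")
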