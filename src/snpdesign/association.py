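"""Trait-association SNP ranking and the two classical design baselines.

Association-based selection ranks SNPs by the additive genetic variance
they explain, ``v = 2 p q a^2`` (p, q allele frequencies, a the per-
allele effect), either raw per trait or standardized by each trait's
total SNP variance and averaged over traits.  The baselines are the
uniform design (UD: evenly spaced picks, map positions only) and
optimization on maximum MAF (OMM: highest-MAF candidate per segment
bin, no spacing adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import allocation as alloc
from . import optimizer as opt
from .maps import CandidateMap


class AssociationError(ValueError):
    pass


@dataclass
class TraitEffectTable:
    """Per-SNP additive effects for one or more traits.

    ``table`` columns: snp_id, maf, alpha_<trait> per trait.
    """

    table: pd.DataFrame

    def __post_init__(self):
        cols = set(self.table.columns)
        if not {"snp_id", "maf"}.issubset(cols):
            raise AssociationError("table needs snp_id and maf columns")
        if not self.traits:
            raise AssociationError("table needs at least one alpha_<trait> column")
        if self.table[["maf"] + [f"alpha_{t}" for t in self.traits]].isna().any().any():
            raise AssociationError("missing effect or frequency values")

    @property
    def traits(self) -> list[str]:
        return [c[len("alpha_"):] for c in self.table.columns
                if c.startswith("alpha_")]

    @classmethod
    def read(cls, path) -> "TraitEffectTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"snp_id": str}))

    def filter_maf(self, threshold: float = 0.05) -> "TraitEffectTable":
        """Drop SNPs at or below the MAF threshold (pre-ranking filter)."""
        return TraitEffectTable(self.table[self.table["maf"] > threshold]
                                .reset_index(drop=True))


def snp_variance(p, alpha):
    """Additive variance contributed by a SNP: 2 p (1-p) alpha^2."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise AssociationError("allele frequency outside [0, 1]")
    out = 2.0 * p * (1.0 - p) * np.asarray(alpha, dtype=float) ** 2
    return float(out) if out.ndim == 0 else out


def variance_frame(table: TraitEffectTable) -> pd.DataFrame:
    """Raw per-SNP, per-trait variances v_j(k), indexed by snp_id."""
    df = table.table
    out = pd.DataFrame(index=df["snp_id"])
    for t in table.traits:
        out[t] = snp_variance(df["maf"].to_numpy(), df[f"alpha_{t}"].to_numpy())
    return out


def standardized_variances(table: TraitEffectTable) -> pd.DataFrame:
    """v_j(k) / w(k) with w(k) the trait's total variance; columns sum to 1."""
    v = variance_frame(table)
    for t in v.columns:
        w = v[t].sum()
        if w <= 0:
            raise AssociationError(f"trait {t!r} has zero total SNP variance")
        v[t] = v[t] / w
    return v


def select_top_pooled(table: TraitEffectTable, per_trait_k: int) -> set[str]:
    """Union of each trait's top-k SNPs by raw variance (single-trait pooling)."""
    v = variance_frame(table)
    if per_trait_k > len(v):
        raise AssociationError("per_trait_k exceeds SNP count")
    out: set[str] = set()
    for t in v.columns:
        out |= set(v[t].sort_values(ascending=False).index[:per_trait_k])
    return out


def select_top_multitrait(table: TraitEffectTable, k: int) -> set[str]:
    """Top-k SNPs by the mean standardized variance over traits."""
    if k > len(table.table):
        raise AssociationError("k exceeds SNP count")
    mean_v = standardized_variances(table).mean(axis=1)
    order = mean_v.sort_values(ascending=False, kind="stable")
    return set(order.index[:k])


def augment_with_molo(selected_ids, cmap: CandidateMap, extra: int,
                      **molo_settings) -> set[str]:
    """Add ``extra`` optimally placed SNPs around an existing panel.

    Runs the chip optimizer with the existing panel as obligatory and a
    budget of ``len(selected) + extra``; returns the union of ids.
    """
    if extra < 0:
        raise AssociationError("extra must be >= 0")
    selected = list(selected_ids)
    if extra == 0:
        return set(selected)
    result = opt.optimize_chip(
        cmap, len(selected) + extra, obligatory_ids=selected, **molo_settings)
    return set(result.snp_ids)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def _baseline_slots(cmap: CandidateMap, N: int):
    """Shared machinery: per-chromosome uniform VF positions for N picks."""
    lengths = cmap.chrom_lengths
    chroms = sorted(lengths)
    caps = [len(cmap.chromosome(k)) for k in chroms]
    counts = alloc.largest_remainder([lengths[k] for k in chroms], N,
                                     maxima=caps)
    for k, n_k in zip(chroms, counts):
        pos = cmap.positions(k)
        if n_k <= 0:
            continue
        if n_k == 1:
            vf = np.array([0.5 * (pos[0] + pos[-1])])
        else:
            vf = np.linspace(pos[0], pos[-1], n_k)
        yield k, vf


def baseline_uniform(cmap: CandidateMap, N: int) -> set[str]:
    """UD baseline: evenly spaced picks, first and last candidate included."""
    out: set[str] = set()
    for k, vf in _baseline_slots(cmap, N):
        out |= set(opt.select_map_oriented(cmap.chromosome(k), vf))
    return out


def baseline_maf(cmap: CandidateMap, N: int) -> set[str]:
    """OMM baseline: highest-MAF candidate in each VF segment bin.

    Bins partition each chromosome at midpoints between adjacent VF
    positions; ties go to the lower position; empty bins fall back to
    the nearest remaining candidate.
    """
    out: set[str] = set()
    for k, vf in _baseline_slots(cmap, N):
        grp = cmap.chromosome(k)
        pos = grp["pos"].to_numpy(dtype=float)
        edges = np.concatenate([[-np.inf], 0.5 * (vf[1:] + vf[:-1]), [np.inf]])
        taken: set[str] = set()
        for j, w in enumerate(vf):
            cell = grp[(pos >= edges[j]) & (pos < edges[j + 1])
                       & ~grp["snp_id"].isin(taken)]
            if cell.empty:
                avail = grp[~grp["snp_id"].isin(taken)]
                if avail.empty:
                    continue
                order = (avail["pos"] - w).abs()
                pick = avail.loc[order.sort_values(kind="stable").index[0]]
            else:
                pick = cell.sort_values(["maf", "pos"],
                                        ascending=[False, True]).iloc[0]
            taken.add(pick["snp_id"])
        out |= taken
    return out
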