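"""Candidate-map and haplotype containers with readers and writers.

A *candidate map* is the universe of SNPs a low-density array may draw
from: one record per SNP carrying its chromosome, base-pair position,
minor allele frequency (MAF) and an optional *obligatory* flag (the SNP
must appear on the final array).  Chromosome labels are carried as
ordinals; the X chromosome is mapped to ordinal 30, the convention used
for bovine maps.  Positions are 1-based base pairs as in PLINK ``.bim``
files, and interval lengths are plain position differences.

A *haplotype panel* is a binary haplotypes x SNPs matrix (1 = minor
allele) used to estimate joint haplotype frequencies for the
haplotype-entropy selection criterion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordinal used for the X chromosome.
X_ORDINAL = 30

MAP_COLUMNS = ["snp_id", "chrom", "pos", "maf", "obligatory", "no_map"]

SELECTION_COLUMNS = ["snp_id", "chrom", "pos", "maf", "provenance", "bin_index"]


class MapValidationError(ValueError):
    """Raised when a candidate map or haplotype panel violates an invariant."""


class MapParseError(ValueError):
    """Raised when an input file cannot be parsed; carries the line number."""


def chrom_ordinal(label) -> int:
    """Map a chromosome label (autosome number or ``"X"``) to an ordinal."""
    if isinstance(label, str):
        s = label.strip().upper()
        if s in {"X", "CHRX"}:
            return X_ORDINAL
        if s.startswith("CHR"):
            s = s[3:]
        try:
            return int(s)
        except ValueError as exc:
            raise MapParseError(f"unrecognized chromosome label {label!r}") from exc
    return int(label)


@dataclass(frozen=True)
class SnpRecord:
    """A single candidate SNP.

    ``no_map`` marks SNPs whose chromosome/position is unknown; they are
    excluded from placement but retained for reserved-slot accounting.
    """

    snp_id: str
    chromosome: int
    position: int
    maf: float
    obligatory: bool = False
    no_map: bool = False

    def __post_init__(self):
        if not self.no_map and self.position < 1:
            raise MapValidationError(
                f"SNP {self.snp_id}: position must be >= 1, got {self.position}"
            )
        if not (0.0 <= self.maf <= 0.5):
            raise MapValidationError(
                f"SNP {self.snp_id}: MAF out of range [0, 0.5]: {self.maf}"
            )


class CandidateMap:
    """Ordered collection of candidate SNPs grouped by chromosome.

    Within each chromosome positions are strictly increasing; duplicate
    positions are resolved at load time by keeping the higher-MAF record
    (ties broken by lexicographic SNP id).  Chromosome lengths default
    to the span of observed candidates (first to last SNP) and can be
    overridden with a user-supplied table.
    """

    def __init__(self, records: Iterable[SnpRecord],
                 chrom_lengths: Mapping[int, float] | None = None):
        rows = [
            (r.snp_id, r.chromosome, r.position, r.maf, r.obligatory, r.no_map)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=MAP_COLUMNS)
        if df.empty:
            raise MapValidationError("candidate map contains zero records")
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise MapValidationError(f"duplicate snp_id in map: {dup!r}")
        mapped = df[~df["no_map"]].copy()
        # resolve duplicate positions: keep highest MAF, ties -> lexicographic id
        mapped = mapped.sort_values(
            ["chrom", "pos", "maf", "snp_id"],
            ascending=[True, True, False, True],
        )
        dropped = mapped.duplicated(subset=["chrom", "pos"], keep="first")
        if dropped.any():
            for sid in mapped.loc[dropped, "snp_id"]:
                logger.info("dropping duplicate-position SNP %s", sid)
        mapped = mapped[~dropped]
        unmapped = df[df["no_map"]]
        self._df = pd.concat([mapped, unmapped], ignore_index=True)
        self._lengths = dict(chrom_lengths) if chrom_lengths else {}

    @property
    def df(self) -> pd.DataFrame:
        """Underlying record table (mapped records sorted by chrom, pos)."""
        return self._df

    @property
    def mapped(self) -> pd.DataFrame:
        return self._df[~self._df["no_map"]]

    @property
    def unmapped(self) -> pd.DataFrame:
        return self._df[self._df["no_map"]]

    def __len__(self) -> int:
        return len(self._df)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.mapped["chrom"].unique())

    def chromosome(self, chrom: int) -> pd.DataFrame:
        """Records of one chromosome, sorted by position."""
        return self.mapped[self.mapped["chrom"] == chrom]

    def positions(self, chrom: int) -> np.ndarray:
        return self.chromosome(chrom)["pos"].to_numpy(dtype=float)

    def chrom_length(self, chrom: int) -> float:
        """Map length L_k: user override, else span first-to-last candidate."""
        if chrom in self._lengths:
            return float(self._lengths[chrom])
        pos = self.positions(chrom)
        if len(pos) == 0:
            raise MapValidationError(f"no mapped candidates on chromosome {chrom}")
        return float(pos[-1] - pos[0])

    @property
    def chrom_lengths(self) -> dict[int, float]:
        return {k: self.chrom_length(k) for k in self.chromosomes}

    def obligatory_ids(self) -> list[str]:
        return list(self._df.loc[self._df["obligatory"], "snp_id"])

    def with_obligatory(self, ids: Sequence[str]) -> "CandidateMap":
        """Return a copy with ``obligatory`` set for the given ids.

        Ids absent from the map are reported in the error message so
        unplaced obligatory SNPs never vanish silently.
        """
        ids = set(ids)
        known = set(self._df["snp_id"])
        missing = ids - known
        if missing:
            raise MapValidationError(
                f"obligatory ids not in map: {sorted(missing)[:10]}"
            )
        clone = CandidateMap.__new__(CandidateMap)
        clone._df = self._df.copy()
        clone._df["obligatory"] = clone._df["obligatory"] | clone._df[
            "snp_id"
        ].isin(ids)
        clone._lengths = dict(self._lengths)
        return clone

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   chrom_lengths: Mapping[int, float] | None = None
                   ) -> "CandidateMap":
        records = [
            SnpRecord(
                snp_id=str(r.snp_id),
                chromosome=int(r.chrom),
                position=int(r.pos) if not bool(getattr(r, "no_map", False)) else 0,
                maf=float(r.maf),
                obligatory=bool(getattr(r, "obligatory", False)),
                no_map=bool(getattr(r, "no_map", False)),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(records, chrom_lengths)


@dataclass
class HaplotypePanel:
    """Phased haplotypes as a binary matrix (haplotypes x SNPs, 1 = minor)."""

    allele_matrix: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.allele_matrix = np.asarray(self.allele_matrix, dtype=np.int8)
        if self.allele_matrix.ndim != 2:
            raise MapValidationError("allele matrix must be 2-dimensional")
        bad = ~np.isin(self.allele_matrix, (0, 1))
        if bad.any():
            raise MapValidationError(
                f"allele matrix entries must be 0/1; found {self.allele_matrix[bad][0]}"
            )
        if self.snp_ids and len(self.snp_ids) != self.allele_matrix.shape[1]:
            raise MapValidationError("snp_ids length does not match matrix columns")

    @property
    def n_haplotypes(self) -> int:
        return self.allele_matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.allele_matrix.shape[1]

    def frequencies(self) -> np.ndarray:
        """Minor-allele frequency per column."""
        return self.allele_matrix.mean(axis=0)

    def align(self, snp_ids: Sequence[str]) -> "HaplotypePanel":
        """Reorder columns to the given snp_id order; unknown ids error."""
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise MapValidationError(f"snp_ids not in panel: {missing[:10]}")
        cols = [index[s] for s in snp_ids]
        return HaplotypePanel(self.allele_matrix[:, cols], list(snp_ids))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_candidate_map(path: str | Path, format: str = "tsv",
                       chrom_lengths: Mapping[int, float] | None = None
                       ) -> CandidateMap:
    """Read a candidate map from TSV or a PLINK ``.bim``/``.frq`` pair.

    TSV columns: ``snp_id  chrom  pos  maf  obligatory`` (obligatory
    optional).  For ``format="plink"``, ``path`` is the shared prefix of
    a 6-column ``.bim`` and a ``.frq`` allele-frequency table (columns
    CHR, SNP, A1, A2, MAF, NCHROBS).  SNPs lacking position or frequency
    are flagged ``no_map`` and excluded from placement.
    """
    if format == "tsv":
        return _read_map_tsv(Path(path), chrom_lengths)
    if format == "plink":
        return _read_map_plink(Path(path), chrom_lengths)
    raise ValueError(f"unknown map format {format!r}")


def _read_map_tsv(path: Path, chrom_lengths) -> CandidateMap:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    except pd.errors.EmptyDataError as exc:
        raise MapValidationError(f"{path}: empty candidate map file") from exc
    required = {"snp_id", "chrom", "pos", "maf"}
    if not required.issubset(df.columns):
        raise MapParseError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise MapValidationError(f"{path}: candidate map has zero records")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            no_map = pd.isna(row.chrom) or pd.isna(row.pos) or pd.isna(row.maf)
            records.append(
                SnpRecord(
                    snp_id=str(row.snp_id),
                    chromosome=0 if no_map else chrom_ordinal(row.chrom),
                    position=0 if no_map else int(row.pos),
                    maf=0.0 if pd.isna(row.maf) else float(row.maf),
                    obligatory=_parse_bool(getattr(row, "obligatory", False)),
                    no_map=bool(no_map),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, MapValidationError):
                raise
            raise MapParseError(f"{path}: malformed row at line {i}: {exc}") from exc
    return CandidateMap(records, chrom_lengths)


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "yes"}
    try:
        if pd.isna(v):
            return False
    except TypeError:
        pass
    return bool(v)


def _read_map_plink(prefix: Path, chrom_lengths) -> CandidateMap:
    bim_path = prefix.with_suffix(".bim")
    frq_path = prefix.with_suffix(".frq")
    for p in (bim_path, frq_path):
        if not p.exists():
            raise FileNotFoundError(p)
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype={"snp_id": str},
    )
    frq = pd.read_csv(frq_path, sep=r"\s+", dtype={"SNP": str})
    need = {"SNP", "MAF"}
    if not need.issubset(frq.columns):
        raise MapParseError(f"{frq_path}: missing columns {sorted(need - set(frq.columns))}")
    merged = bim.merge(frq[["SNP", "MAF"]], left_on="snp_id", right_on="SNP",
                       how="left")
    records = []
    for i, row in enumerate(merged.itertuples(index=False), start=1):
        no_map = pd.isna(row.MAF) or row.pos <= 0 or row.chrom in (0, "0")
        try:
            chrom = 0 if no_map else chrom_ordinal(row.chrom)
        except MapParseError:
            no_map, chrom = True, 0
        records.append(
            SnpRecord(
                snp_id=str(row.snp_id),
                chromosome=chrom,
                position=0 if no_map else int(row.pos),
                maf=0.0 if pd.isna(row.MAF) else float(row.MAF),
                no_map=bool(no_map),
            )
        )
    return CandidateMap(records, chrom_lengths)


def read_haplotypes(path: str | Path, format: str = "matrix_tsv") -> HaplotypePanel:
    """Read phased haplotypes from a VCF (phased GT) or a 0/1 matrix TSV.

    The matrix TSV has one row per haplotype and one column per SNP,
    with a header row of SNP ids.  VCF genotypes must be phased
    (``|``-separated); each sample contributes two haplotypes.
    """
    if format == "matrix_tsv":
        df = pd.read_csv(path, sep="\t")
        mat = df.to_numpy()
        return HaplotypePanel(mat, [str(c) for c in df.columns])
    if format == "vcf":
        return _read_haplotypes_vcf(str(path))
    raise ValueError(f"unknown haplotype format {format!r}")


def _read_haplotypes_vcf(path: str) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        alleles = []
        for g in variant.genotypes:  # [a0, a1, phased]
            if not g[-1]:
                raise MapValidationError(
                    f"unphased genotype at {ids[-1]}; phased GT ('|') required"
                )
            alleles.extend(g[:-1])
        columns.append(np.asarray(alleles, dtype=np.int8))
    if not columns:
        raise MapValidationError(f"{path}: VCF contains no variants")
    return HaplotypePanel(np.column_stack(columns), ids)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_selection(result, path: str | Path, summary: dict | None = None) -> None:
    """Write a SelectionResult to TSV plus a JSON sidecar of its summary.

    Columns: ``snp_id  chrom  pos  maf  provenance  bin_index``.
    Obligatory SNPs without map data appear with empty position and
    provenance ``obligatory_unmapped``.  The sidecar ``<path>.json``
    records the chip summary (or the result's settings when no summary
    is supplied).
    """
    path = Path(path)
    df = result.chosen if hasattr(result, "chosen") else result
    out = df.reindex(columns=SELECTION_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = summary if summary is not None else {
        "settings": getattr(result, "settings", {}),
        "n_chosen": int(len(df)),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=_js))


def _js(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_selection(path: str | Path) -> pd.DataFrame:
    """Re-read a selection TSV written by :func:`write_selection`."""
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str})
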