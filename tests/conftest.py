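import numpy as np
import pandas as pd
import pytest

from snpdesign import CandidateMap, SnpRecord, SimulationConfig, simulate_candidate_map

# Four-candidate worked example: one SNP to be picked from a length-100
# segment anchored by boundary SNPs at 0 and 100.  MAFs as in the
# illustrative example; positions are fixture choices consistent with it
# (the 0.2000 SNP sits exactly at the center).
FIG_CANDIDATES = [
    ("A", 31, 0.4239),
    ("B", 48, 0.3524),
    ("C", 50, 0.2000),
    ("D", 69, 0.1708),
]


@pytest.fixture
def fig_segment() -> pd.DataFrame:
    return pd.DataFrame(
        [(sid, 1, pos, maf, False) for sid, pos, maf in FIG_CANDIDATES],
        columns=["snp_id", "chrom", "pos", "maf", "obligatory"],
    )


@pytest.fixture
def four_snp_map() -> CandidateMap:
    """Candidate map matching the canonical 4-row TSV example."""
    rows = [("A", 10, 0.4239), ("B", 48, 0.3524), ("C", 50, 0.2000),
            ("D", 90, 0.1708)]
    return CandidateMap(
        [SnpRecord(sid, 1, pos, maf) for sid, pos, maf in rows]
    )


def make_map(n_candidates=300, n_chromosomes=2, seed=0, obligatory_fraction=0.0,
             lengths_bp=2_000_000.0):
    cfg = SimulationConfig(
        n_chromosomes=n_chromosomes,
        lengths=(lengths_bp,) * n_chromosomes,
        n_candidates=(n_candidates,) * n_chromosomes,
        obligatory_fraction=obligatory_fraction,
        seed=seed,
    )
    return simulate_candidate_map(cfg)


@pytest.fixture
def dense_map() -> CandidateMap:
    return make_map(n_candidates=300, n_chromosomes=2, seed=11)


def panel_lase(cmap: CandidateMap, ids) -> float:
    from snpdesign import lase

    mafs = cmap.df.set_index("snp_id").loc[list(ids), "maf"]
    return lase(mafs.to_numpy(dtype=float))
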