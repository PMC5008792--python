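"""Panel summary statistics and design comparisons.

Reports per-chromosome SNP counts, map length, maximum gap, root-mean-
square (RMS) neighbor spacing and locus-average Shannon entropy (LASE),
plus genome totals and the percent LASE increment over a control
design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import entropy as ent


class EvaluationError(ValueError):
    pass


def rms_spacing(positions) -> float:
    """Square root of the mean squared neighbor distance."""
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 2:
        raise EvaluationError("RMS spacing needs at least 2 positions")
    d = np.diff(np.sort(pos))
    return float(np.sqrt(np.mean(d ** 2)))


def increment_over_control(value: float, control: float) -> float:
    """Percent increment of an entropy value over a control design."""
    if control <= 0:
        raise EvaluationError(f"control must be positive, got {control}")
    return 100.0 * (value - control) / control


def summarize_chip(selection, cmap=None) -> dict:
    """ChipSummary for a selection (SelectionResult or selection frame).

    Per-chromosome entries: chrom, n, length_bp, max_gap_bp,
    rms_spacing_bp, lase (spacing fields are None for single-SNP
    chromosomes).  Gap counting on the selected set uses twice the
    chip's per-chromosome mean spacing as the threshold.
    """
    df = selection.chosen if hasattr(selection, "chosen") else selection
    if df.empty:
        return {"per_chromosome": [], "genome": {"n": 0, "n_unmapped": 0},
                "settings": getattr(selection, "settings", {})}
    placed = df.dropna(subset=["pos"])
    per_chrom = []
    for chrom, grp in placed.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(dtype=float))
        entry = {
            "chrom": int(chrom),
            "n": int(len(grp)),
            "lase": ent.lase(grp["maf"].to_numpy(dtype=float)),
        }
        if len(pos) >= 2:
            d = np.diff(pos)
            entry.update({
                "length_bp": float(pos[-1] - pos[0]),
                "max_gap_bp": float(d.max()),
                "rms_spacing_bp": rms_spacing(pos),
                "n_gaps": int((d > 2.0 * d.mean()).sum()),
            })
        else:
            entry.update({"length_bp": None, "max_gap_bp": None,
                          "rms_spacing_bp": None, "n_gaps": None})
        per_chrom.append(entry)
    genome = {
        "n": int(len(df)),
        "n_mapped": int(len(placed)),
        "n_unmapped": int(len(df) - len(placed)),
        "lase": ent.lase(placed["maf"].to_numpy(dtype=float)),
        "total_length_bp": float(sum(e["length_bp"] or 0 for e in per_chrom)),
        "provenance_counts": df["provenance"].value_counts().to_dict(),
    }
    return {
        "per_chromosome": per_chrom,
        "genome": genome,
        "settings": dict(getattr(selection, "settings", {})),
    }
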