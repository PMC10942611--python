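"""Per-cell barcode QC, error correction and role assignment.

Turns raw per-cell barcode observations into QC-passed cell-barcode calls:
cells are filtered on total counts and gene numbers, barcodes within a cell
are error-corrected towards the most abundant neighbours, calls are retained
on a count threshold and a linguistic-complexity threshold, and barcoded
cells are assigned source/presynaptic roles from glycoprotein transcript
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from barnet import _seq

#: complexity threshold below which barcode calls are rejected
DEFAULT_MIN_COMPLEXITY = 10 ** -0.9


@dataclass(frozen=True)
class CallProfile:
    """Named threshold set for barcode calling and role assignment."""

    min_count: int
    min_complexity: float = DEFAULT_MIN_COMPLEXITY
    g_source_min: int = 2
    g_exclude_exact: int = 1


#: the in situ retrograde experiment called barcodes at >=6 reads; the
#: transsynaptic experiment at >=8; "conventional" raises the glycoprotein
#: source threshold to 12 for sensitivity analysis
PROFILES = {
    "retrograde": CallProfile(min_count=6),
    "transsynaptic": CallProfile(min_count=8),
    "conventional": CallProfile(min_count=8, g_source_min=12),
}


@dataclass
class ComplexityProfile:
    """Linguistic sequence complexity of a barcode.

    ``vocabulary_usage[n-1]`` is U_n, the number of distinct n-grams divided
    by the maximum possible (min of 4^n and the number of n-gram positions);
    ``complexity`` is the product of all U_n.
    """

    length: int
    vocabulary_usage: np.ndarray
    complexity: float


def qc_filter_cells(
    cells: pd.DataFrame, min_counts: int = 20, min_genes: int = 5
) -> pd.DataFrame:
    """Keep cells with at least ``min_counts`` total counts and at least
    ``min_genes`` detected genes (both inclusive)."""
    if min_counts < 0 or min_genes < 0:
        raise ValueError("thresholds must be non-negative")
    if not len(cells):
        return cells.copy()
    keep = (cells["total_count"] >= min_counts) & (cells["n_genes"] >= min_genes)
    return cells[keep].reset_index(drop=True)


def linguistic_complexity(seq: str) -> ComplexityProfile:
    """Linguistic sequence complexity of a nucleotide string.

    U_n = (#distinct overlapping n-grams) / min(4^n, L - n + 1) for
    n = 1..L; the complexity is the product over all n. A maximally diverse
    sequence scores 1; a homopolymer scores far below any practical
    threshold.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if set(seq) - set(_seq.ALPHABET):
        raise ValueError(f"non-ACGT character in {seq!r}")
    length = len(seq)
    usage = np.empty(length)
    for n in range(1, length + 1):
        n_positions = length - n + 1
        distinct = len({seq[i : i + n] for i in range(n_positions)})
        usage[n - 1] = distinct / min(4**n, n_positions)
    return ComplexityProfile(
        length=length, vocabulary_usage=usage, complexity=float(np.prod(usage))
    )


def _correct_one_cell(group: pd.DataFrame, max_mismatch: int) -> pd.DataFrame:
    lengths = group["barcode"].str.len().unique()
    if len(lengths) > 1:
        cell = group["cell_id"].iloc[0]
        raise ValueError(f"mixed barcode lengths within cell {cell!r}")
    # descending count, ties broken lexicographically on the barcode
    ordered = group.sort_values(
        ["count", "barcode"], ascending=[False, True]
    ).reset_index(drop=True)
    kept: list[str] = []
    merged: dict[str, int] = {}
    for barcode, count in zip(ordered["barcode"], ordered["count"]):
        target = None
        for k in kept:
            if _seq.hamming(barcode, k) <= max_mismatch:
                target = k
                break
        if target is None:
            kept.append(barcode)
            merged[barcode] = int(count)
        else:
            merged[target] += int(count)
    out = pd.DataFrame(
        {
            "cell_id": group["cell_id"].iloc[0],
            "barcode": kept,
            "count": [merged[k] for k in kept],
        }
    )
    return out


def correct_within_cell(reads: pd.DataFrame, max_mismatch: int = 2) -> pd.DataFrame:
    """Within-cell barcode error correction.

    Processing barcodes of each cell in descending count order (ties broken
    lexicographically), every barcode within ``max_mismatch`` of an
    already-retained barcode is merged into it, counts added. Retained
    barcodes end up pairwise more than ``max_mismatch`` apart, so the
    operation is idempotent. Cells are processed independently.
    """
    if not len(reads):
        return reads.copy()
    if (reads["count"] <= 0).any():
        raise ValueError("read counts must be positive")
    parts = [
        _correct_one_cell(group, max_mismatch)
        for _, group in reads.groupby("cell_id", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)


def call_cell_barcodes(
    reads: pd.DataFrame,
    min_count: int,
    min_complexity: float = DEFAULT_MIN_COMPLEXITY,
) -> pd.DataFrame:
    """Threshold corrected per-cell barcode counts into calls.

    A call is retained iff its count is at least ``min_count`` and the
    barcode's linguistic complexity exceeds ``min_complexity``. The
    max-count retained call of each cell is flagged primary (ties broken
    lexicographically); ``primary_fraction`` is that call's count divided by
    the cell's pre-threshold read total.

    Columns: cell_id, barcode, count, complexity, is_primary,
    primary_fraction.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    cols = ["cell_id", "barcode", "count", "complexity", "is_primary", "primary_fraction"]
    if not len(reads):
        return pd.DataFrame(columns=cols)
    df = reads.copy()
    totals = df.groupby("cell_id")["count"].sum()
    complexity_cache: dict[str, float] = {}

    def _cx(bc: str) -> float:
        if bc not in complexity_cache:
            complexity_cache[bc] = linguistic_complexity(bc).complexity
        return complexity_cache[bc]

    df["complexity"] = df["barcode"].map(_cx)
    df = df[(df["count"] >= min_count) & (df["complexity"] > min_complexity)]
    if not len(df):
        return pd.DataFrame(columns=cols)
    df = df.sort_values(
        ["cell_id", "count", "barcode"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["is_primary"] = ~df.duplicated("cell_id")
    primary_count = df.groupby("cell_id")["count"].transform("max")
    df["primary_fraction"] = (
        df["cell_id"].map(totals).rdiv(primary_count).astype(float)
    )
    return df[cols]


def classify_cell_roles(
    calls: pd.DataFrame,
    cells: pd.DataFrame,
    g_source_min: int = 2,
    g_exclude_exact: int = 1,
) -> pd.DataFrame:
    """Assign source/presynaptic roles from glycoprotein counts.

    Barcoded cells with g_count >= ``g_source_min`` are sources; cells with
    exactly ``g_exclude_exact`` glycoprotein reads are excluded from further
    analysis; cells with zero glycoprotein are potential presynaptic cells.
    Returns the calls table with a ``role`` column.
    """
    if not len(calls):
        out = calls.copy()
        out["role"] = pd.Series(dtype=object)
        return out
    g = cells.set_index("cell_id")["g_count"]
    missing = set(calls["cell_id"]) - set(g.index)
    if missing:
        raise KeyError(f"cells missing from metadata: {sorted(missing)[:5]}")
    out = calls.copy()
    g_count = out["cell_id"].map(g)
    role = np.where(
        g_count >= g_source_min,
        "source",
        np.where(g_count == g_exclude_exact, "excluded", "presynaptic"),
    )
    out["role"] = role
    return out


def run_calling_pipeline(
    reads: pd.DataFrame,
    cells: pd.DataFrame,
    profile: CallProfile | str,
    max_mismatch: int = 2,
    min_counts: int = 20,
    min_genes: int = 5,
) -> pd.DataFrame:
    """QC cells, correct, call and role-assign in one pass."""
    if isinstance(profile, str):
        profile = PROFILES[profile]
    cells_qc = qc_filter_cells(cells, min_counts=min_counts, min_genes=min_genes)
    reads_qc = reads[reads["cell_id"].isin(set(cells_qc["cell_id"]))]
    corrected = correct_within_cell(reads_qc, max_mismatch=max_mismatch)
    calls = call_cell_barcodes(
        corrected, min_count=profile.min_count, min_complexity=profile.min_complexity
    )
    return classify_cell_roles(
        calls,
        cells_qc,
        g_source_min=profile.g_source_min,
        g_exclude_exact=profile.g_exclude_exact,
    )


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
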