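"""Synaptic-convergence statistics across neuronal subclasses.

For every filtered barcode-sharing network, all unordered pairs of
presynaptic member cells are treated as converging outputs and accumulated
by subclass pair. Observed counts are compared to a random-connectivity
expectation proportional to subclass cell-count products, and significance
is assessed by permuting subclass labels over the pooled participating
cells.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from barnet.library_tools import BarcodeLibrary
from barnet.network_inference import BarcodeNetwork


@dataclass
class ConvergenceMatrix:
    """Observed/expected converging-pair counts with permutation p-values.

    All matrices are symmetric and indexed by ``subclasses``; ``mask`` marks
    entries significant at ``fpr_alpha``.
    """

    subclasses: list[str]
    observed: np.ndarray
    expected: np.ndarray
    bias: np.ndarray
    p_values: np.ndarray | None = None
    mask: np.ndarray | None = None
    n_permutations: int = 0
    fpr_alpha: float = 0.05
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.subclasses)
        for i in range(k):
            for j in range(i, k):
                rows.append(
                    {
                        "subclass_a": self.subclasses[i],
                        "subclass_b": self.subclasses[j],
                        "observed": int(self.observed[i, j]),
                        "expected": float(self.expected[i, j]),
                        "bias": float(self.bias[i, j]),
                        "p": float(self.p_values[i, j])
                        if self.p_values is not None
                        else np.nan,
                        "significant": bool(self.mask[i, j])
                        if self.mask is not None
                        else False,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            meta = dict(self.metadata)
            meta.update(
                {"n_permutations": self.n_permutations, "fpr_alpha": self.fpr_alpha}
            )
            Path(json_path).write_text(json.dumps(meta, indent=1))


def filter_for_convergence(
    networks: Sequence[BarcodeNetwork],
    library: BarcodeLibrary | None,
    min_cells: int = 5,
    max_barcode_freq: float | None = None,
) -> list[BarcodeNetwork]:
    """Keep networks usable for convergence analysis.

    Retained networks have at least ``min_cells`` member cells (removing
    most no-source networks) and a library barcode frequency at most
    ``max_barcode_freq`` (removing likely double-labeled networks). Barcodes
    absent from the library are retained — the unsequenced tail is treated
    as rare.
    """
    out = []
    for net in networks:
        if net.n_cells < min_cells:
            continue
        if max_barcode_freq is not None and library is not None:
            freq = library.frequency_of(net.barcode)
            if freq > max_barcode_freq:
                continue
        out.append(net)
    return out


def _participating_cells(
    networks: Sequence[BarcodeNetwork], include_sources: bool
) -> tuple[list[str], list[list[int]]]:
    """Pooled participating cells and per-network member index lists."""
    cell_index: dict[str, int] = {}
    memberships: list[list[int]] = []
    for net in networks:
        members = net.member_cell_ids if include_sources else (
            net.member_cell_ids - net.source_cell_ids
        )
        idx = []
        for cell in sorted(members):
            if cell not in cell_index:
                cell_index[cell] = len(cell_index)
            idx.append(cell_index[cell])
        memberships.append(idx)
    cells = [c for c, _ in sorted(cell_index.items(), key=lambda kv: kv[1])]
    return cells, memberships


def _pair_matrix(
    memberships: Sequence[Sequence[int]], labels: np.ndarray, n_subclasses: int
) -> np.ndarray:
    """Accumulate converging pairs per subclass pair over networks.

    For each network with per-subclass member counts c, the off-diagonal
    entry (a, b) gains c_a * c_b and the diagonal gains C(c_a, 2).
    Symmetric; each unordered pair is represented once (mirrored off the
    diagonal).
    """
    n_networks = len(memberships)
    counts = np.zeros((n_networks, n_subclasses), dtype=np.int64)
    for i, members in enumerate(memberships):
        if len(members):
            counts[i] = np.bincount(labels[members], minlength=n_subclasses)
    cross = counts.T @ counts  # sum over networks of c c^T
    sq = (counts * counts).sum(axis=0)
    lin = counts.sum(axis=0)
    out = cross.astype(np.float64)
    np.fill_diagonal(out, (sq - lin) / 2.0)
    return out


def converging_pairs(
    networks: Sequence[BarcodeNetwork],
    subclass_of_cell: Mapping[str, str],
    include_sources: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Observed converging-pair counts by subclass pair.

    Every unordered pair of (by default presynaptic) member cells of a
    network counts once; distinct barcodes contribute independently even
    when they involve the same cells. Returns the sorted subclass label
    list and the symmetric observed matrix.
    """
    cells, memberships = _participating_cells(networks, include_sources)
    missing = [c for c in cells if c not in subclass_of_cell]
    if missing:
        raise KeyError(f"cells without subclass label: {missing[:5]}")
    subclasses = sorted({subclass_of_cell[c] for c in cells})
    if not subclasses:
        return [], np.zeros((0, 0))
    index = {s: i for i, s in enumerate(subclasses)}
    labels = np.array([index[subclass_of_cell[c]] for c in cells], dtype=np.int64)
    observed = _pair_matrix(memberships, labels, len(subclasses))
    return subclasses, observed


def expected_and_bias(
    observed: np.ndarray,
    subclass_counts: Sequence[int],
    diagonal: str = "squared",
) -> tuple[np.ndarray, np.ndarray]:
    """Random-connectivity expectation and observed/expected bias.

    Expected weights follow products of subclass cell counts. With the
    default ``diagonal='squared'`` the diagonal weight is n_a**2 and the
    off-diagonal 2 * n_a * n_b (an unordered cross pair accumulates both
    ordered directions, so the square-of-counts model is calibrated against
    i.i.d. labels). ``diagonal='choose2'`` uses the finite-size-corrected
    combination counts n_a * (n_a - 1) / 2 and n_a * n_b. Weights are scaled
    so the upper-triangle totals of expected and observed match.
    """
    n = np.asarray(subclass_counts, dtype=float)
    if observed.shape != (len(n), len(n)):
        raise ValueError("observed shape does not match subclass counts")
    appearing = observed.sum(axis=0) + observed.sum(axis=1) > 0
    if np.any((n <= 0) & appearing):
        raise ValueError("zero cell count for a subclass with observed pairs")
    if diagonal == "squared":
        weights = 2.0 * np.outer(n, n)
        np.fill_diagonal(weights, n * n)
    elif diagonal == "choose2":
        weights = np.outer(n, n)
        np.fill_diagonal(weights, n * (n - 1) / 2.0)
    else:
        raise ValueError("diagonal must be 'squared' or 'choose2'")
    triu = np.triu_indices(len(n))
    total_observed = observed[triu].sum()
    if total_observed <= 0:
        raise ValueError("no observed converging pairs")
    total_weight = weights[triu].sum()
    expected = weights * (total_observed / total_weight)
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = np.where(expected > 0, observed / expected, np.nan)
    return expected, bias


def permutation_significance(
    networks: Sequence[BarcodeNetwork],
    subclass_of_cell: Mapping[str, str],
    n_iter: int = 10000,
    seed: int | None = None,
    fpr_alpha: float = 0.05,
    include_sources: bool = False,
    pseudocount: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation p-values for convergence biases.

    Each iteration permutes subclass labels over the pooled participating
    cells (network memberships and sizes preserved, marginal subclass
    counts preserved) and recomputes the pair matrix. The p-value is
    min(1, 2 * min(fraction of iterations at or above the observed count,
    fraction at or below)). With ``pseudocount=True`` a +1 correction bounds
    p away from zero at 1/(n_iter + 1).
    """
    if not networks:
        raise ValueError("need at least one filtered network")
    cells, memberships = _participating_cells(networks, include_sources)
    subclasses = sorted({subclass_of_cell[c] for c in cells})
    index = {s: i for i, s in enumerate(subclasses)}
    labels = np.array([index[subclass_of_cell[c]] for c in cells], dtype=np.int64)
    k = len(subclasses)
    observed = _pair_matrix(memberships, labels, k)

    rng = np.random.default_rng(seed)
    ge = np.zeros((k, k), dtype=np.int64)
    le = np.zeros((k, k), dtype=np.int64)
    perm_labels = labels.copy()
    for _ in range(n_iter):
        rng.shuffle(perm_labels)
        perm = _pair_matrix(memberships, perm_labels, k)
        ge += perm >= observed
        le += perm <= observed
    if pseudocount:
        p = 2.0 * (np.minimum(ge, le) + 1) / (n_iter + 1)
    else:
        p = 2.0 * np.minimum(ge, le) / n_iter
    p = np.minimum(p, 1.0)
    return p, p < fpr_alpha


def convergence_analysis(
    networks: Sequence[BarcodeNetwork],
    subclass_of_cell: Mapping[str, str],
    library: BarcodeLibrary | None = None,
    min_cells: int = 5,
    max_barcode_freq: float | None = None,
    n_iter: int = 10000,
    seed: int | None = None,
    fpr_alpha: float = 0.05,
    include_sources: bool = False,
    diagonal: str = "squared",
) -> ConvergenceMatrix:
    """Filter networks, count pairs, compute expectation/bias and
    permutation significance in one pass."""
    filtered = filter_for_convergence(
        networks, library, min_cells=min_cells, max_barcode_freq=max_barcode_freq
    )
    if not filtered:
        raise ValueError("no networks pass the convergence filters")
    subclasses, observed = converging_pairs(
        filtered, subclass_of_cell, include_sources=include_sources
    )
    cells, _ = _participating_cells(filtered, include_sources)
    counts = pd.Series([subclass_of_cell[c] for c in cells]).value_counts()
    n_per_subclass = [int(counts.get(s, 0)) for s in subclasses]
    expected, bias = expected_and_bias(observed, n_per_subclass, diagonal=diagonal)
    p, mask = permutation_significance(
        filtered,
        subclass_of_cell,
        n_iter=n_iter,
        seed=seed,
        fpr_alpha=fpr_alpha,
        include_sources=include_sources,
    )
    return ConvergenceMatrix(
        subclasses=subclasses,
        observed=observed,
        expected=expected,
        bias=bias,
        p_values=p,
        mask=mask,
        n_permutations=n_iter,
        fpr_alpha=fpr_alpha,
        metadata={
            "min_cells": min_cells,
            "max_barcode_freq": max_barcode_freq,
            "seed": seed,
            "include_sources": include_sources,
            "diagonal": diagonal,
            "n_networks": len(filtered),
            "n_participating_cells": len(cells),
        },
    )
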