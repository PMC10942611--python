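"""Barcode-sharing networks, the infection-count posterior, and the
source-ledger decomposition.

Groups barcoded cells into per-barcode networks, classifies them
(single-source / multi-source / no-source / lost-source), models barcode
multiplicity as a binomial in the number of infection events, estimates the
posterior over the number of independent infections that produced the
observed unique source barcodes, and splits shared source-cell/barcode
combinations into double-labeled versus connected-source pairs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from barnet.library_tools import BarcodeLibrary

NETWORK_CLASSES = ("single_source", "multi_source", "no_source", "lost_source")


@dataclass
class BarcodeNetwork:
    barcode: str
    member_cell_ids: frozenset
    source_cell_ids: frozenset
    network_class: str

    def __post_init__(self) -> None:
        if not self.source_cell_ids <= self.member_cell_ids:
            raise ValueError("source cells must be a subset of members")
        if self.network_class not in NETWORK_CLASSES:
            raise ValueError(f"unknown network class {self.network_class!r}")

    @property
    def n_cells(self) -> int:
        return len(self.member_cell_ids)

    @property
    def n_sources(self) -> int:
        return len(self.source_cell_ids)


@dataclass
class InfectionPosterior:
    """Posterior over the number of independent infection events N given
    M unique source barcodes, supported on M..C where C is the number of
    unique source-cell/barcode combinations."""

    m_unique: int
    c_combinations: int
    support: np.ndarray
    mass: np.ndarray
    mode: int
    ci95: tuple[int, int]
    mc_reps: int
    seed: int | None

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["support"] = [int(x) for x in self.support]
        payload["mass"] = [float(x) for x in self.mass]
        payload["ci95"] = [int(x) for x in self.ci95]
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class LedgerDecomposition:
    singles: int
    est_independent_infections: int
    est_double_labeled_pairs: int
    est_connected_pairs: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def build_networks(
    calls: pd.DataFrame, min_cells_lost_source: int = 5
) -> list[BarcodeNetwork]:
    """One network per barcode from role-annotated calls.

    Cells with role ``excluded`` are dropped first. A network is
    single_source with one source, multi_source with two or more,
    lost_source with no source but at least ``min_cells_lost_source``
    members, and no_source otherwise.
    """
    if not len(calls):
        return []
    if "role" not in calls.columns:
        raise ValueError("calls must carry a 'role' column")
    usable = calls[calls["role"] != "excluded"]
    networks = []
    for barcode, group in usable.groupby("barcode", sort=True):
        members = frozenset(group["cell_id"])
        sources = frozenset(group.loc[group["role"] == "source", "cell_id"])
        if len(sources) == 1:
            cls = "single_source"
        elif len(sources) >= 2:
            cls = "multi_source"
        elif len(members) >= min_cells_lost_source:
            cls = "lost_source"
        else:
            cls = "no_source"
        networks.append(BarcodeNetwork(str(barcode), members, sources, cls))
    return networks


def networks_to_frame(networks: list[BarcodeNetwork]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "barcode": [n.barcode for n in networks],
            "n_cells": [n.n_cells for n in networks],
            "n_sources": [n.n_sources for n in networks],
            "network_class": [n.network_class for n in networks],
            "member_cell_ids": [",".join(sorted(n.member_cell_ids)) for n in networks],
            "source_cell_ids": [",".join(sorted(n.source_cell_ids)) for n in networks],
        }
    )


def multiplicity_prob(f: float, n_total: int, m_min: int) -> float:
    """P(X >= m_min) for X ~ Binomial(n_total, f): the probability that a
    barcode of library frequency ``f`` is involved in at least ``m_min`` of
    ``n_total`` independent infection events."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    if n_total < 1 or m_min < 0 or m_min > n_total:
        raise ValueError("require n_total >= 1 and 0 <= m_min <= n_total")
    if m_min == 0:
        return 1.0
    return float(stats.binom.sf(m_min - 1, n_total, f))


def _exact_distinct_pmf(freq: np.ndarray, n_draws: int, m: int) -> float:
    """P(exactly m distinct barcodes among n i.i.d. draws) by
    inclusion-exclusion over barcode subsets; exponential in library size,
    used as an oracle for tiny libraries."""
    k = len(freq)
    if m > min(k, n_draws):
        return 0.0
    total = 0.0
    for subset in itertools.combinations(range(k), m):
        p_sub = freq[list(subset)]
        for r in range(m + 1):
            sign = (-1) ** (m - r)
            for inner in itertools.combinations(range(m), r):
                total += sign * float(p_sub[list(inner)].sum()) ** n_draws
    return total


def _mc_distinct_trajectories(
    freq: np.ndarray, max_draws: int, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """(reps, max_draws) array: number of distinct barcodes after each draw
    of an i.i.d. sequence drawn by frequency."""
    cum = np.cumsum(freq)
    cum[-1] = 1.0
    draws = np.searchsorted(cum, rng.random((reps, max_draws)), side="right")
    order = np.argsort(draws, axis=1, kind="stable")
    sorted_draws = np.take_along_axis(draws, order, axis=1)
    new_value = np.ones_like(sorted_draws, dtype=bool)
    new_value[:, 1:] = sorted_draws[:, 1:] != sorted_draws[:, :-1]
    first_occurrence = np.empty_like(new_value)
    np.put_along_axis(first_occurrence, order, new_value, axis=1)
    return np.cumsum(first_occurrence, axis=1)


def infection_posterior(
    m_unique: int,
    c_combinations: int,
    library: BarcodeLibrary,
    mc_reps: int = 2000,
    seed: int | None = None,
    exact_max_barcodes: int = 12,
) -> InfectionPosterior:
    """Posterior over the number of independent infection events.

    For each N in [M, C] the likelihood P(M | N) is the probability that N
    i.i.d. draws by library frequency yield exactly M distinct barcodes; the
    prior on N is uniform on [M, C]. For libraries of at most
    ``exact_max_barcodes`` barcodes the likelihood is computed exactly by
    inclusion-exclusion; otherwise it is estimated from ``mc_reps``
    Monte-Carlo draw sequences of length C (each N's likelihood read off the
    distinct-count trajectory, which is unbiased per N).

    The 95% interval is the central interval of the cumulative posterior,
    widened if necessary to contain the mode.
    """
    if not 1 <= m_unique <= c_combinations:
        raise ValueError("require 1 <= m_unique <= c_combinations")
    support = np.arange(m_unique, c_combinations + 1)
    freq = np.asarray(library.frequencies, dtype=float)

    if len(library) <= exact_max_barcodes:
        lik = np.array(
            [_exact_distinct_pmf(freq, int(n), m_unique) for n in support]
        )
    else:
        rng = np.random.default_rng(seed)
        traj = _mc_distinct_trajectories(freq, c_combinations, mc_reps, rng)
        lik = (traj[:, support - 1] == m_unique).mean(axis=0)

    if lik.sum() <= 0:
        raise ValueError(
            "likelihood is zero over the whole support; increase mc_reps"
        )
    mass = lik / lik.sum()
    mode = int(support[int(np.argmax(mass))])
    cdf = np.cumsum(mass)
    lo = int(support[int(np.searchsorted(cdf, 0.025))])
    hi = int(support[int(np.searchsorted(cdf, 0.975))])
    lo, hi = min(lo, mode), max(hi, mode)
    return InfectionPosterior(
        m_unique=m_unique,
        c_combinations=c_combinations,
        support=support,
        mass=mass,
        mode=mode,
        ci95=(lo, hi),
        mc_reps=mc_reps,
        seed=seed,
    )


def decompose_ledger(
    networks: list[BarcodeNetwork] | int, posterior: InfectionPosterior
) -> LedgerDecomposition:
    """Split source-cell/barcode combinations into single-source,
    double-labeled and connected-source pairs.

    ``networks`` may be the network table (singles are counted as barcodes
    with exactly one source) or the singles count itself. Double-labeled
    pairs = posterior mode - singles; connected pairs = C - mode.
    """
    if isinstance(networks, int):
        singles = networks
    else:
        singles = sum(1 for n in networks if n.n_sources == 1)
    mode = posterior.mode
    if mode < singles:
        raise ValueError(
            f"posterior mode {mode} < single-source barcodes {singles}: "
            "model inconsistency"
        )
    connected = posterior.c_combinations - mode
    if connected < 0:
        raise ValueError("posterior mode exceeds combination count")
    return LedgerDecomposition(
        singles=singles,
        est_independent_infections=mode,
        est_double_labeled_pairs=mode - singles,
        est_connected_pairs=connected,
    )


def source_detection_fraction(
    reads: pd.DataFrame,
    roles: pd.DataFrame,
    min_cells_per_barcode: int = 12,
    min_reads_per_cell: int = 10,
    source_read_thresholds: tuple[int, int] = (10, 3),
) -> tuple[float, float]:
    """Bounds on the fraction of barcodes whose source cell was detected.

    Restricted to barcodes with at least ``min_reads_per_cell`` reads in at
    least one cell and present in at least ``min_cells_per_barcode`` cells;
    for each threshold X the fraction of such barcodes found in a source
    cell with at least X reads is computed. Returns the (conservative,
    permissive) pair in the order of ``source_read_thresholds`` — by default
    (X=10 lower bound, X=3 upper bound).

    ``roles`` maps cell_id to role ('source' marks source cells).
    """
    if min(source_read_thresholds) < 1 or min_reads_per_cell < 1:
        raise ValueError("thresholds must be positive")
    source_cells = set(roles.loc[roles["role"] == "source", "cell_id"])
    per_barcode = reads.groupby("barcode")
    qualifying = [
        barcode
        for barcode, g in per_barcode
        if g["count"].max() >= min_reads_per_cell
        and g["cell_id"].nunique() >= min_cells_per_barcode
    ]
    if not qualifying:
        raise ValueError("no barcodes qualify for source-detection estimation")
    fractions = []
    for x in source_read_thresholds:
        hit = 0
        for barcode in qualifying:
            g = per_barcode.get_group(barcode)
            in_source = g[(g["cell_id"].isin(source_cells)) & (g["count"] >= x)]
            if len(in_source):
                hit += 1
        fractions.append(hit / len(qualifying))
    return tuple(fractions)


def _freq_threshold_for_draws(n_draws: int, alpha: float) -> float:
    """Largest frequency f with P(X>=2 | X>=1) <= alpha for
    X ~ Binomial(n_draws, f); 1.0 when no constraint binds (n_draws = 1)."""

    def cond(f: float) -> float:
        p_ge1 = -np.expm1(n_draws * np.log1p(-f))
        if p_ge1 <= 0:
            return 0.0
        p_ge2 = float(stats.binom.sf(1, n_draws, f))
        return p_ge2 / p_ge1

    if cond(1.0 - 1e-12) <= alpha:
        return 1.0
    return float(optimize.brentq(lambda f: cond(f) - alpha, 1e-12, 1.0 - 1e-12))


def single_infection_threshold(
    library: BarcodeLibrary,
    n_observed_barcodes: int,
    confidence: float = 0.95,
    reps: int = 10000,
    seed: int | None = None,
    conditional: bool = True,
) -> tuple[float, int]:
    """Maximum library frequency that keeps barcodes single-infection.

    Per replicate, barcodes are drawn by library frequency until
    ``n_observed_barcodes`` distinct barcodes are obtained; the number of
    draws N_r and the largest f with P(X>=2 | X>=1) <= 1 - confidence for
    X ~ Binomial(N_r, f) are recorded. Returns (median frequency threshold,
    median estimated infection count). With ``conditional=False`` the
    unconditional form P(X>=2) <= 1 - confidence is used instead.
    """
    if n_observed_barcodes < 1:
        raise ValueError("n_observed_barcodes must be >= 1")
    if n_observed_barcodes > len(library):
        raise ValueError(
            f"library has only {len(library)} barcodes; cannot observe "
            f"{n_observed_barcodes} distinct"
        )
    rng = np.random.default_rng(seed)
    freq = np.asarray(library.frequencies, dtype=float)
    cum = np.cumsum(freq)
    cum[-1] = 1.0
    alpha = 1.0 - confidence

    n_draws = np.empty(reps, dtype=np.int64)
    block = max(16, int(n_observed_barcodes * 1.5))
    for r in range(reps):
        seen: set[int] = set()
        draws = 0
        while len(seen) < n_observed_barcodes:
            batch = np.searchsorted(cum, rng.random(block), side="right")
            for b in batch:
                draws += 1
                seen.add(int(b))
                if len(seen) == n_observed_barcodes:
                    break
        n_draws[r] = draws

    med_n = int(np.median(n_draws))
    thresholds = {}
    for n in np.unique(n_draws):
        if conditional:
            thresholds[int(n)] = _freq_threshold_for_draws(int(n), alpha)
        else:
            if int(n) < 2:
                thresholds[int(n)] = 1.0
            else:
                thresholds[int(n)] = float(
                    optimize.brentq(
                        lambda f, nn=int(n): stats.binom.sf(1, nn, f) - alpha,
                        1e-12,
                        1.0 - 1e-12,
                    )
                )
    med_f = float(np.median([thresholds[int(n)] for n in n_draws]))
    return med_f, med_n
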