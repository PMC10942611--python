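"""Multiplexed retrograde projection analysis.

Assigns projection targets from library-matched barcodes, cross-tabulates
projecting cells by area and subclass, computes per-cubelet projection
probabilities, and decomposes their variance into area / subclass / type
components with a shuffled-area control.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from barnet import library_tools
from barnet.library_tools import AMBIGUOUS, UNMATCHED, BarcodeLibrary


@dataclass
class CubeletMatrix:
    """Projection probabilities P[cubelet, type] with denominators; entries
    with zero denominator are NaN and excluded downstream."""

    cubelets: list[str]
    types: list[str]
    P: np.ndarray
    counts: np.ndarray
    n_projecting: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.cubelets):
            for j, t in enumerate(self.types):
                rows.append(
                    {
                        "cubelet_id": c,
                        "type": t,
                        "n": int(self.counts[i, j]),
                        "n_projecting": int(self.n_projecting[i, j]),
                        "P": float(self.P[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class VarianceDecomposition:
    grand_mean: float
    total_variance: float
    ve_area: float
    ve_subclass: float
    ve_type: float
    ve_type_area: float
    shuffled_ve: list[float] = field(default_factory=list)
    p_value: float = float("nan")
    p_value_ttest: float = float("nan")
    weighted: bool = False
    p_method: str = "permutation"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class FprEstimate:
    fp: int
    tn: int
    fpr: float
    upper_bound: float


def assign_projections(
    calls: pd.DataFrame,
    libraries: Sequence[BarcodeLibrary],
    site_map: Mapping[str, str],
    max_mismatch: int = 1,
    prefix_len: int = 15,
) -> pd.DataFrame:
    """Match each call's barcode to the injection libraries.

    Returns one row per (cell, barcode) with the matched injection-site
    target, or an empty target plus the reason (``unmatched`` or
    ``ambiguous``). A cell carrying barcodes from both libraries appears
    with both targets (dual-projecting).
    """
    for lib in libraries:
        if lib.library_id not in site_map:
            raise KeyError(f"site_map missing library {lib.library_id!r}")
    ids = [set(lib.barcodes) for lib in libraries]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if ids[i] & ids[j]:
                raise ValueError("libraries must be disjoint")
    cols = ["cell_id", "barcode", "target", "reason", "distance"]
    if not len(calls):
        return pd.DataFrame(columns=cols)
    matches = library_tools.match_many(
        calls["barcode"].tolist(), libraries, max_mismatch=max_mismatch,
        prefix_len=prefix_len,
    )
    dist_cols = [f"dist_{lib.library_id}" for lib in libraries]
    best_dist = matches[dist_cols].min(axis=1)
    assignment = matches["assignment"]
    target = assignment.map(lambda a: site_map.get(a, ""))
    reason = assignment.where(assignment.isin([UNMATCHED, AMBIGUOUS]), "")
    return pd.DataFrame(
        {
            "cell_id": calls["cell_id"].to_numpy(),
            "barcode": calls["barcode"].to_numpy(),
            "target": target.to_numpy(),
            "reason": reason.to_numpy(),
            "distance": best_dist.to_numpy(),
        }
    )


def targets_by_cell(assignments: pd.DataFrame) -> dict[str, set]:
    """Cell -> set of assigned injection-site targets."""
    ok = assignments[assignments["target"] != ""]
    return {c: set(g["target"]) for c, g in ok.groupby("cell_id")}


def projection_matrix(
    assignments: pd.DataFrame, cells: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-target area x subclass counts of projecting cells.

    Each cell counts once per target it projects to (dual-projecting cells
    appear in both targets' tables).
    """
    meta = cells.set_index("cell_id")[["area", "subclass"]]
    ok = assignments[assignments["target"] != ""]
    out: dict[str, pd.DataFrame] = {}
    for target, group in ok.groupby("target"):
        unique_cells = group["cell_id"].drop_duplicates()
        sub = meta.loc[meta.index.intersection(unique_cells)]
        out[str(target)] = pd.crosstab(sub["area"], sub["subclass"])
    return out


def assign_cubelets_by_position(
    cells: pd.DataFrame, width_um: float = 110.0
) -> pd.Series:
    """Bin cells into cubelets by slice and mediolateral position.

    Simulation helper standing in for the manually drawn cubelets of a real
    experiment: within each slice, cells are binned along x into strips of
    ``width_um``. Returns a cell_id-indexed Series of cubelet ids.
    """
    bins = (cells["x_um"] // width_um).astype(int)
    labels = cells["slice"].astype(str) + "_cb" + bins.astype(str)
    return pd.Series(labels.to_numpy(), index=cells["cell_id"].to_numpy())


def cubelet_probabilities(
    cells: pd.DataFrame,
    assignments: pd.DataFrame,
    cubelet_of_cell: Mapping[str, str] | pd.Series,
    target: str,
) -> CubeletMatrix:
    """P[cubelet, type] = fraction of type-t cells in cubelet c that project
    to ``target``; zero-denominator entries are NaN."""
    cubelet_of_cell = pd.Series(dict(cubelet_of_cell))
    missing = set(cells["cell_id"]) - set(cubelet_of_cell.index)
    if missing:
        raise KeyError(f"cells without cubelet label: {sorted(missing)[:5]}")
    df = cells[["cell_id", "type"]].copy()
    df["cubelet"] = df["cell_id"].map(cubelet_of_cell)
    projecting = {
        c for c, t in targets_by_cell(assignments).items() if target in t
    }
    df["projects"] = df["cell_id"].isin(projecting)
    cubelets = sorted(df["cubelet"].unique())
    types = sorted(df["type"].unique())
    counts = (
        df.pivot_table(index="cubelet", columns="type", values="cell_id",
                       aggfunc="count", fill_value=0)
        .reindex(index=cubelets, columns=types, fill_value=0)
        .to_numpy(dtype=np.int64)
    )
    n_proj = (
        df.pivot_table(index="cubelet", columns="type", values="projects",
                       aggfunc="sum", fill_value=0)
        .reindex(index=cubelets, columns=types, fill_value=0)
        .to_numpy(dtype=np.int64)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(counts > 0, n_proj / np.maximum(counts, 1), np.nan)
    return CubeletMatrix(
        cubelets=list(map(str, cubelets)),
        types=list(map(str, types)),
        P=P,
        counts=counts,
        n_projecting=n_proj,
    )


def _group_ve(
    P: np.ndarray,
    grand_mean: float,
    tv: float,
    groups: Sequence[np.ndarray],
    weighted: bool,
) -> float:
    """Sum over groups of (group mean - grand mean)^2 / TV; each group is a
    boolean mask over P's cells. Weighted mode multiplies each term by the
    group's defined-cell count (classical between-group sum of squares)."""
    total = 0.0
    for mask in groups:
        vals = P[mask]
        vals = vals[~np.isnan(vals)]
        if not len(vals):
            continue
        term = (vals.mean() - grand_mean) ** 2
        if weighted:
            term *= len(vals)
        total += term
    return total / tv


def variance_explained(
    P: CubeletMatrix | np.ndarray,
    area_of_cubelet: Sequence[str],
    subclass_of_type: Sequence[str],
    n_shuffles: int = 100,
    seed: int | None = None,
    weighted: bool = False,
    p_method: str = "permutation",
) -> VarianceDecomposition:
    """Decompose projection-probability variance over cubelets and types.

    With ``M`` the mean of all defined P entries and ``TV`` the sum of
    squared deviations from M, each component sums squared deviations of
    group means from M over the grouping's levels (areas; subclasses; types;
    type-by-area cells), divided by TV. The default follows the unweighted
    group-sum formulas; ``weighted=True`` switches to the classical one-way
    ANOVA between-group sum of squares. NaN entries (undefined
    probabilities) are excluded from all means.

    ``shuffled_ve`` holds ve_type_area recomputed after permuting area
    labels over cubelets ``n_shuffles`` times. ``p_value`` defaults to the
    calibrated two-tailed empirical permutation p-value (+1-corrected);
    ``p_method='ttest'`` instead uses the two-tailed one-sample t-test of
    the shuffled sample against the observed value, which is far more
    sensitive but anti-conservative under exchangeability. The t-test
    p-value is always reported in ``p_value_ttest``.
    """
    if p_method not in ("permutation", "ttest"):
        raise ValueError("p_method must be 'permutation' or 'ttest'")
    mat = P.P if isinstance(P, CubeletMatrix) else np.asarray(P, dtype=float)
    n_cub, n_typ = mat.shape
    if n_cub < 2 or n_typ < 2:
        raise ValueError("need at least 2 cubelets and 2 types")
    areas = np.asarray(area_of_cubelet)
    subclasses = np.asarray(subclass_of_type)
    if len(areas) != n_cub or len(subclasses) != n_typ:
        raise ValueError("label lengths do not match P")

    defined = ~np.isnan(mat)
    if not defined.any():
        raise ValueError("P has no defined entries")
    grand_mean = float(mat[defined].mean())
    tv = float(np.nansum((mat - grand_mean) ** 2))
    if tv == 0:
        raise ValueError("no variance to decompose")

    def area_groups(area_labels: np.ndarray) -> list[np.ndarray]:
        out = []
        for a in np.unique(area_labels):
            mask = np.zeros_like(mat, dtype=bool)
            mask[area_labels == a, :] = True
            out.append(mask)
        return out

    def type_area_groups(area_labels: np.ndarray) -> list[np.ndarray]:
        out = []
        for a in np.unique(area_labels):
            rows = area_labels == a
            for j in range(n_typ):
                mask = np.zeros_like(mat, dtype=bool)
                mask[rows, j] = True
                out.append(mask)
        return out

    subclass_groups = []
    for h in np.unique(subclasses):
        mask = np.zeros_like(mat, dtype=bool)
        mask[:, subclasses == h] = True
        subclass_groups.append(mask)
    type_groups = []
    for j in range(n_typ):
        mask = np.zeros_like(mat, dtype=bool)
        mask[:, j] = True
        type_groups.append(mask)

    ve_area = _group_ve(mat, grand_mean, tv, area_groups(areas), weighted)
    ve_subclass = _group_ve(mat, grand_mean, tv, subclass_groups, weighted)
    ve_type = _group_ve(mat, grand_mean, tv, type_groups, weighted)
    ve_type_area = _group_ve(mat, grand_mean, tv, type_area_groups(areas), weighted)

    rng = np.random.default_rng(seed)
    shuffled = []
    for _ in range(n_shuffles):
        perm = rng.permutation(areas)
        shuffled.append(
            _group_ve(mat, grand_mean, tv, type_area_groups(perm), weighted)
        )
    p_value = p_ttest = float("nan")
    if n_shuffles >= 2:
        p_ttest = float(stats.ttest_1samp(shuffled, ve_type_area).pvalue)
        arr = np.asarray(shuffled)
        ge = int((arr >= ve_type_area).sum())
        le = int((arr <= ve_type_area).sum())
        p_perm = min(1.0, 2.0 * (min(ge, le) + 1) / (n_shuffles + 1))
        p_value = p_perm if p_method == "permutation" else p_ttest
    return VarianceDecomposition(
        grand_mean=grand_mean,
        total_variance=tv,
        ve_area=ve_area,
        ve_subclass=ve_subclass,
        ve_type=ve_type,
        ve_type_area=ve_type_area,
        shuffled_ve=[float(v) for v in shuffled],
        p_value=p_value,
        p_value_ttest=p_ttest,
        weighted=weighted,
        p_method=p_method,
    )


def shuffled_area_test(
    P: CubeletMatrix | np.ndarray,
    area_of_cubelet: Sequence[str],
    subclass_of_type: Sequence[str],
    n_iter: int = 100,
    seed: int | None = None,
    weighted: bool = False,
    p_method: str = "permutation",
) -> float:
    """p-value of the observed type-by-area variance explained against
    ``n_iter`` shuffles of the cubelet area labels (two-tailed; see
    :func:`variance_explained` for the estimator choice)."""
    areas = np.asarray(area_of_cubelet)
    if len(np.unique(areas)) < 2:
        raise ValueError("need at least two distinct areas")
    dec = variance_explained(
        P,
        area_of_cubelet,
        subclass_of_type,
        n_shuffles=n_iter,
        seed=seed,
        weighted=weighted,
        p_method=p_method,
    )
    return dec.p_value


def fpr_upper_bound(fp: int, tn: int) -> FprEstimate:
    """False-positive-rate point estimate fp/(fp+tn) and the conservative
    upper bound (1+fp)/(fp+tn) used when no false positive was observed."""
    if fp < 0 or tn < 0:
        raise ValueError("fp and tn must be non-negative")
    if fp + tn == 0:
        raise ValueError("fp + tn must be positive")
    denom = fp + tn
    return FprEstimate(
        fp=fp, tn=tn, fpr=fp / denom, upper_bound=(1 + fp) / denom
    )
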