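"""Distance-based species delimitation: threshold optimisation, MOTU
partitioning, barcode-gap / nearest-neighbour diagnostics, and an
ABGD-style recursive barcode-gap partitioner.

The threshold machinery mirrors the classic barcoding identification
framework: for a query ``q`` and threshold ``t`` the match set is
``M(q, t) = {r != q : d(q, r) <= t}``. A query is a *true positive* when M
is non-empty and purely conspecific, a *false positive* when M contains any
heterospecific, a *false negative* when M is empty although conspecifics
exist in the data, and a *true negative* when M is empty and the query is a
singleton species. The cumulative error FP + FN is minimised over a
threshold grid; among equally good thresholds the smallest (most
conservative) is chosen.

Undefined (saturated) distances are treated as +infinity throughout: never
within any threshold, never a nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

__all__ = [
    "ThresholdScan",
    "MotuPartition",
    "AbgdConfig",
    "AbgdResult",
    "default_threshold_grid",
    "threshold_scan",
    "optimal_threshold",
    "thresh_id",
    "motus_from_threshold",
    "nearest_neighbour_check",
    "barcode_gap",
    "abgd_partition",
]

ID_OUTCOMES = ("correct", "incorrect", "ambiguous", "no_id")


def default_threshold_grid() -> np.ndarray:
    """0.05% to 5% in 0.05% steps (distance units)."""
    return np.round(np.arange(1, 101) * 0.0005, 6)


def _finite_values(D: DistanceMatrix) -> np.ndarray:
    """Distance matrix with undefined cells as +inf and self as +inf."""
    vals = np.where(np.isnan(D.values), np.inf, D.values)
    np.fill_diagonal(vals, np.inf)
    return vals


def _conspecific_matrix(D: DistanceMatrix, species_map: dict[str, str]) -> np.ndarray:
    sp = np.array([species_map[i] for i in D.ids])
    same = sp[:, None] == sp[None, :]
    np.fill_diagonal(same, False)
    return same


@dataclass(frozen=True)
class ThresholdScan:
    grid: np.ndarray
    table: pd.DataFrame  # columns: threshold, tp, tn, fp, fn, cumulative_error

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def threshold_scan(
    D: DistanceMatrix,
    species_map: dict[str, str],
    grid: np.ndarray | None = None,
) -> ThresholdScan:
    """TP/TN/FP/FN and cumulative error over an ascending threshold grid."""
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be non-empty and strictly ascending")
    vals = _finite_values(D)
    same = _conspecific_matrix(D, species_map)
    has_conspecific = same.any(axis=1)
    rows = []
    for t in grid:
        within = vals <= t
        any_match = within.any(axis=1)
        any_hetero = (within & ~same).any(axis=1)
        tp = int((any_match & ~any_hetero).sum())
        fp = int(any_hetero.sum())
        fn = int((~any_match & has_conspecific).sum())
        tn = int((~any_match & ~has_conspecific).sum())
        rows.append(
            {"threshold": t, "tp": tp, "tn": tn, "fp": fp, "fn": fn,
             "cumulative_error": fp + fn}
        )
    return ThresholdScan(grid=grid, table=pd.DataFrame(rows))


def optimal_threshold(scan: ThresholdScan) -> float:
    """Smallest threshold attaining the minimum cumulative error."""
    tab = scan.table
    best = tab["cumulative_error"].min()
    return float(tab.loc[tab["cumulative_error"] == best, "threshold"].iloc[0])


def thresh_id(
    D: DistanceMatrix, species_map: dict[str, str], t: float
) -> dict[str, str]:
    """Per-sequence identification outcome at threshold ``t``.

    ``correct``: all matches conspecific; ``incorrect``: matches exist but
    none conspecific; ``ambiguous``: mixed matches; ``no_id``: no matches.
    """
    if t < 0:
        raise ValueError("threshold must be >= 0")
    vals = _finite_values(D)
    same = _conspecific_matrix(D, species_map)
    out: dict[str, str] = {}
    for i, name in enumerate(D.ids):
        matches = vals[i] <= t
        if not matches.any():
            out[name] = "no_id"
        elif not (matches & ~same[i]).any():
            out[name] = "correct"
        elif not (matches & same[i]).any():
            out[name] = "incorrect"
        else:
            out[name] = "ambiguous"
    return out


@dataclass(frozen=True)
class MotuPartition:
    """Specimen -> MOTU index map (indices by first-specimen appearance)."""

    assignment: dict[str, int]

    @property
    def motu_count(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for name, m in self.assignment.items():
            out.setdefault(m, []).append(name)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.assignment), "motu": list(self.assignment.values())}
        )


def _components_to_partition(ids: list[str], labels: np.ndarray) -> MotuPartition:
    relabel: dict[int, int] = {}
    assignment = {}
    for name, lab in zip(ids, labels):
        lab = int(lab)
        if lab not in relabel:
            relabel[lab] = len(relabel)
        assignment[name] = relabel[lab]
    return MotuPartition(assignment)


def motus_from_threshold(D: DistanceMatrix, t: float) -> MotuPartition:
    """Single-linkage MOTUs: connected components of pairs with d <= t.

    Sequences without any match within ``t`` ("no ID") are necessarily
    singleton MOTUs.
    """
    vals = _finite_values(D)
    adj = csr_matrix(vals <= t)
    _, labels = connected_components(adj, directed=False)
    return _components_to_partition(D.ids, labels)


def nearest_neighbour_check(
    D: DistanceMatrix,
    species_map: dict[str, str],
    exclude_singletons: bool = True,
) -> tuple[dict[str, bool], float]:
    """Per-sequence "nearest neighbour is conspecific" check.

    Ties count as correct when any minimum-distance neighbour is
    conspecific. Singleton species are excluded by default (they cannot
    have a conspecific neighbour). Returns the per-sequence map and the
    fraction correct over the included sequences.
    """
    if len(D) < 2:
        raise ValueError("need >= 2 sequences")
    vals = _finite_values(D)
    same = _conspecific_matrix(D, species_map)
    result: dict[str, bool] = {}
    for i, name in enumerate(D.ids):
        if exclude_singletons and not same[i].any():
            continue
        row = vals[i]
        m = row.min()
        if np.isinf(m):
            result[name] = False
            continue
        ties = row == m
        result[name] = bool((ties & same[i]).any())
    frac = sum(result.values()) / len(result) if result else float("nan")
    return result, frac


def barcode_gap(D: DistanceMatrix, species_map: dict[str, str]) -> pd.DataFrame:
    """Per-specimen max intraspecific vs min interspecific distance.

    Singletons are excluded (no intraspecific distance exists). The gap
    exists for a specimen iff its smallest heterospecific distance exceeds
    its largest conspecific distance.
    """
    vals = _finite_values(D)
    same = _conspecific_matrix(D, species_map)
    rows = []
    for i, name in enumerate(D.ids):
        if not same[i].any():
            continue
        intra = vals[i][same[i]]
        mask = ~same[i]
        mask[i] = False
        inter = vals[i][mask]
        max_intra = float(intra.max())
        min_inter = float(inter.min()) if inter.size else float("inf")
        rows.append(
            {
                "id": name,
                "species": species_map[name],
                "max_intra": max_intra,
                "min_inter": min_inter,
                "gap_exists": bool(min_inter > max_intra),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ABGD-style recursive barcode-gap partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbgdConfig:
    """Priors and gap rule for recursive barcode-gap partitioning.

    ``priors`` defaults to 10 log-spaced prior maximum intraspecific
    divergences between 0.001 and 0.1. ``relative_gap_width`` (X) is the
    factor by which a candidate gap must exceed the local scale of the
    ranked-distance curve; the local scale is the mean of the preceding
    ``slope_window`` inter-rank gaps.
    """

    priors: tuple[float, ...] = tuple(np.geomspace(0.001, 0.1, 10).round(6))
    relative_gap_width: float = 0.8
    slope_window: int = 10
    min_rank: int = 1  # a candidate gap needs this many distances below it

    def __post_init__(self) -> None:
        if not all(0 < p < 1 for p in self.priors):
            raise ValueError("priors must be in (0, 1)")
        if self.relative_gap_width <= 0:
            raise ValueError("relative gap width must be > 0")


@dataclass(frozen=True)
class AbgdResult:
    partitions: dict[float, MotuPartition]

    def group_counts(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prior": list(self.partitions),
                "groups": [p.motu_count for p in self.partitions.values()],
            }
        )


def _gap_link_threshold(dists: np.ndarray, prior: float, cfg: AbgdConfig) -> float | None:
    """Largest distance below the first significant gap beyond the prior.

    Scans the ranked pairwise distances for the first interval whose width
    exceeds X times the mean of the preceding ``slope_window`` inter-rank
    gaps (the running local scale). Returns None when no such gap exists.
    """
    ds = np.sort(dists[np.isfinite(dists)])
    for i in range(cfg.min_rank, len(ds) - 1):
        if ds[i + 1] <= prior:
            # the distances above this interval are still within the prior
            # maximum intraspecific divergence - not a barcode gap
            continue
        gap = ds[i + 1] - ds[i]
        if gap <= 0:
            continue
        lo = max(0, i - cfg.slope_window)
        local = float(np.diff(ds[lo : i + 1]).mean()) if i > lo else 0.0
        if gap > cfg.relative_gap_width * local:
            return float(ds[i])
    return None


def _abgd_split(
    vals: np.ndarray, indices: np.ndarray, prior: float, cfg: AbgdConfig
) -> list[np.ndarray]:
    """Recursively split one group; returns leaf groups as index arrays."""
    if len(indices) < 3:
        return [indices]
    sub = vals[np.ix_(indices, indices)]
    iu = np.triu_indices(len(indices), k=1)
    link = _gap_link_threshold(sub[iu], prior, cfg)
    if link is None:
        return [indices]
    adj = csr_matrix(sub <= link)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp <= 1:
        return [indices]
    out: list[np.ndarray] = []
    for c in range(n_comp):
        out.extend(_abgd_split(vals, indices[labels == c], prior, cfg))
    return out


def abgd_partition(D: DistanceMatrix, cfg: AbgdConfig = AbgdConfig()) -> AbgdResult:
    """Recursive barcode-gap partition for each prior maximum divergence.

    For each prior P the ranked pairwise distances are searched for the
    first significant gap beyond P; sequences linked by distances below the
    gap form groups, and the procedure recurses within groups until stable.
    Degenerate inputs (no significant gap) yield a single group.
    """
    vals = np.where(np.isnan(D.values), np.inf, D.values)
    np.fill_diagonal(vals, 0.0)
    n = len(D)
    partitions: dict[float, MotuPartition] = {}
    for prior in cfg.priors:
        groups = _abgd_split(vals, np.arange(n), prior, cfg)
        labels = np.empty(n, dtype=int)
        for g, idx in enumerate(groups):
            labels[idx] = g
        partitions[float(prior)] = _components_to_partition(D.ids, labels)
    return AbgdResult(partitions)
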