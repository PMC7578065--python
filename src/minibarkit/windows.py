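"""Sliding-window screening for informative mini-barcode regions.

The screen slides fixed-width windows (default 70 bp, stepped 10 bp) along
the alignment and scores each on four criteria:

1. ``mean_dist`` — mean pairwise K2P distance over defined pairs (higher is
   better: more signal);
2. ``zero_noncon`` — proportion of heterospecific pairs with distance zero
   (lower is better: fewer indistinguishable species pairs);
3. ``congruence`` — proportion of the window NJ tree's nontrivial clades
   also found in the full-length reference NJ tree (higher is better);
4. ``diag_sum`` — total count of species-diagnostic nucleotide positions
   inside the window (higher is better).

Windows are ranked per criterion and combined by rank-sum, a scale-free
aggregate of "best indices of all criteria"; ties go to the earlier start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, Model, encode_alignment, matrix_from_codes
from .seq_io import AlignedSeqSet, AlignmentError, RegionCoords
from .trees import neighbor_joining, shared_clade_proportion

__all__ = [
    "SwanConfig",
    "WindowMetrics",
    "diagnostic_nucleotides",
    "slide_analyze",
    "rank_windows",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SwanConfig:
    width: int = 70
    step: int = 10
    model: Model = "k2p"
    keep_partial: bool = False  # keep the incomplete terminal window
    congruence_denominator: str = "first"  # window tree's clade count


@dataclass(frozen=True)
class WindowMetrics:
    start: int  # 1-based first column
    end: int  # 1-based last column
    mean_dist: float
    zero_noncon: float
    congruence: float
    diag_sum: int


def diagnostic_nucleotides(aln: AlignedSeqSet) -> dict[str, list[int]]:
    """Per-species list of diagnostic columns (1-based).

    Column ``j`` is diagnostic for species ``s`` iff every ``s`` specimen
    carries the same unambiguous base at ``j`` (a gap or ambiguity code in
    ``s`` disqualifies) and no specimen of any other species carries that
    base at ``j`` (gaps/ambiguities in other species never match a base).
    """
    species = sorted(set(aln.species))
    if len(species) < 2:
        raise AlignmentError("diagnostic nucleotides need >= 2 species")
    members = {sp: [i for i, r in enumerate(aln) if r.species == sp] for sp in species}
    result: dict[str, list[int]] = {sp: [] for sp in species}
    for col in range(1, aln.length + 1):
        column = aln.column(col)
        for sp in species:
            states = {column[i] for i in members[sp]}
            if len(states) != 1:
                continue
            base = next(iter(states))
            if base not in _BASES:
                continue
            others = (
                column[i]
                for other, idx in members.items()
                if other != sp
                for i in idx
            )
            if base not in others:
                result[sp].append(col)
    return result


def _window_starts(length: int, cfg: SwanConfig) -> list[int]:
    if cfg.width > length:
        raise AlignmentError(f"window width {cfg.width} exceeds alignment length {length}")
    starts = list(range(1, length - cfg.width + 2, cfg.step))
    if cfg.keep_partial:
        last_covered = starts[-1] + cfg.width - 1 if starts else 0
        nxt = (starts[-1] + cfg.step) if starts else 1
        if last_covered < length and nxt <= length:
            starts.append(nxt)
    return starts


def _heterospecific_zero_fraction(D: DistanceMatrix, species: list[str]) -> float:
    vals = D.values
    n = len(species)
    zero = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            if species[i] == species[j]:
                continue
            v = vals[i, j]
            if np.isnan(v):
                continue
            total += 1
            if v == 0.0:
                zero += 1
    return zero / total if total else 0.0


def slide_analyze(
    aln: AlignedSeqSet,
    reference_tree=None,
    cfg: SwanConfig = SwanConfig(),
) -> list[WindowMetrics]:
    """Score every window of ``cfg.width`` stepped by ``cfg.step``.

    ``reference_tree`` defaults to the NJ tree of the full alignment.
    Windows whose distance matrix is entirely undefined (no comparable
    sites) get ``congruence`` 0 and ``mean_dist`` NaN.
    """
    codes = encode_alignment(aln)
    species = aln.species
    if reference_tree is None:
        reference_tree = neighbor_joining(matrix_from_codes(codes, aln.ids, cfg.model))
    diag = diagnostic_nucleotides(aln)
    diag_cols = sorted(col for cols in diag.values() for col in cols)
    diag_arr = np.array(diag_cols, dtype=int) if diag_cols else np.empty(0, dtype=int)

    out: list[WindowMetrics] = []
    for start in _window_starts(aln.length, cfg):
        end = min(start + cfg.width - 1, aln.length)
        window_codes = codes[:, start - 1 : end]
        D = matrix_from_codes(window_codes, aln.ids, cfg.model)
        defined = D.values[np.triu_indices(len(D), k=1)]
        defined = defined[~np.isnan(defined)]
        mean_dist = float(defined.mean()) if defined.size else float("nan")
        zero_noncon = _heterospecific_zero_fraction(D, species)
        if defined.size == 0:
            congruence = 0.0
        else:
            window_tree = neighbor_joining(D)
            congruence = shared_clade_proportion(
                window_tree, reference_tree, denominator=cfg.congruence_denominator
            )
        diag_sum = int(((diag_arr >= start) & (diag_arr <= end)).sum())
        out.append(
            WindowMetrics(
                start=start,
                end=end,
                mean_dist=mean_dist,
                zero_noncon=zero_noncon,
                congruence=congruence,
                diag_sum=diag_sum,
            )
        )
    return out


def rank_windows(metrics: list[WindowMetrics]) -> pd.DataFrame:
    """Rank windows on all four criteria by rank-sum, best first.

    Per criterion ranks (1 = best): ``mean_dist``, ``congruence`` and
    ``diag_sum`` descending, ``zero_noncon`` ascending; ties receive the
    average rank. Ties in the combined rank-sum go to the earlier start.
    """
    if not metrics:
        raise ValueError("no window metrics to rank")
    df = pd.DataFrame([m.__dict__ for m in metrics])
    df["rank_mean_dist"] = df["mean_dist"].rank(ascending=False, na_option="bottom")
    df["rank_zero_noncon"] = df["zero_noncon"].rank(ascending=True)
    df["rank_congruence"] = df["congruence"].rank(ascending=False)
    df["rank_diag_sum"] = df["diag_sum"].rank(ascending=False)
    df["rank_sum"] = (
        df["rank_mean_dist"]
        + df["rank_zero_noncon"]
        + df["rank_congruence"]
        + df["rank_diag_sum"]
    )
    return df.sort_values(["rank_sum", "start"], kind="stable").reset_index(drop=True)


def best_region(metrics: list[WindowMetrics]) -> RegionCoords:
    """Coordinates of the top-ranked window."""
    top = rank_windows(metrics).iloc[0]
    return RegionCoords(int(top["start"]), int(top["end"]))
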