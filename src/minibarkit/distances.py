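"""Pairwise genetic distances and rank-stratified divergence summaries.

Distances are computed with *pairwise deletion*: each pair of sequences is
compared only over sites where both carry an unambiguous base (A/C/G/T);
gaps and IUPAC ambiguity codes are excluded from the comparison. Two models
are provided:

* ``p`` — the raw mismatch proportion over compared sites;
* ``k2p`` — the Kimura two-parameter distance
  ``d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))``, with ``P`` and ``Q`` the
  transition and transversion proportions. When a log argument is
  non-positive the pair is *saturated* and the distance is undefined; such
  cells are stored as ``NaN``, reported as undefined, and treated as
  "infinitely divergent" by downstream delimitation.

Percent summaries are stratified by taxonomic rank: intraspecific (same
species), intrageneric (same genus, different species), intrafamilial (same
family, different genus) and interspecific (all heterospecific pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .seq_io import AlignedSeqSet, AlignmentError

__all__ = [
    "k2p_distance",
    "p_distance",
    "distance_matrix",
    "encode_alignment",
    "matrix_from_codes",
    "divergence_summary",
    "DistanceMatrix",
    "DivergenceSummary",
    "RankClassStats",
]

_UNAMBIGUOUS = frozenset("ACGT")
_PURINES = frozenset("AG")


def _site_counts(seq_a: str, seq_b: str) -> tuple[int, int, int]:
    """(compared sites, transitions, transversions) under pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    n = ts = tv = 0
    for a, b in zip(seq_a, seq_b):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS:
            continue
        n += 1
        if a != b:
            if (a in _PURINES) == (b in _PURINES):
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance; ``NaN`` when saturated or no sites."""
    n, ts, tv = _site_counts(seq_a, seq_b)
    if n == 0:
        return math.nan
    p, q = ts / n, tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(seq_a: str, seq_b: str) -> float:
    """Mismatch proportion over pairwise-deleted sites; ``NaN`` if none."""
    n, ts, tv = _site_counts(seq_a, seq_b)
    if n == 0:
        return math.nan
    return (ts + tv) / n


_MODEL_FN = {"k2p": k2p_distance, "p": p_distance}

Model = Literal["k2p", "p"]


class DistanceMatrix:
    """Symmetric pairwise distance matrix with undefined cells as ``NaN``."""

    def __init__(self, ids: list[str], values: np.ndarray, model: str):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} ids")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(values) < -1e-12:
                raise ValueError("distances must be non-negative")
        self.ids = list(ids)
        self.values = values
        self.model = model
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def offdiag_pairs(self) -> list[tuple[int, int]]:
        n = len(self.ids)
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def submatrix(self, indices: list[int]) -> "DistanceMatrix":
        idx = np.asarray(indices, dtype=int)
        return DistanceMatrix(
            [self.ids[i] for i in indices], self.values[np.ix_(idx, idx)], self.model
        )

    def filled(self, fill: float | None = None) -> np.ndarray:
        """Copy with undefined cells replaced (default: matrix max defined)."""
        out = self.values.copy()
        nan = np.isnan(out)
        if nan.any():
            if fill is None:
                defined = out[~nan]
                fill = float(defined.max()) if defined.size else 0.0
            out[nan] = fill
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        """Square-matrix TSV: ids as header row and first column; NaN blank."""
        self.to_frame().to_csv(path, sep="\t", na_rep="")

    def to_phylip(self, path: str | Path) -> None:
        """Relaxed PHYLIP square distance matrix (undefined written as -1)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for name, row in zip(self.ids, self.values):
                cells = " ".join(
                    "-1.000000" if math.isnan(v) else f"{v:.6f}" for v in row
                )
                fh.write(f"{name}  {cells}\n")


# Base encoding for the vectorized all-pairs path: A,C,G,T -> 0..3, anything
# else (gaps, ambiguity codes) -> 4 and excluded by pairwise deletion.
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i


def encode_alignment(aln: AlignedSeqSet) -> np.ndarray:
    """Encode residues as a (records x columns) uint8 code matrix."""
    rows = [np.frombuffer(r.residues.encode("ascii"), dtype=np.uint8) for r in aln]
    return _CODE_LUT[np.vstack(rows)]


def _pair_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair (compared sites, transitions, transversions) via matmuls."""
    masks = [(codes == b).astype(np.float32) for b in range(4)]
    valid = (codes < 4).astype(np.float32)
    n_sites = valid @ valid.T
    same = sum(m @ m.T for m in masks)
    ts = (
        masks[0] @ masks[2].T
        + masks[2] @ masks[0].T  # A<->G
        + masks[1] @ masks[3].T
        + masks[3] @ masks[1].T  # C<->T
    )
    tv = n_sites - same - ts
    return (
        np.rint(n_sites).astype(np.int64),
        np.rint(ts).astype(np.int64),
        np.rint(tv).astype(np.int64),
    )


def matrix_from_codes(codes: np.ndarray, ids: list[str], model: Model) -> DistanceMatrix:
    """Distance matrix from an encoded alignment (see :func:`encode_alignment`)."""
    n_sites, ts, tv = _pair_counts(codes)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = ts / n_sites
        q = tv / n_sites
        if model == "p":
            values = p + q
        else:
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            values = -0.5 * np.log(w1 * np.sqrt(np.where(w2 > 0, w2, np.nan)))
            values[(w1 <= 0) | (w2 <= 0)] = np.nan
    values[n_sites == 0] = np.nan
    np.fill_diagonal(values, 0.0)
    values = np.where(np.isnan(values), np.nan, np.maximum(values, 0.0))
    return DistanceMatrix(ids, values, model)


def distance_matrix(aln: AlignedSeqSet, model: Model = "k2p") -> DistanceMatrix:
    """All-pairs distance matrix under ``model`` with pairwise deletion.

    Equivalent to calling :func:`k2p_distance` / :func:`p_distance` on every
    unordered pair (the property suite checks this), but vectorized.
    """
    if len(aln) < 2:
        raise AlignmentError("need at least 2 records for a distance matrix")
    return matrix_from_codes(encode_alignment(aln), aln.ids, model)


@dataclass(frozen=True)
class RankClassStats:
    """Min/mean/max (percent) over the defined pairs of one rank class."""

    n_pairs: int
    min_pct: float | None
    mean_pct: float | None
    max_pct: float | None
    min_pair: tuple[str, str] | None
    max_pair: tuple[str, str] | None

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


@dataclass(frozen=True)
class DivergenceSummary:
    intraspecific: RankClassStats
    intrageneric: RankClassStats
    intrafamilial: RankClassStats
    interspecific: RankClassStats

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("intraspecific", "intrageneric", "intrafamilial", "interspecific"):
            s: RankClassStats = getattr(self, name)
            rows.append(
                {
                    "class": name,
                    "n_pairs": s.n_pairs,
                    "min_pct": None if s.empty else round(s.min_pct, 2),
                    "mean_pct": None if s.empty else round(s.mean_pct, 2),
                    "max_pct": None if s.empty else round(s.max_pct, 2),
                    "min_pair": "" if s.min_pair is None else "|".join(s.min_pair),
                    "max_pair": "" if s.max_pair is None else "|".join(s.max_pair),
                }
            )
        return pd.DataFrame(rows)


def _class_of(rec_a, rec_b) -> list[str]:
    classes = []
    if rec_a.species == rec_b.species:
        classes.append("intraspecific")
    else:
        classes.append("interspecific")
        if rec_a.genus and rec_a.genus == rec_b.genus:
            classes.append("intrageneric")
        elif rec_a.family and rec_a.family == rec_b.family:
            classes.append("intrafamilial")
    return classes


def divergence_summary(D: DistanceMatrix, aln: AlignedSeqSet) -> DivergenceSummary:
    """Rank-stratified divergence statistics in percent.

    ``interspecific`` covers *all* heterospecific pairs (the intrageneric and
    intrafamilial classes are subsets reported separately); means are simple
    averages over defined pairwise entries. A class with no defined pairs is
    reported as empty, not zero.
    """
    recs = {r.id: r for r in aln}
    buckets: dict[str, list[tuple[float, str, str]]] = {
        "intraspecific": [],
        "intrageneric": [],
        "intrafamilial": [],
        "interspecific": [],
    }
    for i, j in D.offdiag_pairs():
        v = D.values[i, j]
        if math.isnan(v):
            continue
        a, b = D.ids[i], D.ids[j]
        for cls in _class_of(recs[a], recs[b]):
            buckets[cls].append((v, a, b))

    def stats(entries: list[tuple[float, str, str]]) -> RankClassStats:
        if not entries:
            return RankClassStats(0, None, None, None, None, None)
        vals = np.array([e[0] for e in entries])
        lo, hi = entries[int(vals.argmin())], entries[int(vals.argmax())]
        return RankClassStats(
            n_pairs=len(entries),
            min_pct=float(vals.min()) * 100.0,
            mean_pct=float(vals.mean()) * 100.0,
            max_pct=float(vals.max()) * 100.0,
            min_pair=(lo[1], lo[2]),
            max_pair=(hi[1], hi[2]),
        )

    return DivergenceSummary(**{k: stats(v) for k, v in buckets.items()})
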