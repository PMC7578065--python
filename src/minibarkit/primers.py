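"""Primer-site profiling, primer-pair enumeration, mapping, and in-silico PCR.

Candidate primers are drawn from the consensus of conserved alignment
windows (low per-sequence mismatch counts) and filtered on GC content
(default 20-80%) and melting temperature (default 57-63 C, salt-adjusted
Wallace formula). Pairs are emitted when the amplicon - measured inclusive
of both primer footprints - stays under the configured maximum (default
250 bp, the degraded-DNA/eDNA regime).

In-silico PCR scans unaligned templates on both strands under a
Primer-BLAST-style stringency: a primer site *binds* unless it has both at
least ``max_mismatch`` total mismatches and at least
``three_prime_max_mismatch`` mismatches within the 3'-terminal window
(default: 3 total / 3 in the last 5 bp), i.e. only doubly-poor sites are
rejected. Products longer than ``max_product_bp`` (default 400) are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seq_io import AlignedSeqSet

__all__ = [
    "PrimerCandidate",
    "PrimerConstraints",
    "PcrConfig",
    "AmpliconHit",
    "PrimerSite",
    "column_mismatch_profile",
    "gc_content",
    "melting_temperature",
    "consensus_sequence",
    "enumerate_primer_pairs",
    "insilico_pcr",
    "primer_map",
    "reverse_complement",
]

#: Sentinel written into the mismatch profile for columns containing a gap.
GAP_SENTINEL = 10

_IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """G+C fraction; rejects ambiguity codes and gaps."""
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad or not seq:
        raise ValueError(f"gc_content needs unambiguous bases, got {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str) -> float:
    """Salt-adjusted Wallace/Marmur Tm: ``64.9 + 41*(GC - 16.4)/N`` (C)."""
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad or not seq:
        raise ValueError(f"melting_temperature needs unambiguous bases, got {sorted(bad)}")
    gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def column_mismatch_profile(aln: AlignedSeqSet) -> np.ndarray:
    """Per-column count of sequences differing from the majority base.

    The consensus base is the most frequent of A/C/G/T (ties: lexicographic
    smallest); every other symbol, including ``N`` and ambiguity codes,
    counts as a mismatch. Columns containing any gap are flagged with the
    sentinel value ``10``.
    """
    profile = np.zeros(aln.length, dtype=int)
    for col in range(1, aln.length + 1):
        column = aln.column(col)
        if "-" in column:
            profile[col - 1] = GAP_SENTINEL
            continue
        counts = {b: column.count(b) for b in "ACGT"}
        best = max(sorted(counts), key=lambda b: counts[b])
        profile[col - 1] = len(column) - counts[best]
    return profile


def consensus_sequence(aln: AlignedSeqSet) -> str:
    """Majority-base consensus (ties lexicographic; no A/C/G/T at all -> N)."""
    out = []
    for col in range(1, aln.length + 1):
        column = aln.column(col)
        counts = {b: column.count(b) for b in "ACGT"}
        if max(counts.values()) == 0:
            out.append("N")
        else:
            out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


@dataclass(frozen=True)
class PrimerCandidate:
    """A primer with its footprint on the alignment/template forward frame.

    ``sequence`` is always written 5'->3' on the primer's own strand; a
    reverse primer therefore maps onto the forward strand via its reverse
    complement at columns ``start..end`` (1-based inclusive).
    """

    sequence: str
    strand: str  # "forward" | "reverse"
    start: int
    end: int
    gc_frac: float
    tm_celsius: float
    total_mismatches: int = 0
    max_mismatch_per_seq: int = 0

    def __post_init__(self) -> None:
        if not 15 <= len(self.sequence) <= 30:
            raise ValueError(f"primer length {len(self.sequence)} outside 15..30")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class PrimerConstraints:
    max_amplicon_bp: int = 250
    gc_range: tuple[float, float] = (0.20, 0.80)
    tm_range: tuple[float, float] = (57.0, 63.0)
    max_mismatch_per_seq: int = 0
    length_range: tuple[int, int] = (18, 24)


def _conserved_windows(
    aln: AlignedSeqSet, constraints: PrimerConstraints
) -> list[tuple[int, int, str, int, int]]:
    """(start, end, consensus, total_mm, max_per_seq_mm) for passing windows."""
    cons = consensus_sequence(aln)
    n = len(aln)
    # per-sequence per-column mismatch-vs-consensus indicator
    mm = np.zeros((n, aln.length), dtype=np.int32)
    gap_col = np.zeros(aln.length, dtype=bool)
    for j in range(aln.length):
        column = aln.column(j + 1)
        if "-" in column or cons[j] == "N":
            gap_col[j] = True
        for i, c in enumerate(column):
            if c != cons[j]:
                mm[i, j] = 1
    csum = np.cumsum(np.pad(mm, ((0, 0), (1, 0))), axis=1)
    gsum = np.cumsum(np.pad(gap_col.astype(int), (1, 0)))

    windows = []
    lo, hi = constraints.length_range
    for length in range(lo, hi + 1):
        for start0 in range(aln.length - length + 1):
            end0 = start0 + length
            if gsum[end0] - gsum[start0] > 0:
                continue
            per_seq = csum[:, end0] - csum[:, start0]
            worst = int(per_seq.max())
            if worst > constraints.max_mismatch_per_seq:
                continue
            windows.append(
                (start0 + 1, end0, cons[start0:end0], int(per_seq.sum()), worst)
            )
    return windows


def enumerate_primer_pairs(
    aln: AlignedSeqSet, constraints: PrimerConstraints = PrimerConstraints()
) -> list[tuple[PrimerCandidate, PrimerCandidate, int]]:
    """Enumerate (forward, reverse, amplicon length) over conserved windows.

    Candidates are window consensi whose per-sequence mismatch count never
    exceeds ``max_mismatch_per_seq`` and whose GC/Tm fall in the configured
    bands; pairs whose footprint-inclusive amplicon fits in
    ``max_amplicon_bp`` are returned sorted by (total mismatches, amplicon
    length, start). An empty list (no conserved runs) is a valid result.
    """
    sites = []
    for start, end, cons, total_mm, worst in _conserved_windows(aln, constraints):
        gc = gc_content(cons)
        tm = melting_temperature(cons)
        if not (constraints.gc_range[0] <= gc <= constraints.gc_range[1]):
            continue
        if not (constraints.tm_range[0] <= tm <= constraints.tm_range[1]):
            continue
        sites.append((start, end, cons, gc, tm, total_mm, worst))

    pairs: list[tuple[PrimerCandidate, PrimerCandidate, int]] = []
    for fs, fe, fcons, fgc, ftm, fmm, fworst in sites:
        for rs, re, rcons, rgc, rtm, rmm, rworst in sites:
            if rs <= fe:
                continue
            amplicon = re - fs + 1
            if amplicon > constraints.max_amplicon_bp:
                continue
            fwd = PrimerCandidate(
                sequence=fcons, strand="forward", start=fs, end=fe,
                gc_frac=fgc, tm_celsius=ftm,
                total_mismatches=fmm, max_mismatch_per_seq=fworst,
            )
            rev = PrimerCandidate(
                sequence=reverse_complement(rcons), strand="reverse",
                start=rs, end=re, gc_frac=rgc, tm_celsius=rtm,
                total_mismatches=rmm, max_mismatch_per_seq=rworst,
            )
            pairs.append((fwd, rev, amplicon))
    pairs.sort(key=lambda p: (p[0].total_mismatches + p[1].total_mismatches, p[2], p[0].start))
    return pairs


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcrConfig:
    """Stringency for in-silico PCR site binding.

    ``binding_rule="lenient"`` (default) treats a template site as
    amplifiable unless it reaches *both* stringency bounds (>= max_mismatch
    total AND >= three_prime_max_mismatch in the 3' window) - the
    unintended-target exclusion rule inverted for intended targets.
    ``"strict"`` requires a site to beat both bounds to bind.
    """

    max_mismatch: int = 3
    three_prime_window: int = 5
    three_prime_max_mismatch: int = 3
    max_product_bp: int = 400
    binding_rule: str = "lenient"

    def __post_init__(self) -> None:
        if self.binding_rule not in ("lenient", "strict"):
            raise ValueError(f"unknown binding rule {self.binding_rule!r}")


@dataclass(frozen=True)
class PrimerSite:
    start: int  # 1-based on the template forward strand
    end: int
    strand: str  # "+" | "-"
    mismatches: int
    three_prime_mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    template_id: str
    start: int
    end: int
    length: int
    fwd_site: PrimerSite
    rev_site: PrimerSite
    orientation: str  # "fwd+/rev-" or "rev+/fwd-"

    def __post_init__(self) -> None:
        if self.length != self.end - self.start + 1:
            raise ValueError("inconsistent amplicon length")


def _matches(primer_base: str, template_base: str) -> bool:
    return primer_base in _IUPAC.get(template_base, frozenset())


def _site_mismatches(primer: str, segment: str, minus: bool) -> tuple[int, list[int]]:
    """Total mismatches and their primer-coordinate positions (0-based, 5'->3')."""
    if minus:
        segment = reverse_complement(segment)
    positions = [
        k for k, (p, t) in enumerate(zip(primer, segment)) if not _matches(p, t)
    ]
    return len(positions), positions


def _scan_sites(primer: str, template: str, strand: str, cfg: PcrConfig) -> list[PrimerSite]:
    """All binding sites of a primer on one strand, per the stringency rule."""
    L = len(primer)
    sites = []
    for i in range(len(template) - L + 1):
        segment = template[i : i + L]
        total, positions = _site_mismatches(primer, segment, minus=(strand == "-"))
        three = sum(1 for k in positions if k >= L - cfg.three_prime_window)
        if cfg.binding_rule == "lenient":
            if total >= cfg.max_mismatch and three >= cfg.three_prime_max_mismatch:
                continue  # doubly poor site: rejected
        else:
            if total >= cfg.max_mismatch or three >= cfg.three_prime_max_mismatch:
                continue
        sites.append(PrimerSite(i + 1, i + L, strand, total, three))
    return sites


def insilico_pcr(
    fwd: PrimerCandidate | str,
    rev: PrimerCandidate | str,
    templates: Mapping[str, str] | Iterable[tuple[str, str]],
    cfg: PcrConfig = PcrConfig(),
) -> list[AmpliconHit]:
    """Predict amplification products of a primer pair on plain templates.

    Both strands are scanned for both primers; every convergent site pair
    (plus-strand site upstream of a minus-strand site) with product length
    at most ``cfg.max_product_bp`` is reported. Zero hits is a valid result.
    """
    fseq = fwd.sequence if isinstance(fwd, PrimerCandidate) else fwd.upper()
    rseq = rev.sequence if isinstance(rev, PrimerCandidate) else rev.upper()
    items = templates.items() if isinstance(templates, Mapping) else templates
    hits: list[AmpliconHit] = []
    for tid, tmpl in items:
        tmpl = tmpl.upper().replace("U", "T")
        combos = [
            (fseq, rseq, "fwd+/rev-"),
            (rseq, fseq, "rev+/fwd-"),
        ]
        for plus_primer, minus_primer, orientation in combos:
            plus_sites = _scan_sites(plus_primer, tmpl, "+", cfg)
            minus_sites = _scan_sites(minus_primer, tmpl, "-", cfg)
            for ps in plus_sites:
                for ms in minus_sites:
                    if ms.start <= ps.end:
                        continue
                    length = ms.end - ps.start + 1
                    if length > cfg.max_product_bp:
                        continue
                    fwd_site, rev_site = (ps, ms) if orientation == "fwd+/rev-" else (ms, ps)
                    hits.append(
                        AmpliconHit(
                            template_id=tid,
                            start=ps.start,
                            end=ms.end,
                            length=length,
                            fwd_site=fwd_site,
                            rev_site=rev_site,
                            orientation=orientation,
                        )
                    )
    return hits


# ---------------------------------------------------------------------------
# primer mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerMapResult:
    sites: dict  # (set_name, role) -> PrimerSite (best per primer)
    amplicons: dict  # set_name -> (start, end)
    overlaps: list  # (set_a, set_b, overlap_bp)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "set": name, "role": role, "start": s.start, "end": s.end,
                "strand": s.strand, "mismatches": s.mismatches,
            }
            for (name, role), s in self.sites.items()
        ]
        return pd.DataFrame(rows)


def _best_site(primer: str, template: str, strand: str) -> PrimerSite | None:
    """Lowest-mismatch site on one strand (ties: leftmost); no stringency cut."""
    permissive = PcrConfig(max_mismatch=10**9, three_prime_max_mismatch=10**9)
    sites = _scan_sites(primer, template, strand, permissive)
    if not sites:
        return None
    return min(sites, key=lambda s: (s.mismatches, s.start))


def primer_map(
    template: str, primer_sets: Mapping[str, tuple[str, str]]
) -> PrimerMapResult:
    """Best annealing site per primer on a template and inter-set overlaps.

    Forward primers are mapped on the plus strand, reverse primers on the
    minus strand; each amplicon spans the forward site start to the reverse
    site end. Overlaps between amplicons of different sets are reported in
    bp (0 rows when disjoint).
    """
    template = template.upper().replace("U", "T")
    sites: dict[tuple[str, str], PrimerSite] = {}
    amplicons: dict[str, tuple[int, int]] = {}
    for name, (fseq, rseq) in primer_sets.items():
        fsite = _best_site(fseq.upper(), template, "+")
        rsite = _best_site(rseq.upper(), template, "-")
        if fsite is not None:
            sites[(name, "forward")] = fsite
        if rsite is not None:
            sites[(name, "reverse")] = rsite
        if fsite is not None and rsite is not None and rsite.end > fsite.start:
            amplicons[name] = (fsite.start, rsite.end)
    overlaps = []
    names = sorted(amplicons)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, ea = amplicons[a]
            sb, eb = amplicons[b]
            ov = min(ea, eb) - max(sa, sb) + 1
            if ov > 0:
                overlaps.append((a, b, ov))
    return PrimerMapResult(sites=sites, amplicons=amplicons, overlaps=overlaps)
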