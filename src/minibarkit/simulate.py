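"""Synthetic taxonomy-labelled alignments with known divergence structure.

The generator emulates the shape of a curated single-marker reference
library: a few dozen species with 1-3 specimens each, small intraspecific
divergence, much larger interspecific divergence, conserved primer-flank
blocks bracketing a variable core, occasional short alignment gaps, ragged
ambiguous ends, and singleton species. Defaults mirror a 132-specimen /
67-species / 19-singleton library over a 565 bp marker.

Sequences evolve along a random ultrametric species tree under the
two-rate Kimura model (transitions at rate ``kappa`` relative to each
transversion) - the same model the distance stage assumes, so parameter
recovery is a clean end-to-end test. Every stochastic choice flows from
``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .seq_io import AlignedSeqSet, RegionCoords, SeqRecord, write_alignment, write_taxonomy
from .distances import distance_matrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_species_tree",
    "evolve_alignment",
    "make_fixture",
]

_BASES = "ACGT"
_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TV_FIRST = np.array([1, 0, 1, 0])  # A->C, C->A, G->C, T->A
_TV_SECOND = np.array([3, 2, 3, 2])  # A->T, C->G, G->T, T->G


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic reference library."""

    seed: int
    n_species: int = 67
    n_singletons: int = 19
    total_specimens: int | None = 132
    specimens_range: tuple[int, int] = (1, 3)
    seq_length: int = 565
    target_intra: float = 0.004  # max expected intraspecific distance
    target_inter: float = 0.02  # min expected interspecific distance
    inter_depth_max: float = 0.08  # deepest split (path length up to ~2x this)
    kappa: float = 2.0
    #: None -> two 20 bp flanks bracketing a variable core in the second
    #: half of the marker (columns 321-340 and 481-500 at the default 565 bp)
    conserved_blocks: tuple[RegionCoords, ...] | None = None
    indels_per_specimen: float = 0.5  # Poisson mean; lengths 1-3 columns
    end_pad: int = 0  # ragged N-padded columns added at each end

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not 0 <= self.n_singletons <= self.n_species:
            raise ValueError("n_singletons must be within n_species")
        if self.target_intra >= self.target_inter:
            raise ValueError("target_intra must be below target_inter")
        if self.target_inter >= 0.7:
            raise ValueError("target_inter too large: distances would saturate")
        if self.conserved_blocks is None:
            # scale the default flank placement (321-340 / 481-500 at 565 bp)
            s1 = max(1, int(round(self.seq_length * 321 / 565)))
            s2 = max(s1 + 40, int(round(self.seq_length * 481 / 565)))
            if s2 + 19 > self.seq_length:
                raise ValueError("seq_length too short for default conserved blocks")
            object.__setattr__(
                self,
                "conserved_blocks",
                (RegionCoords(s1, s1 + 19), RegionCoords(s2, s2 + 19)),
            )
        for blk in self.conserved_blocks:
            if blk.end > self.seq_length:
                raise ValueError(f"conserved block {blk} outside 1..{self.seq_length}")
        if self.total_specimens is not None:
            non_single = self.n_species - self.n_singletons
            needed = self.total_specimens - self.n_singletons
            lo = max(2, self.specimens_range[0])
            if not (non_single * lo <= needed <= non_single * self.specimens_range[1]):
                raise ValueError("total_specimens incompatible with species counts")


@dataclass
class GroundTruth:
    """Everything a test needs to verify pipeline output against the design."""

    species_map: dict[str, str]
    taxonomy: dict[str, dict[str, str]]  # id -> {order, family, genus, species}
    species_tree_newick: str
    conserved_blocks: list[tuple[int, int]]
    core_region: tuple[int, int]  # alignment columns holding the unpadded core
    realized_max_intra: float
    realized_min_inter: float
    n_species: int
    n_singletons: int
    template_offset: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


class _Node:
    __slots__ = ("name", "depth", "children", "seq")

    def __init__(self, name: str | None, depth: float, children=()):
        self.name = name
        self.depth = depth
        self.children = list(children)
        self.seq: np.ndarray | None = None

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(
            f"{c.newick()}:{self.depth - c.depth:.6f}" for c in self.children
        )
        return f"({inner})"


def simulate_species_tree(cfg: SimConfig, rng: np.random.Generator | None = None) -> _Node:
    """Random ultrametric species tree honouring the divergence targets.

    Split depths are drawn uniformly between ``0.75 * target_inter`` (so the
    shallowest species pair sits at expected distance 1.5x the minimum
    target) and ``inter_depth_max``, then clusters are joined shallowest
    first - a Yule-like topology with controlled depth range. Deterministic
    under ``cfg.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    depth_min = 0.75 * cfg.target_inter
    if depth_min >= cfg.inter_depth_max:
        raise ValueError("inter_depth_max must exceed 0.75 * target_inter")
    clusters = [_Node(f"sp{i + 1:02d}", 0.0) for i in range(cfg.n_species)]
    depths = np.sort(rng.uniform(depth_min, cfg.inter_depth_max, cfg.n_species - 1))
    for d in depths:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = _Node(None, float(d), (clusters[i], clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return clusters[0]


def _k2p_probs(d: float, kappa: float) -> tuple[float, float]:
    """(transition prob, each-transversion prob) after branch length ``d``."""
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def _evolve_branch(
    seq: np.ndarray, d: float, cfg: SimConfig, mutable: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One K2P step of length ``d`` substitutions/site; conserved sites fixed."""
    out = seq.copy()
    if d <= 0:
        return out
    p_ts, p_tv = _k2p_probs(d, cfg.kappa)
    u = rng.random(len(seq))
    ts = (u < p_ts) & mutable
    tv1 = (u >= p_ts) & (u < p_ts + p_tv) & mutable
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv) & mutable
    out[ts] = _TS_PARTNER[seq[ts]]
    out[tv1] = _TV_FIRST[seq[tv1]]
    out[tv2] = _TV_SECOND[seq[tv2]]
    return out


def _allocate_specimens(cfg: SimConfig, rng: np.random.Generator) -> list[int]:
    """Specimen count per species (singletons first in species order)."""
    counts = [1] * cfg.n_singletons
    non_single = cfg.n_species - cfg.n_singletons
    lo = max(2, cfg.specimens_range[0])
    hi = cfg.specimens_range[1]
    if cfg.total_specimens is None:
        counts += [int(rng.integers(lo, hi + 1)) for _ in range(non_single)]
    else:
        needed = cfg.total_specimens - cfg.n_singletons
        base = [lo] * non_single
        surplus = needed - lo * non_single
        room = [hi - lo] * non_single
        while surplus > 0:
            candidates = [k for k in range(non_single) if room[k] > 0]
            k = int(rng.choice(candidates))
            base[k] += 1
            room[k] -= 1
            surplus -= 1
        counts += base
    # shuffle which species are singletons
    order = rng.permutation(cfg.n_species)
    return [counts[k] for k in order]


def _taxonomy_from_tree(root: _Node, cfg: SimConfig) -> dict[str, dict[str, str]]:
    """Genus/family/order labels by cutting the species tree at three depths."""
    cuts = {
        "genus": 0.3 * cfg.inter_depth_max,
        "family": 0.6 * cfg.inter_depth_max,
        "order": 0.9 * cfg.inter_depth_max,
    }
    groups: dict[str, dict[str, int]] = {k: {} for k in cuts}

    def walk(node: _Node, anc: dict[str, int]):
        here = dict(anc)
        for rank, cut in cuts.items():
            if node.depth <= cut and rank not in here:
                here[rank] = id(node)
        if not node.children:
            for rank in cuts:
                groups[rank][node.name] = here.get(rank, id(node))
        for c in node.children:
            walk(c, here)

    walk(root, {})
    prefix = {"genus": "Genus", "family": "Family", "order": "Order"}
    # compact group ids into 1-based labels per rank
    out: dict[str, dict[str, str]] = {}
    relabel: dict[str, dict[int, int]] = {k: {} for k in cuts}
    for rank in cuts:
        for sp, gid in groups[rank].items():
            relabel[rank].setdefault(gid, len(relabel[rank]) + 1)
    for sp in groups["genus"]:
        out[sp] = {
            rank: f"{prefix[rank]}{relabel[rank][groups[rank][sp]]:02d}"
            for rank in cuts
        }
    return out


def _inject_indels(
    residues: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Replace short runs with gap symbols, never inside conserved blocks."""
    n_indels = rng.poisson(cfg.indels_per_specimen)
    blocked = np.zeros(cfg.seq_length, dtype=bool)
    for blk in cfg.conserved_blocks:
        blocked[blk.start - 1 : blk.end] = True
    out = residues.copy()
    for _ in range(n_indels):
        length = int(rng.integers(1, 4))
        for _attempt in range(20):
            start = int(rng.integers(0, cfg.seq_length - length + 1))
            if not blocked[start : start + length].any():
                out[start : start + length] = 4  # gap code
                break
    return out


_DECODE = np.array(list("ACGT-N"))


def evolve_alignment(
    root: _Node, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[AlignedSeqSet, GroundTruth]:
    """Evolve specimen sequences along the species tree; return truth too.

    The root sequence is uniform over A/C/G/T; conserved blocks never
    change; specimens hang off their species tip with intraspecific-scale
    branch lengths; short gap runs are injected per specimen outside the
    blocks; optional ragged N-padding is added at both ends.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    mutable = np.ones(cfg.seq_length, dtype=bool)
    for blk in cfg.conserved_blocks:
        mutable[blk.start - 1 : blk.end] = False

    root.seq = rng.integers(0, 4, cfg.seq_length)
    # Conserved blocks act as primer flanks: give them the GC-rich
    # composition (65%) that a 57-63 C melting-temperature band implies for
    # 20-mers, so downstream primer enumeration has satisfiable targets.
    for blk in cfg.conserved_blocks:
        length = blk.length
        n_gc = int(round(0.65 * length))
        block = np.empty(length, dtype=int)
        gc_pos = rng.choice(length, size=n_gc, replace=False)
        is_gc = np.zeros(length, dtype=bool)
        is_gc[gc_pos] = True
        block[is_gc] = rng.choice([1, 2], size=n_gc)  # C or G
        block[~is_gc] = rng.choice([0, 3], size=length - n_gc)  # A or T
        root.seq[blk.start - 1 : blk.end] = block

    species_nodes: list[_Node] = []

    def descend(node: _Node):
        for child in node.children:
            child.seq = _evolve_branch(
                node.seq, node.depth - child.depth, cfg, mutable, rng
            )
            descend(child)
        if not node.children:
            species_nodes.append(node)

    descend(root)
    species_nodes.sort(key=lambda n: n.name)

    counts = _allocate_specimens(cfg, rng)
    taxonomy_ranks = _taxonomy_from_tree(root, cfg)

    records: list[SeqRecord] = []
    taxonomy: dict[str, dict[str, str]] = {}
    spec_no = 0
    for node, k in zip(species_nodes, counts):
        for _ in range(k):
            spec_no += 1
            branch = rng.uniform(0.0, cfg.target_intra / 2.0)
            seq = _evolve_branch(node.seq, branch, cfg, mutable, rng)
            seq = _inject_indels(seq, cfg, rng)
            rec_id = f"spec{spec_no:03d}"
            ranks = taxonomy_ranks[node.name]
            taxonomy[rec_id] = {**ranks, "species": node.name}
            records.append(
                SeqRecord(
                    id=rec_id,
                    species=node.name,
                    genus=ranks["genus"],
                    family=ranks["family"],
                    order=ranks["order"],
                    residues="".join(_DECODE[seq]),
                )
            )

    core_start = cfg.end_pad + 1
    core_end = cfg.end_pad + cfg.seq_length
    if cfg.end_pad > 0:
        n = len(records)
        pad_cols_left = np.full((n, cfg.end_pad), "N", dtype="<U1")
        pad_cols_right = np.full((n, cfg.end_pad), "N", dtype="<U1")
        keep = max(1, int(np.floor(0.2 * n)))  # 80% of specimens padded per column
        for j in range(cfg.end_pad):
            for pad in (pad_cols_left, pad_cols_right):
                clear = rng.choice(n, size=keep, replace=False)
                for i in clear:
                    pad[i, j] = _BASES[int(rng.integers(0, 4))]
        records = [
            SeqRecord(
                id=r.id, species=r.species, genus=r.genus, family=r.family,
                order=r.order,
                residues="".join(pad_cols_left[i]) + r.residues + "".join(pad_cols_right[i]),
            )
            for i, r in enumerate(records)
        ]

    aln = AlignedSeqSet(records)

    # realized divergences on the emitted alignment (recomputable by anyone)
    D = distance_matrix(aln, "k2p")
    sp = np.array([r.species for r in records])
    same = sp[:, None] == sp[None, :]
    iu = np.triu_indices(len(records), k=1)
    vals = D.values[iu]
    same_u = same[iu]
    intra = vals[same_u & ~np.isnan(vals)]
    inter = vals[~same_u & ~np.isnan(vals)]
    truth = GroundTruth(
        species_map={r.id: r.species for r in records},
        taxonomy=taxonomy,
        species_tree_newick=root.newick() + ";",
        conserved_blocks=[
            (b.start + cfg.end_pad, b.end + cfg.end_pad) for b in cfg.conserved_blocks
        ],
        core_region=(core_start, core_end),
        realized_max_intra=float(intra.max()) if intra.size else 0.0,
        realized_min_inter=float(inter.min()) if inter.size else float("nan"),
        n_species=cfg.n_species,
        n_singletons=sum(1 for c in counts if c == 1),
    )
    return aln, truth


@dataclass(frozen=True)
class FixtureBundle:
    alignment: Path
    taxonomy: Path
    template: Path
    truth: Path


def make_fixture(cfg: SimConfig, outdir: str | Path) -> tuple[FixtureBundle, GroundTruth]:
    """Write a complete on-disk bundle: alignment, taxonomy, template, truth.

    The template is the ungapped root sequence with 100 bp random flanks, so
    the conserved blocks (and hence any primers enumerated from them) appear
    verbatim at a known offset - in-silico PCR has planted answers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_species_tree(cfg, rng)
    aln, truth = evolve_alignment(tree, cfg, rng)

    flank = 100
    pad_left = rng.integers(0, 4, flank)
    pad_right = rng.integers(0, 4, flank)
    template_seq = "".join(_DECODE[np.concatenate([pad_left, tree.seq, pad_right])])
    truth.template_offset = flank

    bundle = FixtureBundle(
        alignment=outdir / "alignment.fasta",
        taxonomy=outdir / "taxonomy.tsv",
        template=outdir / "template.fasta",
        truth=outdir / "truth.json",
    )
    write_alignment(aln, bundle.alignment)
    write_taxonomy(aln, bundle.taxonomy)
    with open(bundle.template, "w") as fh:
        fh.write(">template_synthetic\n")
        for i in range(0, len(template_seq), 70):
            fh.write(template_seq[i : i + 70] + "\n")
    truth.to_json(bundle.truth)
    return bundle, truth
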