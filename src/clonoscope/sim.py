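"""Clonal tumour-evolution simulator.

The generative model is deliberately simple and encodes two dynamics:

* single-nucleotide substitutions accrue as a Poisson process at a
  time-constant rate per lineage, independent of how many driver genes have
  been hit;
* copy-number events are gated on Tp53 loss — their rate is
  ``cna_rate_per_week_tp53null`` on Tp53-null branches and (by default) zero
  elsewhere.

Substitution sequence contexts follow a configurable mixture of a
signature-1-like class (C>T at NpCpG), a signature-17-like class (T>G/T>C at
CpTpT), and a uniform remainder.  Positions are rejection-sampled from the
genome until the pyrimidine-collapsed context matches the drawn class, under
an infinite-sites assumption (no site is hit twice per simulation).

Sampling layers then emit per-sample variant calls (binomial read counts)
and per-bin read depths for single-cell-derived organoids and for
purity-diluted bulk mixtures.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .cna import DepthBins
from .genome import BASES, GenomeModel, collapse_triplet
from .variants import Variant, VariantCall

SIG1_CONTEXTS = ("ACG", "CCG", "GCG", "TCG")  # C>T
SIG17_CONTEXT = "CTT"  # T>G and T>C


@dataclass(frozen=True)
class CnaEvent:
    chrom: str
    start: int
    end: int
    kind: str  # loss | gain

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("CNA must have positive length")
        if self.kind not in ("loss", "gain"):
            raise ValueError(f"unknown CNA kind {self.kind!r}")

    @property
    def copy_delta(self) -> int:
        return -1 if self.kind == "loss" else +1

    def overlaps(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class SimConfig:
    """Parameters of one simulated tumour lineage tree.

    ``genome_scale`` maps real-genome lengths onto the toy genome (toy
    chromosome length / 100 Mb nominal); the default CNA length range is
    5–80 Mb-equivalent after that scaling, so both sub-10 Mb and large-scale
    (>10 Mb-equivalent) events occur.
    """

    sns_rate_per_week: float = 0.8
    normal_sns_rate_per_week: float = 0.08
    signature_weights: dict[str, float] = field(
        default_factory=lambda: {"sig1": 0.55, "sig17": 0.25, "uniform": 0.20}
    )
    cna_rate_per_week_tp53null: float = 0.10
    cna_rate_per_week_tp53wt: float = 0.0
    genome_scale: float | None = None  # derived from the genome when None
    cna_length_range_bp: tuple[int, int] | None = None  # 5-80 Mb-equivalent when None
    driver_schedule: dict[str, float | None] = field(
        default_factory=lambda: {"apc": 0.0, "kras": 0.0, "tp53": 0.0}
    )
    branching_times: list[float] = field(default_factory=lambda: [5.0, 12.0])
    duration_weeks: float = 25.0
    sns_territory: str = "coding"  # "coding" or "genome"
    seed: int = 0

    def validate(self) -> None:
        for name in ("sns_rate_per_week", "normal_sns_rate_per_week",
                     "cna_rate_per_week_tp53null", "cna_rate_per_week_tp53wt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.signature_weights.values()) - 1.0) > 1e-9:
            raise ValueError("signature_weights must sum to 1")
        if self.duration_weeks <= 0:
            raise ValueError("duration_weeks must be > 0")
        if self.sns_territory not in ("coding", "genome"):
            raise ValueError("sns_territory must be 'coding' or 'genome'")


@dataclass
class CloneNode:
    node_id: str
    parent: str | None
    birth_time_weeks: float
    apc_mut: bool = False
    kras_mut: bool = False
    tp53_mut: bool = False
    sns: list[Variant] = field(default_factory=list)
    cnas: list[CnaEvent] = field(default_factory=list)
    children: list[str] = field(default_factory=list)


class CloneTree:
    """True simulated lineage: nodes carry private SNS/CNA sets; a node's
    full mutation set is the union along its root path."""

    def __init__(self) -> None:
        self.nodes: dict[str, CloneNode] = {}
        self.root: str | None = None

    def add(self, node: CloneNode) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id}")
        self.nodes[node.node_id] = node
        if node.parent is None:
            if self.root is not None:
                raise ValueError("tree already has a root")
            self.root = node.node_id
        else:
            parent = self.nodes[node.parent]
            # genotype flags are monotone along root-to-leaf paths
            for flag in ("apc_mut", "kras_mut", "tp53_mut"):
                if getattr(parent, flag) and not getattr(node, flag):
                    raise ValueError(f"genotype flag {flag} reverts at {node.node_id}")
            parent.children.append(node.node_id)

    def path(self, node_id: str) -> list[CloneNode]:
        out = []
        cur: str | None = node_id
        while cur is not None:
            node = self.nodes[cur]
            out.append(node)
            cur = node.parent
        return out[::-1]

    def full_sns(self, node_id: str) -> list[Variant]:
        return [v for n in self.path(node_id) for v in n.sns]

    def full_cnas(self, node_id: str) -> list[CnaEvent]:
        return [c for n in self.path(node_id) for c in n.cnas]

    def leaves(self) -> list[str]:
        return [nid for nid, n in self.nodes.items() if not n.children]

    def mrca(self, node_ids: list[str]) -> str:
        paths = [[n.node_id for n in self.path(nid)] for nid in node_ids]
        shared = None
        for depth in range(min(len(p) for p in paths)):
            ids = {p[depth] for p in paths}
            if len(ids) == 1:
                shared = ids.pop()
            else:
                break
        assert shared is not None
        return shared

    def to_json(self) -> str:
        def node_dict(n: CloneNode):
            return {
                "node_id": n.node_id,
                "parent": n.parent,
                "birth_time_weeks": n.birth_time_weeks,
                "apc_mut": n.apc_mut,
                "kras_mut": n.kras_mut,
                "tp53_mut": n.tp53_mut,
                "sns": [[v.chrom, v.pos, v.ref, v.alt] for v in n.sns],
                "cnas": [[c.chrom, c.start, c.end, c.kind] for c in n.cnas],
            }

        order = [n.node_id for n in self._preorder()]
        return json.dumps({"nodes": [node_dict(self.nodes[i]) for i in order]}, indent=1)

    def _preorder(self) -> list[CloneNode]:
        out: list[CloneNode] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    @classmethod
    def from_json(cls, text: str) -> "CloneTree":
        tree = cls()
        for d in json.loads(text)["nodes"]:
            tree.add(
                CloneNode(
                    node_id=d["node_id"],
                    parent=d["parent"],
                    birth_time_weeks=d["birth_time_weeks"],
                    apc_mut=d["apc_mut"],
                    kras_mut=d["kras_mut"],
                    tp53_mut=d["tp53_mut"],
                    sns=[Variant(c, p, r, a) for c, p, r, a in d["sns"]],
                    cnas=[CnaEvent(c, s, e, k) for c, s, e, k in d["cnas"]],
                )
            )
        return tree

    def to_newick(self) -> str:
        def render(nid: str) -> str:
            node = self.nodes[nid]
            if not node.children:
                return node.node_id
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.node_id}"

        return render(self.root) + ";"


# ---------------------------------------------------------------------------
# context-conditional position sampling


class ContextSampler:
    """Rejection-samples genomic positions whose pyrimidine-collapsed 3-mer
    matches a requested class, drawing in batches and pooling misses for
    later requests."""

    BATCH = 4096

    def __init__(
        self,
        genome: GenomeModel,
        rng: np.random.Generator,
        territory: list[tuple[str, int, int]] | None = None,
    ) -> None:
        self.genome = genome
        self.rng = rng
        if territory is None:
            territory = [(c, 0, len(s)) for c, s in genome.chromosomes.items()]
        self.intervals = [
            (c, max(s, 1), min(e, len(genome.chromosomes[c]) - 1))
            for c, s, e in territory
        ]
        self.intervals = [iv for iv in self.intervals if iv[2] > iv[1]]
        if not self.intervals:
            raise ValueError("territory contains no position with full 3-mer context")
        lengths = np.array([e - s for _, s, e in self.intervals], dtype=np.int64)
        self.cum = np.cumsum(lengths)
        self.total = int(self.cum[-1])
        self.pools: dict[str, list[tuple[str, int]]] = {}
        self.used: set[tuple[str, int]] = set()
        self._max_attempts = 200

    def _fill(self) -> None:
        global_idx = self.rng.integers(0, self.total, size=self.BATCH)
        iv_idx = np.searchsorted(self.cum, global_idx, side="right")
        for g, i in zip(global_idx, iv_idx):
            chrom, s, _e = self.intervals[i]
            offset = int(g) - (int(self.cum[i - 1]) if i > 0 else 0)
            pos = s + offset
            ctx = self.genome.context(chrom, pos)
            if ctx is None:
                continue
            self.pools.setdefault(ctx, []).append((chrom, pos))

    def draw(self, triplet: str) -> tuple[str, int]:
        """One unused position with the given collapsed context."""
        for _ in range(self._max_attempts):
            pool = self.pools.get(triplet)
            while pool:
                chrom, pos = pool.pop()
                if (chrom, pos) not in self.used:
                    self.used.add((chrom, pos))
                    return chrom, pos
            self._fill()
        raise RuntimeError(
            f"no genomic position with context class {triplet!r} found "
            f"after {self._max_attempts * self.BATCH} draws"
        )

    def draw_any(self) -> tuple[str, int]:
        for _ in range(self._max_attempts):
            for pool in list(self.pools.values()):
                while pool:
                    chrom, pos = pool.pop()
                    if (chrom, pos) not in self.used:
                        self.used.add((chrom, pos))
                        return chrom, pos
            self._fill()
        raise RuntimeError("genome exhausted")


def _draw_variant(
    sampler: ContextSampler, weights: dict[str, float], rng: np.random.Generator
) -> Variant:
    classes = list(weights)
    which = classes[int(rng.choice(len(classes), p=[weights[c] for c in classes]))]
    genome = sampler.genome
    if which == "sig1":
        triplet = SIG1_CONTEXTS[int(rng.integers(len(SIG1_CONTEXTS)))]
        chrom, pos = sampler.draw(triplet)
        pyr_alt = "T"
    elif which == "sig17":
        chrom, pos = sampler.draw(SIG17_CONTEXT)
        pyr_alt = "G" if rng.random() < 0.5 else "C"
    else:
        chrom, pos = sampler.draw_any()
        ref_collapsed = collapse_triplet(
            genome.chromosomes[chrom][pos - 1 : pos + 2]
        )[1]
        pyr_alt = str(rng.choice([b for b in BASES if b != ref_collapsed]))
    ref = genome.base(chrom, pos)
    if ref in "CT":  # centre already pyrimidine: mutate as drawn
        alt = pyr_alt
    else:  # purine centre: apply the reverse-complement substitution
        alt = {"A": "T", "C": "G", "G": "C", "T": "A"}[pyr_alt]
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)


def _draw_cna(
    genome: GenomeModel,
    config: SimConfig,
    existing: list[CnaEvent],
    rng: np.random.Generator,
) -> CnaEvent:
    chrom_names = list(genome.chromosomes)
    lo, hi = config.cna_length_range_bp
    for _ in range(500):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        size = len(genome.chromosomes[chrom])
        length = int(np.exp(rng.uniform(np.log(lo), np.log(min(hi, size)))))
        if length >= size:
            continue
        start = int(rng.integers(0, size - length))
        event = CnaEvent(
            chrom=chrom,
            start=start,
            end=start + length,
            kind="loss" if rng.random() < 0.5 else "gain",
        )
        clash = any(
            e.chrom == event.chrom and e.start < event.end and event.start < e.end
            for e in existing
        )
        if not clash:
            return event
    raise RuntimeError("could not place a non-overlapping CNA")


def simulate_lineage(genome: GenomeModel, config: SimConfig) -> CloneTree:
    """Simulate one tumour's clone tree.

    Branching times each split a randomly chosen extant tip in two.  Driver
    events hit all tips extant at their scheduled time (clonal when the
    event precedes the first branching, which is the default schedule).
    Mutations are then drawn per tree segment: SNS counts are Poisson with
    mean rate × segment duration regardless of genotype; CNA counts use the
    Tp53-dependent rate of the segment's genotype.
    """
    config.validate()
    if config.genome_scale is None:
        mean_len = float(np.mean([len(s) for s in genome.chromosomes.values()]))
        config.genome_scale = mean_len / 100_000_000
    if config.cna_length_range_bp is None:
        config.cna_length_range_bp = (
            max(1000, int(5_000_000 * config.genome_scale)),
            max(2000, int(80_000_000 * config.genome_scale)),
        )
    rng = np.random.default_rng(config.seed)
    territory = (
        genome.territory_intervals("coding")
        if config.sns_territory == "coding"
        else None
    )
    if config.sns_territory == "coding" and not territory:
        raise ValueError("genome has no coding territory to place SNSs in")
    sampler = ContextSampler(genome, rng, territory)

    tree = CloneTree()
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"n{counter[0]:03d}"

    tree.add(CloneNode(node_id=new_id(), parent=None, birth_time_weeks=0.0))

    events: list[tuple[float, str, str | None]] = []
    for gene, t in config.driver_schedule.items():
        if t is not None:
            events.append((float(t), "driver", gene))
    for t in config.branching_times:
        if 0 < t < config.duration_weeks:
            events.append((float(t), "branch", None))
    events.sort(key=lambda e: (e[0], e[1]))

    tips = [tree.root]
    for t, kind, gene in events:
        if kind == "driver":
            new_tips = []
            for tip in tips:
                flags = {
                    f: getattr(tree.nodes[tip], f)
                    for f in ("apc_mut", "kras_mut", "tp53_mut")
                }
                flags[f"{gene}_mut"] = True
                child = CloneNode(
                    node_id=new_id(), parent=tip, birth_time_weeks=t, **flags
                )
                tree.add(child)
                new_tips.append(child.node_id)
            tips = new_tips
        else:
            which = int(rng.integers(len(tips)))
            tip = tips.pop(which)
            flags = {
                f: getattr(tree.nodes[tip], f)
                for f in ("apc_mut", "kras_mut", "tp53_mut")
            }
            for _ in range(2):
                child = CloneNode(
                    node_id=new_id(), parent=tip, birth_time_weeks=t, **flags
                )
                tree.add(child)
                tips.append(child.node_id)

    # draw mutations per segment
    for node in tree.nodes.values():
        if node.children:
            end_time = min(tree.nodes[c].birth_time_weeks for c in node.children)
        else:
            end_time = config.duration_weeks
        elapsed = max(0.0, end_time - node.birth_time_weeks)
        n_sns = int(rng.poisson(config.sns_rate_per_week * elapsed))
        node.sns = [
            _draw_variant(sampler, config.signature_weights, rng)
            for _ in range(n_sns)
        ]
        cna_rate = (
            config.cna_rate_per_week_tp53null
            if node.tp53_mut
            else config.cna_rate_per_week_tp53wt
        )
        n_cna = int(rng.poisson(cna_rate * elapsed))
        lineage_cnas = tree.full_cnas(node.node_id)
        for _ in range(n_cna):
            event = _draw_cna(genome, config, lineage_cnas, rng)
            node.cnas.append(event)
            lineage_cnas.append(event)
    return tree


# ---------------------------------------------------------------------------
# sampling: organoids and bulk biopsies


def _copy_fate_coin(variant: Variant, cna: CnaEvent) -> bool:
    """Stable fair coin deciding whether a post-SNS CNA hit the mutated copy;
    deterministic per (variant, event) so all samples of one simulation agree."""
    key = f"{variant.chrom}:{variant.pos}:{variant.alt}|{cna.chrom}:{cna.start}:{cna.end}:{cna.kind}"
    return bool(zlib.crc32(key.encode()) & 1)


def _local_copies(tree: CloneTree, node_id: str, variant: Variant) -> tuple[int, int]:
    """(total copies, mutated copies) at a variant's position in one clone.

    At most one CNA overlaps any position along a lineage (overlap is
    disallowed at simulation time).  A loss/gain acquired strictly after the
    SNS removes/duplicates the mutated copy on a stable fair coin; a CNA
    acquired before (or in the same segment as) the SNS just changes the copy
    count the SNS lands on.
    """
    path = tree.path(node_id)
    sns_depth = next(
        (i for i, n in enumerate(path) if variant in n.sns), None
    )
    cna = None
    cna_depth = None
    for i, n in enumerate(path):
        for event in n.cnas:
            if event.overlaps(variant.chrom, variant.pos):
                cna, cna_depth = event, i
                break
    tot = 2 if cna is None else 2 + cna.copy_delta
    if sns_depth is None:
        return tot, 0
    if cna is None:
        return 2, 1
    if cna_depth <= sns_depth:
        return tot, 1
    hit_mutated = _copy_fate_coin(variant, cna)
    if cna.kind == "loss":
        return 1, 0 if hit_mutated else 1
    return 3, 2 if hit_mutated else 1


def _depth_bins(
    genome: GenomeModel,
    copy_expectation,  # callable (chrom, start, end) -> expected copies
    depth_mean: float,
    bin_width: int,
    rng: np.random.Generator,
) -> DepthBins:
    rows = []
    for chrom, seq in genome.chromosomes.items():
        pos = 0
        n = len(seq)
        while pos < n:
            end = min(pos + bin_width, n)
            copies = copy_expectation(chrom, pos, end)
            lam = depth_mean * copies / 2.0 * (end - pos) / bin_width
            rows.append((chrom, pos, end, int(rng.poisson(lam))))
            pos = end
    return DepthBins.from_rows(rows)


def _copies_in_bin(cnas: list[CnaEvent], chrom: str, start: int, end: int) -> float:
    copies = 2.0
    for event in cnas:
        if event.chrom != chrom:
            continue
        overlap = min(end, event.end) - max(start, event.start)
        if overlap > 0:
            copies += event.copy_delta * overlap / (end - start)
    return copies


def sample_organoid(
    tree: CloneTree,
    node_id: str,
    genome: GenomeModel,
    depth_mean: float = 100.0,
    seed: int = 0,
    sample_id: str | None = None,
    bin_width: int = 50_000,
) -> tuple[list[VariantCall], DepthBins]:
    """Emit variant calls and depth bins for a single-cell-derived organoid.

    Every mutation carried by the clone is emitted with
    alt ~ Binomial(depth, mutated copies / total copies); heterozygous
    variants in copy-neutral diploid regions are therefore expected at
    VAF 0.5.  Variants whose mutated copy was lost to a deletion are absent.
    """
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    rng = np.random.default_rng(seed)
    sample_id = sample_id or node_id
    cnas = tree.full_cnas(node_id)
    calls = []
    for variant in tree.full_sns(node_id):
        tot, mut = _local_copies(tree, node_id, variant)
        if mut == 0:
            continue
        depth = int(rng.poisson(depth_mean * tot / 2.0))
        alt = int(rng.binomial(depth, mut / tot)) if depth > 0 else 0
        calls.append(
            VariantCall(sample_id=sample_id, variant=variant, alt_depth=alt, total_depth=depth)
        )
    bins = _depth_bins(
        genome,
        lambda c, s, e: _copies_in_bin(cnas, c, s, e),
        depth_mean,
        bin_width,
        rng,
    )
    return calls, bins


def sample_bulk(
    tree: CloneTree,
    mixture: list[tuple[str, float]],
    genome: GenomeModel,
    purity: float = 0.6,
    depth_mean: float = 100.0,
    seed: int = 0,
    sample_id: str = "bulk",
    bin_width: int = 50_000,
) -> tuple[list[VariantCall], DepthBins]:
    """Emit calls and depth bins for a purity-diluted mixture of clones.

    For a heterozygous copy-neutral SNS carried by clones totalling cell
    fraction f, the expected VAF is purity·f/2; depth-bin expectations are
    2 + purity·Σ f·copy_delta over carrying clones, as a ratio to diploid.
    """
    if not mixture:
        raise ValueError("mixture must contain at least one clone")
    fractions = np.array([f for _, f in mixture], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)

    universe: dict[tuple[str, int, str], Variant] = {}
    for node_id, _f in mixture:
        for v in tree.full_sns(node_id):
            universe[v.key] = v

    clone_cnas = {node_id: tree.full_cnas(node_id) for node_id, _ in mixture}
    calls = []
    for variant in universe.values():
        num = 0.0
        denom = 2.0 * (1.0 - purity)
        for node_id, f in mixture:
            tot, mut = _local_copies(tree, node_id, variant)
            denom += purity * f * tot
            num += purity * f * mut
        frac = num / denom
        if frac <= 0:
            continue
        depth = int(rng.poisson(depth_mean * denom / 2.0))
        alt = int(rng.binomial(depth, frac)) if depth > 0 else 0
        calls.append(
            VariantCall(sample_id=sample_id, variant=variant, alt_depth=alt, total_depth=depth)
        )

    def copies(chrom: str, start: int, end: int) -> float:
        c = 2.0 * (1.0 - purity)
        for node_id, f in mixture:
            c += purity * f * _copies_in_bin(clone_cnas[node_id], chrom, start, end)
        return c

    bins = _depth_bins(genome, copies, depth_mean, bin_width, rng)
    return calls, bins
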