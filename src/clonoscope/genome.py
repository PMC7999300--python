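"""Toy reference genome: sequences, gene models, replication-timing domains.

Builds a small synthetic reference with controllable trinucleotide
composition (CpG-dinucleotide depletion) so that every downstream analysis
stage — consequence annotation, spectrum normalization, gene-size testing,
timing stratification — is testable without any external download.

All coordinates are 0-based half-open.  Triplet censuses are collapsed to
the 32 pyrimidine-centred classes (purine-centred positions are counted via
their reverse complement), the same convention the mutation spectrum uses,
so numerator and denominator of any normalization share one indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE2INT = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the 32 pyrimidine-centred triplets, lexicographic within each centre
PYRIMIDINE_TRIPLETS = tuple(
    f"{five}{centre}{three}"
    for centre in "CT"
    for five in BASES
    for three in BASES
)

TIMING_STRATA = ("early", "mid", "late")


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def collapse_triplet(triplet: str) -> str:
    """Map a 3-mer to its pyrimidine-centred class (centre must be ACGT)."""
    if triplet[1] in "CT":
        return triplet
    return revcomp(triplet)


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered set of coding exons on one strand."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"{self.gene_id}: empty exon ({start},{end})")
            if start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def genomic_span_bp(self) -> int:
        return self.end - self.start

    @property
    def coding_length_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    def splice_sites(self) -> list[tuple[int, int]]:
        """Intronic ±2 bp windows flanking each internal exon boundary."""
        sites = []
        for i in range(len(self.exons) - 1):
            donor_start = self.exons[i][1]
            acceptor_end = self.exons[i + 1][0]
            sites.append((donor_start, donor_start + 2))
            sites.append((acceptor_end - 2, acceptor_end))
        return sites


@dataclass
class GenomeModel:
    """Chromosome sequences plus gene models and timing domains."""

    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    timing_domains: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene in self.genes:
            size = len(self.chromosomes.get(gene.chrom, ""))
            if gene.chrom not in self.chromosomes:
                raise ValueError(f"{gene.gene_id}: unknown chromosome {gene.chrom}")
            if gene.end > size:
                raise ValueError(
                    f"{gene.gene_id}: extends to {gene.end} beyond "
                    f"{gene.chrom} length {size}"
                )
        for chrom, start, end, stratum in self.timing_domains:
            if stratum not in TIMING_STRATA:
                raise ValueError(f"unknown timing stratum {stratum!r}")
            if not 0 <= start < end <= len(self.chromosomes[chrom]):
                raise ValueError(f"timing domain out of bounds on {chrom}")

    # -- sequence access ---------------------------------------------------

    def base(self, chrom: str, pos: int) -> str:
        return self.chromosomes[chrom][pos]

    def context(self, chrom: str, pos: int) -> str | None:
        """Pyrimidine-collapsed 3-mer around pos, or None at chromosome ends."""
        seq = self.chromosomes[chrom]
        if pos < 1 or pos >= len(seq) - 1:
            return None
        return collapse_triplet(seq[pos - 1 : pos + 2])

    # -- territories -------------------------------------------------------

    def territory_masks(self, chrom: str) -> dict[str, np.ndarray]:
        """Boolean masks partitioning one chromosome into
        coding / intronic / intergenic territory."""
        n = len(self.chromosomes[chrom])
        coding = np.zeros(n, dtype=bool)
        genic = np.zeros(n, dtype=bool)
        for gene in self.genes:
            if gene.chrom != chrom:
                continue
            genic[gene.start : gene.end] = True
            for s, e in gene.exons:
                coding[s:e] = True
        intronic = genic & ~coding
        intergenic = ~genic
        return {"coding": coding, "intronic": intronic, "intergenic": intergenic}

    def territory_intervals(self, territory: str) -> list[tuple[str, int, int]]:
        out = []
        for chrom in self.chromosomes:
            mask = self.territory_masks(chrom)[territory]
            out.extend((chrom, int(s), int(e)) for s, e in _mask_to_intervals(mask))
        return out

    def stratum_at(self, chrom: str, pos: int) -> str | None:
        for c, s, e, stratum in self.timing_domains:
            if c == chrom and s <= pos < e:
                return stratum
        return None


def _mask_to_intervals(mask: np.ndarray):
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return zip(starts, ends)


# ---------------------------------------------------------------------------
# construction


@dataclass
class GenomeConfig:
    """Targets for :func:`build_genome`.

    ``cpg_depletion`` rescales the conditional probability of a G following
    a C, so NpCpG-class triplet frequency lands near ``depletion/8`` of all
    positions (the uniform expectation is 1/8 after pyrimidine collapse).
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    n_genes: int = 60
    gene_span_range_bp: tuple[int, int] = (5_000, 400_000)
    exons_per_gene: tuple[int, int] = (2, 8)
    coding_fraction: float = 0.10
    cpg_depletion: float = 0.2
    timing_domain_bp: int = 250_000

    def validate(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("config must specify at least one chromosome")
        if self.cpg_depletion <= 0 or self.cpg_depletion > 1:
            raise ValueError("cpg_depletion must be in (0, 1]")
        lo, hi = self.gene_span_range_bp
        if self.n_genes and lo >= hi:
            raise ValueError("gene span range must be a non-empty interval")
        if self.n_genes and hi > max(self.chrom_sizes.values()):
            raise ValueError(
                f"maximum gene span {hi} exceeds the longest chromosome "
                f"({max(self.chrom_sizes.values())} bp)"
            )

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["gene_span_range_bp"] = list(self.gene_span_range_bp)
        d["exons_per_gene"] = list(self.exons_per_gene)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GenomeConfig":
        d = json.loads(text)
        d["gene_span_range_bp"] = tuple(d["gene_span_range_bp"])
        d["exons_per_gene"] = tuple(d["exons_per_gene"])
        return cls(**d)


def _simulate_sequence(n: int, depletion: float, rng: np.random.Generator) -> str:
    """Uniform i.i.d. sequence, then thin CpG dinucleotides to `depletion`
    of their uniform frequency; the removed G becomes A or T so base
    composition stays near-uniform and no new CpG is created."""
    arr = rng.integers(0, 4, size=n, dtype=np.int8)
    if depletion < 1.0 and n >= 2:
        is_cg = (arr[:-1] == 1) & (arr[1:] == 2)
        idx = np.nonzero(is_cg)[0]
        drop = idx[rng.random(idx.size) >= depletion]
        # replace the G (index drop+1) with A or T
        arr[drop + 1] = np.where(rng.random(drop.size) < 0.5, 0, 3)
    return "".join(BASES[i] for i in arr)


def _simulate_gene(
    gene_id: str,
    chrom: str,
    start: int,
    span: int,
    config: GenomeConfig,
    rng: np.random.Generator,
) -> GeneModel:
    n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    coding = max(n_exons * 30, int(span * config.coding_fraction))
    coding = min(coding, span)
    coding -= coding % 3
    # split coding length over exons, then pack exons left-to-right with the
    # leftover intron space spread between them
    cuts = np.sort(rng.choice(np.arange(1, coding // 3), size=n_exons - 1, replace=False)) * 3
    exon_lens = np.diff(np.concatenate(([0], cuts, [coding])))
    intron_total = span - coding
    gaps = rng.multinomial(intron_total - 5 * (n_exons - 1), np.full(n_exons - 1, 1 / (n_exons - 1))) + 5 if n_exons > 1 else np.array([], dtype=int)
    exons = []
    pos = start
    for i, length in enumerate(exon_lens):
        exons.append((int(pos), int(pos + length)))
        pos += length
        if i < len(gaps):
            pos += gaps[i]
    # force last exon to close the span exactly
    if exons[-1][1] != start + span:
        shift = start + span - exons[-1][1]
        exons[-1] = (exons[-1][0] + shift, start + span)
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=tuple(exons))


def build_genome(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Build a deterministic toy genome from ``config`` and ``seed``.

    Gene spans are log-uniform over the configured range, so the default
    fixture populates both the ≤150 kb and the >150 kb gene-size classes.
    Genes are placed without overlap; placement failures resample a smaller
    span rather than erroring out.
    """
    if config is None:
        config = GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    chromosomes = {
        name: _simulate_sequence(size, config.cpg_depletion, rng)
        for name, size in config.chrom_sizes.items()
    }

    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chromosomes}
    chrom_names = list(chromosomes)
    lo, hi = config.gene_span_range_bp
    for k in range(config.n_genes):
        span = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        placed = False
        for _attempt in range(200):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            size = config.chrom_sizes[chrom]
            if span >= size:
                span = max(lo, span // 2)
                continue
            start = int(rng.integers(0, size - span))
            if any(start < e and start + span > s for s, e in occupied[chrom]):
                if _attempt % 20 == 19:
                    span = max(lo, int(span * 0.7))
                continue
            occupied[chrom].append((start, start + span))
            genes.append(
                _simulate_gene(f"gene{k:03d}", chrom, start, span, config, rng)
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(f"could not place gene {k} (genome too crowded)")
    genes.sort(key=lambda g: (g.chrom, g.start))

    timing = []
    for chrom, size in config.chrom_sizes.items():
        pos = 0
        i = 0
        while pos < size:
            end = min(pos + config.timing_domain_bp, size)
            timing.append((chrom, pos, end, TIMING_STRATA[i % 3]))
            pos = end
            i += 1

    return GenomeModel(chromosomes=chromosomes, genes=genes, timing_domains=timing)


# ---------------------------------------------------------------------------
# triplet census


def triplet_census(
    genome: GenomeModel,
    territory: list[tuple[str, int, int]] | None = None,
) -> dict[str, int]:
    """Count the 32 pyrimidine-centred 3-mer classes over a territory.

    Every position whose centre lies in the territory and has both flanks
    inside its chromosome is counted exactly once; purine-centred positions
    count toward their reverse-complement class.  An empty territory yields
    an all-zero census.
    """
    counts = np.zeros(32, dtype=np.int64)
    if territory is None:
        territory = [(c, 0, len(s)) for c, s in genome.chromosomes.items()]
    triplet_index = {t: i for i, t in enumerate(PYRIMIDINE_TRIPLETS)}
    encoded: dict[str, np.ndarray] = {}

    def encode(chrom: str) -> np.ndarray:
        if chrom not in encoded:
            arr = np.frombuffer(genome.chromosomes[chrom].encode(), dtype=np.uint8)
            code = np.zeros(arr.size, dtype=np.int8)
            for b, i in _BASE2INT.items():
                code[arr == ord(b)] = i
            encoded[chrom] = code
        return encoded[chrom]

    for chrom, start, end in territory:
        seq = genome.chromosomes[chrom]
        if not 0 <= start <= end <= len(seq):
            raise ValueError(f"territory interval out of bounds on {chrom}")
        lo = max(start, 1)
        hi = min(end, len(seq) - 1)
        if hi <= lo:
            continue
        code = encode(chrom)
        five = code[lo - 1 : hi - 1].astype(np.int32)
        centre = code[lo:hi].astype(np.int32)
        three = code[lo + 1 : hi + 1].astype(np.int32)
        purine = (centre == 0) | (centre == 2)  # A or G centre: reverse complement
        five_c = np.where(purine, 3 - three, five)
        three_c = np.where(purine, 3 - five, three)
        centre_c = np.where(purine, 3 - centre, centre)
        # classes: centre C -> block 0, centre T -> block 1
        block = (centre_c == 3).astype(np.int32)
        cls = block * 16 + five_c * 4 + three_c
        counts += np.bincount(cls, minlength=32)
    return {t: int(counts[triplet_index[t]]) for t in PYRIMIDINE_TRIPLETS}


# ---------------------------------------------------------------------------
# I/O: FASTA for sequences, BED for genes and timing domains


def write_fasta(genome: GenomeModel, path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_genes_bed(genes: list[GeneModel], path: str) -> None:
    """BED12: one line per gene, exons as blocks."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes},\t{starts},\n"
            )


def read_genes_bed(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons))
    return genes


def write_timing_bed(domains: list[tuple[str, int, int, str]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, stratum in domains:
            fh.write(f"{chrom}\t{start}\t{end}\t{stratum}\n")


def read_timing_bed(path: str) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, stratum = line.split("\t")[:4]
            out.append((chrom, int(start), int(end), stratum.strip()))
    return out
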