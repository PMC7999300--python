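"""Somatic variant containers, consequence annotation, and presence calling.

Variants are single-base substitutions with 0-based positions internally;
VCF output is 1-based.  Consequence annotation translates the reference and
mutated codon on the coding strand with the standard genetic code; the
splice-site class covers the two intronic bases flanking each internal exon
boundary (canonical donor/acceptor), configurable via ``splice_window``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from Bio.Seq import Seq

from .genome import GeneModel, GenomeModel

logger = logging.getLogger(__name__)


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    SPLICE_SITE = "splice_site"
    NONCODING = "noncoding"


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)

    def context(self, genome: GenomeModel) -> str | None:
        return genome.context(self.chrom, self.pos)


@dataclass(frozen=True)
class VariantCall:
    sample_id: str
    variant: Variant
    alt_depth: int
    total_depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} outside [0, {self.total_depth}]"
            )

    @property
    def vaf(self) -> float:
        if self.total_depth == 0:
            return 0.0
        return self.alt_depth / self.total_depth


def check_ref(variant: Variant, genome: GenomeModel) -> None:
    actual = genome.base(variant.chrom, variant.pos)
    if actual != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"variant says {variant.ref}, genome has {actual}"
        )


# ---------------------------------------------------------------------------
# consequence annotation


def _cds_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of the CDS in translation order."""
    pos = [p for s, e in gene.exons for p in range(s, e)]
    if gene.strand == "-":
        pos.reverse()
    return pos


def annotate_consequence(
    variant: Variant,
    genes: list[GeneModel],
    genome: GenomeModel,
    splice_window: int = 2,
) -> Consequence:
    """Classify a substitution against the gene models.

    CDS positions are translated codon-wise on the coding strand; positions
    within ``splice_window`` intronic bp of an internal exon boundary are
    splice_site; everything else is noncoding.  CDS membership beats
    splice_site (exonic boundary bases are coding).
    """
    check_ref(variant, genome)
    in_splice = False
    for gene in genes:
        if gene.chrom != variant.chrom or not gene.start <= variant.pos < gene.end:
            continue
        exon_idx = next(
            (i for i, (s, e) in enumerate(gene.exons) if s <= variant.pos < e), None
        )
        if exon_idx is None:
            for i in range(len(gene.exons) - 1):
                donor = gene.exons[i][1]
                acceptor = gene.exons[i + 1][0]
                if donor <= variant.pos < donor + splice_window:
                    in_splice = True
                if acceptor - splice_window <= variant.pos < acceptor:
                    in_splice = True
            continue
        cds = _cds_positions(gene)
        idx = cds.index(variant.pos)  # translation-order index
        codon_i = idx // 3
        codon_pos = cds[codon_i * 3 : codon_i * 3 + 3]
        if len(codon_pos) < 3:
            continue  # trailing partial codon (malformed model); treat as noncoding
        ref_codon = "".join(genome.base(variant.chrom, p) for p in codon_pos)
        alt_codon = "".join(
            variant.alt if p == variant.pos else genome.base(variant.chrom, p)
            for p in codon_pos
        )
        if gene.strand == "-":
            ref_codon = str(Seq(ref_codon).complement())
            alt_codon = str(Seq(alt_codon).complement())
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        if alt_aa == ref_aa:
            return Consequence.SYNONYMOUS
        if alt_aa == "*":
            return Consequence.NONSENSE
        return Consequence.MISSENSE
    return Consequence.SPLICE_SITE if in_splice else Consequence.NONCODING


# ---------------------------------------------------------------------------
# presence tiers


@dataclass(frozen=True)
class PresenceThresholds:
    """Tier cut-offs mirroring the low/mid-saturation rendering of shared
    variant tables: default <10% low, 10–20% mid, ≥20% high."""

    t_low: float = 0.10
    t_mid: float = 0.20
    min_alt_reads: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.t_low < self.t_mid <= 1:
            raise ValueError("need 0 < t_low < t_mid <= 1")
        if self.min_alt_reads < 0:
            raise ValueError("min_alt_reads must be >= 0")


TIERS = ("absent", "low", "mid", "high")


def call_presence(call: VariantCall, thresholds: PresenceThresholds | None = None) -> str:
    if thresholds is None:
        thresholds = PresenceThresholds()
    if call.total_depth == 0:
        logger.debug("zero depth for %s at %s", call.sample_id, call.variant.key)
        return "absent"
    if call.alt_depth < thresholds.min_alt_reads:
        return "absent"
    if call.vaf >= thresholds.t_mid:
        return "high"
    if call.vaf >= thresholds.t_low:
        return "mid"
    return "low"


def vaf_summary(calls_by_role: dict[str, list[VariantCall]]) -> pd.DataFrame:
    """Per-role mean/median VAF and call count."""
    rows = []
    for role, calls in calls_by_role.items():
        if not calls:
            continue
        vafs = pd.Series([c.vaf for c in calls])
        rows.append(
            {"role": role, "mean_vaf": vafs.mean(), "median_vaf": vafs.median(), "n": len(calls)}
        )
    return pd.DataFrame(rows, columns=["role", "mean_vaf", "median_vaf", "n"])


# ---------------------------------------------------------------------------
# I/O: minimal VCF 4.2 and flat TSV

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total depth">
"""


def write_vcf(calls: list[VariantCall], path: str, sample_id: str | None = None) -> None:
    """One-sample VCF; POS is 1-based; AD carries (ref, alt) depths."""
    if sample_id is None:
        if not calls:
            raise ValueError("sample_id required for an empty call set")
        sample_id = calls[0].sample_id
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n"
        )
        for call in sorted(calls, key=lambda c: c.variant.key):
            v = call.variant
            ref_depth = call.total_depth - call.alt_depth
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                f"AD:DP\t{ref_depth},{call.alt_depth}:{call.total_depth}\n"
            )


def read_vcf(path: str) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        sample_id = None
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_id = line.rstrip("\n").split("\t")[9]
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError("malformed VCF data line")
            fmt_keys = f[8].split(":")
            fmt_vals = f[9].split(":")
            fmt = dict(zip(fmt_keys, fmt_vals))
            ref_d, alt_d = (int(x) for x in fmt["AD"].split(","))
            calls.append(
                VariantCall(
                    sample_id=sample_id,
                    variant=Variant(chrom=f[0], pos=int(f[1]) - 1, ref=f[3], alt=f[4]),
                    alt_depth=alt_d,
                    total_depth=int(fmt["DP"]),
                )
            )
    return calls


def calls_to_frame(calls: list[VariantCall], genome: GenomeModel | None = None) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "sample_id": c.sample_id,
            "chrom": c.variant.chrom,
            "pos": c.variant.pos,
            "ref": c.variant.ref,
            "alt": c.variant.alt,
            "alt_depth": c.alt_depth,
            "total_depth": c.total_depth,
            "vaf": c.vaf,
        }
        if genome is not None:
            row["context"] = c.variant.context(genome)
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls_tsv(calls: list[VariantCall], path: str) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        VariantCall(
            sample_id=str(r.sample_id),
            variant=Variant(chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt)),
            alt_depth=int(r.alt_depth),
            total_depth=int(r.total_depth),
        )
        for r in df.itertuples()
    ]
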