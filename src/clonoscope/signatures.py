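"""96-context mutation spectra, triplet-prevalence normalization, and
non-negative decomposition against fixed reference profiles.

Class ordering is fixed: substitution type (C>A, C>G, C>T, T>A, T>C, T>G)
major, then 5' flank, then 3' flank, both in A,C,G,T order; labels look like
``A[C>T]G``.  Purine-centred substitutions are reverse-complemented into
these pyrimidine-centred classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genome import BASES, GenomeModel, PYRIMIDINE_TRIPLETS, revcomp
from .variants import Variant

SUB_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: fixed 96-class labels, substitution-major
CLASS_LABELS = tuple(
    f"{five}[{sub}]{three}" for sub in SUB_TYPES for five in BASES for three in BASES
)
N_CLASSES = len(CLASS_LABELS)  # 96


def class_index(sub: str, five: str, three: str) -> int:
    return SUB_TYPES.index(sub) * 16 + BASES.index(five) * 4 + BASES.index(three)


def class_triplet(index: int) -> str:
    """Reference 3-mer of a class (the census key for normalization)."""
    sub = SUB_TYPES[index // 16]
    five = BASES[(index % 16) // 4]
    three = BASES[index % 4]
    return f"{five}{sub[0]}{three}"


def substitution_class(variant: Variant, genome: GenomeModel) -> int | None:
    """96-class index of a substitution, or None without full 3-mer context."""
    seq = genome.chromosomes[variant.chrom]
    pos = variant.pos
    if pos < 1 or pos >= len(seq) - 1:
        return None
    ref, alt = variant.ref, variant.alt
    five, three = seq[pos - 1], seq[pos + 1]
    if seq[pos] != ref:
        raise ValueError(f"reference mismatch at {variant.chrom}:{pos}")
    if ref in "AG":  # purine centre: reverse-complement the whole event
        five, three = revcomp(three), revcomp(five)
        ref, alt = revcomp(ref), revcomp(alt)
    return class_index(f"{ref}>{alt}", five, three)


@dataclass
class Spectrum96:
    """Counts over the 96 trinucleotide substitution classes."""

    counts: np.ndarray
    normalized: bool = False
    territory: str = "genome"
    skipped: int = 0  # variants without a full 3-mer context

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CLASSES,):
            raise ValueError(f"spectrum must have exactly {N_CLASSES} entries")
        if (self.counts < 0).any():
            raise ValueError("negative spectrum counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CLASS_LABELS))

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame({"class": CLASS_LABELS, "count": self.counts})
        df["normalized"] = self.normalized
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "Spectrum96":
        df = pd.read_csv(path, sep="\t")
        if list(df["class"]) != list(CLASS_LABELS):
            raise ValueError("spectrum TSV classes out of order")
        return cls(counts=df["count"].to_numpy(), normalized=bool(df["normalized"].iloc[0]))


def spectrum96(
    variants: list[Variant], genome: GenomeModel, territory: str = "genome"
) -> Spectrum96:
    counts = np.zeros(N_CLASSES)
    skipped = 0
    for v in variants:
        idx = substitution_class(v, genome)
        if idx is None:
            skipped += 1
            continue
        counts[idx] += 1
    return Spectrum96(counts=counts, territory=territory, skipped=skipped)


def normalize_spectrum(spec: Spectrum96, census: dict[str, int]) -> Spectrum96:
    """Divide each class by the prevalence of its reference triplet, then
    rescale so the total is preserved (shape changes, total does not)."""
    missing = set(PYRIMIDINE_TRIPLETS) - set(census)
    if missing:
        raise ValueError(f"census missing triplets: {sorted(missing)}")
    weights = np.zeros(N_CLASSES)
    for i in range(N_CLASSES):
        triplet = class_triplet(i)
        c = census[triplet]
        if c == 0:
            if spec.counts[i] > 0:
                raise ValueError(
                    f"nonzero spectrum count for class {CLASS_LABELS[i]} but "
                    f"census of triplet {triplet} is zero"
                )
            weights[i] = 0.0
        else:
            weights[i] = spec.counts[i] / c
    total = spec.total
    if total > 0 and weights.sum() > 0:
        weights *= total / weights.sum()
    return Spectrum96(
        counts=weights, normalized=True, territory=spec.territory, skipped=spec.skipped
    )


# ---------------------------------------------------------------------------
# reference profiles and supervised decomposition


def _unit(v: np.ndarray) -> np.ndarray:
    return v / v.sum()


def sig1_like_profile(cpg_mass: float = 0.9) -> np.ndarray:
    """C>T at NpCpG concentrated; the remainder uniform over other classes."""
    v = np.zeros(N_CLASSES)
    cpg = [class_index("C>T", five, "G") for five in BASES]
    v[cpg] = cpg_mass / len(cpg)
    rest = [i for i in range(N_CLASSES) if i not in cpg]
    v[rest] = (1 - cpg_mass) / len(rest)
    return _unit(v)


def sig17_like_profile(ctt_mass: float = 0.8) -> np.ndarray:
    """T>G and T>C at CpTpT concentrated; remainder uniform."""
    v = np.zeros(N_CLASSES)
    ctt = [class_index("T>G", "C", "T"), class_index("T>C", "C", "T")]
    v[ctt] = ctt_mass / len(ctt)
    rest = [i for i in range(N_CLASSES) if i not in ctt]
    v[rest] = (1 - ctt_mass) / len(rest)
    return _unit(v)


def uniform_profile() -> np.ndarray:
    return np.full(N_CLASSES, 1.0 / N_CLASSES)


@dataclass
class ReferenceProfiles:
    """Named unit-sum 96-vectors used for supervised decomposition."""

    profiles: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "sig1_like": sig1_like_profile(),
            "sig17_like": sig17_like_profile(),
            "uniform": uniform_profile(),
        }
    )

    def __post_init__(self) -> None:
        for name, v in self.profiles.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (N_CLASSES,) or (v < 0).any():
                raise ValueError(f"profile {name} is not a non-negative 96-vector")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"profile {name} does not sum to 1")
            self.profiles[name] = v

    @property
    def names(self) -> list[str]:
        return list(self.profiles)

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.profiles[n] for n in self.names])

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({n: list(v) for n, v in self.profiles.items()}, fh)

    @classmethod
    def from_json(cls, path: str) -> "ReferenceProfiles":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(profiles={n: np.asarray(v) for n, v in raw.items()})


@dataclass
class SignatureFit:
    weights: dict[str, float]  # normalized to sum 1 (all-zero if flagged)
    residual_norm: float
    zero_spectrum: bool = False


def fit_signatures(spec: Spectrum96, refs: ReferenceProfiles | None = None) -> SignatureFit:
    """Non-negative least squares of the unit-normalized spectrum on the
    reference profiles (active-set NNLS); weights reported normalized."""
    refs = refs or ReferenceProfiles()
    if spec.total <= 0:
        return SignatureFit(
            weights={n: 0.0 for n in refs.names}, residual_norm=0.0, zero_spectrum=True
        )
    target = spec.counts / spec.total
    coef, resid = nnls(refs.matrix(), target)
    total = coef.sum()
    if total > 0:
        weights = {n: float(c / total) for n, c in zip(refs.names, coef)}
    else:
        weights = {n: 0.0 for n in refs.names}
    return SignatureFit(weights=weights, residual_norm=float(resid))
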