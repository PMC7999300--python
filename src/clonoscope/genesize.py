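"""Monte-Carlo test for SNS enrichment in large genes.

Each substitution is assigned independently to the "large" gene group
(genomic span above a size threshold) with probability equal to the group's
share of total coding length, one million times by default; the p value is
the fraction of replicates in which more (or at least as many, under the
alternative rule) randomly assigned substitutions land in large genes than
observed.  Because the assignments are independent Bernoulli draws, the
exact binomial tail is available as a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel

DEFAULT_SIZE_THRESHOLD_BP = 150_000
DEFAULT_N_REPS = 1_000_000
RULES = ("strict_greater", "greater_or_equal")


@dataclass
class PermutationResult:
    observed_large_count: int
    expected_large_count: float
    p_large: float
    p_value: float
    n_reps: int
    rule: str
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def _group_lengths(
    genes: list[GeneModel], size_threshold_bp: int
) -> tuple[float, float]:
    small = sum(g.coding_length_bp for g in genes if g.genomic_span_bp <= size_threshold_bp)
    large = sum(g.coding_length_bp for g in genes if g.genomic_span_bp > size_threshold_bp)
    return float(small), float(large)


def permutation_test(
    sns_gene_assignments: list[str],
    genes: list[GeneModel],
    size_threshold_bp: int = DEFAULT_SIZE_THRESHOLD_BP,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    rule: str = "strict_greater",
) -> PermutationResult:
    """Monte-Carlo enrichment test of substitutions in large genes.

    ``sns_gene_assignments`` maps each substitution to a gene_id present in
    ``genes``.  Assignment probability to the large group is the large
    group's share of total coding length.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    if not sns_gene_assignments:
        raise ValueError("no substitutions to test")
    by_id = {g.gene_id: g for g in genes}
    missing = [g for g in sns_gene_assignments if g not in by_id]
    if missing:
        raise ValueError(f"substitutions assigned to unknown genes: {sorted(set(missing))}")

    small_len, large_len = _group_lengths(genes, size_threshold_bp)
    n_sns = len(sns_gene_assignments)
    observed = sum(
        1 for g in sns_gene_assignments if by_id[g].genomic_span_bp > size_threshold_bp
    )
    if small_len == 0 or large_len == 0:
        # all coding length in one group: randomization cannot exceed the
        # forced assignment; report p = 1 with the degenerate p_large
        p_large = 1.0 if large_len > 0 else 0.0
        return PermutationResult(
            observed_large_count=observed,
            expected_large_count=n_sns * p_large,
            p_large=p_large,
            p_value=1.0,
            n_reps=0,
            rule=rule,
            seed=seed,
        )
    p_large = large_len / (small_len + large_len)
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n_sns, p_large, size=n_reps)
    if rule == "strict_greater":
        hits = int((draws > observed).sum())
    else:
        hits = int((draws >= observed).sum())
    return PermutationResult(
        observed_large_count=observed,
        expected_large_count=n_sns * p_large,
        p_large=p_large,
        p_value=hits / n_reps,
        n_reps=n_reps,
        rule=rule,
        seed=seed,
    )


def exact_tail(n_sns: int, p_large: float, observed: int, rule: str = "strict_greater") -> float:
    """Closed-form binomial tail matching the permutation scheme."""
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    if not 0 <= p_large <= 1:
        raise ValueError("p_large outside [0, 1]")
    if not 0 <= observed <= n_sns:
        raise ValueError("observed outside [0, n_sns]")
    if rule == "strict_greater":
        return float(stats.binom.sf(observed, n_sns, p_large))
    return float(stats.binom.sf(observed - 1, n_sns, p_large))


def obs_exp_ratios(
    sns_gene_assignments: list[str],
    genes: list[GeneModel],
    bin_edges_bp: list[float] | None = None,
) -> pd.DataFrame:
    """Observed vs expected substitution counts per gene-size bin.

    Expected counts distribute the total proportionally to each bin's share
    of coding length; ratios are NaN where expected is zero.  Bin edges are
    half-open [lo, hi); the last edge may be inf.
    """
    if bin_edges_bp is None:
        bin_edges_bp = [0, 50_000, 100_000, 150_000, float("inf")]
    edges = list(bin_edges_bp)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    by_id = {g.gene_id: g for g in genes}
    if max(g.genomic_span_bp for g in genes) >= edges[-1]:
        raise ValueError("bins do not cover all gene sizes")

    def bin_of(span: int) -> int:
        for i in range(len(edges) - 1):
            if edges[i] <= span < edges[i + 1]:
                return i
        raise ValueError(f"gene span {span} outside bins")

    n_bins = len(edges) - 1
    coding = np.zeros(n_bins)
    for g in genes:
        coding[bin_of(g.genomic_span_bp)] += g.coding_length_bp
    observed = np.zeros(n_bins)
    for gid in sns_gene_assignments:
        observed[bin_of(by_id[gid].genomic_span_bp)] += 1
    total = observed.sum()
    expected = total * coding / coding.sum() if coding.sum() > 0 else np.zeros(n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.nan)
    return pd.DataFrame(
        {
            "bin_lo_bp": edges[:-1],
            "bin_hi_bp": edges[1:],
            "observed": observed,
            "expected": expected,
            "ratio": ratio,
        }
    )
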