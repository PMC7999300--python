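"""Mutation-rate analyses: burden-vs-age regression, doubling time,
replication-timing/territory stratification, and group comparisons."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeModel
from .variants import Variant


@dataclass
class RegressionResult:
    slope: float  # substitutions per week
    intercept: float
    r_squared: float
    p_value: float
    n: int
    degenerate: bool = False  # n == 2 forces R^2 = 1

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared outside [0, 1]")
        if self.n < 2:
            raise ValueError("regression needs n >= 2")


def fit_rate_regression(points: list[tuple[float, float]]) -> RegressionResult:
    """OLS of per-organoid substitution count on tumour age in weeks."""
    if len(points) < 2:
        raise ValueError("need at least two points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("tumour ages are constant; slope undefined")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        p_value=float(res.pvalue) if not math.isnan(res.pvalue) else 1.0,
        n=len(points),
        degenerate=len(points) == 2,
    )


def doubling_time(
    cells_at_seeding: float, cells_at_harvest: float, duration_hours: float
) -> float:
    """duration · log 2 / (log N_harvest − log N_seed); base-invariant."""
    if cells_at_seeding <= 0 or cells_at_harvest <= 0:
        raise ValueError("cell counts must be positive")
    if cells_at_harvest <= cells_at_seeding:
        raise ValueError("harvest count must exceed seeding count")
    if duration_hours <= 0:
        raise ValueError("duration must be positive")
    return duration_hours * math.log(2) / (
        math.log(cells_at_harvest) - math.log(cells_at_seeding)
    )


# ---------------------------------------------------------------------------
# timing / territory stratification


def timing_strata(
    variants: list[Variant],
    genome: GenomeModel,
    census_by_stratum: dict[tuple[str, str], dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Substitution density per (timing stratum × territory) cell.

    Density is count per Mb of the stratum's territory; when a per-stratum
    triplet census is supplied, a triplet-matched density (count per million
    census positions) is emitted alongside.  Variants outside any timing
    domain land in an "undefined" stratum.
    """
    masks_by_chrom = {c: genome.territory_masks(c) for c in genome.chromosomes}
    territory_bp: dict[tuple[str, str], int] = {}
    for c, s, e, stratum in genome.timing_domains:
        for territory, mask in masks_by_chrom[c].items():
            key = (stratum, territory)
            territory_bp[key] = territory_bp.get(key, 0) + int(mask[s:e].sum())

    counts: dict[tuple[str, str], int] = {}
    for v in variants:
        stratum = genome.stratum_at(v.chrom, v.pos) or "undefined"
        masks = masks_by_chrom[v.chrom]
        territory = next(t for t, m in masks.items() if m[v.pos])
        key = (stratum, territory)
        counts[key] = counts.get(key, 0) + 1

    rows = []
    for key in sorted(set(territory_bp) | set(counts)):
        stratum, territory = key
        bp = territory_bp.get(key, 0)
        n = counts.get(key, 0)
        row = {
            "stratum": stratum,
            "territory": territory,
            "sns_count": n,
            "territory_bp": bp,
            "density_per_mb": n / (bp / 1e6) if bp else float("nan"),
        }
        if census_by_stratum is not None and key in census_by_stratum:
            census_total = sum(census_by_stratum[key].values())
            row["density_per_m_triplets"] = (
                n / (census_total / 1e6) if census_total else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multi-group burden comparison


def compare_burden(
    groups: dict[str, list[float]], welch: bool = False
) -> pd.DataFrame:
    """All-pairs two-sided t tests with Benjamini–Hochberg adjustment.

    Classic Student's t by default (``welch=True`` switches to the unequal-
    variance variant).  Identical constant groups get t = 0, p = 1.
    """
    names = list(groups)
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa = np.asarray(groups[a], dtype=float)
            xb = np.asarray(groups[b], dtype=float)
            if np.var(xa) == 0 and np.var(xb) == 0 and xa.mean() == xb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
            rows.append({"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    return df


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p values, input order preserved."""
    return list(multipletests(p_values, method="fdr_bh")[1])
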