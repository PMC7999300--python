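"""Read-depth copy-number analysis.

Depth ratios between a tumour sample and its matched normal are segmented by
recursive binary change-point splitting (a documented simplification of
circular binary segmentation: the split point maximizes the two-sample t
statistic, accepted when |t| exceeds a threshold).  Recurrent artefacts are
removed against a panel of normals by reciprocal overlap, large events are
flagged against a scaled >10 Mb-equivalent threshold, and CNA burden is
associated with Tp53 status by Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: nominal real-chromosome length the toy genome miniaturizes (see genome_scale)
NOMINAL_CHROM_BP = 100_000_000
LARGE_SCALE_REAL_BP = 10_000_000


@dataclass
class DepthBins:
    """Per-bin read counts tiling the genome."""

    frame: pd.DataFrame  # columns: chrom, start, end, count

    @classmethod
    def from_rows(cls, rows: list[tuple[str, int, int, int]]) -> "DepthBins":
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end", "count"]))

    def __post_init__(self) -> None:
        df = self.frame
        if (df["count"] < 0).any():
            raise ValueError("negative bin count")
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["end"].to_numpy()[:-1] > s["start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping bins on {chrom}")

    @property
    def total(self) -> int:
        return int(self.frame["count"].sum())

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "DepthBins":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class CnaSegment:
    chrom: str
    start: int
    end: int
    mean_log2_ratio: float
    call: str  # loss | gain | neutral
    large_scale: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must have positive length")
        if self.call not in ("loss", "gain", "neutral"):
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def large_scale_threshold_bp(genome_scale: float) -> int:
    """Toy-genome equivalent of the >10 Mb large-scale cut-off."""
    return int(round(LARGE_SCALE_REAL_BP * genome_scale))


# ---------------------------------------------------------------------------


def log2_ratios(
    tumour: DepthBins, normal: DepthBins, min_normal_count: int = 10
) -> pd.DataFrame:
    """Library-size-normalized per-bin log2(tumour/normal) ratio series.

    Bins where the normal has fewer than ``min_normal_count`` reads are
    masked (ratio NaN) rather than dropped, so binning stays aligned.
    """
    t = tumour.frame.reset_index(drop=True)
    n = normal.frame.reset_index(drop=True)
    if len(t) != len(n) or not (
        (t["chrom"].to_numpy() == n["chrom"].to_numpy()).all()
        and (t["start"].to_numpy() == n["start"].to_numpy()).all()
        and (t["end"].to_numpy() == n["end"].to_numpy()).all()
    ):
        raise ValueError("tumour and normal depth bins use different binning")
    T = max(tumour.total, 1)
    N = max(normal.total, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((t["count"].to_numpy() / T) / (n["count"].to_numpy() / N))
    ratio = np.where(n["count"].to_numpy() < min_normal_count, np.nan, ratio)
    ratio = np.where(t["count"].to_numpy() == 0, np.nan, ratio)
    out = t[["chrom", "start", "end"]].copy()
    out["log2_ratio"] = ratio
    return out


def _best_split(values: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Index and t statistic of the split maximizing the two-sample t.

    Welch's form (per-side variances) rather than the pooled form: when one
    side still contains a change point its inflated variance would otherwise
    wash out a genuine mean shift.
    """
    n = values.size
    idx = np.arange(min_bins, n - min_bins + 1)
    if idx.size == 0:
        return -1, 0.0
    csum = np.cumsum(values)
    csq = np.cumsum(values**2)
    total, total_sq = csum[-1], csq[-1]
    n1 = idx.astype(float)
    n2 = n - n1
    s1 = csum[idx - 1]
    m1 = s1 / n1
    m2 = (total - s1) / n2
    v1 = np.maximum(csq[idx - 1] / n1 - m1**2, 0.0) * n1 / np.maximum(n1 - 1, 1)
    v2 = np.maximum((total_sq - csq[idx - 1]) / n2 - m2**2, 0.0) * n2 / np.maximum(n2 - 1, 1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m2) / np.sqrt(se2)
    t = np.where(se2 <= 0, np.where(m1 != m2, np.inf, 0.0), t)
    k = int(np.argmax(t))
    return int(idx[k]), float(t[k])


def _refine_boundaries(values: np.ndarray, pieces: list[tuple[int, int]], max_iter: int = 10) -> None:
    """Re-optimize each adjacent boundary within the union of its two
    segments; with a single change point in the window the t statistic peaks
    at the true boundary, correcting splits displaced by neighbouring events."""
    for _ in range(max_iter):
        moved = False
        for j in range(len(pieces) - 1):
            lo, mid = pieces[j]
            mid2, hi = pieces[j + 1]
            window = values[lo:hi]
            i, _t = _best_split(window, 1)
            if i > 0 and lo + i != mid:
                pieces[j] = (lo, lo + i)
                pieces[j + 1] = (lo + i, hi)
                moved = True
        if not moved:
            return


def _merge_pieces(
    values: np.ndarray, pieces: list[tuple[int, int]], min_bins: int, t_threshold: float
) -> None:
    """Dissolve boundaries that no longer separate distinct means: merge the
    weakest adjacent pair while its two-sample t is below threshold or one
    side is shorter than min_bins (pruning after refinement)."""
    while len(pieces) > 1:
        ts = []
        for j in range(len(pieces) - 1):
            lo, mid = pieces[j]
            _mid, hi = pieces[j + 1]
            a, b = values[lo:mid], values[mid:hi]
            se2 = (a.var(ddof=1) / a.size if a.size > 1 else 0.0) + (
                b.var(ddof=1) / b.size if b.size > 1 else 0.0
            )
            if se2 <= 0:
                t = np.inf if a.mean() != b.mean() else 0.0
            else:
                t = abs(a.mean() - b.mean()) / np.sqrt(se2)
            if a.size < min_bins or b.size < min_bins:
                t = min(t, 0.0)
            ts.append(t)
        j = int(np.argmin(ts))
        if ts[j] >= t_threshold:
            return
        pieces[j] = (pieces[j][0], pieces[j + 1][1])
        del pieces[j + 1]


def segment(
    ratios: pd.DataFrame,
    min_bins: int = 5,
    t_threshold: float = 5.0,
    loss_cutoff: float = -0.3,
    gain_cutoff: float = 0.3,
    genome_scale: float = 0.02,
) -> list[CnaSegment]:
    """Recursive binary change-point segmentation of a log2-ratio series.

    Each chromosome's unmasked bins are split recursively at the position
    maximizing the two-sample t statistic, accepting the split when
    |t| >= t_threshold with both sides >= min_bins.  Final segments are
    called loss/gain/neutral against the mean-ratio cut-offs and flagged
    large_scale when longer than the scaled >10 Mb-equivalent threshold.
    """
    ls_threshold = large_scale_threshold_bp(genome_scale)
    segments: list[CnaSegment] = []
    for chrom, sub in ratios.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        mask = sub["log2_ratio"].notna().to_numpy()
        if not mask.any():
            logger.info("chromosome %s fully masked; no segments", chrom)
            continue
        values = sub.loc[mask, "log2_ratio"].to_numpy()
        starts = sub.loc[mask, "start"].to_numpy()
        ends = sub.loc[mask, "end"].to_numpy()

        pieces: list[tuple[int, int]] = []

        def split(lo: int, hi: int) -> None:
            n = hi - lo
            if n >= 2 * min_bins:
                i, t = _best_split(values[lo:hi], min_bins)
                if i > 0 and t >= t_threshold:
                    split(lo, lo + i)
                    split(lo + i, hi)
                    return
            pieces.append((lo, hi))

        split(0, values.size)
        pieces.sort()
        for _ in range(3):
            _refine_boundaries(values, pieces)
            before = len(pieces)
            _merge_pieces(values, pieces, min_bins, t_threshold)
            if len(pieces) == before:
                break
        for lo, hi in pieces:
            mean = float(values[lo:hi].mean())
            call = "loss" if mean <= loss_cutoff else "gain" if mean >= gain_cutoff else "neutral"
            seg = CnaSegment(
                chrom=str(chrom),
                start=int(starts[lo]),
                end=int(ends[hi - 1]),
                mean_log2_ratio=mean,
                call=call,
            )
            seg.large_scale = call != "neutral" and seg.length > ls_threshold
            segments.append(seg)
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def reciprocal_overlap(a: CnaSegment, b: CnaSegment) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return min(inter / a.length, inter / b.length)


def filter_panel(
    segments: list[CnaSegment],
    normal_panel: list[list[CnaSegment]],
    min_reciprocal_overlap: float = 0.5,
) -> list[CnaSegment]:
    """Drop tumour segments matched by a same-call non-neutral segment in any
    panel-of-normals sample at >= the reciprocal-overlap threshold."""
    kept = []
    for seg in segments:
        if seg.call == "neutral":
            kept.append(seg)
            continue
        match = None
        for panel in normal_panel:
            for nseg in panel:
                if (
                    nseg.call == seg.call
                    and reciprocal_overlap(seg, nseg) >= min_reciprocal_overlap
                ):
                    match = nseg
                    break
            if match:
                break
        if match is None:
            kept.append(seg)
        else:
            logger.info(
                "excluding %s:%d-%d %s (matches normal %s:%d-%d)",
                seg.chrom, seg.start, seg.end, seg.call,
                match.chrom, match.start, match.end,
            )
    return kept


# ---------------------------------------------------------------------------
# targeted-locus recombination status from depth ratios


@dataclass(frozen=True)
class RecombinationThresholds:
    homozygous_below: float = 0.25
    heterozygous_below: float = 0.75


def recombination_status(
    tumour: DepthBins,
    normal: DepthBins,
    targets: dict[str, tuple[str, int, int]],
    thresholds: RecombinationThresholds | None = None,
) -> dict[str, str]:
    """Per-locus excision call from the normalized tumour/normal depth ratio.

    ratio < 0.25 -> homozygous_recombined (both copies excised),
    0.25-0.75 -> heterozygous, >= 0.75 -> not_recombined.
    """
    thresholds = thresholds or RecombinationThresholds()
    T = max(tumour.total, 1)
    N = max(normal.total, 1)
    out = {}
    for name, (chrom, start, end) in targets.items():
        t_count = _interval_count(tumour.frame, chrom, start, end)
        n_count = _interval_count(normal.frame, chrom, start, end)
        if n_count == 0:
            out[name] = "undetermined"
            continue
        r = (t_count / T) / (n_count / N)
        if r < thresholds.homozygous_below:
            out[name] = "homozygous_recombined"
        elif r < thresholds.heterozygous_below:
            out[name] = "heterozygous"
        else:
            out[name] = "not_recombined"
    return out


def _interval_count(frame: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    sub = frame[(frame["chrom"] == chrom) & (frame["end"] > start) & (frame["start"] < end)]
    total = 0.0
    for row in sub.itertuples():
        overlap = min(end, row.end) - max(start, row.start)
        total += row.count * overlap / (row.end - row.start)
    return total


# ---------------------------------------------------------------------------
# CNA–genotype association


@dataclass
class AssociationResult:
    table: list[list[int]]  # rows: tp53 null/wt; cols: has/lacks large-scale CNA
    p_value: float
    odds_ratio: float
    note: str = ""


def associate_cna_genotype(samples: list[tuple[bool, bool]]) -> AssociationResult:
    """Fisher exact test of large-scale CNA presence vs Tp53 inactivation.

    ``samples`` holds (tp53_null, has_large_scale_cna) per sample.
    """
    table = [[0, 0], [0, 0]]
    for tp53_null, has_cna in samples:
        table[0 if tp53_null else 1][0 if has_cna else 1] += 1
    arr = np.array(table)
    note = ""
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        note = "degenerate margins; association untestable"
        return AssociationResult(table=table, p_value=1.0, odds_ratio=float("nan"), note=note)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return AssociationResult(table=table, p_value=float(p), odds_ratio=float(odds), note=note)


# ---------------------------------------------------------------------------
# I/O


def write_segments_bed(segments: list[CnaSegment], path: str) -> None:
    """BED5+: chrom, start, end, call, mean_log2, large_scale."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.call}\t"
                f"{s.mean_log2_ratio:.6f}\t{int(s.large_scale)}\n"
            )


def read_segments_bed(path: str) -> list[CnaSegment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, call, mean, large = line.rstrip("\n").split("\t")
            out.append(
                CnaSegment(
                    chrom=chrom, start=int(start), end=int(end),
                    mean_log2_ratio=float(mean), call=call, large_scale=bool(int(large)),
                )
            )
    return out
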