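"""Samples × variants presence matrix and mutation-sharing classification.

Sharing classes are defined over the single-cell-derived organoids of one
tumour: a variant present in every organoid is truncal, in exactly one is
private, and in more than one but not all is semi-private.  Biopsy samples
are carried in the matrix for display and seeding-event counting but do not
enter the classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .variants import PresenceThresholds, VariantCall, call_presence

SAMPLE_ROLES = ("organoid", "primary_biopsy", "metastasis", "normal")
TIER_CODES = {"absent": 0, "low": 1, "mid": 2, "high": 3}
TIER_NAMES = {v: k for k, v in TIER_CODES.items()}


@dataclass
class PresenceMatrix:
    """Tiered presence of every variant in every sample.

    ``tiers`` is a samples × variants DataFrame of integer tier codes
    (0 absent, 1 low, 2 mid, 3 high); ``roles`` maps sample id to role.
    """

    tiers: pd.DataFrame
    roles: dict[str, str]
    thresholds: PresenceThresholds = field(default_factory=PresenceThresholds)

    def __post_init__(self) -> None:
        if self.tiers.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.tiers.columns.duplicated().any():
            raise ValueError("duplicate variant ids")
        unknown = set(self.roles.values()) - set(SAMPLE_ROLES)
        if unknown:
            raise ValueError(f"unknown sample roles: {sorted(unknown)}")
        missing = set(self.tiers.index) - set(self.roles)
        if missing:
            raise ValueError(f"samples without a role: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tiers.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.tiers.columns)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.sample_ids if self.roles[s] == role]

    def present(self) -> pd.DataFrame:
        """Binary presence: any non-absent tier counts as present."""
        return self.tiers > 0

    def to_tsv(self, path: str, sidecar_path: str | None = None) -> None:
        self.tiers.to_csv(path, sep="\t", index_label="sample_id")
        if sidecar_path:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"roles": self.roles, "thresholds": self.thresholds.__dict__},
                    fh, indent=2,
                )

    @classmethod
    def from_tsv(cls, path: str, sidecar_path: str) -> "PresenceMatrix":
        tiers = pd.read_csv(path, sep="\t", index_col="sample_id")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            tiers=tiers,
            roles=meta["roles"],
            thresholds=PresenceThresholds(**meta["thresholds"]),
        )


def variant_id(call: VariantCall) -> str:
    v = call.variant
    return f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


def build_presence_matrix(
    tables: dict[str, list[VariantCall]],
    roles: dict[str, str],
    thresholds: PresenceThresholds | None = None,
) -> PresenceMatrix:
    """Assemble the union-of-variants matrix from per-sample call tables.

    Missing (sample, variant) pairs are tier absent.  Two calls for one pair
    with different depths are rejected as inconsistent input.  Row order is
    the given sample order; columns sort by (chrom, pos, alt).
    """
    if not tables:
        raise ValueError("at least one sample required")
    thresholds = thresholds or PresenceThresholds()
    seen: dict[tuple[str, str], VariantCall] = {}
    variants = {}
    for sample_id, calls in tables.items():
        for call in calls:
            key = (sample_id, variant_id(call))
            if key in seen:
                prev = seen[key]
                if (prev.alt_depth, prev.total_depth) != (call.alt_depth, call.total_depth):
                    raise ValueError(
                        f"inconsistent duplicate call for {key[1]} in {sample_id}"
                    )
                continue
            seen[key] = call
            variants[variant_id(call)] = call.variant

    ordered_variants = sorted(variants, key=lambda vid: variants[vid].key)
    tiers = pd.DataFrame(
        0, index=list(tables), columns=ordered_variants, dtype=int
    )
    for (sample_id, vid), call in seen.items():
        tiers.loc[sample_id, vid] = TIER_CODES[call_presence(call, thresholds)]
    return PresenceMatrix(tiers=tiers, roles=dict(roles), thresholds=thresholds)


# ---------------------------------------------------------------------------
# sharing classes

SHARING_CLASSES = ("trunk", "semi_private", "private")


def classify_sharing(
    matrix: PresenceMatrix, organoid_subset: list[str] | None = None
) -> pd.Series:
    """Per-variant sharing class over the organoid samples.

    Returns a Series indexed by variant id with values trunk / semi_private
    / private; variants present in no organoid are labelled ``unclassified``
    (e.g. biopsy-only variants).  With exactly two organoids, "trunk" and
    "shared" coincide and are reported as trunk.
    """
    organoids = organoid_subset or matrix.samples_with_role("organoid")
    if len(organoids) < 2:
        raise ValueError(
            "sharing classification needs >= 2 organoids: trunk/semi-private/"
            "private are defined by counts across multiple organoids"
        )
    present = matrix.present().loc[organoids]
    counts = present.sum(axis=0)
    n = len(organoids)

    def label(c: int) -> str:
        if c == 0:
            return "unclassified"
        if c == n:
            return "trunk"
        if c == 1:
            return "private"
        return "semi_private"

    return counts.map(label)


def sharing_counts(classes: pd.Series) -> dict[str, int]:
    out = {c: int((classes == c).sum()) for c in SHARING_CLASSES}
    out["unclassified"] = int((classes == "unclassified").sum())
    return out


def count_seeding_events(matrix: PresenceMatrix) -> int:
    """Lower bound on metastasis seeding events: the number of distinct
    variant-presence profiles among metastasis samples."""
    mets = matrix.samples_with_role("metastasis")
    if not mets:
        return 0
    present = matrix.present().loc[mets]
    profiles = {tuple(row) for _, row in present.iterrows()}
    return len(profiles)
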