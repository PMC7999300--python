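"""Bundled worked-example presence matrices.

Two small hand-built datasets exercise the sharing classification and the
phylogeny end of the pipeline without simulation:

* ``two_organoid_tumour`` — one tumour, two organoids; 14 shared and 8
  private substitutions (2 + 6 between the organoids).
* ``metastatic_tumour`` — seven organoids from two biopsies, two primary
  biopsies, and four metastatic lesions; character groups form a trunk with
  three branches, two of which nest further, plus two substitutions carried
  by a sample set that crosses the main split and cannot be placed.
"""

from __future__ import annotations

import pandas as pd

from .clonality import PresenceMatrix
from .variants import PresenceThresholds

ORGANOIDS_IV = ("O1A", "O1B", "O1C", "O2A", "O2B", "O2C", "O2D")
METS_IV = ("MT1", "MT2", "MT3", "MT4")
BIOPSIES_IV = ("PT1", "PT2")

#: character groups of the metastatic tumour: name -> (members, carrier samples)
METASTATIC_GROUPS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "SNS-TRUNK": (
        tuple(f"sns_trunk_{i}" for i in range(1, 5)),
        ORGANOIDS_IV + METS_IV,
    ),
    "CNA-TRUNK": (("cna_loss_chr13",), ORGANOIDS_IV + METS_IV),
    "SNS-B1": (
        tuple(f"sns_b1_{i}" for i in range(1, 9)),
        ("O2A",),
    ),
    "CNA-B2": (
        ("cna_gain_chr9", "cna_gain_chrX", "cna_loss_chr1", "cna_loss_chr9"),
        ("MT1",),
    ),
    "SNS-B3": (
        tuple(f"sns_b3_{i}" for i in range(1, 7)),
        ("O1A", "O1B", "O1C", "O2B", "O2C", "O2D", "MT2", "MT3", "MT4"),
    ),
    "SNS-B3A": (
        tuple(f"sns_b3a_{i}" for i in range(1, 5)),
        ("O1A", "MT2"),
    ),
    "CNA-B3A": (
        ("cna_gain_chr6", "cna_gain_chr8", "cna_gain_chr12"),
        ("O1A", "MT2"),
    ),
    "SNS-B3Aa": (
        tuple(f"sns_b3aa_{i}" for i in range(1, 7)),
        ("O1A",),
    ),
    "CNA-B3Aa": (("cna_gain_chr5",), ("O1A",)),
    "SNS-B3B": (
        ("sns_vnn2r99",),
        ("O1B", "O1C", "O2B", "O2C", "O2D", "MT3", "MT4"),
    ),
    "CNA-B3B": (
        ("cna_gain_chr11", "cna_loss_chr9b"),
        ("O1B", "O1C", "O2B", "O2C", "O2D", "MT3", "MT4"),
    ),
    "SNS-B3Ba": (
        tuple(f"sns_b3ba_{i}" for i in range(1, 8)),
        ("O1B",),
    ),
    "CNA-B3Ba": (("cna_gain_chr6b",), ("O1B",)),
    "SNS-B3Bb": (("sns_cntnap5b",), ("O1C", "O2B", "O2C", "O2D", "MT3", "MT4")),
    "SNS-B3Bb1": (("sns_b3bb1_1",), ("O2B", "O2C")),
    "SNS-B3Bb1a": (("sns_b3bb1a_1",), ("O2B",)),
    "SNS-B3Bb1b": (("sns_b3bb1b_1",), ("O2C",)),
    # carried by three organoids straddling the B3A/B3B split: unplaceable
    "SNS-CROSS": (("sns_ociad2", "sns_vmn1r119"), ("O1A", "O1B", "O1C")),
}

UNPLACEABLE_CHARACTERS = ("sns_ociad2", "sns_vmn1r119")


def _matrix(
    samples: dict[str, str],
    columns: list[str],
    presence: dict[str, set[str]],
    biopsy_tiers: dict[tuple[str, str], int] | None = None,
) -> PresenceMatrix:
    tiers = pd.DataFrame(0, index=list(samples), columns=columns, dtype=int)
    for col, carriers in presence.items():
        for s in carriers:
            tiers.loc[s, col] = 3
    for (s, col), tier in (biopsy_tiers or {}).items():
        tiers.loc[s, col] = tier
    return PresenceMatrix(tiers=tiers, roles=samples, thresholds=PresenceThresholds())


def two_organoid_tumour() -> PresenceMatrix:
    """Two organoids from one biopsy: 14 shared, 2 + 6 private SNSs."""
    columns = (
        [f"sns_shared_{i:02d}" for i in range(1, 15)]
        + [f"sns_o1_{i}" for i in range(1, 3)]
        + [f"sns_o2_{i}" for i in range(1, 7)]
    )
    presence = {c: {"O1", "O2"} for c in columns[:14]}
    presence.update({c: {"O1"} for c in columns[14:16]})
    presence.update({c: {"O2"} for c in columns[16:]})
    return _matrix({"O1": "organoid", "O2": "organoid"}, columns, presence)


def metastatic_tumour() -> PresenceMatrix:
    """Seven organoids, two primary biopsies, four metastatic lesions."""
    samples = {s: "organoid" for s in ORGANOIDS_IV}
    samples |= {s: "metastasis" for s in METS_IV}
    samples |= {s: "primary_biopsy" for s in BIOPSIES_IV}
    columns: list[str] = []
    presence: dict[str, set[str]] = {}
    for _name, (chars, carriers) in METASTATIC_GROUPS.items():
        for c in chars:
            columns.append(c)
            presence[c] = set(carriers)
    # biopsies: truncal variants strong, the large shared branch attenuated,
    # the crossing pair near-truncal frequency — display only, not classified
    biopsy_tiers: dict[tuple[str, str], int] = {}
    for b in BIOPSIES_IV:
        for c, carriers in presence.items():
            if c.startswith("sns_trunk") or c == "cna_loss_chr13":
                biopsy_tiers[(b, c)] = 3
            elif c.startswith("sns_b3_"):
                biopsy_tiers[(b, c)] = 2
            elif c in UNPLACEABLE_CHARACTERS:
                biopsy_tiers[(b, c)] = 3
    return _matrix(samples, columns, presence, biopsy_tiers)
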