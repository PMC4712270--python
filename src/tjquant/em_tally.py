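"""Tallying of categorical per-capillary ultrastructure annotations.

Electron-microscopy readouts of capillary state are recorded by a human
annotator as one categorical judgement per feature per image (luminal
membrane, tight junction, basal membrane, perivascular astroglia).  This
module validates those records and aggregates them into percentage tables by
brain region and experimental group, alongside capillary and image counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

REGIONS = ("frontal cortex", "hippocampus")
GROUPS = ("control", "1d", "3d", "21d")

#: feature name -> allowed categories
FEATURES: dict[str, tuple[str, ...]] = {
    "luminal_membrane": ("smooth", "protrusions"),
    "tight_junction": ("intact", "discontinuous"),
    "basal_membrane": ("intact", "increased_thickness", "detachment"),
    "astroglia": ("intact", "edematous"),
}


@dataclass(frozen=True)
class EMAnnotation:
    region: str
    group: str
    capillary_id: str
    image_id: str
    luminal_membrane: str
    tight_junction: str
    basal_membrane: str
    astroglia: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r} (allowed: {REGIONS})")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r} (allowed: {GROUPS})")
        for feat, allowed in FEATURES.items():
            val = getattr(self, feat)
            if val not in allowed:
                raise ValidationError(
                    f"record ({self.region}, {self.group}, {self.capillary_id}, "
                    f"{self.image_id}): {feat}={val!r} not in {allowed}"
                )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.region, self.group, self.capillary_id, self.image_id)


def validate_annotations(rows: Iterable[Mapping[str, str]] | pd.DataFrame) -> list[EMAnnotation]:
    """Parse and validate annotation rows; duplicates and bad vocab raise."""
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    required = ["region", "group", "capillary_id", "image_id", *FEATURES]
    out: list[EMAnnotation] = []
    seen: set[tuple[str, str, str, str]] = set()
    errors: list[str] = []
    for i, row in enumerate(rows):
        missing = [f for f in required if f not in row or pd.isna(row[f])]
        if missing:
            errors.append(f"row {i}: missing fields {missing}")
            continue
        try:
            ann = EMAnnotation(**{f: str(row[f]) for f in required})
        except ValidationError as exc:
            errors.append(f"row {i}: {exc}")
            continue
        if ann.key in seen:
            errors.append(f"row {i}: duplicate key {ann.key}")
            continue
        seen.add(ann.key)
        out.append(ann)
    if errors:
        raise ValidationError("; ".join(errors))
    return out


def tally(annotations: list[EMAnnotation], denominator: str = "image") -> pd.DataFrame:
    """Percentage of records per category, by region x group x feature.

    ``denominator='image'`` counts every annotated image; ``'capillary'``
    first collapses each capillary to its modal category per feature (ties
    broken by category order), matching per-capillary reporting.  Returns a
    tidy frame with exact fractions, integer percentages, counts, and the
    per-cell capillary/image totals.
    """
    if not annotations:
        raise ValidationError("annotation list is empty")
    if denominator not in ("image", "capillary"):
        raise ValidationError(f"denominator must be 'image' or 'capillary', got {denominator!r}")
    df = pd.DataFrame([vars(a) for a in annotations])
    rows = []
    for (region, group), cell in df.groupby(["region", "group"], sort=False):
        n_caps = cell["capillary_id"].nunique()
        n_imgs = len(cell)
        for feat, cats in FEATURES.items():
            if denominator == "image":
                counts = cell[feat].value_counts()
                denom = n_imgs
            else:
                modal = cell.groupby("capillary_id")[feat].agg(
                    lambda s: min(s.mode(), key=cats.index)
                )
                counts = modal.value_counts()
                denom = n_caps
            for cat in cats:
                k = int(counts.get(cat, 0))
                rows.append(
                    {
                        "region": region,
                        "group": group,
                        "feature": feat,
                        "category": cat,
                        "count": k,
                        "n_capillaries": n_caps,
                        "n_images": n_imgs,
                        "fraction": k / denom,
                        "percent": round(100.0 * k / denom),
                    }
                )
    return pd.DataFrame(rows)


def format_region_table(tallied: pd.DataFrame, region: str) -> pd.DataFrame:
    """Wide report for one region: capillary/image counts then one row per
    feature category, columns ordered control / 1d / 3d / 21d, integer
    percentages."""
    sub = tallied[tallied["region"] == region]
    if sub.empty:
        raise ValidationError(f"no tallied records for region {region!r}")
    groups = [g for g in GROUPS if g in set(sub["group"])]
    header_rows = {
        "Number of capillaries": {
            g: int(sub[sub["group"] == g]["n_capillaries"].iloc[0]) for g in groups
        },
        "Number of images": {
            g: int(sub[sub["group"] == g]["n_images"].iloc[0]) for g in groups
        },
    }
    body = {}
    for feat, cats in FEATURES.items():
        for cat in cats:
            row = {}
            for g in groups:
                m = sub[(sub["group"] == g) & (sub["feature"] == feat) & (sub["category"] == cat)]
                row[g] = f"{int(m['percent'].iloc[0])}%" if len(m) else ""
            body[f"{feat} / {cat}"] = row
    table = pd.DataFrame({**header_rows, **body}).T
    table.index.name = region
    return table[groups]
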