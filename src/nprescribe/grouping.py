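"""Canonical group keys and the leakage-free grouped split.

Deployment of a prescription rule means applying it to region/crop/season/year
combinations never seen during training, so evaluation partitions whole groups
rather than rows. Each record's grouping fields are normalized (trimmed,
lowercased, missing -> "unknown", year as a base-10 integer string) and
concatenated with "||" into a canonical key; its SHA-256 hex digest is the
platform-independent group identifier. Unique identifiers are sorted
lexicographically, shuffled with a fixed seed, and assigned greedily to
train/calibration/test against row-count targets (default 60/20/20), so every
row of a group lands in exactly one partition and the assignment is
reproducible across runs and platforms.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import normalize_category

PARTITIONS = ("train", "calibration", "test")


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class GroupKey:
    region: str
    crop_type: str
    year: str
    season: str

    @property
    def canonical(self) -> str:
        return "||".join([self.region, self.crop_type, self.year, self.season])


def _format_year(value) -> str:
    if value is None or pd.isna(value):
        return "unknown"
    try:
        return str(int(float(value)))
    except (TypeError, ValueError):
        return normalize_category(value)


def canonical_key(record) -> GroupKey:
    """Canonical group key of one record (mapping or Series)."""
    get = record.get if hasattr(record, "get") else record.__getitem__
    return GroupKey(
        region=normalize_category(get("Region")),
        crop_type=normalize_category(get("CropType")),
        year=_format_year(get("Year")),
        season=normalize_category(get("Season")),
    )


def group_id(key: GroupKey) -> str:
    """SHA-256 hex digest (64 lowercase chars) of the UTF-8 canonical key."""
    return hashlib.sha256(key.canonical.encode("utf-8")).hexdigest()


def table_group_ids(table: pd.DataFrame) -> pd.Series:
    """Group identifier per row."""
    keys = [
        group_id(
            GroupKey(
                normalize_category(r),
                normalize_category(c),
                _format_year(y),
                normalize_category(s),
            )
        )
        for r, c, y, s in zip(
            table["Region"], table["CropType"], table["Year"], table["Season"]
        )
    ]
    return pd.Series(keys, index=table.index, name="group_id")


@dataclass
class SplitAssignment:
    assignment: dict[str, str]
    seed: int
    proportions: tuple[float, float, float]
    row_counts: dict[str, int] = field(default_factory=dict)

    def partition_of(self, gid: str) -> str:
        return self.assignment[gid]

    def to_frame(self, group_sizes: dict[str, int] | None = None) -> pd.DataFrame:
        rows = [
            {
                "group_id": gid,
                "partition": part,
                "n_rows": (group_sizes or {}).get(gid),
            }
            for gid, part in sorted(self.assignment.items())
        ]
        return pd.DataFrame(rows)


def grouped_split(
    table: pd.DataFrame,
    seed: int = 42,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> SplitAssignment:
    """Assign every group to exactly one of train/calibration/test.

    Groups are sorted, shuffled with ``seed`` and accumulated greedily:
    a group goes to train while train is below its row target, then to
    calibration, then test. Permuting input row order does not change the
    result (sort-then-shuffle contract).
    """
    if not math.isclose(sum(proportions), 1.0, abs_tol=1e-9):
        raise SplitError("split proportions must sum to 1")
    gids = table_group_ids(table)
    sizes = gids.value_counts().to_dict()
    unique = sorted(sizes)
    if len(unique) < 3:
        raise SplitError(f"need at least 3 groups to split, got {len(unique)}")

    order = np.random.default_rng(seed).permutation(len(unique))
    shuffled = [unique[i] for i in order]

    n_total = len(table)
    targets = [p * n_total for p in proportions]
    assignment: dict[str, str] = {}
    filled = {p: 0 for p in PARTITIONS}
    for gid in shuffled:
        if filled["train"] < targets[0]:
            part = "train"
        elif filled["calibration"] < targets[1]:
            part = "calibration"
        else:
            part = "test"
        assignment[gid] = part
        filled[part] += sizes[gid]

    return SplitAssignment(
        assignment=assignment,
        seed=seed,
        proportions=proportions,
        row_counts=dict(filled),
    )


def partition_table(
    table: pd.DataFrame, assignment: SplitAssignment
) -> dict[str, pd.DataFrame]:
    """Materialize the three partitions of ``table``."""
    gids = table_group_ids(table)
    labels = gids.map(assignment.assignment)
    return {
        part: table.loc[labels == part].copy() for part in PARTITIONS
    }


def split_diagnostics(
    assignment: SplitAssignment,
    table: pd.DataFrame,
    small_group_threshold: int = 5,
) -> pd.DataFrame:
    """Group-size summary per partition.

    Reports min/median/mean/IQR/max group size plus the count of groups below
    ``small_group_threshold``; empty partitions yield NaN markers, not zeros.
    """
    gids = table_group_ids(table)
    labels = gids.map(assignment.assignment)
    rows = []
    for part in PARTITIONS:
        sizes = gids[labels == part].value_counts().to_numpy()
        if sizes.size == 0:
            rows.append(
                {
                    "partition": part,
                    "n_rows": 0,
                    "n_groups": 0,
                    "min": np.nan,
                    "median": np.nan,
                    "mean": np.nan,
                    "iqr": np.nan,
                    "max": np.nan,
                    "n_small_groups": np.nan,
                }
            )
            continue
        q1, q3 = np.percentile(sizes, [25, 75])
        rows.append(
            {
                "partition": part,
                "n_rows": int(sizes.sum()),
                "n_groups": int(sizes.size),
                "min": float(sizes.min()),
                "median": float(np.median(sizes)),
                "mean": float(sizes.mean()),
                "iqr": float(q3 - q1),
                "max": float(sizes.max()),
                "n_small_groups": int((sizes < small_group_threshold).sum()),
            }
        )
    return pd.DataFrame(rows)
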