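import hashlib
import struct

import numpy as np
import pandas as pd
import pytest

from nprescribe.grouping import (
    GroupKey,
    SplitError,
    canonical_key,
    group_id,
    grouped_split,
    partition_table,
    split_diagnostics,
    table_group_ids,
)

# ---------------------------------------------------------------------------
# compact pure-Python SHA-256 used as an independent reference implementation
# ---------------------------------------------------------------------------

_K = [
    0x428A2F98, 0x71374491, 0xB5C0FBCF, 0xE9B5DBA5, 0x3956C25B, 0x59F111F1,
    0x923F82A4, 0xAB1C5ED5, 0xD807AA98, 0x12835B01, 0x243185BE, 0x550C7DC3,
    0x72BE5D74, 0x80DEB1FE, 0x9BDC06A7, 0xC19BF174, 0xE49B69C1, 0xEFBE4786,
    0x0FC19DC6, 0x240CA1CC, 0x2DE92C6F, 0x4A7484AA, 0x5CB0A9DC, 0x76F988DA,
    0x983E5152, 0xA831C66D, 0xB00327C8, 0xBF597FC7, 0xC6E00BF3, 0xD5A79147,
    0x06CA6351, 0x14292967, 0x27B70A85, 0x2E1B2138, 0x4D2C6DFC, 0x53380D13,
    0x650A7354, 0x766A0ABB, 0x81C2C92E, 0x92722C85, 0xA2BFE8A1, 0xA81A664B,
    0xC24B8B70, 0xC76C51A3, 0xD192E819, 0xD6990624, 0xF40E3585, 0x106AA070,
    0x19A4C116, 0x1E376C08, 0x2748774C, 0x34B0BCB5, 0x391C0CB3, 0x4ED8AA4A,
    0x5B9CCA4F, 0x682E6FF3, 0x748F82EE, 0x78A5636F, 0x84C87814, 0x8CC70208,
    0x90BEFFFA, 0xA4506CEB, 0xBEF9A3F7, 0xC67178F2,
]


def _rotr(x, n):
    return ((x >> n) | (x << (32 - n))) & 0xFFFFFFFF


def reference_sha256(data: bytes) -> str:
    h = [
        0x6A09E667, 0xBB67AE85, 0x3C6EF372, 0xA54FF53A,
        0x510E527F, 0x9B05688C, 0x1F83D9AB, 0x5BE0CD19,
    ]
    length = len(data) * 8
    data += b"\x80" + b"\x00" * ((55 - len(data)) % 64) + struct.pack(">Q", length)
    for off in range(0, len(data), 64):
        w = list(struct.unpack(">16I", data[off : off + 64]))
        for i in range(16, 64):
            s0 = _rotr(w[i - 15], 7) ^ _rotr(w[i - 15], 18) ^ (w[i - 15] >> 3)
            s1 = _rotr(w[i - 2], 17) ^ _rotr(w[i - 2], 19) ^ (w[i - 2] >> 10)
            w.append((w[i - 16] + s0 + w[i - 7] + s1) & 0xFFFFFFFF)
        a, b, c, d, e, f, g, hh = h
        for i in range(64):
            s1 = _rotr(e, 6) ^ _rotr(e, 11) ^ _rotr(e, 25)
            ch = (e & f) ^ (~e & g)
            t1 = (hh + s1 + ch + _K[i] + w[i]) & 0xFFFFFFFF
            s0 = _rotr(a, 2) ^ _rotr(a, 13) ^ _rotr(a, 22)
            maj = (a & b) ^ (a & c) ^ (b & c)
            t2 = (s0 + maj) & 0xFFFFFFFF
            hh, g, f, e, d, c, b, a = g, f, e, (d + t1) & 0xFFFFFFFF, c, b, a, (t1 + t2) & 0xFFFFFFFF
        h = [(x + y) & 0xFFFFFFFF for x, y in zip(h, (a, b, c, d, e, f, g, hh))]
    return "".join(f"{x:08x}" for x in h)


def _group_table(group_specs):
    """Table with given (region, crop, year, season, n_rows) groups."""
    rows = []
    for region, crop, year, season, n in group_specs:
        for _ in range(n):
            rows.append(
                {"Region": region, "CropType": crop, "Year": year, "Season": season}
            )
    return pd.DataFrame(rows)


class TestCanonicalKey:
    def test_normalization(self):
        key = canonical_key(
            {"Region": " North ", "CropType": "Wheat", "Year": 2020, "Season": "Rabi"}
        )
        assert key.canonical == "north||wheat||2020||rabi"

    def test_missing_fields_become_unknown(self):
        key = canonical_key(
            {"Region": None, "CropType": "maize", "Year": 2021, "Season": "kharif"}
        )
        assert key.canonical == "unknown||maize||2021||kharif"

    def test_idempotent_across_formattings(self):
        a = canonical_key(
            {"Region": "NORTH", "CropType": "wheat ", "Year": 2020.0, "Season": "RABI"}
        )
        b = canonical_key(
            {"Region": " North ", "CropType": "Wheat", "Year": 2020, "Season": "Rabi"}
        )
        assert a.canonical == b.canonical


class TestGroupId:
    def test_matches_hashlib(self):
        key = GroupKey("north", "wheat", "2020", "rabi")
        expected = hashlib.sha256(b"north||wheat||2020||rabi").hexdigest()
        assert group_id(key) == expected

    def test_matches_independent_reference_implementation(self, rng):
        """Digest agreement with a from-scratch SHA-256 on random keys."""
        self_check = reference_sha256(b"abc")
        assert self_check == hashlib.sha256(b"abc").hexdigest()
        for _ in range(200):
            parts = [
                "".join(rng.choice(list("abcdefgh 123"), size=rng.integers(1, 10)))
                for _ in range(4)
            ]
            key = canonical_key(
                dict(zip(["Region", "CropType", "Year", "Season"], parts))
            )
            assert group_id(key) == reference_sha256(key.canonical.encode("utf-8"))

    def test_distinct_keys_distinct_digests(self):
        a = group_id(GroupKey("north", "wheat", "2020", "rabi"))
        b = group_id(GroupKey("north", "wheat", "2021", "rabi"))
        assert a != b
        assert len(a) == 64 and a == a.lower()


class TestGroupedSplit:
    def test_equal_groups_fill_targets(self):
        table = _group_table(
            [("r", c, 2020, "rabi", 20) for c in "abcde"]
        )
        assignment = grouped_split(table, seed=42)
        counts = assignment.row_counts
        assert counts == {"train": 60, "calibration": 20, "test": 20}

    def test_partitions_disjoint_and_exhaustive(self, small_table):
        table, _ = small_table
        assignment = grouped_split(table)
        parts = partition_table(table, assignment)
        gid_sets = [set(table_group_ids(t)) for t in parts.values()]
        assert sum(len(t) for t in parts.values()) == len(table)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (gid_sets[i] & gid_sets[j])

    def test_deterministic(self, small_table):
        table, _ = small_table
        a = grouped_split(table, seed=42)
        b = grouped_split(table, seed=42)
        assert a.assignment == b.assignment

    def test_row_order_invariance(self, small_table):
        """Sort-then-shuffle contract: permuting rows leaves the map fixed."""
        table, _ = small_table
        shuffled = table.sample(frac=1.0, random_state=9)
        a = grouped_split(table, seed=42)
        b = grouped_split(shuffled, seed=42)
        assert a.assignment == b.assignment

    def test_too_few_groups_rejected(self):
        table = _group_table([("r", "a", 2020, "rabi", 10), ("r", "b", 2020, "rabi", 10)])
        with pytest.raises(SplitError):
            grouped_split(table)


class TestSplitDiagnostics:
    def test_basic_statistics(self):
        table = _group_table(
            [
                ("r", "a", 2020, "rabi", 1),
                ("r", "b", 2020, "rabi", 2),
                ("r", "c", 2020, "rabi", 3),
                ("r", "d", 2020, "rabi", 5),
                ("r", "e", 2020, "rabi", 5),
            ]
        )
        assignment = grouped_split(table, seed=0)
        diag = split_diagnostics(assignment, table, small_group_threshold=2)
        total_groups = diag["n_groups"].sum()
        assert total_groups == 5
        row = diag.set_index("partition").loc["train"]
        assert row["min"] <= row["median"] <= row["max"]

    def test_empty_partition_reports_undefined(self):
        table = _group_table([("r", c, 2020, "rabi", 1) for c in "abc"])
        assignment = grouped_split(table, seed=0)
        # with 3 singleton groups each partition gets exactly one group;
        # force an empty partition by removing one group's rows
        gone = table_group_ids(table).iloc[0]
        keep = table_group_ids(table) != gone
        diag = split_diagnostics(assignment, table[keep])
        empty = diag[diag.n_groups == 0]
        assert len(empty) == 1
        assert empty[["min", "median", "mean", "iqr", "max"]].isna().all().all()

    def test_small_group_count(self):
        table = _group_table(
            [
                ("r", "a", 2020, "rabi", 1),
                ("r", "b", 2020, "rabi", 4),
                ("r", "c", 2020, "rabi", 4),
            ]
        )
        assignment = grouped_split(table, seed=0)
        diag = split_diagnostics(assignment, table, small_group_threshold=2)
        assert diag["n_small_groups"].sum() == 1
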