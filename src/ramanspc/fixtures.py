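"""Machine-readable transcriptions of the published cohort tables.

``table1.csv`` holds the cohort design (1-based spectrum-index ranges per
diagnostic class and patient counts); ``table2.json`` holds the published
cluster tree bookkeeping: hierarchical cluster ids, sizes, temperature
statistics, and full member lists for the four leaf clusters.  SHA-256
checksums guard the one-time transcription against accidental edits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .records import InputError

_TABLE1_SHA256 = "d2fcc03b68136ae41202d60a19fa5a3bf61810c479d060586f07378ca33a10c6"
_TABLE2_SHA256 = "e00b651212e26f7a169e5e748a541b74f81e0d3a6d44cf7c07eb2ff4c0a6a8f6"


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged fixture fails its checksum or invariants."""


@dataclass(frozen=True)
class CohortDesign:
    """Class ranges as 1-based inclusive index intervals."""

    ranges: tuple[tuple[int, int, str], ...]
    patients: dict[str, int]

    @property
    def n_total(self) -> int:
        return max(end for _, end, _ in self.ranges)


@dataclass(frozen=True)
class PrintedCluster:
    """One row of the published cluster table."""

    cluster_id: str
    size: int
    t_ferro: float | None
    t_cl: float | None
    s_t: float | None
    members: tuple[int, ...] | None  # absent for internal nodes

    @property
    def is_leaf(self) -> bool:
        return self.members is not None


def _read_text(name: str, expected_sha: str) -> str:
    text = resources.files("ramanspc.data").joinpath(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != expected_sha:
        raise FixtureIntegrityError(f"{name}: checksum mismatch ({digest})")
    return text


def load_table1() -> CohortDesign:
    """The cohort design: breast 1-160 (16 patients), cervical 161-310 (21),
    leukemia 311-352 (7)."""
    from io import StringIO

    df = pd.read_csv(StringIO(_read_text("table1.csv", _TABLE1_SHA256)))
    ranges = tuple(
        (int(r["start"]), int(r["end"]), str(r["class"])) for _, r in df.iterrows()
    )
    patients = {str(r["class"]): int(r["n_patients"]) for _, r in df.iterrows()}
    # ranges must be disjoint, contiguous, and cover 1..n
    expect = 1
    for start, end, _ in ranges:
        if start != expect or end < start:
            raise FixtureIntegrityError("class ranges not contiguous from 1")
        expect = end + 1
    return CohortDesign(ranges=ranges, patients=patients)


def load_table2() -> list[PrintedCluster]:
    """The published cluster tree: internal nodes 0, 1, 1 1 (sizes only) and
    leaves 1 1 1, 1 1 2, 1 2, 2 with full member lists."""
    data = json.loads(_read_text("table2.json", _TABLE2_SHA256))
    clusters = [
        PrintedCluster(
            cluster_id=c["id"],
            size=int(c["size"]),
            t_ferro=c["t_ferro"],
            t_cl=c["t_cl"],
            s_t=c["s_t"],
            members=tuple(c["members"]) if c["members"] is not None else None,
        )
        for c in data["clusters"]
    ]
    leaves = [c for c in clusters if c.is_leaf]
    seen: set[int] = set()
    for leaf in leaves:
        assert leaf.members is not None
        if len(leaf.members) != leaf.size:
            raise FixtureIntegrityError(f"cluster {leaf.cluster_id}: member count != size")
        if seen & set(leaf.members):
            raise FixtureIntegrityError("leaf member lists overlap")
        seen |= set(leaf.members)
    root = next(c for c in clusters if c.cluster_id == "0")
    if seen != set(range(1, root.size + 1)):
        raise FixtureIntegrityError("leaf union does not cover the cohort")
    return clusters


def class_of(index: int, design: CohortDesign) -> str:
    """Diagnostic class of a 1-based cohort spectrum index."""
    if not (1 <= index <= design.n_total):
        raise InputError(f"index {index} outside 1..{design.n_total}")
    for start, end, name in design.ranges:
        if start <= index <= end:
            return name
    raise InputError(f"index {index} not covered by any class range")


def composition(members: tuple[int, ...] | list[int], design: CohortDesign) -> dict[str, int]:
    """Per-class member counts for a list of 1-based cohort indices."""
    counts = {name: 0 for _, _, name in design.ranges}
    for idx in members:
        counts[class_of(idx, design)] += 1
    return counts


def fixture_report() -> pd.DataFrame:
    """Published cluster table joined with per-class composition counts."""
    design = load_table1()
    rows = []
    for c in load_table2():
        row = {
            "cluster": c.cluster_id,
            "size": c.size,
            "t_ferro": c.t_ferro,
            "t_cl": c.t_cl,
            "s_t": c.s_t,
        }
        if c.is_leaf:
            row.update(composition(c.members, design))
        rows.append(row)
    return pd.DataFrame(rows)
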