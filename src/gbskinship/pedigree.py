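"""Pedigree records and derived relationship pair groups."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Pedigree", "relationship_groups"]

UNKNOWN = ""


@dataclass
class Pedigree:
    """Sire/dam records: one row per individual, unknown parent = ''.

    The table has columns ``id``, ``sire``, ``dam`` (strings).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"pedigree table needs columns {sorted(required)}")
        tab = self.table.copy()
        for col in ("id", "sire", "dam"):
            tab[col] = tab[col].fillna(UNKNOWN).astype(str)
        if tab["id"].duplicated().any():
            dup = tab.loc[tab["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate individual id in pedigree: {dup!r}")
        self.table = tab.reset_index(drop=True)
        self._check_no_loops()

    def _check_no_loops(self) -> None:
        # an individual may not be its own ancestor
        parent_of = {
            r.id: {p for p in (r.sire, r.dam) if p != UNKNOWN}
            for r in self.table.itertuples()
        }
        for start in parent_of:
            seen = set()
            frontier = set(parent_of[start])
            while frontier:
                if start in frontier:
                    raise ValueError(f"pedigree loop involving {start!r}")
                seen |= frontier
                frontier = {
                    g for p in frontier for g in parent_of.get(p, ()) if g not in seen
                }

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def parents(self) -> list[str]:
        """Ids recorded as sire or dam of anyone, in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.table.itertuples():
            for p in (r.sire, r.dam):
                if p != UNKNOWN and p not in seen:
                    seen[p] = None
        return list(seen)

    def offspring(self) -> pd.DataFrame:
        """Rows with at least one recorded parent."""
        t = self.table
        return t[(t["sire"] != UNKNOWN) | (t["dam"] != UNKNOWN)]


def relationship_groups(ped: Pedigree) -> dict[str, list[tuple[str, str]]]:
    """Derive the standard pair groups used to benchmark a relatedness matrix.

    Returns a dict of group name -> list of (id, id) pairs:

    - ``self``: every individual with itself (uses the matrix diagonal);
    - ``full_sib``: unordered pairs sharing both recorded parents;
    - ``parent_offspring``: each recorded parent-child link;
    - ``between_parents``: all unordered pairs of distinct recorded parents.
    """
    groups: dict[str, list[tuple[str, str]]] = {
        "self": [(i, i) for i in ped.ids],
        "full_sib": [],
        "parent_offspring": [],
        "between_parents": [],
    }
    off = ped.offspring()
    by_parents: dict[tuple[str, str], list[str]] = {}
    for r in off.itertuples():
        if r.sire != UNKNOWN:
            groups["parent_offspring"].append((r.sire, r.id))
        if r.dam != UNKNOWN:
            groups["parent_offspring"].append((r.dam, r.id))
        if r.sire != UNKNOWN and r.dam != UNKNOWN:
            by_parents.setdefault((r.sire, r.dam), []).append(r.id)
    for sibs in by_parents.values():
        groups["full_sib"].extend(itertools.combinations(sibs, 2))
    groups["between_parents"] = list(itertools.combinations(ped.parents(), 2))
    empty = [g for g, pairs in groups.items() if not pairs]
    for g in empty:
        warnings.warn(f"relationship group {g!r} is empty", stacklevel=2)
    return groups
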