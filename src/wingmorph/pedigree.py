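"""Pedigree construction and additive genetic relatedness.

A two-generation full-sib half-sib breeding design produces a pedigree in
which wild-caught founders are assumed unrelated and non-inbred, so the
additive relationship matrix A contains only 0 (unrelated), 0.25 (paternal
half sibs), 0.5 (full sibs) off the diagonal and 1 on the diagonal.  The
implementation nevertheless uses the general recursive (tabular) method, so
arbitrary multi-generation pedigrees are handled; the breeding-design values
are the special case it must reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "RelatednessMatrix",
    "build_pedigree",
    "relatedness_matrix",
    "read_pedigree_csv",
    "write_pedigree_csv",
]

#: tokens in pedigree files that mean "parent unknown / founder"
MISSING_TOKENS = {"", "0", "NA", "na", "nan", "None"}


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree entry: an individual and its (possibly unknown) parents."""

    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.sire is None and self.dam is None


class PedigreeError(ValueError):
    """Invalid pedigree: duplicate ids, dangling parents or cycles."""


@dataclass
class Pedigree:
    """Validated, topologically ordered pedigree (parents before offspring).

    Attributes
    ----------
    ids : list of str
        Individual identifiers in topological order.
    sire_idx, dam_idx : ndarray of int
        Position of each individual's sire/dam in ``ids``; -1 for unknown.
    """

    ids: list
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    index: Mapping[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {iid: k for k, iid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> list:
        return [
            iid
            for iid, s, d in zip(self.ids, self.sire_idx, self.dam_idx)
            if s < 0 and d < 0
        ]

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire_idx < 0) & (self.dam_idx < 0)))


def _normalize_parent(value) -> Optional[str]:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    text = str(value).strip()
    if text in MISSING_TOKENS:
        return None
    return text


def build_pedigree(records: Iterable[PedigreeRecord]) -> Pedigree:
    """Validate records and return a topologically ordered :class:`Pedigree`.

    Raises
    ------
    PedigreeError
        On empty input, duplicate ids, references to absent parents, or
        ancestry cycles.
    """
    records = list(records)
    if not records:
        raise PedigreeError("empty pedigree")

    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        raise PedigreeError(f"duplicate id(s): {sorted(dups)}")

    by_id = {r.id: r for r in records}
    for r in records:
        for role, parent in (("sire", r.sire), ("dam", r.dam)):
            if parent is not None and parent not in by_id:
                raise PedigreeError(
                    f"missing parent: {role} {parent!r} of {r.id!r} "
                    "is not in the pedigree"
                )

    # Kahn topological sort; a leftover individual implies a cycle.
    order: list = []
    state = {i: 0 for i in ids}  # 0 unvisited, 1 on stack, 2 done

    def visit(iid: str) -> None:
        stack = [(iid, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            if state[node] == 2:
                continue
            if state[node] == 1:
                raise PedigreeError(f"cycle detected involving {node!r}")
            state[node] = 1
            stack.append((node, True))
            rec = by_id[node]
            for parent in (rec.sire, rec.dam):
                if parent is not None and state[parent] != 2:
                    if state[parent] == 1:
                        raise PedigreeError(
                            f"cycle detected involving {parent!r}"
                        )
                    stack.append((parent, False))

    for iid in ids:
        if state[iid] == 0:
            visit(iid)

    index = {iid: k for k, iid in enumerate(order)}
    sire_idx = np.empty(len(order), dtype=np.int64)
    dam_idx = np.empty(len(order), dtype=np.int64)
    for k, iid in enumerate(order):
        rec = by_id[iid]
        sire_idx[k] = index[rec.sire] if rec.sire is not None else -1
        dam_idx[k] = index[rec.dam] if rec.dam is not None else -1
    return Pedigree(ids=order, sire_idx=sire_idx, dam_idx=dam_idx, index=index)


@dataclass
class RelatednessMatrix:
    """Additive genetic relationship matrix over an ordered id list."""

    ids: list
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.ids), len(self.ids)):
            raise ValueError("A shape does not match ids")

    def loc(self, id_a: str, id_b: str) -> float:
        idx = {iid: k for k, iid in enumerate(self.ids)}
        return float(self.A[idx[id_a], idx[id_b]])

    def reorder(self, ids: Sequence[str]) -> "RelatednessMatrix":
        idx = {iid: k for k, iid in enumerate(self.ids)}
        sel = np.array([idx[i] for i in ids], dtype=np.int64)
        return RelatednessMatrix(ids=list(ids), A=self.A[np.ix_(sel, sel)])


def _tabular_A(pedigree: Pedigree) -> np.ndarray:
    """Full relationship matrix by the recursive tabular method.

    a_ij = 0.5 (a_{j,sire(i)} + a_{j,dam(i)}) for j earlier than i;
    a_ii = 1 + 0.5 a_{sire(i),dam(i)} (inbreeding from related parents).
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if i > 0:
            row = np.zeros(i)
            if si >= 0:
                row += 0.5 * A[si, :i]
            if di >= 0:
                row += 0.5 * A[di, :i]
            A[i, :i] = row
            A[:i, i] = row
        inb = 0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + inb
    return A


def relatedness_matrix(
    pedigree: Pedigree, subset: Optional[Sequence[str]] = None
) -> RelatednessMatrix:
    """Compute the additive relationship matrix A, optionally for a subset.

    The full matrix is computed by the tabular method (which requires
    ancestors), then restricted to ``subset`` in the given order.
    """
    if subset is not None:
        subset = list(subset)
        if not subset:
            raise ValueError("empty subset")
        missing = [i for i in subset if i not in pedigree.index]
        if missing:
            raise KeyError(f"subset ids not in pedigree: {missing[:5]}")
    A = _tabular_A(pedigree)
    full = RelatednessMatrix(ids=list(pedigree.ids), A=A)
    if subset is None:
        return full
    return full.reorder(subset)


def read_pedigree_csv(path) -> Pedigree:
    """Read a 3-column ``id,sire,dam`` CSV (founders: empty or 0 parents)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"pedigree file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    records = [
        PedigreeRecord(
            id=str(row.id).strip(),
            sire=_normalize_parent(row.sire),
            dam=_normalize_parent(row.dam),
        )
        for row in df.itertuples(index=False)
    ]
    return build_pedigree(records)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    rows = []
    for iid, s, d in zip(pedigree.ids, pedigree.sire_idx, pedigree.dam_idx):
        rows.append(
            {
                "id": iid,
                "sire": pedigree.ids[s] if s >= 0 else "",
                "dam": pedigree.ids[d] if d >= 0 else "",
            }
        )
    pd.DataFrame(rows, columns=["id", "sire", "dam"]).to_csv(path, index=False)
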