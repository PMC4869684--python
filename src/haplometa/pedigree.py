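"""Pedigree handling and the pedigree-derived relationship matrix.

The relationship matrix ``Phi`` has entries equal to twice the kinship
coefficient between pairs of individuals (1 on the diagonal for non-inbred
individuals, 0.5 for parent-offspring and full-sib pairs, 0 between
unrelated individuals).  It parameterises the polygenic covariance of the
linear mixed model ``Omega = sigma_a^2 * Phi + sigma_e^2 * I`` used by the
cohort-level haplotype regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedigreeRecord",
    "Pedigree",
    "RelationshipMatrix",
    "compute_relationship",
    "read_fam",
    "write_fam",
]

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, missing parent, duplicate id)."""


@dataclass(frozen=True)
class PedigreeRecord:
    family: str
    individual: str
    father: str | None  # None for founders
    mother: str | None
    sex: int  # 1 = male, 2 = female


@dataclass
class Pedigree:
    """A collection of pedigree records, possibly spanning many families.

    Invariants (validated on construction): ids unique within a family,
    non-founders have both parents present in the same family, and no
    individual is its own ancestor.
    """

    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {(r.family, r.individual): i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            raise PedigreeError("duplicate individual id within a family")
        self._validate()

    def _validate(self) -> None:
        for r in self.records:
            if (r.father is None) != (r.mother is None):
                raise PedigreeError(
                    f"individual {r.family}:{r.individual} has exactly one known parent"
                )
            for parent in (r.father, r.mother):
                if parent is not None and (r.family, parent) not in self._index:
                    raise PedigreeError(
                        f"parent {parent!r} of {r.family}:{r.individual} not in pedigree"
                    )
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[int]:
        """Indices ordered parents-before-offspring; raises on ancestry cycles."""
        order: list[int] = []
        state = np.zeros(len(self.records), dtype=np.int8)  # 0 new, 1 active, 2 done

        def visit(i: int) -> None:
            stack = [(i, False)]
            while stack:
                j, processed = stack.pop()
                if processed:
                    state[j] = 2
                    order.append(j)
                    continue
                if state[j] == 2:
                    continue
                if state[j] == 1:
                    raise PedigreeError(
                        f"cycle in pedigree at {self.records[j].family}:"
                        f"{self.records[j].individual}"
                    )
                state[j] = 1
                stack.append((j, True))
                r = self.records[j]
                for parent in (r.father, r.mother):
                    if parent is not None:
                        k = self._index[(r.family, parent)]
                        if state[k] == 1:
                            raise PedigreeError(
                                f"cycle in pedigree at {r.family}:{parent}"
                            )
                        if state[k] == 0:
                            stack.append((k, False))

        for i in range(len(self.records)):
            if state[i] == 0:
                visit(i)
        return order

    def __len__(self) -> int:
        return len(self.records)

    @property
    def individual_ids(self) -> list[str]:
        return [r.individual for r in self.records]

    def families(self) -> dict[str, list[PedigreeRecord]]:
        out: dict[str, list[PedigreeRecord]] = {}
        for r in self.records:
            out.setdefault(r.family, []).append(r)
        return out


@dataclass
class RelationshipMatrix:
    """Symmetric PSD matrix of twice-kinship coefficients with an id order."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("relationship matrix must be symmetric")

    def reorder(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        try:
            idx = np.array([pos[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message clarity
            raise KeyError(f"id {e.args[0]!r} not in relationship matrix") from None
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=float))


def compute_relationship(
    pedigree: Pedigree,
    ids: Sequence[str] | None = None,
    extra_singletons: Iterable[str] = (),
) -> RelationshipMatrix:
    """Build the relationship matrix (twice the kinship coefficient).

    Kinship is computed by the standard recursive algorithm assuming founders
    are unrelated and non-inbred.  ``ids`` selects and orders the output;
    ids listed there (or in ``extra_singletons``) that are absent from the
    pedigree are treated as singleton founders, so cohorts mixing families
    and unrelated subjects need only one call.
    """
    order = pedigree._toposort()
    records = pedigree.records
    n = len(records)
    # phi[i, j] holds the kinship coefficient between pedigree members i and j.
    phi = np.zeros((n, n))
    parent_idx = np.full((n, 2), -1, dtype=int)
    for i, r in enumerate(records):
        if r.father is not None:
            parent_idx[i, 0] = pedigree._index[(r.family, r.father)]
            parent_idx[i, 1] = pedigree._index[(r.family, r.mother)]

    for pos, i in enumerate(order):
        f, m = parent_idx[i]
        if f < 0:
            phi[i, i] = 0.5
        else:
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
        for j in order[:pos]:
            if f < 0:
                k = 0.0  # founder: unrelated to anyone processed earlier
            else:
                k = 0.5 * (phi[f, j] + phi[m, j])
            phi[i, j] = phi[j, i] = k

    all_ids = pedigree.individual_ids
    mat = 2.0 * phi
    extras = [s for s in extra_singletons if s not in set(all_ids)]
    if extras:
        full = np.eye(n + len(extras))
        full[:n, :n] = mat
        mat = full
        all_ids = all_ids + list(extras)

    result = RelationshipMatrix(all_ids, mat)
    if ids is not None:
        known = set(all_ids)
        missing = [s for s in ids if s not in known]
        if missing:
            # phenotyped subjects absent from the pedigree: singleton founders
            full = np.eye(len(all_ids) + len(missing))
            full[: len(all_ids), : len(all_ids)] = result.values
            result = RelationshipMatrix(all_ids + missing, full)
        result = result.reorder(ids)
    return result


def read_fam(path: str | Path) -> Pedigree:
    """Read a whitespace-delimited FAM/PED-style file.

    Columns: family id, individual id, father id, mother id, sex
    (1=male, 2=female); ``0`` marks a missing parent.  Extra columns
    (phenotype etc.) are ignored.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 5:
                raise PedigreeError(f"malformed pedigree line: {line!r}")
            fam, iid, fid, mid, sex = parts[:5]
            records.append(
                PedigreeRecord(
                    family=fam,
                    individual=iid,
                    father=None if fid == MISSING_PARENT else fid,
                    mother=None if mid == MISSING_PARENT else mid,
                    sex=int(sex),
                )
            )
    return Pedigree(records)


def write_fam(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in pedigree.records:
            fh.write(
                f"{r.family}\t{r.individual}\t{r.father or MISSING_PARENT}\t"
                f"{r.mother or MISSING_PARENT}\t{r.sex}\n"
            )
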