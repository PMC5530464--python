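"""Shared element catalog: the coding/promoter/enhancer test units.

Both recurrence tests (SNV and SV) score the same universe of elements:
coding spans (CDS), promoter windows and distal enhancers, each attributed
to a gene. The catalog holds one vectorised overlap index per
(class, chromosome) so assignment and the permutation nulls share one code
path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval, InputError, IntervalIndex, normalize_chrom

ELEMENT_CLASSES = ("CDS", "promoter", "enhancer")


@dataclass(frozen=True, slots=True)
class Element:
    element_id: str
    interval: GenomicInterval
    klass: str  # CDS | promoter | enhancer
    gene: str  # attributed gene id ("" when unlinked)

    def __post_init__(self) -> None:
        if self.klass not in ELEMENT_CLASSES:
            raise InputError(f"unknown element class {self.klass!r}")


class ElementCatalog:
    """Overlap-indexed element collection, one index per (class, chrom)."""

    def __init__(self, elements: Sequence[Element]):
        self.elements = list(elements)
        self._by_class_chrom: dict[tuple[str, str], tuple[IntervalIndex, np.ndarray]] = {}
        groups: dict[tuple[str, str], list[int]] = {}
        for i, el in enumerate(self.elements):
            groups.setdefault((el.klass, el.interval.chrom), []).append(i)
        for key, idxs in groups.items():
            starts = [self.elements[i].interval.start for i in idxs]
            ends = [self.elements[i].interval.end for i in idxs]
            self._by_class_chrom[key] = (
                IntervalIndex(starts, ends),
                np.asarray(idxs, dtype=np.int64),
            )

    def __len__(self) -> int:
        return len(self.elements)

    def of_class(self, klass: str) -> list[Element]:
        return [el for el in self.elements if el.klass == klass]

    def query(self, klass: str, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of class elements overlapping [start, end)."""
        entry = self._by_class_chrom.get((klass, chrom))
        if entry is None:
            return np.empty(0, dtype=np.int64)
        index, global_idx = entry
        return global_idx[index.query(start, end)]

    def query_many(
        self, klass: str, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(query_idx, global_element_idx) overlap pairs for a query batch."""
        entry = self._by_class_chrom.get((klass, chrom))
        if entry is None:
            e = np.empty(0, dtype=np.int64)
            return e, e
        index, global_idx = entry
        qidx, iidx = index.query_many(starts, ends)
        return qidx, global_idx[iidx]


def read_elements(path: str | os.PathLike, chr_prefix: bool = True) -> ElementCatalog:
    """Element BED: chrom, start, end, element_id, class, gene."""
    names = ["chrom", "start", "end", "element_id", "klass", "gene"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, comment="#",
                     dtype={"chrom": str, "element_id": str, "klass": str, "gene": str})
    elements = []
    for row in df.itertuples(index=False):
        elements.append(
            Element(
                element_id=row.element_id,
                interval=GenomicInterval(
                    normalize_chrom(row.chrom, chr_prefix), int(row.start), int(row.end)
                ),
                klass=row.klass,
                gene="" if pd.isna(row.gene) else str(row.gene),
            )
        )
    return ElementCatalog(elements)


def write_elements(path: str | os.PathLike, catalog: ElementCatalog) -> None:
    with open(path, "w") as fh:
        for el in catalog.elements:
            fh.write(
                f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}"
                f"\t{el.element_id}\t{el.klass}\t{el.gene}\n"
            )
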