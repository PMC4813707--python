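"""Target-gene co-occupancy: proxy-set construction, pairwise overlaps,
3-way Venn partitions and the partition -> filter chain.

Gene identity is the uppercased symbol string; lists are consumed as
published (no alias or ortholog resolution, no peak-to-gene assignment).
Percentages are rounded half-up to integers, matching the reporting style of
the source literature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "GeneSet",
    "VennPartition3",
    "read_gene_set",
    "make_gene_set",
    "proxy_set",
    "overlap_percent",
    "venn3",
    "shared_fraction_of_partners",
    "partition_filter_chain",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized (uppercased, deduplicated) gene symbols."""

    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def make_gene_set(name: str, genes: Iterable[str]) -> GeneSet:
    """Normalize an iterable of symbols into a :class:`GeneSet`."""
    normalized = frozenset(g.strip().upper() for g in genes if g and g.strip())
    return GeneSet(name=name, genes=normalized)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a gene list: one symbol per line; blanks and ``#`` comments skipped.

    An empty result triggers a warning, not an error.
    """
    path = Path(path)
    symbols = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.strip().startswith("#")
    ]
    gs = make_gene_set(name or path.stem, symbols)
    if not gs.genes:
        warnings.warn(f"gene list {path} produced an empty set", stacklevel=2)
    return gs


def proxy_set(sets: list[GeneSet], name: str) -> GeneSet:
    """Intersection of >= 2 gene sets, used as a complex-binding proxy."""
    if len(sets) < 2:
        raise ValueError("proxy_set needs at least 2 sets")
    genes = frozenset.intersection(*(s.genes for s in sets))
    return GeneSet(name=name, genes=genes)


def overlap_percent(reference: GeneSet, other: GeneSet) -> tuple[int, int, int]:
    """``(shared, reference_size, percent)`` where percent is the half-up-rounded
    share of *reference* also present in *other*."""
    if not reference.genes:
        raise ValueError(f"reference set {reference.name!r} is empty")
    shared = len(reference.genes & other.genes)
    ref = len(reference.genes)
    return shared, ref, _round_half_up(100.0 * shared / ref)


@dataclass(frozen=True)
class VennPartition3:
    """Exclusive region counts of three named sets A, B, C."""

    names: tuple[str, str, str]
    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    def __post_init__(self) -> None:
        if any(
            c < 0
            for c in (
                self.a_only, self.b_only, self.c_only,
                self.ab_only, self.ac_only, self.bc_only, self.abc,
            )
        ):
            raise ValueError("partition counts must be nonnegative")

    @property
    def union_size(self) -> int:
        return (
            self.a_only + self.b_only + self.c_only
            + self.ab_only + self.ac_only + self.bc_only + self.abc
        )

    def set_total(self, role: str) -> int:
        """Total size of one input set, recovered from its 4 regions."""
        if role == "a":
            return self.a_only + self.ab_only + self.ac_only + self.abc
        if role == "b":
            return self.b_only + self.ab_only + self.bc_only + self.abc
        if role == "c":
            return self.c_only + self.ac_only + self.bc_only + self.abc
        raise ValueError(f"role must be 'a', 'b' or 'c', got {role!r}")


def venn3(a: GeneSet, b: GeneSet, c: GeneSet) -> VennPartition3:
    """Counts of the 7 exclusive regions of three gene sets."""
    sa, sb, sc = a.genes, b.genes, c.genes
    return VennPartition3(
        names=(a.name, b.name, c.name),
        a_only=len(sa - sb - sc),
        b_only=len(sb - sa - sc),
        c_only=len(sc - sa - sb),
        ab_only=len((sa & sb) - sc),
        ac_only=len((sa & sc) - sb),
        bc_only=len((sb & sc) - sa),
        abc=len(sa & sb & sc),
    )


def shared_fraction_of_partners(partition: VennPartition3, complex_set_role: str = "a") -> int:
    """Percent of complex loci bound by either partner that are bound by both.

    With the complex proxy in role *complex_set_role* and the two partners in
    the remaining roles, this is ``100 * ABC / (AB + AC + ABC)`` (half-up
    rounded), where AB and AC are the exclusive two-way regions involving the
    complex set.
    """
    role = complex_set_role.lower()
    if role == "a":
        pairwise = partition.ab_only + partition.ac_only
    elif role == "b":
        pairwise = partition.ab_only + partition.bc_only
    elif role == "c":
        pairwise = partition.ac_only + partition.bc_only
    else:
        raise ValueError(f"complex_set_role must be 'a', 'b' or 'c', got {complex_set_role!r}")
    denom = pairwise + partition.abc
    if denom == 0:
        raise ValueError("no complex loci bound by either partner (zero denominator)")
    return _round_half_up(100.0 * partition.abc / denom)


def partition_filter_chain(
    partition_genes: GeneSet, filter_set: GeneSet
) -> tuple[GeneSet, int]:
    """Reduce a combined partition gene set to members of *filter_set*.

    Returns the filtered set and the half-up-rounded percent retained.
    """
    if not partition_genes.genes:
        raise ValueError("partition gene set is empty")
    filtered = GeneSet(
        name=f"{partition_genes.name}&{filter_set.name}",
        genes=partition_genes.genes & filter_set.genes,
    )
    percent = _round_half_up(100.0 * len(filtered.genes) / len(partition_genes.genes))
    return filtered, percent
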