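"""Constant-region marker vectors and their explanation.

The three C-gene isotypes are nearly identical; what varies across observed
cDNAs is a small set of marker positions (in the sheep data, 14: twelve in
exon 1, two in exon 3).  Per animal each isotype should contribute at most
two germline alleles, yet repertoires show more distinct marker vectors
than alleles.  The excess is explained parsimoniously as either an exon
swap — the exon-1 block of one allele joined to the exon-3 block of another
(alternative cis/trans splicing of the third exon) — or a recombinant — a
single-crossover hybrid of two alleles, possibly of different isotypes
(somatic recombinational diversification).  Preference order is fixed:
allele > exon_swap > recombinant > novel, so a vector that matches a
germline allele exactly is never reported as a hybrid.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .germline import MarkerTable

__all__ = [
    "MarkerVector",
    "AlleleSet",
    "VariantExplanation",
    "extract_vector",
    "collect_marker_vectors",
    "explain_variant",
    "explain_repertoire",
    "load_alleles",
]

VARIANT_CLASSES = ("allele", "exon_swap", "recombinant", "novel")


def load_alleles(layout_path) -> "AlleleSet":
    """Read germline allele vectors from a locus layout file's ``alleles`` block."""
    import yaml

    with open(layout_path) as handle:
        layout = yaml.safe_load(handle)
    if "alleles" not in layout:
        raise ValueError(f"{layout_path} carries no alleles block")
    return AlleleSet(
        alleles={
            str(iso): {str(name): str(vec) for name, vec in vecs.items()}
            for iso, vecs in layout["alleles"].items()
        }
    )


@dataclass(frozen=True)
class MarkerVector:
    """Bases observed at the marker positions of one clone group.

    Positions not covered by the sequenced portion are recorded as ``N``
    and match any donor base during explanation.
    """

    isotype: str
    vector: str
    count: int = 1
    tissue: str | None = None
    animal: str | None = None

    def __post_init__(self) -> None:
        if any(b not in "ACGTN" for b in self.vector):
            raise ValueError(f"marker vector may contain only A/C/G/T/N, got {self.vector!r}")


@dataclass(frozen=True)
class AlleleSet:
    """Germline allele marker vectors, up to two per isotype per animal."""

    alleles: Mapping[str, Mapping[str, str]]  # isotype -> {allele_name: vector}

    def __post_init__(self) -> None:
        lengths = {len(v) for vecs in self.alleles.values() for v in vecs.values()}
        if len(lengths) > 1:
            raise ValueError(f"allele vectors have inconsistent lengths: {sorted(lengths)}")
        for isotype, vecs in self.alleles.items():
            if not 1 <= len(vecs) <= 2:
                raise ValueError(f"{isotype}: expected 1 or 2 alleles, got {len(vecs)}")

    def items(self) -> Iterator[tuple[str, str, str]]:
        """Yield (allele_name, isotype, vector) in deterministic order."""
        for isotype in sorted(self.alleles):
            for name in sorted(self.alleles[isotype]):
                yield name, isotype, self.alleles[isotype][name]

    def vector_of(self, allele_name: str) -> str:
        for name, _iso, vec in self.items():
            if name == allele_name:
                return vec
        raise KeyError(f"unknown allele {allele_name!r}")


@dataclass(frozen=True)
class VariantExplanation:
    observed: MarkerVector
    klass: str
    donors: tuple[str, ...]
    breakpoint: tuple[int, int] | None = None  # crossover after marker k, k in [lo, hi] (1-based)


def extract_vector(c_portion: str, markers: MarkerTable) -> str:
    """Read the marker-position bases out of a C portion (``N`` beyond its end)."""
    return "".join(
        c_portion[m.position - 1] if m.position <= len(c_portion) else "N" for m in markers.markers
    )


def collect_marker_vectors(
    clones: Iterable[tuple[str, str] | tuple[str, str, str | None, str | None]],
    markers: MarkerTable,
) -> list[MarkerVector]:
    """Census of distinct (isotype, vector[, tissue, animal]) groups with counts.

    ``clones`` yields ``(isotype, c_portion)`` or ``(isotype, c_portion,
    tissue, animal)`` tuples; the c_portion may already be a marker vector
    (detected by length).  Counts sum to the number of input clones.
    """
    counter: Counter[tuple] = Counter()
    for entry in clones:
        isotype, portion = entry[0], entry[1]
        tissue = entry[2] if len(entry) > 2 else None
        animal = entry[3] if len(entry) > 3 else None
        vector = portion if len(portion) == len(markers) else extract_vector(portion, markers)
        counter[(isotype, vector, tissue, animal)] += 1
    return [
        MarkerVector(isotype=iso, vector=vec, count=n, tissue=t, animal=a)
        for (iso, vec, t, a), n in sorted(counter.items())
    ]


def _matches(observed: str, donor: str, start: int = 0, end: int | None = None) -> bool:
    end = len(observed) if end is None else end
    return all(o == "N" or o == d for o, d in zip(observed[start:end], donor[start:end]))


def explain_variant(
    observed: MarkerVector, alleles: AlleleSet, markers: MarkerTable
) -> VariantExplanation:
    """Minimal explanation of an observed marker vector.

    Checks, in order: exact allele match; exon swap (first-exon block from
    one allele, remaining block from another); single-crossover recombinant
    (one switch point anywhere except the exon boundary, which is the swap
    case); otherwise novel.  The recombinant breakpoint is reported as the
    maximal feasible interval [lo, hi], meaning the crossover lies after
    marker k for some k in that range.
    """
    n = len(markers)
    vec = observed.vector
    entries = list(alleles.items())
    same_iso_first = sorted(entries, key=lambda e: (e[1] != observed.isotype, e[0]))

    for name, _iso, donor in same_iso_first:
        if _matches(vec, donor):
            return VariantExplanation(observed=observed, klass="allele", donors=(name,))

    blocks = markers.region_blocks()
    regions = list(blocks)
    if len(regions) >= 2:
        boundary = blocks[regions[0]][-1] + 1  # first marker index of the second region
        for a_name, _ai, a_vec in same_iso_first:
            if not _matches(vec, a_vec, 0, boundary):
                continue
            for b_name, _bi, b_vec in same_iso_first:
                if b_name != a_name and _matches(vec, b_vec, boundary, n):
                    return VariantExplanation(
                        observed=observed, klass="exon_swap", donors=(a_name, b_name)
                    )
    else:
        boundary = n  # single-region marker tables admit no exon swap

    for a_name, _ai, a_vec in same_iso_first:
        left = 0
        while left < n and (vec[left] == "N" or vec[left] == a_vec[left]):
            left += 1
        # crossover after marker k possible for k <= left
        for b_name, _bi, b_vec in same_iso_first:
            if b_name == a_name:
                continue
            right = n
            while right > 0 and (vec[right - 1] == "N" or vec[right - 1] == b_vec[right - 1]):
                right -= 1
            # suffix from b feasible for any split k >= right
            lo, hi = max(right, 1), min(left, n - 1)
            ks = [k for k in range(lo, hi + 1) if k != boundary]
            if ks:
                return VariantExplanation(
                    observed=observed,
                    klass="recombinant",
                    donors=(a_name, b_name),
                    breakpoint=(min(ks), max(ks)),
                )

    return VariantExplanation(observed=observed, klass="novel", donors=())


def explain_repertoire(
    vectors: Iterable[MarkerVector], alleles: AlleleSet, markers: MarkerTable
) -> pd.DataFrame:
    """Variant-explanation table for a census of marker vectors."""
    rows = []
    for v in vectors:
        exp = explain_variant(v, alleles, markers)
        rows.append(
            {
                "isotype": v.isotype,
                "vector": v.vector,
                "count": v.count,
                "tissue": v.tissue or "",
                "animal": v.animal or "",
                "class": exp.klass,
                "donors": ";".join(exp.donors),
                "breakpoint_lo": exp.breakpoint[0] if exp.breakpoint else "",
                "breakpoint_hi": exp.breakpoint[1] if exp.breakpoint else "",
            }
        )
    return pd.DataFrame(rows)
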