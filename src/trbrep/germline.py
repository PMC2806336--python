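"""Germline model of a multi-cluster TR beta D-J-C locus.

The T-cell receptor beta locus of ruminants carries, downstream of the V gene
library, several tandem D-J-C clusters, each composed of a single diversity
(D) gene, an ordered set of joining (J) genes and one constant (C) gene.  In
sheep there are three such clusters whose genomic order (1, 3, 2) does not
follow their historical numbering; that order is what decides whether a given
D-J joining or J-C splice is topologically ordinary or requires a trans
event.  This module holds the validated in-memory representation of such a
locus — genes, clusters, genomic ranks — together with the table of
diagnostic marker positions in the constant region, plus the layout/FASTA
round-trip used to load a user-supplied reference or the synthetic fixture.

Coordinates are 0-based half-open internally; layout files and reports use
1-based inclusive positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GermlineGene",
    "Cluster",
    "Marker",
    "MarkerTable",
    "LocusModel",
    "LocusError",
    "UnknownClusterError",
    "load_locus",
    "write_locus",
    "upstream_of",
    "fgxg_offset",
]

_ACGT = frozenset("ACGT")
_KINDS = frozenset({"D", "J", "C"})


class LocusError(ValueError):
    """A germline layout or sequence violates a locus invariant."""


class UnknownClusterError(KeyError):
    """A cluster id was looked up that does not exist in the locus."""


@dataclass(frozen=True)
class GermlineGene:
    """A single germline D, J or C gene.

    For C genes ``exons`` partitions the spliced cDNA sequence into exon
    intervals (0-based half-open); D and J genes have no partition.
    """

    name: str
    kind: str
    cluster_id: str
    sequence: str
    functional: bool = True
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise LocusError(f"{self.name}: kind must be one of {sorted(_KINDS)}, got {self.kind!r}")
        if not self.sequence:
            raise LocusError(f"{self.name}: empty sequence")
        for i, base in enumerate(self.sequence):
            if base not in _ACGT:
                raise LocusError(f"{self.name}: non-ACGT character {base!r} at position {i + 1}")
        if self.kind == "D" and len(self.sequence) < 4:
            raise LocusError(f"{self.name}: D gene shorter than 4 nt makes the assignment rule vacuous")
        if self.kind == "C":
            if not self.exons:
                raise LocusError(f"{self.name}: C gene requires at least one exon interval")
            pos = 0
            for start, end in self.exons:
                if start != pos or end <= start:
                    raise LocusError(f"{self.name}: exon partition must tile the sequence contiguously")
                pos = end
            if pos != len(self.sequence):
                raise LocusError(f"{self.name}: exon partition does not cover the sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@lru_cache(maxsize=512)
def _fgxg_offset_of(sequence: str) -> int:
    """Nucleotide offset of the F codon of the unique F-G-X-G motif.

    The motif anchors the 3' end of the CDR3; it must occur exactly once
    across the three forward reading frames of the germline J sequence.
    """
    hits: list[int] = []
    for frame in range(3):
        trimmed = sequence[frame : frame + 3 * ((len(sequence) - frame) // 3)]
        if len(trimmed) < 12:
            continue
        aa = str(Seq(trimmed).translate())
        for m in re.finditer(r"(?=FG.G)", aa):
            hits.append(frame + 3 * m.start())
    if len(hits) != 1:
        raise LocusError(f"expected exactly one FGXG motif in J sequence, found {len(hits)}")
    return hits[0]


def fgxg_offset(gene: GermlineGene) -> int:
    if gene.kind != "J":
        raise LocusError(f"{gene.name}: FGXG motif is only defined for J genes")
    try:
        return _fgxg_offset_of(gene.sequence)
    except LocusError as exc:
        raise LocusError(f"{gene.name}: {exc}") from None


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    d_gene: GermlineGene
    j_genes: tuple[GermlineGene, ...]
    c_gene: GermlineGene
    genomic_rank: int

    def __post_init__(self) -> None:
        if self.d_gene.kind != "D" or self.c_gene.kind != "C":
            raise LocusError(f"cluster {self.cluster_id}: D/C slots hold wrong gene kinds")
        if not self.j_genes:
            raise LocusError(f"cluster {self.cluster_id}: at least one J gene required")
        for j in self.j_genes:
            if j.kind != "J":
                raise LocusError(f"cluster {self.cluster_id}: {j.name} is not a J gene")
        for g in (self.d_gene, self.c_gene, *self.j_genes):
            if g.cluster_id != self.cluster_id:
                raise LocusError(
                    f"cluster {self.cluster_id}: member {g.name} is annotated for cluster {g.cluster_id}"
                )

    @property
    def genes(self) -> tuple[GermlineGene, ...]:
        return (self.d_gene, *self.j_genes, self.c_gene)


@dataclass(frozen=True)
class Marker:
    """One diagnostic variable position of the constant region.

    ``position`` is 1-based, counted from the first nucleotide of the C
    portion in the spliced cDNA.  ``states`` optionally maps an allele name
    to the base it carries at this position.
    """

    region: str
    position: int
    states: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise LocusError(f"marker position must be >= 1, got {self.position}")
        if self.states is not None and len(set(self.states.values())) < 2:
            raise LocusError(f"marker at {self.region}:{self.position} needs >= 2 distinct states")


@dataclass(frozen=True)
class MarkerTable:
    """Variable positions of the C region and the isotype-diagnostic subset.

    ``diagnostics`` maps each C-gene name to the bases it carries at the
    diagnostic positions ({position: base}); jointly these must distinguish
    every isotype from every other.
    """

    markers: tuple[Marker, ...]
    diagnostics: Mapping[str, Mapping[int, str]]

    def __post_init__(self) -> None:
        positions = [m.position for m in self.markers]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise LocusError("marker positions must be strictly increasing")
        marker_pos = set(positions)
        isotypes = sorted(self.diagnostics)
        diag_pos: set[int] = set()
        for iso in isotypes:
            diag_pos |= set(self.diagnostics[iso].keys())
        if not diag_pos <= marker_pos:
            raise LocusError("isotype diagnostic positions must be a subset of marker positions")
        for a in isotypes:
            for b in isotypes:
                if a < b and all(
                    self.diagnostics[a].get(p) == self.diagnostics[b].get(p) for p in diag_pos
                ):
                    raise LocusError(f"diagnostics do not distinguish {a} from {b}")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.markers)

    def region_blocks(self) -> dict[str, tuple[int, ...]]:
        """Marker indices (0-based into ``markers``) grouped by exon region."""
        blocks: dict[str, list[int]] = {}
        for i, m in enumerate(self.markers):
            blocks.setdefault(m.region, []).append(i)
        return {k: tuple(v) for k, v in blocks.items()}

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class LocusModel:
    """Validated multi-cluster D-J-C locus."""

    clusters: tuple[Cluster, ...]
    species_label: str = ""
    provenance: str = ""
    marker_table: MarkerTable | None = None
    _by_name: dict[str, GermlineGene] = field(init=False, repr=False)
    _cluster_by_id: dict[str, Cluster] = field(init=False, repr=False)
    _cluster_of: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.clusters = tuple(self.clusters)
        self._by_name = {}
        self._cluster_by_id = {}
        self._cluster_of = {}
        ranks = sorted(c.genomic_rank for c in self.clusters)
        if ranks != list(range(1, len(self.clusters) + 1)):
            raise LocusError(f"genomic ranks must be a permutation of 1..{len(self.clusters)}, got {ranks}")
        for cluster in self.clusters:
            if cluster.cluster_id in self._cluster_by_id:
                raise LocusError(f"duplicate cluster id {cluster.cluster_id}")
            self._cluster_by_id[cluster.cluster_id] = cluster
            for gene in cluster.genes:
                if gene.name in self._by_name:
                    raise LocusError(f"duplicate gene name {gene.name}")
                self._by_name[gene.name] = gene
                self._cluster_of[gene.name] = cluster.cluster_id
        if self.marker_table is not None:
            c_names = {c.c_gene.name for c in self.clusters}
            missing = c_names - set(self.marker_table.diagnostics)
            if missing:
                raise LocusError(f"marker table lacks diagnostics for isotypes: {sorted(missing)}")

    # -- lookups -----------------------------------------------------------
    def gene(self, name: str) -> GermlineGene:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown gene {name!r}") from None

    def cluster(self, cluster_id: str) -> Cluster:
        try:
            return self._cluster_by_id[cluster_id]
        except KeyError:
            raise UnknownClusterError(f"unknown cluster {cluster_id!r}") from None

    def cluster_of(self, gene_name: str) -> str:
        if gene_name not in self._cluster_of:
            raise KeyError(f"unknown gene {gene_name!r}")
        return self._cluster_of[gene_name]

    def genes(self, kind: str | None = None) -> tuple[GermlineGene, ...]:
        out = []
        for cluster in self.clusters:
            for gene in cluster.genes:
                if kind is None or gene.kind == kind:
                    out.append(gene)
        return tuple(out)

    def j_census(self) -> dict[str, int]:
        return {c.cluster_id: len(c.j_genes) for c in self.clusters}

    def clusters_by_rank(self) -> tuple[Cluster, ...]:
        return tuple(sorted(self.clusters, key=lambda c: c.genomic_rank))

    def upstream_of(self, a: str, b: str) -> bool:
        """True iff cluster ``a`` lies strictly 5' of cluster ``b``."""
        return self.cluster(a).genomic_rank < self.cluster(b).genomic_rank


def upstream_of(locus: LocusModel, a: str, b: str) -> bool:
    return locus.upstream_of(a, b)


# ---------------------------------------------------------------------------
# layout + FASTA round trip
# ---------------------------------------------------------------------------

def _parse_description(record) -> dict[str, str]:
    tokens: dict[str, str] = {}
    for token in record.description.split()[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            tokens[key] = value
    return tokens


def _genes_from_fasta(fasta_path: str | Path) -> dict[str, GermlineGene]:
    genes: dict[str, GermlineGene] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in genes:
            raise LocusError(f"duplicate gene name {record.id} in {fasta_path}")
        tokens = _parse_description(record)
        if "kind" not in tokens or "cluster" not in tokens:
            raise LocusError(f"{record.id}: FASTA description must carry kind= and cluster= tokens")
        exons = None
        if "exons" in tokens:
            lengths = [int(x) for x in tokens["exons"].split(",")]
            bounds, pos = [], 0
            for length in lengths:
                bounds.append((pos, pos + length))
                pos += length
            exons = tuple(bounds)
        genes[record.id] = GermlineGene(
            name=record.id,
            kind=tokens["kind"],
            cluster_id=tokens["cluster"],
            sequence=str(record.seq).upper(),
            functional=tokens.get("functional", "1") not in ("0", "false", "False"),
            exons=exons,
        )
    return genes


def _marker_table_from_layout(layout: Mapping) -> MarkerTable | None:
    if "markers" not in layout:
        return None
    markers = tuple(
        Marker(
            region=str(m["region"]),
            position=int(m["position"]),
            states={str(k): str(v) for k, v in m["states"].items()} if m.get("states") else None,
        )
        for m in layout["markers"]
    )
    diagnostics = {
        str(iso): {int(p): str(b) for p, b in bases.items()}
        for iso, bases in layout.get("isotype_diagnostics", {}).items()
    }
    return MarkerTable(markers=markers, diagnostics=diagnostics)


def load_locus(layout_path: str | Path, fasta_path: str | Path) -> LocusModel:
    """Instantiate a :class:`LocusModel` from a layout file plus germline FASTA.

    Raises :class:`LocusError` naming the offending gene for missing genes,
    duplicate names or non-ACGT characters.
    """
    with open(layout_path) as handle:
        layout = yaml.safe_load(handle)
    genes = _genes_from_fasta(fasta_path)

    def take(name: str, kind: str, cluster_id: str) -> GermlineGene:
        if name not in genes:
            raise LocusError(f"gene {name} named in layout is missing from {fasta_path}")
        gene = genes[name]
        if gene.kind != kind:
            raise LocusError(f"gene {name}: layout expects kind {kind}, FASTA says {gene.kind}")
        if gene.cluster_id != cluster_id:
            raise LocusError(
                f"gene {name}: layout places it in cluster {cluster_id}, FASTA says {gene.cluster_id}"
            )
        return gene

    clusters = []
    for spec in layout["clusters"]:
        cid = str(spec["id"])
        clusters.append(
            Cluster(
                cluster_id=cid,
                d_gene=take(spec["d"], "D", cid),
                j_genes=tuple(take(name, "J", cid) for name in spec["j"]),
                c_gene=take(spec["c"], "C", cid),
                genomic_rank=int(spec["genomic_rank"]),
            )
        )
    used = {g.name for c in clusters for g in c.genes}
    unused = set(genes) - used
    if unused:
        raise LocusError(f"FASTA genes not referenced by the layout: {sorted(unused)}")
    for gene in genes.values():
        if gene.kind == "J":
            fgxg_offset(gene)  # validates presence/uniqueness of the motif
    return LocusModel(
        clusters=tuple(clusters),
        species_label=str(layout.get("species", "")),
        provenance=str(layout.get("provenance", "")),
        marker_table=_marker_table_from_layout(layout),
    )


def write_locus(
    locus: LocusModel,
    layout_path: str | Path,
    fasta_path: str | Path,
    alleles: Mapping[str, Mapping[str, str]] | None = None,
) -> None:
    """Serialize a locus back to layout + FASTA (inverse of :func:`load_locus`)."""
    records = []
    for gene in locus.genes():
        desc = f"kind={gene.kind} cluster={gene.cluster_id}"
        if not gene.functional:
            desc += " functional=0"
        if gene.exons:
            desc += " exons=" + ",".join(str(e - s) for s, e in gene.exons)
        records.append(SeqRecord(Seq(gene.sequence), id=gene.name, description=desc))
    SeqIO.write(records, str(fasta_path), "fasta")

    layout: dict = {
        "species": locus.species_label,
        "provenance": locus.provenance,
        "clusters": [
            {
                "id": c.cluster_id,
                "genomic_rank": c.genomic_rank,
                "d": c.d_gene.name,
                "j": [j.name for j in c.j_genes],
                "c": c.c_gene.name,
            }
            for c in locus.clusters
        ],
    }
    if locus.marker_table is not None:
        layout["markers"] = [
            {"region": m.region, "position": m.position, **({"states": dict(m.states)} if m.states else {})}
            for m in locus.marker_table.markers
        ]
        layout["isotype_diagnostics"] = {
            iso: {int(p): b for p, b in bases.items()}
            for iso, bases in locus.marker_table.diagnostics.items()
        }
    if alleles is not None:
        layout["alleles"] = {iso: dict(vecs) for iso, vecs in alleles.items()}
    with open(layout_path, "w") as handle:
        yaml.safe_dump(layout, handle, sort_keys=False)
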