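"""Topology classification of D-J rearrangements and J-C splices.

With the genomic order of the D-J-C clusters known, every annotated clone
can be classified without further alignment:

* recombination — a D joined to a J of its own cluster is ``intra_cluster``;
  to a J of a downstream cluster, ``inter_cluster`` (ordinary deletional
  joining); to a J of an *upstream* cluster, ``trans_rearrangement``, which
  on a single chromatid could only arise by inversion and is more plausibly
  an inter-chromatid event (the two mechanisms are indistinguishable in
  cDNA, so a single class carries a note naming both);

* splicing — a J spliced to its own cluster's C is ``canonical``; to a
  downstream C, ``cis_splice`` (alternative splicing of one precursor); to
  an upstream C, ``trans_splice``, which requires a second precursor RNA.

The C isotype itself is called from the diagnostic nucleotide positions at
the N-terminus of the constant portion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .germline import LocusModel, MarkerTable

__all__ = [
    "EventCall",
    "IsotypeCall",
    "TruncatedCError",
    "classify_rearrangement",
    "classify_splice",
    "call_c_isotype",
    "classify_clone",
    "classify_records",
]

REARRANGEMENT_CLASSES = ("intra_cluster", "inter_cluster", "trans_rearrangement", "no_d")
SPLICE_CLASSES = ("canonical", "cis_splice", "trans_splice")

TRANS_NOTE = "chromosomal inversion or trans-rearrangement (indistinguishable in cDNA)"


class TruncatedCError(ValueError):
    """The C portion does not cover all isotype-diagnostic positions."""


def classify_rearrangement(d_cluster: str | None, j_cluster: str, locus: LocusModel) -> str:
    """Classify a D-J joining by cluster topology; ``d_cluster=None`` means no D call."""
    if d_cluster is None:
        return "no_d"
    if d_cluster == j_cluster:
        locus.cluster(d_cluster)  # raises on unknown id
        return "intra_cluster"
    if locus.upstream_of(d_cluster, j_cluster):
        return "inter_cluster"
    return "trans_rearrangement"


def classify_splice(j_cluster: str, c_cluster: str, locus: LocusModel) -> str:
    """Classify a J-C pairing by cluster topology."""
    if j_cluster == c_cluster:
        locus.cluster(j_cluster)
        return "canonical"
    if locus.upstream_of(j_cluster, c_cluster):
        return "cis_splice"
    return "trans_splice"


@dataclass(frozen=True)
class IsotypeCall:
    gene: str | None
    status: str  # ok | ambiguous | novel
    matched: tuple[str, ...] = ()
    observed: tuple[str, ...] = ()


def call_c_isotype(c_portion: str, markers: MarkerTable) -> IsotypeCall:
    """Call the C isotype from the diagnostic positions of the C portion.

    Positions are 1-based from the first nucleotide of the constant region
    in the cDNA.  An ambiguous diagnostic vector is reported as such, never
    defaulted; a vector matching no isotype is flagged ``novel``.
    """
    positions = sorted({p for bases in markers.diagnostics.values() for p in bases})
    missing = [p for p in positions if p > len(c_portion)]
    if missing:
        raise TruncatedCError(f"C portion truncated before diagnostic position(s) {missing}")
    observed = {p: c_portion[p - 1] for p in positions}
    matched = [
        iso
        for iso, bases in sorted(markers.diagnostics.items())
        if all(observed[p] == b for p, b in bases.items())
    ]
    obs = tuple(observed[p] for p in positions)
    if len(matched) == 1:
        return IsotypeCall(gene=matched[0], status="ok", matched=tuple(matched), observed=obs)
    if matched:
        return IsotypeCall(gene=None, status="ambiguous", matched=tuple(matched), observed=obs)
    return IsotypeCall(gene=None, status="novel", matched=(), observed=obs)


@dataclass(frozen=True)
class EventCall:
    transcript_id: str
    rearrangement_class: str
    splice_class: str
    c_isotype: str
    notes: str = ""


def classify_clone(
    transcript_id: str,
    d_gene: str | None,
    j_gene: str,
    c_gene: str,
    locus: LocusModel,
) -> EventCall:
    """Classify one clone given its gene calls (table-driven entry point)."""
    d_cluster = locus.cluster_of(d_gene) if d_gene else None
    j_cluster = locus.cluster_of(j_gene)
    c_cluster = locus.cluster_of(c_gene)
    rearr = classify_rearrangement(d_cluster, j_cluster, locus)
    splice = classify_splice(j_cluster, c_cluster, locus)
    return EventCall(
        transcript_id=transcript_id,
        rearrangement_class=rearr,
        splice_class=splice,
        c_isotype=c_gene,
        notes=TRANS_NOTE if rearr == "trans_rearrangement" else "",
    )


def classify_records(df: pd.DataFrame, locus: LocusModel) -> pd.DataFrame:
    """Append rearrangement_class / splice_class columns to an annotated table.

    Expects ``d_gene`` (empty string for no D), ``j_gene`` and ``c_gene``
    columns; returns a copy.
    """
    out = df.copy()
    calls = [
        classify_clone(
            str(row.get("clone_id", row.get("sequence_id", i))),
            row["d_gene"] or None,
            row["j_gene"],
            row["c_gene"],
            locus,
        )
        for i, row in out.iterrows()
    ]
    out["rearrangement_class"] = [c.rearrangement_class for c in calls]
    out["splice_class"] = [c.splice_class for c in calls]
    return out
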