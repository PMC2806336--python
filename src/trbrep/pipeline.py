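"""End-to-end orchestration: annotate, call isotypes, classify events.

Thin glue between the junction, event and constant-region modules; the CLI
and the test suite both run through here so that a repertoire FASTA turns
into one AIRR-style table with per-record failure reasons rather than
silent drops.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .constant import extract_vector
from .events import TruncatedCError, call_c_isotype, classify_rearrangement, classify_splice
from .germline import LocusModel, MarkerTable
from .junctions import (
    JunctionAnnotation,
    Transcript,
    VAnchorSpec,
    annotate_repertoire,
    to_airr,
)

__all__ = ["read_transcripts", "run_pipeline"]


def read_transcripts(
    fasta_path: str | Path, sample_sheet: pd.DataFrame | None = None
) -> list[Transcript]:
    """Load transcripts from FASTA, optionally merging a sample sheet (id -> tissue/animal)."""
    meta: dict[str, dict] = {}
    if sample_sheet is not None:
        for _, row in sample_sheet.iterrows():
            meta[str(row["id"])] = {
                "tissue": row.get("tissue"),
                "animal": row.get("animal"),
            }
    transcripts = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        info = meta.get(record.id, {})
        transcripts.append(
            Transcript(
                id=record.id,
                sequence=str(record.seq).upper(),
                tissue=info.get("tissue"),
                animal=info.get("animal"),
            )
        )
    if not transcripts:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return transcripts


def _event_columns(
    transcript: Transcript, annotation: JunctionAnnotation, locus: LocusModel, markers: MarkerTable | None
) -> dict[str, object]:
    cols: dict[str, object] = {}
    d_cluster = locus.cluster_of(annotation.d_call.gene) if annotation.d_call.gene else None
    j_cluster = locus.cluster_of(annotation.j_gene)
    cols["rearrangement_class"] = classify_rearrangement(d_cluster, j_cluster, locus)
    if markers is not None:
        c_portion = transcript.sequence[annotation.c_start :].upper()
        try:
            iso = call_c_isotype(c_portion, markers)
        except TruncatedCError as exc:
            cols["c_call"] = ""
            cols["c_status"] = f"truncated: {exc}"
            return cols
        cols["c_call"] = iso.gene or ""
        cols["c_status"] = iso.status
        cols["c_vector"] = extract_vector(c_portion, markers)
        if iso.gene is not None:
            cols["splice_class"] = classify_splice(j_cluster, locus.cluster_of(iso.gene), locus)
    return cols


def run_pipeline(
    transcripts: Sequence[Transcript],
    locus: LocusModel,
    anchor: VAnchorSpec | None = None,
    markers: MarkerTable | None = None,
    **annotate_kwargs,
) -> tuple[pd.DataFrame, list[JunctionAnnotation]]:
    """Annotate a repertoire and classify every clone's topology and isotype.

    Returns the AIRR-style table (one row per input record, failures
    included with reasons) and the raw annotations for callers that need
    the full decomposition objects.
    """
    markers = markers if markers is not None else locus.marker_table
    annotations, failures = annotate_repertoire(transcripts, locus, anchor, **annotate_kwargs)
    by_id = {t.id: t for t in transcripts}
    extra = {
        a.transcript_id: _event_columns(by_id[a.transcript_id], a, locus, markers)
        for a in annotations
    }
    table = to_airr(annotations, failures, extra_columns=extra)
    return table, annotations
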