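"""CDR3 junction extraction and V-N1-D-N2-J decomposition.

Each transcript covers the 3' end of a V gene (anchored on a conserved
amino-acid motif ending at the second conserved cysteine, position 104),
the hypervariable CDR3 junction, a J gene and the start of a C gene.  The
CDR3 runs from the codon after the anchor cysteine up to, but not
including, the codon of the J-gene FGXG phenylalanine.

Decomposition follows maximal germline attribution:

* the J gene is the germline J whose 5'-trimmed suffix matches the
  transcript exactly (longest match wins);
* the D gene is assigned when a stretch of at least ``min_run`` (default 4)
  consecutive nucleotides matches a germline D; the exact seed is then
  extended outward, optionally tolerating recorded substitutions and a
  single indel;
* nucleotides between the V-derived prefix, the D segment and the J prefix
  that match no template are reported as N additions (N1, N2).

Ambiguity is surfaced, never resolved silently: equal-best D matches yield
no call plus the candidate list (or follow an explicit priority order), and
transcripts with zero or multiple anchor hits raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineGene, LocusModel, fgxg_offset

__all__ = [
    "VAnchorSpec",
    "Transcript",
    "DCall",
    "Cdr3Extraction",
    "JunctionAnnotation",
    "AnchorError",
    "JAssignmentError",
    "JunctionError",
    "extract_cdr3",
    "assign_d",
    "decompose_junction",
    "annotate_transcript",
    "annotate_repertoire",
    "cdr3_length",
    "to_airr",
]

D_PRIORITY_DEFAULT = ("TRBD1", "TRBD3", "TRBD2")


class JunctionError(ValueError):
    """Base class for junction-analysis failures."""


class AnchorError(JunctionError):
    """The V anchor motif is absent or occurs more than once."""


class JAssignmentError(JunctionError):
    """No germline J suffix matches the transcript, or the best match is ambiguous."""


@dataclass(frozen=True)
class VAnchorSpec:
    """V-gene anchor used to locate the start of the CDR3.

    ``motif_aa`` must contain the designated conserved cysteine at
    ``cys_index``; the CDR3 starts at the codon after it.  Optional
    ``v_end_suffixes`` are germline V-gene continuations (nucleotides
    following the motif) used to attribute the junction prefix to the V
    gene; without them the V-retained part is the anchor tail only and N1
    absorbs the rest.
    """

    motif_aa: str = "YLCASS"
    cys_index: int = 2
    v_end_suffixes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.cys_index < len(self.motif_aa)) or self.motif_aa[self.cys_index] != "C":
            raise ValueError(f"anchor motif {self.motif_aa!r} has no cysteine at index {self.cys_index}")

    @property
    def tail_len_nt(self) -> int:
        """Nucleotides of the motif that fall inside the CDR3 (after the cysteine)."""
        return 3 * (len(self.motif_aa) - self.cys_index - 1)


@dataclass
class Transcript:
    id: str
    sequence: str
    tissue: str | None = None
    animal: str | None = None


@dataclass(frozen=True)
class DCall:
    """D-gene assignment for one junction.

    ``start``/``end`` delimit the observed D-derived segment inside the
    searched region (0-based half-open).  Trims count germline nucleotides
    removed from the 5' and 3' ends; substitutions are (offset-in-germline,
    germline-base, observed-base); indels are (offset, "ins"|"del").
    """

    gene: str | None
    start: int = 0
    end: int = 0
    five_prime_trim: int = 0
    three_prime_trim: int = 0
    substitutions: tuple[tuple[int, str, str], ...] = ()
    indels: tuple[tuple[int, str], ...] = ()
    candidates: tuple[str, ...] = ()

    @property
    def matched_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Cdr3Extraction:
    transcript_id: str
    cdr3_nt: str
    cdr3_aa: str | None
    j_gene: str
    j_trim: int
    frame: int
    cdr3_start: int
    j_start: int
    c_start: int
    productive: bool
    flags: tuple[str, ...]


@dataclass(frozen=True)
class JunctionAnnotation:
    """Full per-transcript junction decomposition.

    The concatenation ``anchor_tail + v_retained + n1 + d_observed + n2 +
    j_retained`` reconstructs ``cdr3_nt`` byte-exactly (test-guarded).
    """

    transcript_id: str
    anchor_tail: str
    v_retained: str
    n1: str
    d_call: DCall
    d_observed: str
    n2: str
    j_gene: str
    j_five_prime_trim: int
    j_retained: str
    cdr3_nt: str
    cdr3_aa: str | None
    productive: bool
    flags: tuple[str, ...]
    j_start: int
    c_start: int
    tissue: str | None = None

    @property
    def cdr3_len_nt(self) -> int:
        return len(self.cdr3_nt)

    @property
    def cdr3_len_aa(self) -> int:
        if self.cdr3_len_nt % 3:
            raise JunctionError(f"{self.transcript_id}: CDR3 length {self.cdr3_len_nt} nt is not a codon multiple")
        return self.cdr3_len_nt // 3


def cdr3_length(annotation: JunctionAnnotation) -> int:
    """CDR3 length in amino acids (includes the three anchor-tail residues)."""
    return annotation.cdr3_len_aa


# ---------------------------------------------------------------------------
# anchor + J assignment
# ---------------------------------------------------------------------------

def _find_anchor(seq: str, anchor: VAnchorSpec) -> tuple[int, int]:
    """Locate the anchor motif across the three frames; return (frame, aa_pos)."""
    hits: list[tuple[int, int]] = []
    for frame in range(3):
        trimmed = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
        aa = str(Seq(trimmed).translate()) if len(trimmed) >= 3 else ""
        start = 0
        while True:
            pos = aa.find(anchor.motif_aa, start)
            if pos < 0:
                break
            hits.append((frame, pos))
            start = pos + 1
    if not hits:
        raise AnchorError(f"anchor motif {anchor.motif_aa} not found in any frame")
    if len(hits) > 1:
        raise AnchorError(f"anchor motif {anchor.motif_aa} found {len(hits)} times; transcript is ambiguous")
    return hits[0]


def extract_cdr3(
    transcript: Transcript,
    locus: LocusModel,
    anchor: VAnchorSpec | None = None,
    min_j_suffix: int = 6,
) -> Cdr3Extraction:
    """Delimit the CDR3 and assign the J gene by exact trimmed-suffix match.

    The J call scans every germline J over every 5' trim (longest retained
    suffix of at least ``min_j_suffix`` nt wins); the CDR3 ends at the codon
    of that gene's FGXG phenylalanine.  A frameshifted or stop-containing
    CDR3 is flagged nonproductive rather than rejected.
    """
    anchor = anchor or VAnchorSpec()
    seq = transcript.sequence.upper()
    frame, aa_pos = _find_anchor(seq, anchor)
    cdr3_start = frame + 3 * (aa_pos + anchor.cys_index + 1)
    search_from = cdr3_start + anchor.tail_len_nt

    best: tuple[int, GermlineGene, int, int] | None = None  # (matched_len, gene, trim, pos)
    tied: list[str] = []
    for gene in locus.genes("J"):
        gseq = gene.sequence
        for trim in range(0, len(gseq) - min_j_suffix + 1):
            pos = seq.find(gseq[trim:], search_from)
            if pos >= 0:
                matched = len(gseq) - trim
                if best is None or matched > best[0]:
                    best = (matched, gene, trim, pos)
                    tied = [gene.name]
                elif matched == best[0] and gene.name != best[1].name:
                    tied.append(gene.name)
                break  # first (smallest) trim is the longest match for this gene
    if best is None:
        raise JAssignmentError(f"{transcript.id}: no germline J suffix of >= {min_j_suffix} nt matches")
    if len(tied) > 1:
        raise JAssignmentError(f"{transcript.id}: ambiguous J assignment among {sorted(tied)}")
    matched, gene, trim, j_start = best
    f_nt = fgxg_offset(gene)
    if trim > f_nt:
        raise JAssignmentError(f"{transcript.id}: J trim {trim} reaches past the FGXG phenylalanine")
    cdr3_end = j_start + (f_nt - trim)
    cdr3_nt = seq[cdr3_start:cdr3_end]
    c_start = j_start + (len(gene.sequence) - trim)

    flags: list[str] = []
    cdr3_aa: str | None = None
    productive = False
    if len(cdr3_nt) % 3:
        flags.append("out_of_frame")
    else:
        cdr3_aa = str(Seq(cdr3_nt).translate())
        if "*" in cdr3_aa:
            flags.append("stop_in_cdr3")
        else:
            productive = True
    return Cdr3Extraction(
        transcript_id=transcript.id,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        j_gene=gene.name,
        j_trim=trim,
        frame=frame,
        cdr3_start=cdr3_start,
        j_start=j_start,
        c_start=c_start,
        productive=productive,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# D assignment: exact longest-run seed, optional substitution/indel extension
# ---------------------------------------------------------------------------

def _longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """(length, start_in_a, start_in_b) of the longest common substring.

    Ties resolve to the smallest start_in_a, then smallest start_in_b, so
    the result is deterministic and reproducible by brute force.
    """
    best = (0, 0, 0)
    if not a or not b:
        return best
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                run = prev[j - 1] + 1
                cur[j] = run
                cand = (run, i - run, j - run)
                if run > best[0]:
                    best = cand
        prev = cur
    return best


def _extend(
    region: str, germ: str, r0: int, d0: int, k: int, lookahead: int = 3
) -> tuple[int, int, int, int, list[tuple[int, str, str]], list[tuple[int, str]]]:
    """Extend an exact seed outward, recording substitutions and at most one indel.

    A mismatch is accepted as a substitution only when the next ``lookahead``
    positions on both sides match exactly, which keeps genuinely
    non-templated (N) nucleotides out of the D segment.
    """
    subs: list[tuple[int, str, str]] = []
    indels: list[tuple[int, str]] = []
    gap_used = False

    def run_matches(ri: int, gi: int, step: int) -> bool:
        for off in range(1, lookahead + 1):
            r, g = ri + step * off, gi + step * off
            if r < 0 or g < 0 or r >= len(region) or g >= len(germ):
                return False
            if region[r] != germ[g]:
                return False
        return True

    # leftward
    ri, gi = r0 - 1, d0 - 1
    while ri >= 0 and gi >= 0:
        if region[ri] == germ[gi]:
            ri -= 1
            gi -= 1
        elif run_matches(ri, gi, -1):
            subs.append((gi, germ[gi], region[ri]))
            ri -= 1
            gi -= 1
        elif not gap_used and gi >= 1 and region[ri] == germ[gi - 1] and run_matches(ri, gi - 1, -1):
            indels.append((gi, "del"))
            gap_used = True
            gi -= 1
        elif not gap_used and ri >= 1 and region[ri - 1] == germ[gi] and run_matches(ri - 1, gi, -1):
            indels.append((gi, "ins"))
            gap_used = True
            ri -= 1
        else:
            break
    r_lo, d_lo = ri + 1, gi + 1

    # rightward
    ri, gi = r0 + k, d0 + k
    while ri < len(region) and gi < len(germ):
        if region[ri] == germ[gi]:
            ri += 1
            gi += 1
        elif run_matches(ri, gi, +1):
            subs.append((gi, germ[gi], region[ri]))
            ri += 1
            gi += 1
        elif not gap_used and gi + 1 < len(germ) and region[ri] == germ[gi + 1] and run_matches(ri, gi + 1, +1):
            indels.append((gi, "del"))
            gap_used = True
            gi += 1
        elif not gap_used and ri + 1 < len(region) and region[ri + 1] == germ[gi] and run_matches(ri + 1, gi, +1):
            indels.append((gi, "ins"))
            gap_used = True
            ri += 1
        else:
            break
    r_hi, d_hi = ri, gi
    subs.sort()
    return r_lo, r_hi, d_lo, d_hi, subs, indels


def assign_d(
    region: str,
    locus: LocusModel,
    min_run: int = 4,
    extend_substitutions: bool = True,
    tie_policy: str = "none",
    priority: Sequence[str] = D_PRIORITY_DEFAULT,
) -> DCall:
    """Assign the D gene of a junction region by the >= ``min_run`` rule.

    The longest exact common substring with each germline D is the seed;
    the gene with the longest seed of at least ``min_run`` nt wins.  Equal
    best seeds across genes yield no call with the candidates listed
    (``tie_policy='none'``) or follow ``priority`` (``tie_policy='priority'``).
    Absence of any qualifying D is a valid outcome, not an error.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if tie_policy not in ("none", "priority"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    seeds: list[tuple[int, int, int, GermlineGene]] = []
    for gene in locus.genes("D"):
        length, r_start, d_start = _longest_common_substring(region, gene.sequence)
        if length >= min_run:
            seeds.append((length, r_start, d_start, gene))
    if not seeds:
        return DCall(gene=None)
    best_len = max(s[0] for s in seeds)
    winners = [s for s in seeds if s[0] == best_len]
    if len(winners) > 1:
        names = tuple(sorted(w[3].name for w in winners))
        if tie_policy == "none":
            return DCall(gene=None, candidates=names)
        order = {name: i for i, name in enumerate(priority)}
        winners.sort(key=lambda s: order.get(s[3].name, len(order)))
    length, r0, d0, gene = winners[0]
    if extend_substitutions:
        r_lo, r_hi, d_lo, d_hi, subs, indels = _extend(region, gene.sequence, r0, d0, length)
    else:
        r_lo, r_hi, d_lo, d_hi, subs, indels = r0, r0 + length, d0, d0 + length, [], []
    return DCall(
        gene=gene.name,
        start=r_lo,
        end=r_hi,
        five_prime_trim=d_lo,
        three_prime_trim=len(gene.sequence) - d_hi,
        substitutions=tuple(subs),
        indels=tuple(indels),
        candidates=(gene.name,),
    )


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _v_retained(middle: str, anchor: VAnchorSpec) -> str:
    """Longest junction prefix attributable to a supplied germline V end."""
    best = 0
    for suffix in anchor.v_end_suffixes:
        n = 0
        for a, b in zip(middle, suffix):
            if a != b:
                break
            n += 1
        best = max(best, n)
    return middle[:best]


def decompose_junction(
    transcript: Transcript,
    extraction: Cdr3Extraction,
    locus: LocusModel,
    anchor: VAnchorSpec | None = None,
    min_run: int = 4,
    extend_substitutions: bool = True,
    tie_policy: str = "none",
    priority: Sequence[str] = D_PRIORITY_DEFAULT,
) -> JunctionAnnotation:
    """Split the CDR3 into anchor tail, V-retained, N1, D, N2 and J parts."""
    anchor = anchor or VAnchorSpec()
    seq = transcript.sequence.upper()
    tail = anchor.tail_len_nt
    middle_start = extraction.cdr3_start + tail
    if extraction.j_start < middle_start:
        raise JAssignmentError(
            f"{transcript.id}: J match begins inside the anchor tail; junction is not decomposable"
        )
    anchor_tail = seq[extraction.cdr3_start : middle_start]
    middle = seq[middle_start : extraction.j_start]
    v_ret = _v_retained(middle, anchor)
    region = middle[len(v_ret) :]
    d_call = assign_d(
        region,
        locus,
        min_run=min_run,
        extend_substitutions=extend_substitutions,
        tie_policy=tie_policy,
        priority=priority,
    )
    if d_call.gene is None:
        n1, d_obs, n2 = region, "", ""
    else:
        n1 = region[: d_call.start]
        d_obs = region[d_call.start : d_call.end]
        n2 = region[d_call.end :]
    j_retained = seq[extraction.j_start : extraction.cdr3_start + len(extraction.cdr3_nt)]
    annotation = JunctionAnnotation(
        transcript_id=transcript.id,
        anchor_tail=anchor_tail,
        v_retained=v_ret,
        n1=n1,
        d_call=d_call,
        d_observed=d_obs,
        n2=n2,
        j_gene=extraction.j_gene,
        j_five_prime_trim=extraction.j_trim,
        j_retained=j_retained,
        cdr3_nt=extraction.cdr3_nt,
        cdr3_aa=extraction.cdr3_aa,
        productive=extraction.productive,
        flags=extraction.flags,
        j_start=extraction.j_start,
        c_start=extraction.c_start,
        tissue=transcript.tissue,
    )
    rebuilt = anchor_tail + v_ret + n1 + d_obs + n2 + j_retained
    if rebuilt != extraction.cdr3_nt:
        raise JunctionError(
            f"{transcript.id}: internal decomposition inconsistency (must be impossible by construction)"
        )
    return annotation


def annotate_transcript(
    transcript: Transcript,
    locus: LocusModel,
    anchor: VAnchorSpec | None = None,
    min_j_suffix: int = 6,
    min_run: int = 4,
    extend_substitutions: bool = True,
    tie_policy: str = "none",
    priority: Sequence[str] = D_PRIORITY_DEFAULT,
) -> JunctionAnnotation:
    extraction = extract_cdr3(transcript, locus, anchor, min_j_suffix=min_j_suffix)
    return decompose_junction(
        transcript,
        extraction,
        locus,
        anchor,
        min_run=min_run,
        extend_substitutions=extend_substitutions,
        tie_policy=tie_policy,
        priority=priority,
    )


def annotate_repertoire(
    transcripts: Iterable[Transcript],
    locus: LocusModel,
    anchor: VAnchorSpec | None = None,
    **kwargs,
) -> tuple[list[JunctionAnnotation], list[tuple[Transcript, str]]]:
    """Annotate every transcript; failures are collected, never dropped silently."""
    annotations: list[JunctionAnnotation] = []
    failures: list[tuple[Transcript, str]] = []
    for transcript in transcripts:
        try:
            annotations.append(annotate_transcript(transcript, locus, anchor, **kwargs))
        except JunctionError as exc:
            failures.append((transcript, str(exc)))
    return annotations, failures


def to_airr(
    annotations: Iterable[JunctionAnnotation],
    failures: Iterable[tuple[Transcript, str]] = (),
    extra_columns: dict[str, dict[str, object]] | None = None,
) -> pd.DataFrame:
    """AIRR-style rearrangement table, one row per transcript including failures."""
    rows = []
    for a in annotations:
        row = {
            "sequence_id": a.transcript_id,
            "productive": a.productive,
            "d_call": a.d_call.gene or "",
            "j_call": a.j_gene,
            "junction": a.cdr3_nt,
            "junction_aa": a.cdr3_aa or "",
            "cdr3_length_aa": (len(a.cdr3_nt) // 3) if len(a.cdr3_nt) % 3 == 0 else "",
            "np1_length": len(a.n1),
            "np2_length": len(a.n2),
            "v_retained": a.v_retained,
            "d_5_trim": a.d_call.five_prime_trim if a.d_call.gene else "",
            "d_3_trim": a.d_call.three_prime_trim if a.d_call.gene else "",
            "j_5_trim": a.j_five_prime_trim,
            "d_substitutions": ";".join(f"{o}:{g}>{s}" for o, g, s in a.d_call.substitutions),
            "d_candidates": ";".join(a.d_call.candidates),
            "tissue": a.tissue or "",
            "flags": ";".join(a.flags),
            "status": "ok",
            "failure_reason": "",
        }
        if extra_columns and a.transcript_id in extra_columns:
            row.update(extra_columns[a.transcript_id])
        rows.append(row)
    for transcript, reason in failures:
        rows.append(
            {
                "sequence_id": transcript.id,
                "productive": False,
                "tissue": transcript.tissue or "",
                "status": "failed",
                "failure_reason": reason,
            }
        )
    return pd.DataFrame(rows)
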