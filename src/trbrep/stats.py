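"""Repertoire summary statistics: gene usage, CDR3 lengths, event fractions.

Percentages and means are reported truncated (not rounded) to one decimal,
the convention under which every printed figure of the source study's
clone table reproduces exactly (e.g. 38/72 -> 52.7%, 25/60 -> 41.6%,
339/8 -> 42.3 bp).  Every fraction is emitted together with its counts and
an explicit denominator label — in particular D-usage and rearrangement
fractions are given both over all clones and over the D-assigned subset,
because only the latter denominator reproduces the study's printed
41.6%/53.3%/60%/26.6%/13.3% figures.

The packaged 72-clone table (``load_table1``) transcribes the study's
per-clone annotations: id, tissue, CDR3 amino-acid parts, D/J/C calls and
CDR3 length.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .germline import LocusModel

__all__ = [
    "report_value",
    "pct",
    "load_table1",
    "cdr3_stats",
    "summarize",
    "RepertoireSummary",
]

logger = logging.getLogger(__name__)


def report_value(x: float, decimals: int = 1) -> float:
    """Truncate toward zero at ``decimals`` places (the study's reporting style)."""
    scale = 10**decimals
    return math.trunc(round(x * scale, 6)) / scale


def pct(count: int, denom: int) -> float:
    if denom == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return report_value(100.0 * count / denom)


def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    """The packaged 72-clone annotation table (or a user table in the same dialect)."""
    if path is None:
        source = resources.files("trbrep.data").joinpath("table1_clones.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["cdr3_len_aa"] = df["cdr3_len_aa"].astype(int)
    return df


def cdr3_stats(df: pd.DataFrame, group_by: str = "tissue", unit: str = "aa") -> pd.DataFrame:
    """Mean (truncated to 1 decimal) and min-max CDR3 length per group.

    ``group_by`` is ``tissue`` or ``d_group`` (D gene, with no-D clones
    pooled under ``no_D``); ``unit`` is ``aa`` or ``nt`` (nt = 3 x aa).
    Groups with no records are omitted with a log notice.
    """
    if unit not in ("aa", "nt"):
        raise ValueError(f"unit must be 'aa' or 'nt', got {unit!r}")
    work = df.copy()
    if group_by == "d_group":
        work["d_group"] = work["d_gene"].where(work["d_gene"] != "", "no_D")
        key = "d_group"
    elif group_by == "tissue":
        key = "tissue"
    else:
        raise ValueError(f"group_by must be 'tissue' or 'd_group', got {group_by!r}")
    factor = 1 if unit == "aa" else 3
    lengths = work["cdr3_len_aa"] * factor
    rows = []
    for group, idx in work.groupby(key).groups.items():
        values = lengths.loc[idx]
        if values.empty:
            logger.info("group %r has no records; omitted", group)
            continue
        rows.append(
            {
                "group": group,
                "n": len(values),
                "mean": report_value(values.mean()),
                "min": int(values.min()),
                "max": int(values.max()),
                "unit": unit,
            }
        )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def _usage(series: pd.Series, denom: int) -> pd.DataFrame:
    counts = series.value_counts().sort_index()
    return pd.DataFrame(
        {"count": counts, "percent": [pct(c, denom) for c in counts], "denominator": denom}
    )


@dataclass
class RepertoireSummary:
    """Deterministic summary of an annotated clone table.

    All percentages are recomputed from the stored counts on access paths
    (`to_dict`, `report`); nothing is cached as a formatted string.
    """

    n_records: int
    n_d_assigned: int
    d_usage: pd.DataFrame
    j_usage: pd.DataFrame
    j_cluster_usage: pd.DataFrame
    c_usage: pd.DataFrame
    rearrangement: pd.DataFrame
    splice: pd.DataFrame
    cdr3_aa_by_tissue: pd.DataFrame
    cdr3_nt_by_d_group: pd.DataFrame

    def to_dict(self) -> dict:
        def table(df: pd.DataFrame) -> dict:
            return json.loads(df.to_json(orient="index"))

        return {
            "n_records": self.n_records,
            "n_d_assigned": self.n_d_assigned,
            "d_usage": table(self.d_usage),
            "j_usage": table(self.j_usage),
            "j_cluster_usage": table(self.j_cluster_usage),
            "c_usage": table(self.c_usage),
            "rearrangement": table(self.rearrangement),
            "splice": table(self.splice),
            "cdr3_aa_by_tissue": json.loads(self.cdr3_aa_by_tissue.to_json(orient="records")),
            "cdr3_nt_by_d_group": json.loads(self.cdr3_nt_by_d_group.to_json(orient="records")),
        }

    def report(self) -> str:
        parts = [
            f"records: {self.n_records} (D-assigned: {self.n_d_assigned})",
            "",
            "D usage (denominators: all clones / D-assigned):",
            self.d_usage.to_string(),
            "",
            "J-cluster usage:",
            self.j_cluster_usage.to_string(),
            "",
            "J-gene usage:",
            self.j_usage.to_string(),
            "",
            "C usage:",
            self.c_usage.to_string(),
            "",
            "rearrangement classes (denominators: all clones / D-assigned):",
            self.rearrangement.to_string(),
            "",
            "splice classes (denominator: all clones):",
            self.splice.to_string(),
            "",
            "CDR3 length (aa) by tissue:",
            self.cdr3_aa_by_tissue.to_string(index=False),
            "",
            "CDR3 length (nt) by D group:",
            self.cdr3_nt_by_d_group.to_string(index=False),
        ]
        return "\n".join(parts)


def summarize(df: pd.DataFrame, locus: LocusModel) -> RepertoireSummary:
    """Summarize an annotated clone table (requires d_gene/j_gene/c_gene/tissue columns).

    Rearrangement and splice classes are recomputed from the locus topology
    if absent from ``df``.
    """
    if df.empty:
        raise ValueError("cannot summarize an empty clone table")
    from .events import classify_records

    work = df.copy()
    if "rearrangement_class" not in work.columns or "splice_class" not in work.columns:
        work = classify_records(work, locus)
    work["j_cluster"] = [locus.cluster_of(j) for j in work["j_gene"]]

    n = len(work)
    d_assigned = work[work["d_gene"] != ""]
    n_d = len(d_assigned)

    d_usage = _usage(d_assigned["d_gene"], n_d)
    d_usage.insert(1, "percent_of_all", [pct(c, n) for c in d_usage["count"]])

    rearr_counts = work["rearrangement_class"].value_counts()
    rearr = pd.DataFrame(
        {
            "count": rearr_counts,
            "percent_of_d_assigned": [
                pct(c, n_d) if k != "no_d" and n_d else float("nan")
                for k, c in rearr_counts.items()
            ],
            "percent_of_all": [pct(c, n) for c in rearr_counts],
        }
    ).sort_index()

    summary = RepertoireSummary(
        n_records=n,
        n_d_assigned=n_d,
        d_usage=d_usage,
        j_usage=_usage(work["j_gene"], n),
        j_cluster_usage=_usage(work["j_cluster"], n),
        c_usage=_usage(work["c_gene"], n),
        rearrangement=rearr,
        splice=_usage(work["splice_class"], n),
        cdr3_aa_by_tissue=cdr3_stats(work, "tissue", "aa"),
        cdr3_nt_by_d_group=cdr3_stats(work, "d_group", "nt"),
    )
    return summary
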