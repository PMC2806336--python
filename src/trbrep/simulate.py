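"""Labelled repertoire simulator and the synthetic sheep-shaped fixture locus.

The generator emits transcripts with the exact generative structure the
analysis assumes — anchored V end, exonuclease-trimmed D and J segments,
non-templated N additions, rare substitutions inside D, cluster-aware D-J
joining with configurable intra/inter/trans mixtures, canonical/cis/trans
J-C splicing, and biallelic C genes whose marker vectors are subject to
exon-swap and single-crossover diversification — together with a
ground-truth table for every transcript, so each upstream module is
testable end to end without any external data.

Default mixtures are the study regime: D-J classes 25:32:3 over the 60
D-assigned clones and splice classes 49:7:16 over all 72 clones; trimming
is truncated-geometric and N additions Poisson with per-side mean 3 nt,
placing the simulated N-D-N stretch in the 13-16 nt band the study reports.

``make_fixture_locus`` builds a synthetic sheep-like locus: three clusters
with genomic order 1 < 3 < 2, J census 6/5/7 (17 of 18 functional), three
C isotypes distinguished by N-terminal diagnostic codons, and 14 marker
positions (12 in exon 1, two in exon 3; six non-synonymous).  Sequences
are deterministic functions of the seed and are synthetic stand-ins — the
topology and censuses are real, the nucleotides are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .constant import AlleleSet
from .germline import (
    Cluster,
    GermlineGene,
    LocusModel,
    Marker,
    MarkerTable,
    fgxg_offset,
)
from .junctions import Transcript, VAnchorSpec, _longest_common_substring

__all__ = [
    "SimConfig",
    "SimConfigError",
    "SimResult",
    "FixtureLocus",
    "make_fixture_locus",
    "simulate",
    "fixture_anchor",
    "ANCHOR_NT",
    "DEFAULT_V_END",
]

# nucleotides of the YLCASS anchor; the CDR3 starts at the GCC (Ala) codon
ANCHOR_NT = "TATCTCTGTGCCAGCAGC"
ANCHOR_TAIL_NT = "GCCAGCAGC"
DEFAULT_V_END = "CAGGAC"

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_SAFE_CODONS = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS
)

REARR_ORDER = ("intra_cluster", "inter_cluster", "trans_rearrangement")
SPLICE_ORDER = ("canonical", "cis_splice", "trans_splice")


class SimConfigError(ValueError):
    """The simulation configuration is inconsistent or infeasible for the locus."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters; the defaults are the study regime.

    Trim parameters are (geometric p, cap) per site; N lengths are Poisson
    per side (or a uniform integer range).  Mixtures must sum to 1.
    """

    seed: int
    n_transcripts: int = 100
    trim_v3: tuple[float, int] = (0.5, 6)
    trim_d5: tuple[float, int] = (0.5, 4)
    trim_d3: tuple[float, int] = (0.5, 4)
    trim_j5: tuple[float, int] = (0.35, 9)
    n_dist: tuple = ("poisson", 3.0)
    d_sub_rate: float = 0.01
    rearrangement_mix: tuple[float, float, float] = (25 / 60, 32 / 60, 3 / 60)
    splice_mix: tuple[float, float, float] = (49 / 72, 7 / 72, 16 / 72)
    exon_swap_rate: float = 0.05
    recombinant_rate: float = 0.05
    nonproductive_rate: float = 0.0
    min_d_retained: int = 0
    v_end: str = DEFAULT_V_END

    def __post_init__(self) -> None:
        for name, mix in (("rearrangement_mix", self.rearrangement_mix), ("splice_mix", self.splice_mix)):
            if len(mix) != 3 or any(not 0 <= p <= 1 for p in mix) or abs(sum(mix) - 1) > 1e-9:
                raise SimConfigError(f"{name} must be three probabilities summing to 1, got {mix}")
        for name, rate in (
            ("d_sub_rate", self.d_sub_rate),
            ("exon_swap_rate", self.exon_swap_rate),
            ("recombinant_rate", self.recombinant_rate),
            ("nonproductive_rate", self.nonproductive_rate),
        ):
            if not 0 <= rate <= 1:
                raise SimConfigError(f"{name} must be in [0,1], got {rate}")
        if self.exon_swap_rate + self.recombinant_rate > 1:
            raise SimConfigError("exon_swap_rate + recombinant_rate must not exceed 1")
        if self.n_transcripts < 0:
            raise SimConfigError("n_transcripts must be non-negative")


class FixtureLocus(NamedTuple):
    locus: LocusModel
    markers: MarkerTable
    alleles: AlleleSet


def fixture_anchor(v_end: str = DEFAULT_V_END) -> VAnchorSpec:
    """Anchor spec carrying the simulator's germline V end for decomposition."""
    return VAnchorSpec(v_end_suffixes=(v_end,))


# ---------------------------------------------------------------------------
# fixture locus construction
# ---------------------------------------------------------------------------

def _codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n))


def _make_d_genes(rng: np.random.Generator) -> dict[str, str]:
    lengths = {"TRBD1": 12, "TRBD3": 15, "TRBD2": 18}
    for _ in range(500):
        seqs = {name: _codons(rng, n // 3) for name, n in lengths.items()}
        pairs = [("TRBD1", "TRBD3"), ("TRBD1", "TRBD2"), ("TRBD3", "TRBD2")]
        if all(_longest_common_substring(seqs[a], seqs[b])[0] <= 3 for a, b in pairs):
            return seqs
    raise RuntimeError("could not draw D genes with pairwise shared runs <= 3")


def _make_j_sequence(rng: np.random.Generator) -> str:
    from .germline import _fgxg_offset_of, LocusError

    for _ in range(200):
        j5 = _codons(rng, 4)
        x = _SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))]
        tail = _codons(rng, 3)
        seq = j5 + "TTT" + "GGA" + x + "GGC" + tail
        try:
            if _fgxg_offset_of(seq) == 12:
                return seq
        except LocusError:
            continue
    raise RuntimeError("could not draw a J gene with a unique FGXG motif")


_EXON1_CODONS = 20
_EXON2_CODONS = 6
_EXON3_CODONS = 10

# marker layout: (region, 1-based cDNA position, codon index, base offset in codon)
# third-base markers sit in CTx leucine codons (silent); first-base markers in
# xCC codons (non-synonymous) -- six of each, matching the study's census
_MARKER_LAYOUT = (
    ("EX1", 3, 0, 2),
    ("EX1", 7, 2, 0),
    ("EX1", 10, 3, 0),
    ("EX1", 16, 5, 0),
    ("EX1", 21, 6, 2),
    ("EX1", 22, 7, 0),
    ("EX1", 27, 8, 2),
    ("EX1", 28, 9, 0),
    ("EX1", 33, 10, 2),
    ("EX1", 34, 11, 0),
    ("EX1", 39, 12, 2),
    ("EX1", 42, 13, 2),
    ("EX3", 84, 27, 2),
    ("EX3", 93, 30, 2),
)

_DIAGNOSTICS = {
    "TRBC1": {3: "A", 7: "A", 10: "T"},
    "TRBC2": {3: "G", 7: "G", 10: "C"},
    "TRBC3": {3: "A", 7: "G", 10: "C"},
}


def _draw_allele_vectors(rng: np.random.Generator) -> dict[str, dict[str, str]]:
    """Six allele vectors (two per isotype) over the 14 markers.

    Diagnostic bases (markers 1-3) are fixed per isotype; the nine other
    exon-1 bases are drawn so every allele pair differs at three or more of
    them and every marker column is polymorphic; the two exon-3 bases form
    six pairwise-distinct blocks.
    """
    isotypes = ("TRBC1", "TRBC2", "TRBC3")
    diag = {iso: [_DIAGNOSTICS[iso][p] for p in (3, 7, 10)] for iso in isotypes}
    for _ in range(2000):
        mid = [[_BASES[i] for i in rng.integers(0, 4, size=9)] for _ in range(6)]
        ok = all(
            sum(a != b for a, b in zip(mid[i], mid[j])) >= 3
            for i in range(6)
            for j in range(i + 1, 6)
        ) and all(len({row[k] for row in mid}) >= 2 for k in range(9))
        if not ok:
            continue
        combos = [(a, b) for a in _BASES for b in _BASES]
        picked = [combos[i] for i in rng.choice(len(combos), size=6, replace=False)]
        vectors: dict[str, dict[str, str]] = {}
        for idx, iso in enumerate(isotypes):
            vectors[iso] = {}
            for allele in range(2):
                row = 2 * idx + allele
                vec = "".join(diag[iso]) + "".join(mid[row]) + "".join(picked[row])
                vectors[iso][f"{iso}*0{allele + 1}"] = vec
        return vectors
    raise RuntimeError("could not draw informative allele vectors")


def _c_backbone(rng: np.random.Generator) -> str:
    return _codons(rng, _EXON1_CODONS + _EXON2_CODONS + _EXON3_CODONS)


def _c_sequence(backbone: str, vector: str) -> str:
    """Apply a 14-marker vector onto the shared C backbone.

    Marker codons are templated (CTx for silent, xCC for replacement sites)
    so that base identity at the marker position fully determines the codon.
    """
    seq = list(backbone)
    for (region, pos, codon_idx, offset), base in zip(_MARKER_LAYOUT, vector):
        start = 3 * codon_idx
        codon = ["C", "T", "x"] if offset == 2 else ["x", "C", "C"]
        codon[offset] = base
        seq[start : start + 3] = codon
    return "".join(seq)


def make_fixture_locus(seed: int = 0) -> FixtureLocus:
    """Deterministic synthetic locus with the sheep topology and censuses."""
    rng = np.random.default_rng(seed)
    d_seqs = _make_d_genes(rng)
    j_plan = {"1": 6, "3": 5, "2": 7}
    j_seqs: dict[str, str] = {}
    for cid, count in j_plan.items():
        for i in range(1, count + 1):
            j_seqs[f"TRBJ{cid}.{i}"] = _make_j_sequence(rng)
    if len(set(j_seqs.values())) != len(j_seqs):
        raise RuntimeError("drew duplicate J sequences")
    backbone = _c_backbone(rng)
    allele_vectors = _draw_allele_vectors(rng)
    exons = (
        (0, 3 * _EXON1_CODONS),
        (3 * _EXON1_CODONS, 3 * (_EXON1_CODONS + _EXON2_CODONS)),
        (3 * (_EXON1_CODONS + _EXON2_CODONS), 3 * (_EXON1_CODONS + _EXON2_CODONS + _EXON3_CODONS)),
    )

    def genes_for(cid: str, rank: int) -> Cluster:
        d_name = f"TRBD{cid}"
        c_name = f"TRBC{cid}"
        d = GermlineGene(d_name, "D", cid, d_seqs[d_name])
        js = tuple(
            GermlineGene(
                f"TRBJ{cid}.{i}",
                "J",
                cid,
                j_seqs[f"TRBJ{cid}.{i}"],
                functional=not (cid == "1" and i == 3),
            )
            for i in range(1, j_plan[cid] + 1)
        )
        c = GermlineGene(
            c_name,
            "C",
            cid,
            _c_sequence(backbone, allele_vectors[c_name][f"{c_name}*01"]),
            exons=exons,
        )
        return Cluster(cluster_id=cid, d_gene=d, j_genes=js, c_gene=c, genomic_rank=rank)

    markers = MarkerTable(
        markers=tuple(
            Marker(
                region=region,
                position=pos,
                states={
                    name: vec[i]
                    for iso in sorted(allele_vectors)
                    for name, vec in allele_vectors[iso].items()
                },
            )
            for i, (region, pos, _ci, _off) in enumerate(_MARKER_LAYOUT)
        ),
        diagnostics=_DIAGNOSTICS,
    )
    locus = LocusModel(
        clusters=(genes_for("1", 1), genes_for("3", 2), genes_for("2", 3)),
        species_label="sheep-like synthetic",
        provenance=f"synthetic fixture (seed={seed}); topology real, sequences invented",
        marker_table=markers,
    )
    for j in locus.genes("J"):
        assert fgxg_offset(j) == 12
    return FixtureLocus(locus=locus, markers=markers, alleles=AlleleSet(alleles=allele_vectors))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _tgeom(rng: np.random.Generator, p: float, cap: int) -> int:
    """Truncated geometric count of trimmed bases (number of failures, <= cap)."""
    if cap <= 0 or p >= 1:
        return 0
    for _ in range(200):
        k = int(rng.geometric(p)) - 1
        if k <= cap:
            return k
    return cap


def _n_len(rng: np.random.Generator, dist: tuple) -> int:
    if dist[0] == "poisson":
        return int(rng.poisson(dist[1]))
    if dist[0] == "uniform":
        return int(rng.integers(dist[1], dist[2] + 1))
    raise SimConfigError(f"unknown N-length distribution {dist!r}")


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(0, len(items)))]


def _mix_draw(rng: np.random.Generator, order: tuple[str, ...], probs: tuple[float, ...]) -> str:
    u = rng.random()
    acc = 0.0
    for name, p in zip(order, probs):
        acc += p
        if u < acc:
            return name
    return order[-1]


def _check_feasibility(locus: LocusModel, cfg: SimConfig) -> None:
    up = {c.cluster_id: [o.cluster_id for o in locus.clusters if o.genomic_rank < c.genomic_rank] for c in locus.clusters}
    down = {c.cluster_id: [o.cluster_id for o in locus.clusters if o.genomic_rank > c.genomic_rank] for c in locus.clusters}
    rearr_ok = {
        "intra_cluster": [c.cluster_id for c in locus.clusters],
        "inter_cluster": [cid for cid in up if up[cid]],
        "trans_rearrangement": [cid for cid in down if down[cid]],
    }
    splice_ok = {
        "canonical": [c.cluster_id for c in locus.clusters],
        "cis_splice": [cid for cid in down if down[cid]],
        "trans_splice": [cid for cid in up if up[cid]],
    }
    for r, pr in zip(REARR_ORDER, cfg.rearrangement_mix):
        for s, ps in zip(SPLICE_ORDER, cfg.splice_mix):
            if pr > 0 and ps > 0 and not set(rearr_ok[r]) & set(splice_ok[s]):
                raise SimConfigError(
                    f"no cluster can host rearrangement={r} together with splice={s} in this locus"
                )


def _canonical_variant(
    vector: str, alleles: AlleleSet, a_name: str, b_name: str | None, k: int | None, boundary: int
) -> tuple[str, tuple[str, ...], int | None]:
    """Label the emitted vector by what it is, not by the mechanism drawn.

    A crossover whose product equals a pure allele, or leaves a donor
    exon-1 block intact, is indistinguishable from (respectively) plain
    allele usage or an exon swap, so truth records the observable class.
    """
    entries = list(alleles.items())
    for name, _iso, vec in entries:
        if vec == vector:
            return "allele", (name,), None
    for x_name, _xi, x_vec in entries:
        if x_vec[:boundary] == vector[:boundary]:
            for y_name, _yi, y_vec in entries:
                if y_name != x_name and y_vec[boundary:] == vector[boundary:]:
                    return "exon_swap", (x_name, y_name), None
    assert b_name is not None and k is not None
    return "recombinant", (a_name, b_name), k


@dataclass
class SimResult:
    transcripts: list[Transcript]
    truth: pd.DataFrame
    fixture: FixtureLocus
    config: SimConfig

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for t in self.transcripts:
                handle.write(f">{t.id}\n{t.sequence}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate(config: SimConfig, fixture: FixtureLocus | None = None) -> SimResult:
    """Generate a labelled repertoire; reproducible byte-for-byte given the seed."""
    fixture = fixture or make_fixture_locus(config.seed)
    locus, markers, alleles = fixture
    _check_feasibility(locus, config)
    rng = np.random.default_rng(config.seed)

    up = {c.cluster_id: sorted(o.cluster_id for o in locus.clusters if o.genomic_rank < c.genomic_rank) for c in locus.clusters}
    down = {c.cluster_id: sorted(o.cluster_id for o in locus.clusters if o.genomic_rank > c.genomic_rank) for c in locus.clusters}
    all_cids = sorted(c.cluster_id for c in locus.clusters)
    rearr_ok = {
        "intra_cluster": all_cids,
        "inter_cluster": sorted(cid for cid in up if up[cid]),
        "trans_rearrangement": sorted(cid for cid in down if down[cid]),
    }
    splice_ok = {
        "canonical": all_cids,
        "cis_splice": sorted(cid for cid in down if down[cid]),
        "trans_splice": sorted(cid for cid in up if up[cid]),
    }
    boundary = len(markers.region_blocks()[markers.markers[0].region])

    transcripts: list[Transcript] = []
    rows: list[dict] = []
    for i in range(config.n_transcripts):
        rearr = _mix_draw(rng, REARR_ORDER, config.rearrangement_mix)
        splice = _mix_draw(rng, SPLICE_ORDER, config.splice_mix)
        feasible = sorted(set(rearr_ok[rearr]) & set(splice_ok[splice]))
        jc = _pick(rng, feasible)
        if rearr == "intra_cluster":
            dc = jc
        elif rearr == "inter_cluster":
            dc = _pick(rng, up[jc])
        else:
            dc = _pick(rng, down[jc])
        if splice == "canonical":
            cc = jc
        elif splice == "cis_splice":
            cc = _pick(rng, down[jc])
        else:
            cc = _pick(rng, up[jc])
        j_gene = locus.gene(_pick(rng, sorted(j.name for j in locus.cluster(jc).j_genes if j.functional)))
        d_gene = locus.cluster(dc).d_gene
        isotype = locus.cluster(cc).c_gene.name

        want_productive = rng.random() >= config.nonproductive_rate
        f_off = fgxg_offset(j_gene)

        # constant-region variant
        u = rng.random()
        allele_names = sorted(alleles.alleles[isotype])
        a_name = _pick(rng, allele_names)
        a_vec = alleles.vector_of(a_name)
        others = sorted(n for n, _i, _v in alleles.items() if n != a_name)
        k: int | None = None
        b_name: str | None = None
        if u < config.exon_swap_rate:
            b_name = _pick(rng, others)
            vector = a_vec[:boundary] + alleles.vector_of(b_name)[boundary:]
        elif u < config.exon_swap_rate + config.recombinant_rate:
            b_name = _pick(rng, others)
            k = 3 + int(rng.integers(0, boundary - 3))  # crossover after marker k, diag block intact
            vector = a_vec[:k] + alleles.vector_of(b_name)[k:]
        else:
            vector = a_vec
        klass, donors, bp = _canonical_variant(vector, alleles, a_name, b_name, k, boundary)
        c_seq = _c_sequence(locus.cluster(cc).c_gene.sequence, vector)

        # assemble the transcript; redraw junction/pad until the anchor is unique
        for _ in range(100):
            parts = _draw_junction(rng, config, d_gene, j_gene, want_productive)
            body = (
                ANCHOR_NT
                + parts["v_kept"]
                + parts["n1"]
                + parts["d_obs"]
                + parts["n2"]
                + j_gene.sequence[parts["j_trim"] :]
                + c_seq
            )
            seq = _rand_nt(rng, 10) + body
            if _anchor_count(seq) == 1:
                break
        else:
            raise RuntimeError("could not place a unique anchor")

        tid = f"sim{i:05d}"
        transcripts.append(Transcript(id=tid, sequence=seq))
        rows.append(
            {
                "sequence_id": tid,
                "rearrangement_class": rearr,
                "splice_class": splice,
                "d_gene": d_gene.name,
                "j_gene": j_gene.name,
                "c_gene": isotype,
                "v_trim": parts["v_trim"],
                "v_retained": parts["v_kept"],
                "n1": parts["n1"],
                "n2": parts["n2"],
                "d_5_trim": parts["d5"],
                "d_3_trim": parts["d3"],
                "d_observed": parts["d_obs"],
                "d_substitutions": ";".join(f"{o}:{g}>{s}" for o, g, s in parts["subs"]),
                "j_5_trim": parts["j_trim"],
                "junction": ANCHOR_TAIL_NT
                + parts["v_kept"]
                + parts["n1"]
                + parts["d_obs"]
                + parts["n2"]
                + j_gene.sequence[parts["j_trim"] : f_off],
                "productive": parts["productive"],
                "c_allele": a_name,
                "c_variant_class": klass,
                "c_donors": ";".join(donors),
                "c_breakpoint": "" if bp is None else bp,
                "c_vector": vector,
            }
        )
    truth = pd.DataFrame(rows)
    return SimResult(transcripts=transcripts, truth=truth, fixture=fixture, config=config)


def _anchor_count(seq: str) -> int:
    count = 0
    for frame in range(3):
        trimmed = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
        aa = str(Seq(trimmed).translate()) if len(trimmed) >= 3 else ""
        count += aa.count("YLCASS")
    return count


def _draw_junction(
    rng: np.random.Generator,
    cfg: SimConfig,
    d_gene: GermlineGene,
    j_gene: GermlineGene,
    want_productive: bool,
) -> dict:
    """Draw trims, N additions and substitutions; enforce frame and stop status."""
    d_len = len(d_gene.sequence)
    f_off = fgxg_offset(j_gene)
    for _ in range(200):
        v_trim = _tgeom(rng, *cfg.trim_v3)
        v_trim = min(v_trim, len(cfg.v_end))
        d5 = _tgeom(rng, *cfg.trim_d5)
        d3 = _tgeom(rng, *cfg.trim_d3)
        if d_len - d5 - d3 < max(cfg.min_d_retained, 0):
            continue
        j_trim = _tgeom(rng, cfg.trim_j5[0], min(cfg.trim_j5[1], f_off))
        n1_len = _n_len(rng, cfg.n_dist)
        n2_len = _n_len(rng, cfg.n_dist)
        v_kept = cfg.v_end[: len(cfg.v_end) - v_trim]
        retained = d_gene.sequence[d5 : d_len - d3]
        subs: list[tuple[int, str, str]] = []
        d_obs = list(retained)
        for idx in range(len(d_obs)):
            if rng.random() < cfg.d_sub_rate:
                alt = _pick(rng, [b for b in _BASES if b != d_obs[idx]])
                subs.append((d5 + idx, d_obs[idx], alt))
                d_obs[idx] = alt
        d_str = "".join(d_obs)

        total = len(ANCHOR_TAIL_NT) + len(v_kept) + n1_len + len(d_str) + n2_len + (f_off - j_trim)
        if want_productive:
            n2_len += (3 - total % 3) % 3
        elif total % 3 == 0:
            n2_len += 1

        for _ in range(40):
            n1 = _rand_nt(rng, n1_len)
            n2 = _rand_nt(rng, n2_len)
            cdr3 = (
                ANCHOR_TAIL_NT + v_kept + n1 + d_str + n2 + j_gene.sequence[j_trim:f_off]
            )
            if not want_productive:
                return {
                    "v_trim": v_trim,
                    "v_kept": v_kept,
                    "n1": n1,
                    "n2": n2,
                    "d5": d5,
                    "d3": d3,
                    "d_obs": d_str,
                    "subs": subs,
                    "j_trim": j_trim,
                    "productive": False,
                }
            if len(cdr3) % 3 == 0 and "*" not in str(Seq(cdr3).translate()):
                return {
                    "v_trim": v_trim,
                    "v_kept": v_kept,
                    "n1": n1,
                    "n2": n2,
                    "d5": d5,
                    "d3": d3,
                    "d_obs": d_str,
                    "subs": subs,
                    "j_trim": j_trim,
                    "productive": True,
                }
    raise RuntimeError("could not draw a junction satisfying the frame/stop constraints")
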