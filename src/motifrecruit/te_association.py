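"""Transposable-element evidence for recruitment events.

Three pieces of evidence link a TE to a candidate recruitment: (1) the donor
lies close to the acceptor on the chromosome, measured as the signed
chromosome-relative distance d = (donor start - acceptor start) / chromosome
length with |d| < 0.1 called proximal; (2) a TE carrying the motif aligns
locally to the donor's promoter (iterated Smith-Waterman with affine gaps
replaces a BLAST search); and (3) a motif occurrence falls entirely inside
the TE-promoter overlap.  An event is TE-supported when at least one donor
shows a motif-in-overlap alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seqio import ChromosomeInfo, GeneModel, revcomp
from .motif_tools import MotifOccurrence, Promoter, consensus_to_pwm, scan_consensus, scan_pwm
from .recruitment import RecruitmentEvent
from .synthetic_data import TERecord

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@dataclass(frozen=True)
class DistanceResult:
    acceptor: str
    donor: str
    d: float  # signed, dimensionless; NaN when on different chromosomes
    same_chromosome: bool
    proximal: bool  # same chromosome and |d| < 0.1 (strict)


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0  # cost of the first base of a gap
    gap_extend: float = -2.0
    min_identity: float = 80.0  # percent
    min_length: int = 20  # alignment columns


@dataclass(frozen=True)
class LocalAlignment:
    prom_start: int  # promoter interval, 0-based half-open
    prom_end: int
    te_start: int  # TE interval in original TE coordinates
    te_end: int
    strand: str  # orientation of the TE in the alignment
    score: float
    identity: float  # percent of aligned columns that match
    length: int  # alignment columns


@dataclass
class TEEvidence:
    motif_id: str
    acceptor: str
    donor: str
    te_id: str
    te_class: str
    distance: DistanceResult
    alignments: list[LocalAlignment] = field(default_factory=list)
    motif_in_overlap: bool = False


def _chrom_lengths(chromosomes) -> dict[str, int]:
    if isinstance(chromosomes, Mapping):
        return dict(chromosomes)
    return {c.name: c.length for c in chromosomes}


def chromosome_distance(
    acceptor: GeneModel, donor: GeneModel, chromosomes: Mapping[str, int] | Sequence[ChromosomeInfo]
) -> DistanceResult:
    """Chromosome-relative signed distance between donor and acceptor starts."""
    lengths = _chrom_lengths(chromosomes)
    for g in (acceptor, donor):
        if g.chrom not in lengths:
            raise KeyError(f"unknown chromosome {g.chrom!r}")
    if acceptor.chrom != donor.chrom:
        return DistanceResult(acceptor.gene_id, donor.gene_id, math.nan, False, False)
    d = (donor.start - acceptor.start) / lengths[acceptor.chrom]
    return DistanceResult(acceptor.gene_id, donor.gene_id, d, True, abs(d) < 0.1)


def proximal_donor_proportion(
    event: RecruitmentEvent,
    gene_models: Mapping[str, GeneModel],
    chromosomes,
) -> float:
    """Fraction of an event's donors proximal to the acceptor's C3 ortholog.

    Distances are computed in C3 coordinates (the acceptor is represented by
    its C3 ortholog), since only one species' chromosome table is assumed.
    """
    if not event.donors:
        raise ValueError("event has no donors")
    acceptor = gene_models[event.acceptor_c3_ortholog]
    n_prox = sum(
        chromosome_distance(acceptor, gene_models[d], chromosomes).proximal
        for d in event.donors
    )
    return n_prox / len(event.donors)


_NEG = -1e18
_FORBID = -1e9  # masked/N positions can never align


@njit
def _sw_core(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jit
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG)
    F = np.full((n + 1, m + 1), _NEG)
    best = 0.0
    bi, bj = 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i - 1, j] + gap_open, E[i - 1, j] + gap_extend)
            F[i, j] = max(H[i, j - 1] + gap_open, F[i, j - 1] + gap_extend)
            if a[i - 1] >= 4 or b[j - 1] >= 4:
                s = _FORBID
            elif a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, best, bi, bj


@njit
def _sw_traceback(H, E, F, a, b, bi, bj, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    i, j = bi, bj
    n_match = 0
    aln_len = 0
    state = 0  # 0=H, 1=E (gap consuming a), 2=F (gap consuming b)
    while True:
        if state == 0:
            if H[i, j] <= 0.0:
                break
            if a[i - 1] >= 4 or b[j - 1] >= 4:
                s = _FORBID
            elif a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    n_match += 1
                aln_len += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            if E[i, j] == E[i - 1, j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = 0
        else:
            aln_len += 1
            if F[i, j] == F[i, j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = 0
    return i, j, n_match, aln_len


_SW_LUT = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _SW_LUT[ord(_b)] = _i


def _sw_codes(seq: str) -> np.ndarray:
    return _SW_LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)].copy()


def smith_waterman(te_codes: np.ndarray, prom_codes: np.ndarray, params: AlignParams):
    """Single best local alignment; returns None when the best score is 0."""
    H, E, F, best, bi, bj = _sw_core(
        te_codes, prom_codes, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    if best <= 0.0:
        return None
    i0, j0, n_match, aln_len = _sw_traceback(
        H, E, F, te_codes, prom_codes, bi, bj,
        params.match, params.mismatch, params.gap_open, params.gap_extend,
    )
    identity = 100.0 * n_match / aln_len if aln_len else 0.0
    return dict(
        te_start=i0, te_end=bi, prom_start=j0, prom_end=bj,
        score=float(best), identity=identity, length=aln_len,
    )


def local_align(
    te_seq: str,
    promoter_seq: str,
    params: AlignParams | None = None,
    max_hits: int = 10,
) -> list[LocalAlignment]:
    """Non-overlapping local alignments of a TE to a promoter, both TE strands.

    Iterated Smith-Waterman: the best alignment is reported and its promoter
    interval masked before re-searching, until the best remaining alignment
    fails the identity/length gates.  TE intervals on the '-' strand are
    mapped back to original TE coordinates.
    """
    params = params or AlignParams()
    if not te_seq or not promoter_seq:
        raise ValueError("empty sequence")
    te_len = len(te_seq)
    te_fwd = _sw_codes(te_seq)
    te_rev = _sw_codes(revcomp(te_seq))
    prom = _sw_codes(promoter_seq)

    hits: list[LocalAlignment] = []
    for _ in range(max_hits):
        candidates = []
        for strand, te_codes in (("+", te_fwd), ("-", te_rev)):
            res = smith_waterman(te_codes, prom, params)
            if res is not None:
                candidates.append((strand, res))
        if not candidates:
            break
        strand, res = max(candidates, key=lambda c: c[1]["score"])
        if res["length"] < params.min_length or res["identity"] < params.min_identity:
            break
        ts, te_ = res["te_start"], res["te_end"]
        if strand == "-":
            ts, te_ = te_len - te_, te_len - ts
        hits.append(
            LocalAlignment(
                prom_start=res["prom_start"], prom_end=res["prom_end"],
                te_start=ts, te_end=te_, strand=strand,
                score=res["score"], identity=res["identity"], length=res["length"],
            )
        )
        prom[res["prom_start"] : res["prom_end"]] = 4  # mask
    return hits


def motif_in_overlap(
    alignments: Iterable[LocalAlignment], occurrence: MotifOccurrence
) -> bool:
    """True iff the occurrence footprint lies entirely inside some alignment."""
    a, b = occurrence.offset, occurrence.offset + occurrence.length
    return any(al.prom_start <= a and b <= al.prom_end for al in alignments)


def te_contains_motif(te_seq: str, motif, method: str = "consensus", tau: float = 0.8) -> bool:
    """Motif presence inside a TE, decided by the same scanner as promoters."""
    if method == "consensus":
        return bool(scan_consensus(te_seq, motif))
    pwm = motif if not isinstance(motif, str) else consensus_to_pwm(motif)
    return bool(scan_pwm(te_seq, pwm, tau=tau))


def te_evidence(
    events: Sequence[RecruitmentEvent],
    motifs: Mapping[str, str],
    te_library: Sequence[TERecord],
    donor_promoters: Mapping[str, Promoter],
    occurrences: Sequence[MotifOccurrence],
    gene_models: Mapping[str, GeneModel],
    chromosomes,
    params: AlignParams | None = None,
    method: str = "consensus",
    tau: float = 0.8,
) -> tuple[pd.DataFrame, dict[tuple[str, str], bool]]:
    """TE evidence for every event x donor; events flagged te_supported.

    ``occurrences`` are the motif occurrences in donor promoters (promoter
    coordinates).  For each donor, every TE containing the event's motif is
    aligned to the donor promoter and each occurrence is tested for full
    containment in an alignment; an event is supported when any donor shows a
    contained occurrence.
    """
    params = params or AlignParams()
    occ_by_key: dict[tuple[str, str], list[MotifOccurrence]] = {}
    for o in occurrences:
        occ_by_key.setdefault((o.motif_id, o.gene_id), []).append(o)

    tes_with_motif: dict[str, list[TERecord]] = {}
    for motif_id in {e.motif_id for e in events}:
        tes_with_motif[motif_id] = [
            t for t in te_library if te_contains_motif(t.seq, motifs[motif_id], method, tau)
        ]

    rows = []
    supported: dict[tuple[str, str], bool] = {}
    for event in events:
        key = (event.motif_id, event.acceptor)
        supported[key] = False
        acceptor_gene = gene_models[event.acceptor_c3_ortholog]
        for donor in event.donors:
            dist = chromosome_distance(acceptor_gene, gene_models[donor], chromosomes)
            donor_occs = occ_by_key.get((event.motif_id, donor), [])
            for te in tes_with_motif[event.motif_id]:
                alns = local_align(te.seq, donor_promoters[donor].seq, params)
                in_overlap = any(motif_in_overlap(alns, o) for o in donor_occs)
                if in_overlap:
                    supported[key] = True
                best = max(alns, key=lambda a: a.score, default=None)
                rows.append(
                    dict(
                        motif_id=event.motif_id,
                        acceptor=event.acceptor,
                        donor=donor,
                        te_id=te.te_id,
                        te_class=te.te_class,
                        d=dist.d,
                        proximal=dist.proximal,
                        n_alignments=len(alns),
                        overlap_start=best.prom_start if best else -1,
                        overlap_end=best.prom_end if best else -1,
                        identity=best.identity if best else float("nan"),
                        motif_in_overlap=in_overlap,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "motif_id", "acceptor", "donor", "te_id", "te_class", "d", "proximal",
            "n_alignments", "overlap_start", "overlap_end", "identity", "motif_in_overlap",
        ],
    )
    return df, supported
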