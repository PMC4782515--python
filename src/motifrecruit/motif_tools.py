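"""Promoter extraction and motif scanning.

Promoters are the 3 kb of sequence immediately upstream of the TSS, oriented
5'->3' relative to the gene and clipped at chromosome edges.  Motifs are
either IUPAC consensus strings or position weight matrices (4 x L base
probabilities, rows in A, C, G, T order); scanning reports occurrences on
both strands with 0-based offsets inside the promoter.  A simple
overrepresented-k-mer finder provides de novo discovery of candidate motifs
from a foreground promoter set against a background set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._seqio import GeneModel, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class Promoter:
    gene_id: str
    seq: str  # 5'->3' relative to gene orientation
    chrom: str
    start: int  # genomic interval on the forward strand, 0-based half-open
    end: int
    strand: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    gene_id: str
    offset: int  # 0-based within the promoter, 5'->3'
    strand: str  # '+': motif as given; '-': its reverse complement
    score: float
    length: int


def extract_promoters(
    genome: Mapping[str, str],
    genes: Iterable[GeneModel],
    promoter_length: int = 3000,
    errors: list[dict] | None = None,
) -> list[Promoter]:
    """Extract the upstream promoter of every gene; clipped at chromosome ends.

    Genes whose chromosome is missing from the genome produce an error record
    (appended to ``errors`` when given) and are skipped; the run continues.
    """
    promoters = []
    for g in genes:
        if g.chrom not in genome:
            if errors is not None:
                errors.append({"gene_id": g.gene_id, "error": f"chromosome {g.chrom} missing"})
            continue
        chrom_seq = genome[g.chrom]
        if g.strand == "+":
            a = max(0, g.start - promoter_length)
            b = g.start
            seq = chrom_seq[a:b]
        else:
            a = g.end
            b = min(len(chrom_seq), g.end + promoter_length)
            seq = revcomp(chrom_seq[a:b])
        promoters.append(Promoter(g.gene_id, seq.upper(), g.chrom, a, b, g.strand))
    return promoters


def _consensus_regex(consensus: str) -> str:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in consensus")
        bases = IUPAC[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan_consensus(
    promoter: Promoter | str, consensus: str, motif_id: str = ""
) -> list[MotifOccurrence]:
    """All occurrences of an IUPAC consensus in a promoter, both strands.

    'N' in the promoter matches nothing.  A reverse-strand hit with the same
    footprint as a forward hit (palindromes) is deduplicated to one '+' hit.
    Occurrences are sorted by offset, '+' before '-'.
    """
    seq = promoter.seq if isinstance(promoter, Promoter) else promoter.upper()
    gene_id = promoter.gene_id if isinstance(promoter, Promoter) else ""
    L = len(consensus)
    if L == 0 or L > len(seq):
        return []
    fwd = re.compile(f"(?=({_consensus_regex(consensus)}))")
    hits: list[MotifOccurrence] = []
    fwd_offsets = set()
    for m in fwd.finditer(seq):
        hits.append(MotifOccurrence(motif_id, gene_id, m.start(), "+", 1.0, L))
        fwd_offsets.add(m.start())
    rc = revcomp(consensus)
    rev = re.compile(f"(?=({_consensus_regex(rc)}))")
    for m in rev.finditer(seq):
        if m.start() in fwd_offsets:
            continue  # palindromic footprint already reported on '+'
        hits.append(MotifOccurrence(motif_id, gene_id, m.start(), "-", 1.0, L))
    hits.sort(key=lambda o: (o.offset, o.strand))
    return hits


def validate_pwm(pwm: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError("PWM must be a 4 x L matrix (rows A, C, G, T)")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise ValueError("PWM columns must each sum to 1")
    if (pwm < 0).any():
        raise ValueError("PWM entries must be non-negative")
    return pwm


def _encode_seq(seq: str) -> np.ndarray:
    lut = np.full(128, 4, dtype=np.int8)  # 4 = N / anything else
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    L = logodds.shape[1]
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.empty(0)
    lo = np.vstack([logodds, np.full(L, -np.inf)])  # row 4: N matches nothing
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo[win, np.arange(L)].sum(axis=1)


def scan_pwm(
    promoter: Promoter | str,
    pwm: np.ndarray,
    tau: float = 0.8,
    motif_id: str = "",
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[MotifOccurrence]:
    """PWM log-odds scan of a promoter; report hits scoring >= tau * max.

    The maximum is the best achievable log-odds (sum of column maxima).  Both
    strands are scanned; a reverse hit at the exact footprint of a forward
    hit is reported once on '+'.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    pwm = validate_pwm(pwm)
    seq = promoter.seq if isinstance(promoter, Promoter) else promoter.upper()
    gene_id = promoter.gene_id if isinstance(promoter, Promoter) else ""
    bg = np.asarray(background, dtype=float)[:, None]
    logodds = np.log(np.maximum(pwm, 1e-12) / bg)
    L = pwm.shape[1]
    codes = _encode_seq(seq)
    max_score = logodds.max(axis=0).sum()
    threshold = tau * max_score - 1e-9

    hits: list[MotifOccurrence] = []
    fwd_scores = _window_scores(codes, logodds)
    fwd_offsets = set()
    for off in np.nonzero(fwd_scores >= threshold)[0]:
        hits.append(MotifOccurrence(motif_id, gene_id, int(off), "+", float(fwd_scores[off]), L))
        fwd_offsets.add(int(off))
    rev_scores = _window_scores(codes, logodds[::-1, ::-1])
    for off in np.nonzero(rev_scores >= threshold)[0]:
        if int(off) in fwd_offsets:
            continue
        hits.append(MotifOccurrence(motif_id, gene_id, int(off), "-", float(rev_scores[off]), L))
    hits.sort(key=lambda o: (o.offset, o.strand))
    return hits


def consensus_to_pwm(consensus: str, eps: float = 0.03) -> np.ndarray:
    """Soft PWM from an IUPAC consensus: disallowed bases get ``eps`` each."""
    L = len(consensus)
    pwm = np.zeros((4, L))
    for j, ch in enumerate(consensus.upper()):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r}")
        allowed = [_BASE_INDEX[b] for b in IUPAC[ch]]
        n_dis = 4 - len(allowed)
        pwm[:, j] = eps
        pwm[allowed, j] = (1.0 - n_dis * eps) / len(allowed)
    return pwm


def scan_promoters(
    promoters: Iterable[Promoter],
    motifs: Mapping[str, str] | Mapping[str, np.ndarray],
    method: str = "consensus",
    tau: float = 0.8,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[list[MotifOccurrence], pd.DataFrame]:
    """Scan every promoter for every motif.

    Returns the occurrence list and a boolean presence table (motifs x genes);
    presence means at least one occurrence on either strand.
    """
    promoters = list(promoters)
    occurrences: list[MotifOccurrence] = []
    presence = pd.DataFrame(
        False, index=list(motifs), columns=[p.gene_id for p in promoters]
    )
    for motif_id, motif in motifs.items():
        for p in promoters:
            if method == "consensus":
                occs = scan_consensus(p, motif, motif_id)
            elif method == "pwm":
                pwm = motif if not isinstance(motif, str) else consensus_to_pwm(motif)
                occs = scan_pwm(p, pwm, tau=tau, motif_id=motif_id, background=background)
            else:
                raise ValueError(f"unknown scan method {method!r}")
            occurrences.extend(occs)
            if occs:
                presence.loc[motif_id, p.gene_id] = True
    return occurrences, presence


def occurrences_to_bed(
    occurrences: Iterable[MotifOccurrence], promoters: Mapping[str, Promoter], path
) -> None:
    """Write occurrences as BED6 with genomic forward-strand coordinates."""
    with open(path, "w") as fh:
        for o in occurrences:
            p = promoters[o.gene_id]
            if p.strand == "+":
                gstart = p.start + o.offset
                strand = o.strand
            else:
                gstart = p.end - o.offset - o.length
                strand = "-" if o.strand == "+" else "+"
            fh.write(
                f"{p.chrom}\t{gstart}\t{gstart + o.length}\t"
                f"{o.motif_id}:{o.gene_id}\t{o.score:.4g}\t{strand}\n"
            )


def _kmer_presence(seqs: Sequence[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        seen = set()
        for strand_seq in (s, revcomp(s)):
            for i in range(len(strand_seq) - k + 1):
                km = strand_seq[i : i + k]
                if "N" not in km:
                    seen.add(km)
        # canonical orientation: count each k-mer as itself (both strands
        # contribute, presence is per promoter)
        counts.update({km: counts.get(km, 0) + 1 for km in seen})
    return counts


def discover_overrepresented_kmers(
    foreground: Sequence[Promoter | str],
    background: Sequence[Promoter | str],
    k_range: Sequence[int] = range(6, 13),
    top_n: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank k-mers by hypergeometric enrichment of foreground presence.

    Presence is per promoter (either strand).  The significance flag applies
    a Bonferroni correction over the 4^k candidate k-mers of each width.
    Returns the ``top_n`` k-mers over all widths, best p-value first.
    """
    fg = [p.seq if isinstance(p, Promoter) else p.upper() for p in foreground]
    bg = [p.seq if isinstance(p, Promoter) else p.upper() for p in background]
    if not fg or not bg:
        raise ValueError("both promoter sets must be non-empty")
    n_fg, n_bg = len(fg), len(bg)
    rows = []
    for k in k_range:
        if k > min(len(s) for s in fg + bg):
            import warnings

            warnings.warn(f"k={k} exceeds the shortest promoter; skipped")
            continue
        fg_counts = _kmer_presence(fg, k)
        bg_counts = _kmer_presence(bg, k)
        for km, x in fg_counts.items():
            K = x + bg_counts.get(km, 0)
            p = float(hypergeom.sf(x - 1, n_fg + n_bg, K, n_fg))
            rows.append(
                dict(
                    kmer=km, k=k, fg_present=x, bg_present=bg_counts.get(km, 0),
                    pvalue=p, significant=p * (4**k) < alpha,
                )
            )
    df = pd.DataFrame(rows, columns=["kmer", "k", "fg_present", "bg_present", "pvalue", "significant"])
    df = df.sort_values(["pvalue", "fg_present", "kmer"], ascending=[True, False, True])
    return df.head(top_n).reset_index(drop=True)
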