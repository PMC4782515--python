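"""TF-binding enrichment of a motif set: match ratio and relative match ratio.

For a set of sequence elements and one transcription-factor PWM, the match
ratio is

    MR(elements, TF) = |elements matched to the TF binding site| / |elements|

where an element matches when its best ungapped log-odds alignment to the PWM
(both strands, all offsets of the shorter within the longer, scoring only the
overlapped columns) reaches a fraction tau of the best achievable score over
the same overlap.  The null is built by drawing, for each element, random
sequences of the same length (1,000 per element by default); enrichment is
the relative match ratio MR(motifs, TF) / MR(random, TF), with values above
two-fold flagged as enriched.  Elements of length five or shorter are
excluded up front.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .motif_tools import IUPAC, _BASE_INDEX

MIN_ELEMENT_LENGTH = 6  # elements must be longer than 5 bases


class UndefinedResultError(ValueError):
    """The statistic is undefined (e.g. empty element set after filtering)."""


@dataclass(frozen=True)
class TFMatrix:
    tf_id: str
    pwm: np.ndarray  # 4 x L base probabilities, rows A, C, G, T

    @property
    def length(self) -> int:
        return self.pwm.shape[1]


@dataclass(frozen=True)
class AffinityResult:
    tf_id: str
    mr_motifs: float
    mr_random: float
    relative_mr: float  # may be +inf; NaN never occurs (undefined raises)
    n_random: int
    seed: int

    @property
    def enriched(self) -> bool:
        return self.relative_mr > 2.0  # strict: "more than two-fold"


def counts_to_pwm(counts: np.ndarray, pseudocount: float = 0.01) -> np.ndarray:
    """Count matrix -> column-stochastic probabilities with a pseudocount."""
    counts = np.asarray(counts, dtype=float) + pseudocount
    return counts / counts.sum(axis=0, keepdims=True)


def parse_transfac(path_or_handle) -> list[TFMatrix]:
    """Read TRANSFAC flat-file matrices (ID / P0 row layout)."""
    close = False
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
    try:
        records = bio_motifs.parse(handle, "TRANSFAC")
    finally:
        if close:
            handle.close()
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        tf_id = m.get("ID") or m.get("AC") or m.name or f"TF{len(out)}"
        out.append(TFMatrix(tf_id=tf_id, pwm=counts_to_pwm(counts)))
    return out


def parse_meme_minimal(path_or_handle) -> list[TFMatrix]:
    """Read MEME minimal-format motifs as TF matrices."""
    close = False
    if isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__"):
        handle = open(path_or_handle)
        close = True
    else:
        handle = path_or_handle
    try:
        records = bio_motifs.parse(handle, "minimal")
    finally:
        if close:
            handle.close()
    out = []
    for m in records:
        pwm = np.array([m.pwm[b] for b in "ACGT"], dtype=float)
        out.append(TFMatrix(tf_id=m.name, pwm=pwm / pwm.sum(axis=0, keepdims=True)))
    return out


def _element_profile(element: str) -> np.ndarray:
    """4 x L weights; ambiguity codes spread weight over their expansions."""
    element = element.upper()
    W = np.zeros((4, len(element)))
    for j, ch in enumerate(element):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in element")
        bases = IUPAC[ch]
        for b in bases:
            W[_BASE_INDEX[b], j] = 1.0 / len(bases)
    return W


def element_pwm_match(
    element: str,
    tf: TFMatrix,
    tau: float = 0.8,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[bool, float]:
    """Best ungapped log-odds of an element against a PWM; matched at >= tau.

    The shorter of element and PWM slides along the longer; only overlapped
    columns are scored, against the best achievable score on that same
    overlap.  Ambiguity codes score as the mean over their expansions.
    """
    if len(element) < MIN_ELEMENT_LENGTH:
        raise ValueError("element length must exceed 5")
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    bg = np.asarray(background, dtype=float)[:, None]
    M = np.log(np.maximum(tf.pwm, 1e-12) / bg)  # 4 x Lp
    col_max = M.max(axis=0)
    W = _element_profile(element)
    best_score = -math.inf
    matched = False
    for Wo in (W, W[::-1, ::-1]):  # element as given and reverse-complemented
        Le, Lp = Wo.shape[1], M.shape[1]
        if Le <= Lp:
            for off in range(Lp - Le + 1):
                sc = float((Wo * M[:, off : off + Le]).sum())
                mx = float(col_max[off : off + Le].sum())
                best_score = max(best_score, sc)
                if mx > 0 and sc >= tau * mx - 1e-9:
                    matched = True
        else:
            for off in range(Le - Lp + 1):
                sc = float((Wo[:, off : off + Lp] * M).sum())
                mx = float(col_max.sum())
                best_score = max(best_score, sc)
                if mx > 0 and sc >= tau * mx - 1e-9:
                    matched = True
    return matched, best_score


def _match_plain_batch(codes: np.ndarray, M: np.ndarray, tau: float) -> np.ndarray:
    """Vectorised matched flags for plain-ACGT elements given as code rows.

    Same scoring rule as :func:`element_pwm_match`, restricted to unambiguous
    sequences so the whole batch is evaluated with array indexing.
    """
    n, Le = codes.shape
    Lp = M.shape[1]
    matched = np.zeros(n, dtype=bool)
    for Mo in (M, M[::-1, ::-1]):  # element strand handled via the PWM
        col_max = Mo.max(axis=0)
        if Le <= Lp:
            for off in range(Lp - Le + 1):
                sub = Mo[:, off : off + Le]
                sc = sub[codes, np.arange(Le)].sum(axis=1)
                mx = col_max[off : off + Le].sum()
                if mx > 0:
                    matched |= sc >= tau * mx - 1e-9
        else:
            mx = col_max.sum()
            for off in range(Le - Lp + 1):
                sc = Mo[codes[:, off : off + Lp], np.arange(Lp)].sum(axis=1)
                if mx > 0:
                    matched |= sc >= tau * mx - 1e-9
    return matched


def filter_elements(elements: Iterable[str]) -> tuple[list[str], list[str]]:
    """Split elements into (kept, too-short); the length-5 filter."""
    kept, dropped = [], []
    for e in elements:
        (kept if len(e) >= MIN_ELEMENT_LENGTH else dropped).append(e)
    return kept, dropped


def match_ratio(
    elements: Sequence[str],
    tf: TFMatrix,
    tau: float = 0.8,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Fraction of (length-filtered) elements matching the TF's PWM."""
    kept, _ = filter_elements(elements)
    if not kept:
        raise UndefinedResultError("no elements longer than 5 bases")
    n = sum(element_pwm_match(e, tf, tau, background)[0] for e in kept)
    return n / len(kept)


def relative_match_ratio(
    motif_elements: Sequence[str],
    tf: TFMatrix,
    n_random: int = 1000,
    seed: int = 0,
    tau: float = 0.8,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> AffinityResult:
    """MR of the motif set versus a pooled same-length random-sequence null.

    For every motif, ``n_random`` i.i.d. sequences of the same length are
    drawn from the background composition and pooled into one null set.  A
    null MR of zero with a positive motif MR yields +inf (enriched); both
    zero raises UndefinedResultError.  Deterministic given the seed.
    """
    kept, _ = filter_elements(motif_elements)
    if not kept:
        raise UndefinedResultError("no elements longer than 5 bases")
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=float)
    mr_motifs = match_ratio(kept, tf, tau, background)
    M = np.log(np.maximum(tf.pwm, 1e-12) / bg[:, None])
    n_matched = 0
    n_null = 0
    for e in kept:
        draws = rng.choice(4, size=(n_random, len(e)), p=bg)
        n_matched += int(_match_plain_batch(draws, M, tau).sum())
        n_null += n_random
    mr_random = n_matched / n_null
    if mr_random == 0.0 and mr_motifs == 0.0:
        raise UndefinedResultError("both match ratios are zero")
    rel = math.inf if mr_random == 0.0 else mr_motifs / mr_random
    return AffinityResult(tf.tf_id, mr_motifs, mr_random, rel, n_random, seed)


def affinity_screen(
    motif_elements: Sequence[str],
    pwm_library: Sequence[TFMatrix],
    n_random: int = 1000,
    seed: int = 0,
    tau: float = 0.8,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[pd.DataFrame, list[str]]:
    """Relative MR of the motif set against every TF in a PWM library.

    Returns one row per TF (ordered by tf id) and the list of elements that
    failed the length filter.  TFs whose statistic is undefined are reported
    with NaN ratios and enriched = False.
    """
    if not pwm_library:
        raise ValueError("need at least one PWM")
    kept, dropped = filter_elements(motif_elements)
    rows = []
    for tf in sorted(pwm_library, key=lambda t: t.tf_id):
        try:
            r = relative_match_ratio(kept, tf, n_random, seed, tau, background)
            rows.append(
                dict(
                    tf_id=r.tf_id, mr_motifs=r.mr_motifs, mr_random=r.mr_random,
                    relative_mr=r.relative_mr, enriched=r.enriched,
                )
            )
        except UndefinedResultError:
            rows.append(
                dict(
                    tf_id=tf.tf_id, mr_motifs=math.nan, mr_random=math.nan,
                    relative_mr=math.nan, enriched=False,
                )
            )
    df = pd.DataFrame(rows, columns=["tf_id", "mr_motifs", "mr_random", "relative_mr", "enriched"])
    return df, dropped
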