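"""Detection of candidate motif-recruitment events.

A motif is a recruitment candidate for an ortholog pair when (a) it is
differentially distributed — present in the C4 gene's promoter and absent
from the promoter of its C3 ortholog — and (b) it is present in at least one
gene directly linked to the C3 ortholog in the C3 gene regulatory network
(the candidate donors).  The mode of the event follows the donor's C4
ortholog: a donor that retains the motif indicates copy-and-paste, donors
that all lost it indicate cut-and-paste.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

GAINED, LOST, SHARED, ABSENT = "gained_in_C4", "lost_in_C4", "shared", "absent"
COPY, CUT, UNDETERMINED = "copy_paste", "cut_paste", "undetermined"


@dataclass(frozen=True)
class OrthologPair:
    c4_gene: str
    c3_gene: str


@dataclass
class RecruitmentEvent:
    motif_id: str
    acceptor: str  # C4 gene id
    acceptor_c3_ortholog: str
    donors: list[str] = field(default_factory=list)  # C3 gene ids
    mode: str = UNDETERMINED


def _presence(presence: pd.DataFrame, motif_id: str, gene: str) -> bool:
    if gene not in presence.columns:
        raise KeyError(f"gene {gene!r} missing from the presence table")
    if motif_id not in presence.index:
        raise KeyError(f"motif {motif_id!r} missing from the presence table")
    return bool(presence.loc[motif_id, gene])


def differential_distribution(
    motif_id: str, presence: pd.DataFrame, ortholog_map: pd.DataFrame
) -> pd.Series:
    """Per-pair distribution status of one motif across the ortholog pairs.

    The presence table is boolean (motifs x genes) and must cover both
    members of every pair; a missing gene raises KeyError naming it.
    """
    statuses = {}
    for _, pair in ortholog_map.iterrows():
        c4, c3 = pair["c4_id"], pair["c3_id"]
        in_c4 = _presence(presence, motif_id, c4)
        in_c3 = _presence(presence, motif_id, c3)
        if in_c4 and not in_c3:
            status = GAINED
        elif in_c3 and not in_c4:
            status = LOST
        elif in_c4:
            status = SHARED
        else:
            status = ABSENT
        statuses[c4] = status
    return pd.Series(statuses, name=motif_id)


def find_donors(
    motif_id: str, acceptor_c3_ortholog: str, c3_grn: nx.Graph, presence: pd.DataFrame
) -> list[str]:
    """Direct GRN neighbours of the C3 ortholog whose promoter has the motif."""
    if acceptor_c3_ortholog not in c3_grn:
        warnings.warn(
            f"{acceptor_c3_ortholog} absent from the GRN (variance-filtered?); no donors"
        )
        return []
    return sorted(
        nb
        for nb in c3_grn.neighbors(acceptor_c3_ortholog)
        if _presence(presence, motif_id, nb)
    )


def detect_recruitment(
    presence: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    c3_grn: nx.Graph,
    motif_ids: Iterable[str] | None = None,
) -> list[RecruitmentEvent]:
    """All (motif, acceptor) events: gained in C4 with at least one donor.

    The presence table covers both species' genes (ids are disjoint).
    Events are sorted by (motif, acceptor); invariants are re-checked on the
    output.
    """
    motif_ids = list(motif_ids) if motif_ids is not None else list(presence.index)
    events: list[RecruitmentEvent] = []
    for motif_id in motif_ids:
        status = differential_distribution(motif_id, presence, ortholog_map)
        for _, pair in ortholog_map.iterrows():
            c4, c3 = pair["c4_id"], pair["c3_id"]
            if status[c4] != GAINED:
                continue
            donors = find_donors(motif_id, c3, c3_grn, presence)
            if donors:
                events.append(RecruitmentEvent(motif_id, c4, c3, donors))
    events.sort(key=lambda e: (e.motif_id, e.acceptor))
    for e in events:
        _check_event(e, presence, c3_grn)
    return events


def _check_event(event: RecruitmentEvent, presence: pd.DataFrame, c3_grn: nx.Graph) -> None:
    assert event.donors, "event without donors"
    assert _presence(presence, event.motif_id, event.acceptor)
    assert not _presence(presence, event.motif_id, event.acceptor_c3_ortholog)
    for d in event.donors:
        assert c3_grn.has_edge(event.acceptor_c3_ortholog, d)
        assert _presence(presence, event.motif_id, d)


def classify_mode(
    event: RecruitmentEvent, presence: pd.DataFrame, ortholog_map: pd.DataFrame
) -> str:
    """Copy- vs cut-and-paste from the donors' C4 orthologs.

    Any donor whose C4 ortholog retains the motif -> copy_paste; all donors
    mapped and all lacking it -> cut_paste; otherwise undetermined.  This
    classification extends the donor/acceptor model to the data rather than
    reproducing a reported table.
    """
    c3_to_c4 = dict(zip(ortholog_map["c3_id"], ortholog_map["c4_id"]))
    saw_unmapped = False
    for d in event.donors:
        c4_d = c3_to_c4.get(d)
        if c4_d is None or c4_d not in presence.columns:
            saw_unmapped = True
            continue
        if _presence(presence, event.motif_id, c4_d):
            return COPY
    return UNDETERMINED if saw_unmapped else CUT


def classify_modes(
    events: Iterable[RecruitmentEvent], presence: pd.DataFrame, ortholog_map: pd.DataFrame
) -> None:
    for e in events:
        e.mode = classify_mode(e, presence, ortholog_map)


def events_to_frame(events: Iterable[RecruitmentEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": e.motif_id,
                "acceptor": e.acceptor,
                "acceptor_c3_ortholog": e.acceptor_c3_ortholog,
                "donors": ";".join(e.donors),
                "mode": e.mode,
            }
            for e in events
        ],
        columns=["motif_id", "acceptor", "acceptor_c3_ortholog", "donors", "mode"],
    )
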