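"""End-to-end orchestration: promoters -> scan -> GRN -> recruitment -> TE
evidence -> TF-binding enrichment, with a manifest and an optional evaluation
against a planted truth table.

Every stage writes its artifact as TSV/JSON into the output directory; a rerun
with an identical configuration reproduces the outputs byte for byte.  The GRN
stage either infers the network from an expression matrix (PCA-CMI) or loads a
precomputed edge list, since network reconstruction from large transcriptome
compendia is typically done once, upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from ._seqio import read_chromosome_table, read_fasta, read_gff3
from .binding_affinity import affinity_screen, parse_transfac
from .grn_inference import GRNConfig, pca_cmi, read_grn, write_grn
from .motif_tools import extract_promoters, occurrences_to_bed, scan_promoters
from .recruitment import RecruitmentEvent, classify_modes, detect_recruitment, events_to_frame
from .synthetic_data import TERecord
from .te_association import AlignParams, proximal_donor_proportion, te_evidence


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    # inputs
    genome_c3: str
    genome_c4: str
    genes_c3: str
    genes_c4: str
    orthologs: str
    motifs: str  # TSV: motif_id, consensus
    outdir: str
    te_library: str | None = None
    chromosomes: str | None = None
    expression: str | None = None
    grn_edges: str | None = None
    transfac: str | None = None
    truth_table: str | None = None
    # stage parameters
    promoter_length: int = 3000
    scan_method: str = "consensus"
    tau: float = 0.8
    theta: float = 0.03
    max_order: int = 1
    align: AlignParams = field(default_factory=AlignParams)
    n_random: int = 1000
    seed: int = 0
    run_te_stage: bool = True
    run_affinity_stage: bool = False

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "align" in raw and isinstance(raw["align"], dict):
            raw["align"] = AlignParams(**raw["align"])
        return cls(**raw)


@dataclass
class EvaluationReport:
    n_truth: int
    n_detected: int
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float | None  # None reported as NA when undefined
    recall: float | None
    f1: float | None
    te_confusion: dict[str, int] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("precision", "recall", "f1"):
            if d[k] is None:
                d[k] = "NA"
        return d


def evaluate_against_truth(
    events: list[RecruitmentEvent],
    te_supported: dict[tuple[str, str], bool] | None,
    truth_table: pd.DataFrame,
) -> EvaluationReport:
    """Event-level precision/recall/F1 keyed on (motif, acceptor), plus the
    TE-support confusion matrix against the planted te_mediated flags."""
    detected = {(e.motif_id, e.acceptor) for e in events}
    truth = {
        (row.motif_id, row.acceptor_c4): bool(row.te_mediated)
        for row in truth_table.itertuples()
    }
    tp = len(detected & set(truth))
    fp = len(detected - set(truth))
    fn = len(set(truth) - detected)
    precision = tp / (tp + fp) if detected else None
    recall = tp / (tp + fn) if truth else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)

    confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    if te_supported is not None:
        for key in detected & set(truth):
            pred = bool(te_supported.get(key, False))
            true = truth[key]
            if pred and true:
                confusion["tp"] += 1
            elif pred and not true:
                confusion["fp"] += 1
            elif not pred and true:
                confusion["fn"] += 1
            else:
                confusion["tn"] += 1
    return EvaluationReport(
        n_truth=len(truth), n_detected=len(detected),
        true_positives=tp, false_positives=fp, false_negatives=fn,
        precision=precision, recall=recall, f1=f1, te_confusion=confusion,
    )


def _read_motif_table(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_te_fasta(path) -> list[TERecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(None, 1)
        te_class = parts[1].strip() if len(parts) > 1 else "unknown"
        out.append(TERecord(rec.id, te_class, str(rec.seq).upper()))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a report dict (also written to report.json)."""
    required = {
        "genome_c3": config.genome_c3, "genome_c4": config.genome_c4,
        "genes_c3": config.genes_c3, "genes_c4": config.genes_c4,
        "orthologs": config.orthologs, "motifs": config.motifs,
    }
    if config.run_te_stage:
        required["te_library"] = config.te_library
        required["chromosomes"] = config.chromosomes
    if config.run_affinity_stage:
        required["transfac"] = config.transfac
    if config.grn_edges is None:
        required["expression"] = config.expression
    for name, path in required.items():
        if path is None or not Path(path).exists():
            raise PipelineError(f"stage 'validate': missing input '{name}' ({path})")

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}': {exc}") from exc

    # promoters
    def _promoters():
        genome_c3 = read_fasta(config.genome_c3)
        genome_c4 = read_fasta(config.genome_c4)
        genes_c3 = read_gff3(config.genes_c3)
        genes_c4 = read_gff3(config.genes_c4)
        p3 = extract_promoters(genome_c3, genes_c3, config.promoter_length)
        p4 = extract_promoters(genome_c4, genes_c4, config.promoter_length)
        return genes_c3, genes_c4, p3, p4

    genes_c3, genes_c4, prom_c3, prom_c4 = stage("promoters", _promoters)

    # scan
    motifs = _read_motif_table(config.motifs)

    def _scan():
        occ3, pres3 = scan_promoters(prom_c3, motifs, config.scan_method, config.tau)
        occ4, pres4 = scan_promoters(prom_c4, motifs, config.scan_method, config.tau)
        presence = pd.concat([pres3, pres4], axis=1)
        presence.to_csv(out / "presence.tsv", sep="\t", index_label="motif_id")
        prom_by_gene = {p.gene_id: p for p in prom_c3 + prom_c4}
        occurrences_to_bed(occ3 + occ4, prom_by_gene, out / "occurrences.bed")
        return occ3, occ4, presence

    occ3, occ4, presence = stage("scan", _scan)

    # GRN
    def _grn():
        if config.grn_edges:
            return read_grn(config.grn_edges)
        expr = pd.read_csv(config.expression, sep="\t", index_col=0)
        g = pca_cmi(expr, GRNConfig(theta=config.theta, max_order=config.max_order))
        return g

    grn = stage("grn", _grn)
    write_grn(grn, out / "grn.tsv")

    # recruitment
    ortholog_map = pd.read_csv(config.orthologs, sep="\t")

    def _recruit():
        events = detect_recruitment(presence, ortholog_map, grn)
        classify_modes(events, presence, ortholog_map)
        events_to_frame(events).to_csv(out / "events.tsv", sep="\t", index=False)
        return events

    events = stage("recruitment", _recruit)

    # TE evidence
    te_supported = None
    n_te_supported = 0
    n_proximal_events = 0
    if config.run_te_stage:
        def _te():
            te_library = read_te_fasta(config.te_library)
            chroms = read_chromosome_table(config.chromosomes)
            gm = {g.gene_id: g for g in genes_c3}
            donor_proms = {p.gene_id: p for p in prom_c3}
            ev_df, supported = te_evidence(
                events, motifs, te_library, donor_proms, occ3, gm, chroms,
                params=config.align, method=config.scan_method, tau=config.tau,
            )
            ev_df.to_csv(out / "te_evidence.tsv", sep="\t", index=False)
            props = pd.DataFrame(
                [
                    {
                        "motif_id": e.motif_id,
                        "acceptor": e.acceptor,
                        "proximal_donor_proportion": proximal_donor_proportion(e, gm, chroms),
                    }
                    for e in events
                ],
                columns=["motif_id", "acceptor", "proximal_donor_proportion"],
            )
            props.to_csv(out / "proximal_proportions.tsv", sep="\t", index=False)
            return supported, props

        te_supported, props = stage("te_evidence", _te)
        n_te_supported = sum(te_supported.values())
        n_proximal_events = int((props["proximal_donor_proportion"] > 0).sum())

    # TF-binding enrichment of the recruited motifs
    n_enriched = 0
    if config.run_affinity_stage:
        def _affinity():
            library = parse_transfac(config.transfac)
            recruited = sorted({motifs[e.motif_id] for e in events})
            table, dropped = affinity_screen(
                recruited, library, n_random=config.n_random, seed=config.seed, tau=config.tau
            )
            table.to_csv(out / "affinity.tsv", sep="\t", index=False)
            if dropped:
                (out / "affinity_filtered_elements.txt").write_text("\n".join(dropped) + "\n")
            return table

        affinity_table = stage("affinity", _affinity)
        n_enriched = int(affinity_table["enriched"].sum())

    # report / evaluation
    gained = 0
    for motif_id in presence.index:
        c4p = presence.loc[motif_id, ortholog_map["c4_id"]].to_numpy()
        c3p = presence.loc[motif_id, ortholog_map["c3_id"]].to_numpy()
        gained += int((c4p & ~c3p).sum())
    report = {
        "version": __version__,
        "counts": {
            "motifs": len(motifs),
            "ortholog_pairs": len(ortholog_map),
            "candidate_tests": len(motifs) * len(ortholog_map),
            "differential_gained_in_c4": gained,
            "events_with_donor": len(events),
            "events_with_proximal_donor": n_proximal_events,
            "events_te_supported": n_te_supported,
            "tfs_enriched": n_enriched,
        },
    }
    if config.truth_table:
        truth = pd.read_csv(config.truth_table, sep="\t")
        evaluation = evaluate_against_truth(events, te_supported, truth)
        evaluation.stage_counts = dict(report["counts"])
        report["evaluation"] = evaluation.to_dict()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest = asdict(config)
    manifest["package_version"] = __version__
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
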