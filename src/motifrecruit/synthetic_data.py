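"""Two-species synthetic datasets with planted motif-recruitment events.

The generator emulates the inputs of a comparative promoter study of a C4
species and its C3 relative: two genomes with 1:1 orthologous gene models at
homologous coordinates, 3 kb promoters, a transposable-element library, a
planted gene regulatory network with linear-Gaussian expression, and a truth
table of recruitment events.  Each planted event realises the donor/acceptor
model: the motif is present in the donor's C3 promoter and in the acceptor's
C4 promoter, and absent from the acceptor's C3 promoter; cut-and-paste events
additionally lack the motif in the donor's C4 ortholog promoter, while
copy-and-paste events retain it.  TE-mediated events embed the motif inside a
TE copy that is inserted into both the donor C3 and the acceptor C4 promoter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._seqio import (
    ChromosomeInfo,
    GeneModel,
    revcomp,
    write_chromosome_table,
    write_fasta,
    write_gff3,
)

BASES = "ACGT"
TE_CLASSES = ("retrotransposon", "class_II", "MITE")


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the study conditions.

    40 ortholog pairs, 3 kb promoters, and element lengths above the
    length-5 filter are the conditions of the original analysis; the rest
    are desk-scale choices documented in the methods note.
    """

    seed: int = 42
    n_chromosomes: int = 2
    chromosome_length: int = 300_000
    n_genes_per_chromosome: int = 20
    promoter_length: int = 3000
    gene_length: int = 1000
    n_motifs: int = 10
    motif_length_range: tuple[int, int] = (10, 14)
    n_te: int = 12
    te_length_range: tuple[int, int] = (150, 400)
    n_recruitment_events: int = 10
    te_mediated_fraction: float = 0.5
    copy_paste_fraction: float = 0.5
    background_base_frequencies: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    mutation_rate_per_base: float = 0.0
    grn_edge_density: float = 0.08
    n_expression_samples: int = 200
    expression_noise_sd: float = 1.0
    max_retries: int = 20

    def validate(self) -> None:
        counts = dict(
            n_chromosomes=self.n_chromosomes,
            chromosome_length=self.chromosome_length,
            n_genes_per_chromosome=self.n_genes_per_chromosome,
            promoter_length=self.promoter_length,
            gene_length=self.gene_length,
            n_motifs=self.n_motifs,
            n_te=self.n_te,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_recruitment_events < 0:
            raise ValueError("n_recruitment_events must be >= 0")
        for name in ("te_mediated_fraction", "copy_paste_fraction", "mutation_rate_per_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.motif_length_range[0] <= 5:
            raise ValueError("minimum motif length must exceed 5")
        if self.motif_length_range[0] > self.motif_length_range[1]:
            raise ValueError("motif_length_range must be ordered")
        if self.te_length_range[0] > self.te_length_range[1]:
            raise ValueError("te_length_range must be ordered")
        freqs = np.asarray(self.background_base_frequencies, dtype=float)
        if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise ValueError("background_base_frequencies must be a 4-vector summing to 1")
        if self.n_recruitment_events > self.n_motifs:
            raise ValueError("need at least one motif per recruitment event")
        if self.te_length_range[1] + 40 > self.promoter_length:
            raise ValueError("promoter too short to hold a TE insert")
        if self.te_length_range[0] < self.motif_length_range[1] + 40:
            raise ValueError("TEs must be long enough to embed any motif with margins")
        # Gene layout must keep promoters of neighbouring genes disjoint so a
        # planted insert can never leak into another gene's promoter.
        spacing = self.chromosome_length // (self.n_genes_per_chromosome + 1)
        if spacing < self.gene_length + 2 * self.promoter_length + 100:
            raise ValueError("chromosome too short for non-overlapping promoters")


@dataclass(frozen=True)
class TERecord:
    te_id: str
    te_class: str
    seq: str


@dataclass
class SyntheticDataset:
    config: SimConfig
    chromosomes: list[ChromosomeInfo]
    genome_c3: dict[str, str]
    genome_c4: dict[str, str]
    genes_c3: list[GeneModel]
    genes_c4: list[GeneModel]
    ortholog_map: pd.DataFrame  # columns: c3_id, c4_id
    motifs: dict[str, str]  # motif_id -> consensus
    te_library: list[TERecord]
    grn_truth: nx.Graph  # nodes are c3 gene ids, 'weight' edge attribute
    truth_table: pd.DataFrame
    expression: pd.DataFrame = field(repr=False, default=None)


def _random_codes(rng: np.random.Generator, n: int, freqs: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=freqs).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


_CODE_LUT = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i


def _encode(s: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(s.encode(), dtype=np.uint8)]


def _contains(haystack: str, needle: str) -> bool:
    return needle in haystack or revcomp(needle) in haystack


def _promoter_genomic_interval(gene: GeneModel, plen: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.start - plen, gene.start
    return gene.end, gene.end + plen


def _promoter_seq(genome: Mapping[str, np.ndarray], gene: GeneModel, plen: int) -> str:
    a, b = _promoter_genomic_interval(gene, plen)
    s = _codes_to_str(genome[gene.chrom][a:b])
    return revcomp(s) if gene.strand == "-" else s


def _plant(
    genome: Mapping[str, np.ndarray], gene: GeneModel, plen: int, offset: int, insert: np.ndarray
) -> None:
    """Overwrite promoter bases [offset, offset+len) (5'->3') with ``insert``."""
    a, b = _promoter_genomic_interval(gene, plen)
    if gene.strand == "+":
        gs = a + offset
        genome[gene.chrom][gs : gs + len(insert)] = insert
    else:
        ge = b - offset
        rc = _encode(revcomp(_codes_to_str(insert)))
        genome[gene.chrom][ge - len(insert) : ge] = rc


def _mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    out = codes.copy()
    hits = rng.random(len(out)) < rate
    if hits.any():
        shifts = rng.integers(1, 4, size=int(hits.sum())).astype(np.uint8)
        out[hits] = (out[hits] + shifts) % 4
    return out


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full two-species dataset; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.background_base_frequencies, dtype=float)

    # --- chromosomes, genomes, gene layout ------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chromosomes = [ChromosomeInfo(c, config.chromosome_length) for c in chrom_names]
    genome_c3 = {c: _random_codes(rng, config.chromosome_length, freqs) for c in chrom_names}
    genome_c4 = {c: _random_codes(rng, config.chromosome_length, freqs) for c in chrom_names}

    spacing = config.chromosome_length // (config.n_genes_per_chromosome + 1)
    genes_c3: list[GeneModel] = []
    genes_c4: list[GeneModel] = []
    gi = 0
    for chrom in chrom_names:
        for k in range(config.n_genes_per_chromosome):
            start = (k + 1) * spacing
            strand = "+" if rng.random() < 0.5 else "-"
            genes_c3.append(
                GeneModel(f"c3g{gi:04d}", chrom, start, start + config.gene_length, strand)
            )
            genes_c4.append(
                GeneModel(f"c4g{gi:04d}", chrom, start, start + config.gene_length, strand)
            )
            gi += 1
    n_genes = gi
    ortholog_map = pd.DataFrame(
        {"c3_id": [g.gene_id for g in genes_c3], "c4_id": [g.gene_id for g in genes_c4]}
    )

    # --- planted GRN over C3 genes --------------------------------------
    grn = nx.Graph()
    grn.add_nodes_from(g.gene_id for g in genes_c3)
    ids_c3 = [g.gene_id for g in genes_c3]
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < config.grn_edge_density:
                grn.add_edge(ids_c3[i], ids_c3[j], weight=float(rng.choice((-1.0, 1.0))))

    # --- motifs ----------------------------------------------------------
    motifs: dict[str, str] = {}
    while len(motifs) < config.n_motifs:
        L = int(rng.integers(config.motif_length_range[0], config.motif_length_range[1] + 1))
        m = _codes_to_str(rng.integers(0, 4, size=L).astype(np.uint8))
        if m not in motifs.values():
            motifs[f"motif{len(motifs):03d}"] = m
    motif_ids = list(motifs)

    # --- event design -----------------------------------------------------
    n_ev = config.n_recruitment_events
    acceptor_idx = rng.choice(n_genes, size=n_ev, replace=False) if n_ev else np.array([], int)
    acceptor_set = set(int(i) for i in acceptor_idx)
    used_donors: set[int] = set()
    donor_idx: list[int] = []
    per_chrom = config.n_genes_per_chromosome
    for a in acceptor_idx:
        a = int(a)
        chrom_base = (a // per_chrom) * per_chrom
        k = a - chrom_base
        chosen = None
        for radius in (2, per_chrom):
            offs = [o for o in range(-radius, radius + 1) if o != 0]
            rng.shuffle(offs)
            for o in offs:
                kk = k + o
                cand = chrom_base + kk
                if 0 <= kk < per_chrom and cand not in acceptor_set and cand not in used_donors:
                    chosen = cand
                    break
            if chosen is not None:
                break
        if chosen is None:
            raise RuntimeError("could not place a donor gene for every event")
        used_donors.add(chosen)
        donor_idx.append(chosen)
        u, v = ids_c3[a], ids_c3[chosen]
        if not grn.has_edge(u, v):
            grn.add_edge(u, v, weight=float(rng.choice((-1.0, 1.0))))

    n_te_ev = int(round(config.te_mediated_fraction * n_ev))
    te_flags = np.array([True] * n_te_ev + [False] * (n_ev - n_te_ev))
    rng.shuffle(te_flags)
    n_copy = int(round(config.copy_paste_fraction * n_ev))
    copy_flags = np.array([True] * n_copy + [False] * (n_ev - n_copy))
    rng.shuffle(copy_flags)

    # --- TE library (event TEs carry their motif embedded) ----------------
    te_library: list[TERecord] = []
    event_te: list[str | None] = []
    te_slot = 0
    for e in range(n_ev):
        if te_flags[e]:
            L_te = int(rng.integers(config.te_length_range[0], config.te_length_range[1] + 1))
            codes = _random_codes(rng, L_te, freqs)
            m_codes = _encode(motifs[motif_ids[e]])
            emb = int(rng.integers(20, L_te - len(m_codes) - 20 + 1))
            codes[emb : emb + len(m_codes)] = m_codes
            te_id = f"TE{te_slot:03d}"
            te_library.append(TERecord(te_id, TE_CLASSES[te_slot % 3], _codes_to_str(codes)))
            event_te.append(te_id)
            te_slot += 1
        else:
            event_te.append(None)
    event_motifs = [motifs[motif_ids[e]] for e in range(n_ev)]
    while te_slot < config.n_te:
        L_te = int(rng.integers(config.te_length_range[0], config.te_length_range[1] + 1))
        for _ in range(config.max_retries):
            codes = _random_codes(rng, L_te, freqs)
            s = _codes_to_str(codes)
            if not any(_contains(s, m) for m in event_motifs):
                break
        else:
            raise RuntimeError("could not draw a TE free of event motifs")
        te_library.append(TERecord(f"TE{te_slot:03d}", TE_CLASSES[te_slot % 3], s))
        te_slot += 1

    # --- plant events -----------------------------------------------------
    plen = config.promoter_length
    rows = []
    for e in range(n_ev):
        motif_id = motif_ids[e]
        m_codes = _encode(motifs[motif_id])
        acc3 = genes_c3[int(acceptor_idx[e])]
        acc4 = genes_c4[int(acceptor_idx[e])]
        don3 = genes_c3[donor_idx[e]]
        don4 = genes_c4[donor_idx[e]]

        if te_flags[e]:
            te_codes = next(_encode(t.seq) for t in te_library if t.te_id == event_te[e])
            emb = _codes_to_str(te_codes).find(motifs[motif_id])
            base_insert = te_codes
            motif_span = (emb, emb + len(m_codes))
        else:
            base_insert = m_codes
            motif_span = (0, len(m_codes))
        if len(base_insert) > plen:
            raise ValueError("promoter too short to hold the planted insert")

        def _fresh_insert() -> np.ndarray:
            ins = base_insert.copy()
            a, b = motif_span
            ins[a:b] = _mutate_codes(ins[a:b], config.mutation_rate_per_base, rng)
            return ins

        off_don = int(rng.integers(0, plen - len(base_insert) + 1))
        off_acc = int(rng.integers(0, plen - len(base_insert) + 1))
        _plant(genome_c3, don3, plen, off_don, _fresh_insert())
        _plant(genome_c4, acc4, plen, off_acc, _fresh_insert())
        if copy_flags[e]:
            off_don4 = int(rng.integers(0, plen - len(base_insert) + 1))
            _plant(genome_c4, don4, plen, off_don4, _fresh_insert())

        rows.append(
            dict(
                motif_id=motif_id,
                motif=motifs[motif_id],
                acceptor_c4=acc4.gene_id,
                acceptor_c3=acc3.gene_id,
                donor_c3=don3.gene_id,
                donor_c4=don4.gene_id,
                mode="copy" if copy_flags[e] else "cut",
                te_mediated=bool(te_flags[e]),
                te_id=event_te[e] or "",
                planted_offset_acceptor=off_acc + motif_span[0],
                planted_offset_donor=off_don + motif_span[0],
            )
        )
    truth_table = pd.DataFrame(
        rows,
        columns=[
            "motif_id", "motif", "acceptor_c4", "acceptor_c3", "donor_c3", "donor_c4",
            "mode", "te_mediated", "te_id", "planted_offset_acceptor", "planted_offset_donor",
        ],
    )

    # --- collision scrubbing (bounded retries, then error) ----------------
    def _ensure_absent(genome, gene: GeneModel, motif: str) -> None:
        for _ in range(config.max_retries):
            if not _contains(_promoter_seq(genome, gene, plen), motif):
                return
            a, b = _promoter_genomic_interval(gene, plen)
            genome[gene.chrom][a:b] = _random_codes(rng, b - a, freqs)
        raise RuntimeError(
            f"motif collision in promoter of {gene.gene_id} persisted after retries"
        )

    for e in range(n_ev):
        m = motifs[motif_ids[e]]
        _ensure_absent(genome_c3, genes_c3[int(acceptor_idx[e])], m)
        if not copy_flags[e]:
            _ensure_absent(genome_c4, genes_c4[donor_idx[e]], m)

    # --- expression from the planted GRN ----------------------------------
    expr_seed = int(rng.integers(2**31 - 1))
    expression = generate_expression(
        grn, config.n_expression_samples, config.expression_noise_sd, expr_seed
    )
    expression = expression.loc[ids_c3]  # row order matches gene models

    return SyntheticDataset(
        config=config,
        chromosomes=chromosomes,
        genome_c3={c: _codes_to_str(v) for c, v in genome_c3.items()},
        genome_c4={c: _codes_to_str(v) for c, v in genome_c4.items()},
        genes_c3=genes_c3,
        genes_c4=genes_c4,
        ortholog_map=ortholog_map,
        motifs=motifs,
        te_library=te_library,
        grn_truth=grn,
        truth_table=truth_table,
        expression=expression,
    )


def generate_expression(
    grn_truth: nx.Graph, n_samples: int, noise_sd: float, seed: int
) -> pd.DataFrame:
    """Linear-Gaussian expression from a signed-weight graph.

    Edges are oriented by sorted node order (low -> high), making the model a
    DAG; each gene is the weighted sum of its parents plus N(0, noise_sd^2)
    noise.  Returns a genes x samples DataFrame with no missing values.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3 (downstream covariance undefined)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    order = sorted(grn_truth.nodes)
    idx = {g: i for i, g in enumerate(order)}
    X = np.zeros((len(order), n_samples))
    for g in order:
        i = idx[g]
        val = noise_sd * rng.standard_normal(n_samples)
        for nb in grn_truth.neighbors(g):
            j = idx[nb]
            if j < i:
                val = val + grn_truth[g][nb].get("weight", 1.0) * X[j]
        X[i] = val
    return pd.DataFrame(X, index=order, columns=[f"s{j:04d}" for j in range(n_samples)])


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text; byte-identical for equal configs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_c3": out / "genome_c3.fa",
        "genome_c4": out / "genome_c4.fa",
        "genes_c3": out / "genes_c3.gff3",
        "genes_c4": out / "genes_c4.gff3",
        "orthologs": out / "orthologs.tsv",
        "motifs": out / "motifs.tsv",
        "te_library": out / "te_library.fa",
        "grn_truth": out / "grn_truth.tsv",
        "expression": out / "expression.tsv",
        "truth_table": out / "truth_table.tsv",
        "chromosomes": out / "chromosomes.tsv",
        "config": out / "config.json",
    }
    write_fasta(ds.genome_c3, paths["genome_c3"])
    write_fasta(ds.genome_c4, paths["genome_c4"])
    write_gff3(ds.genes_c3, paths["genes_c3"])
    write_gff3(ds.genes_c4, paths["genes_c4"])
    ds.ortholog_map.to_csv(paths["orthologs"], sep="\t", index=False)
    pd.DataFrame(
        {"motif_id": list(ds.motifs), "consensus": list(ds.motifs.values())}
    ).to_csv(paths["motifs"], sep="\t", index=False)
    write_fasta(
        {t.te_id: t.seq for t in ds.te_library},
        paths["te_library"],
        descriptions={t.te_id: t.te_class for t in ds.te_library},
    )
    edges = pd.DataFrame(
        [(u, v, d.get("weight", 1.0)) for u, v, d in sorted(ds.grn_truth.edges(data=True))],
        columns=["gene_a", "gene_b", "weight"],
    )
    edges.to_csv(paths["grn_truth"], sep="\t", index=False)
    ds.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    ds.truth_table.to_csv(paths["truth_table"], sep="\t", index=False)
    write_chromosome_table(ds.chromosomes, paths["chromosomes"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(ds.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
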