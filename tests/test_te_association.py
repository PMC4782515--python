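"""Distances, Smith-Waterman alignment vs a full-DP oracle, TE evidence."""

import math

import numpy as np
import pytest

import motifrecruit as mr
from motifrecruit._seqio import GeneModel, revcomp
from motifrecruit.te_association import (
    AlignParams,
    chromosome_distance,
    local_align,
    motif_in_overlap,
    proximal_donor_proportion,
    te_evidence,
)
from motifrecruit.motif_tools import MotifOccurrence

CHROMS = {"chr1": 30_000_000, "chr2": 30_000_000}


def gene(gid, chrom, start, strand="+"):
    return GeneModel(gid, chrom, start, start + 1000, strand)


def oracle_affine_sw(a: str, b: str, p: AlignParams):
    """Plain-Python full-DP affine Smith-Waterman (score + intervals)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + p.gap_open, E[i - 1][j] + p.gap_extend)
            F[i][j] = max(H[i][j - 1] + p.gap_open, F[i][j - 1] + p.gap_extend)
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    # traceback for start coordinates
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            if H[i][j] <= 0:
                break
            s = p.match if a[i - 1] == b[j - 1] else p.mismatch
            if H[i][j] == H[i - 1][j - 1] + s:
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i][j] == E[i - 1][j] + p.gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:
            if F[i][j] == F[i][j - 1] + p.gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
    return best, (i, bi), (j, bj)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestChromosomeDistance:
    def test_equal_starts_give_zero_and_proximal(self):
        r = chromosome_distance(gene("a", "chr1", 5_000_000), gene("d", "chr1", 5_000_000), CHROMS)
        assert r.d == 0.0 and r.proximal

    def test_exact_tenth_is_not_proximal(self):
        # d = 3,000,000 / 30,000,000 = 0.1 exactly; the cutoff is strict
        r = chromosome_distance(gene("a", "chr1", 9_000_000), gene("d", "chr1", 12_000_000), CHROMS)
        assert r.d == pytest.approx(0.1)
        assert not r.proximal

    def test_different_chromosomes_never_proximal(self):
        r = chromosome_distance(gene("a", "chr1", 0), gene("d", "chr2", 0), CHROMS)
        assert math.isnan(r.d) and not r.proximal and not r.same_chromosome

    def test_unknown_chromosome_raises(self):
        with pytest.raises(KeyError):
            chromosome_distance(gene("a", "chrX", 0), gene("d", "chr1", 0), CHROMS)

    def test_antisymmetry_on_random_layouts(self):
        rng = np.random.default_rng(40)
        for _ in range(50):
            a = gene("a", "chr1", int(rng.integers(0, 30_000_000)))
            d = gene("d", "chr1", int(rng.integers(0, 30_000_000)))
            assert chromosome_distance(a, d, CHROMS).d == -chromosome_distance(d, a, CHROMS).d


class TestProximalProportion:
    def test_counts_match_enumeration_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            gm = {"acc": gene("acc", "chr1", 15_000_000)}
            donors = []
            for i in range(int(rng.integers(1, 6))):
                gid = f"d{i}"
                gm[gid] = gene(gid, "chr1", int(rng.integers(0, 30_000_000)))
                donors.append(gid)
            event = mr.RecruitmentEvent("m", "x", "acc", donors=donors)
            expected = sum(
                abs((gm[d].start - gm["acc"].start) / 30_000_000) < 0.1 for d in donors
            ) / len(donors)
            assert proximal_donor_proportion(event, gm, CHROMS) == expected

    def test_single_proximal_donor_gives_one(self):
        gm = {"acc": gene("acc", "chr1", 1000), "d": gene("d", "chr1", 2000)}
        event = mr.RecruitmentEvent("m", "x", "acc", donors=["d"])
        assert proximal_donor_proportion(event, gm, CHROMS) == 1.0


class TestLocalAlign:
    def test_exact_copy_aligns_end_to_end_at_full_identity(self):
        rng = np.random.default_rng(42)
        te = random_seq(rng, 60)
        (hit,) = local_align(te, te)
        assert (hit.prom_start, hit.prom_end) == (0, 60)
        assert (hit.te_start, hit.te_end) == (0, 60)
        assert hit.identity == 100.0
        assert hit.score == 60.0  # match * len, the self-alignment invariant

    def test_planted_fragment_interval_matches_dp_oracle(self):
        rng = np.random.default_rng(43)
        te = random_seq(rng, 120)
        frag = te[30:70]  # 40 bp planted fragment
        prom = random_seq(rng, 130) + frag + random_seq(rng, 130)
        hits = local_align(te, prom)
        assert hits, "planted fragment not found"
        top = hits[0]
        score, (ts, te_), (ps, pe) = oracle_affine_sw(te, prom, AlignParams())
        assert (top.prom_start, top.prom_end) == (ps, pe) == (130, 170)
        assert (top.te_start, top.te_end) == (ts, te_) == (30, 70)
        assert top.score == score == 40.0

    def test_reverse_orientation_fragment_detected_with_mapped_interval(self):
        rng = np.random.default_rng(44)
        te = random_seq(rng, 100)
        frag = revcomp(te[20:60])
        prom = random_seq(rng, 50) + frag + random_seq(rng, 50)
        (hit,) = local_align(te, prom)
        assert hit.strand == "-"
        assert (hit.prom_start, hit.prom_end) == (50, 90)
        assert (hit.te_start, hit.te_end) == (20, 60)
        assert revcomp(te[hit.te_start : hit.te_end]) == prom[hit.prom_start : hit.prom_end]

    def test_independent_random_sequences_rarely_align(self):
        # a chance 20-column, 80%-identity hit between 300-mers is possible
        # but rare; such hits are counted, not treated as errors
        rng = np.random.default_rng(45)
        n_hit = sum(
            bool(local_align(random_seq(rng, 300), random_seq(rng, 300)))
            for _ in range(100)
        )
        assert n_hit <= 10

    def test_reported_hits_respect_identity_gate(self):
        rng = np.random.default_rng(46)
        te = random_seq(rng, 80)
        mutated = list(te)
        for pos in rng.choice(80, 8, replace=False):  # 90% identity copy
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        prom = random_seq(rng, 40) + "".join(mutated) + random_seq(rng, 40)
        for hit in local_align(te, prom):
            assert hit.identity >= 80.0

    def test_two_planted_fragments_found_as_non_overlapping_hits(self):
        rng = np.random.default_rng(47)
        te = random_seq(rng, 100)
        prom = (
            random_seq(rng, 30) + te[0:40] + random_seq(rng, 60) + te[50:90] + random_seq(rng, 30)
        )
        hits = local_align(te, prom)
        assert len(hits) == 2
        intervals = sorted((h.prom_start, h.prom_end) for h in hits)
        assert intervals == [(30, 70), (130, 170)]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")


class TestMotifInOverlap:
    ALN = mr.LocalAlignment(100, 160, 0, 60, "+", 60.0, 100.0, 60)

    def occ(self, offset, length=10):
        return MotifOccurrence("m", "g", offset, "+", 1.0, length)

    def test_contained_occurrence_is_true(self):
        assert motif_in_overlap([self.ALN], self.occ(120))

    def test_straddling_occurrence_is_false(self):
        assert not motif_in_overlap([self.ALN], self.occ(155))

    def test_no_alignments_is_false(self):
        assert not motif_in_overlap([], self.occ(120))


class TestTeEvidence:
    def test_supported_flags_equal_planted_te_mediated(
        self, default_dataset, default_presence
    ):
        ds = default_dataset
        events = mr.detect_recruitment(
            default_presence["presence"], ds.ortholog_map, ds.grn_truth
        )
        gm = {g.gene_id: g for g in ds.genes_c3}
        proms = {p.gene_id: p for p in default_presence["p3"]}
        _, supported = te_evidence(
            events, ds.motifs, ds.te_library, proms, default_presence["occ3"],
            gm, {c.name: c.length for c in ds.chromosomes},
        )
        truth = {
            (r.motif_id, r.acceptor_c4): bool(r.te_mediated)
            for r in ds.truth_table.itertuples()
        }
        assert supported == truth
        # bare-motif events are never TE-supported, by construction
        for r in ds.truth_table[~ds.truth_table.te_mediated].itertuples():
            assert supported[(r.motif_id, r.acceptor_c4)] is False

    def test_te_aligning_away_from_occurrence_gives_no_support(self):
        rng = np.random.default_rng(48)
        motif = "ACGTACGTTGCA"
        prom_seq = random_seq(rng, 10) + motif + random_seq(rng, 178) + random_seq(rng, 0)
        copied = prom_seq[100:180]  # TE shares an 80 bp block far from the motif
        te_seq = copied + motif  # the TE itself carries the motif
        prom = mr.Promoter("d", prom_seq, "chr1", 0, len(prom_seq), "+")
        event = mr.RecruitmentEvent("m", "acc4", "acc3", donors=["d"])
        gm = {
            "acc3": gene("acc3", "chr1", 1000),
            "d": gene("d", "chr1", 2000),
        }
        occs = [MotifOccurrence("m", "d", 10, "+", 1.0, len(motif))]
        df, supported = te_evidence(
            [event], {"m": motif}, [mr.TERecord("te1", "MITE", te_seq)],
            {"d": prom}, occs, gm, CHROMS,
        )
        assert supported == {("m", "acc4"): False}
        assert not df.empty and not df["motif_in_overlap"].any()
        # the 80 bp block itself aligns, verified against the DP oracle
        score, _, (ps, pe) = oracle_affine_sw(te_seq, prom_seq, AlignParams())
        assert (df.iloc[0]["overlap_start"], df.iloc[0]["overlap_end"]) == (ps, pe) == (100, 180)
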