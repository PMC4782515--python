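# motifrecruit

Regulatory innovations often arrive second-hand: a promoter acquires a
cis-regulatory motif that already exists elsewhere in the genome, sometimes
carried there by a transposable element (TE). The motivating case is the
evolution of C4 photosynthesis, where C4 genes in a species such as maize show
promoter motifs that their C3 orthologs (e.g. in rice) lack. `motifrecruit`
implements the complete inference chain for detecting such **motif
recruitment** between two species' orthologous promoters, and for weighing the
evidence that a TE mediated it — together with a synthetic-data generator that
plants ground-truth events so every stage is testable without any external
genome or transcriptome downloads.

## The inference

A motif *m* is a **recruitment candidate** for an ortholog pair (C4 gene *a*,
C3 ortholog *a'*) when

1. *m* is **differentially distributed**: present in the 3 kb promoter
   upstream of the TSS of *a*, absent from the promoter of *a'*; and
2. *m* is present in the promoter of at least one **donor** — a gene directly
   linked to *a'* in a C3 gene regulatory network (GRN).

A donor whose own C4 ortholog retains *m* indicates a copy-and-paste
recruitment; donors that all lost it indicate cut-and-paste.

Supporting evidence that a TE moved the motif:

- **Proximity.** The chromosome-relative distance
  `d(acceptor, donor) = (donor start − acceptor start) / chromosome length`
  with `|d| < 0.1` called proximal (small distances favour transposition).
- **TE–promoter overlap.** Every TE containing *m* is locally aligned to the
  donor promoter (iterated Smith–Waterman, affine gaps, ≥ 80 % identity over
  ≥ 20 columns); the event is TE-supported if an occurrence of *m* lies
  entirely inside an alignment.
- **TF binding.** For a motif set *E* and a TF's position weight matrix, the
  match ratio is `MR(E, TF) = |elements matched to the TF binding site| / |E|`
  and enrichment is the relative match ratio
  `MR(motifs, TF) / MR(random same-length elements, TF)` against 1,000 random
  sequences per motif, with > 2-fold flagged as enriched. Elements of length
  ≤ 5 are excluded.

The GRN itself is reconstructed from expression with a path-consistency
algorithm on Gaussian (conditional) mutual information (PCA-CMI), partitioned
into communities with Markov clustering (MCL), and expression clusters are
chosen by K-means with a leave-one-condition-out figure of merit (FOM).

## Worked example

```python
import pandas as pd
import motifrecruit as mr

ds = mr.generate_dataset(mr.SimConfig(seed=42))          # 10 planted events
prom_c3 = mr.extract_promoters(ds.genome_c3, ds.genes_c3)
prom_c4 = mr.extract_promoters(ds.genome_c4, ds.genes_c4)
occ3, pres3 = mr.scan_promoters(prom_c3, ds.motifs)
_, pres4 = mr.scan_promoters(prom_c4, ds.motifs)
presence = pd.concat([pres3, pres4], axis=1)

events = mr.detect_recruitment(presence, ds.ortholog_map, ds.grn_truth)
mr.classify_modes(events, presence, ds.ortholog_map)
for e in events[:3]:
    print(e.motif_id, e.acceptor, e.donors, e.mode)
```

prints

```
motif000 c4g0005 ['c3g0006'] copy_paste
motif001 c4g0029 ['c3g0027'] cut_paste
motif002 c4g0020 ['c3g0021'] cut_paste
```

— each line is one detected event: the motif, the C4 gene that gained it, the
donor genes adjacent to its C3 ortholog in the GRN, and the inferred mode. On
this noise-free dataset all 10 planted events are recovered with no false
positives (precision = recall = 1.0), and `mr.te_evidence(...)` flags exactly
the 5 planted TE-mediated events as TE-supported. The `examples/` directory
holds one short script per capability (simulation, GRN inference and
clustering, scanning and recruitment, TE evidence, binding affinity, the full
file-based pipeline); each prints the numbers it computes and what they mean.

A thin CLI mirrors the pipeline stages:

```bash
motifrecruit simulate --seed 42 --outdir data/
motifrecruit run-all --config pipeline.json
```

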