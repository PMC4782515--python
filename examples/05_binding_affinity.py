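"""Are the recruited motifs plausible TF binding sites?

Computes the match ratio (MR) of a motif set against a TF position weight
matrix and compares it with the MR of 1,000 random same-length sequences per
motif: a relative MR above two-fold flags the TF as preferentially binding
the motifs.  Here the motifs are sampled from a 'planted' TF's PWM, so that
TF should light up while random decoy PWMs should not.
"""

import numpy as np

from motifrecruit.binding_affinity import TFMatrix, affinity_screen

rng = np.random.default_rng(0)
L = 8
consensus = rng.integers(0, 4, L)
pwm = np.full((4, L), 0.1 / 3)
pwm[consensus, np.arange(L)] = 0.9
planted = TFMatrix("planted_TF", pwm)

motifs = ["".join("ACGT"[rng.choice(4, p=pwm[:, j])] for j in range(L))
          for _ in range(10)]
decoys = []
for d in range(5):
    cols = rng.dirichlet(np.ones(4) * 0.5, size=L).T
    decoys.append(TFMatrix(f"decoy_{d}", cols / cols.sum(0)))

table, dropped = affinity_screen(motifs, [planted] + decoys, n_random=1000, seed=0)
print(table.to_string(index=False))
print("\nmr_motifs: fraction of motifs matching the PWM at 80% of its best "
      "log-odds; mr_random: same for the pooled random null; enriched means "
      "relative_mr > 2 (inf when no random sequence matched).")
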