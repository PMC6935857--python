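"""Collapse redundant single-cell transcripts of one species.

Builds a small transcript pool containing exact fragments and a
reverse-complement copy of a longer transcript, then applies the
redundancy rule (identity > 98% over >= 70% of the shorter sequence).
"""

import numpy as np

from ciliaevol import FilterParams, Transcript, collapse_redundant

rng = np.random.default_rng(1)
base = "".join("ACGT"[k] for k in rng.integers(0, 4, 360))
rc = base.translate(str.maketrans("ACGT", "TGCA"))[::-1]

pool = [
    Transcript("full", base, "Loxodes_sp"),
    Transcript("fragment", base[30:300], "Loxodes_sp"),  # exact substring
    Transcript("antisense", rc[10:290], "Loxodes_sp"),  # reverse complement
    Transcript("unrelated", "".join("ACGT"[k] for k in rng.integers(0, 4, 320)),
               "Loxodes_sp"),
]

kept = collapse_redundant(pool, FilterParams())
print(f"input: {len(pool)} transcripts, retained: {len(kept)}")
for t in kept:
    print(f"  kept {t.id} ({len(t)} nt)")
# 'fragment' and 'antisense' collapse onto 'full'; the unrelated transcript
# survives — this is the pool a diversity count should be built from.
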