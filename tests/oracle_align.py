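"""Exhaustive local-alignment oracle for small duplexes.

Enumerates every monotone pairing between miRNA positions and (reversed)
window positions, scoring pairs and affine gap runs directly from the scoring
parameters — no dynamic programming, so it is an independent check of the
aligner.  Feasible for miRNA <= 8 nt vs windows <= 12 nt.
"""

from itertools import combinations

from mirswitch.seedscan import AlignParams


def best_local_score(mirna: str, window: str, params: AlignParams = AlignParams()) -> float:
    rev = window[::-1]
    M, N = len(mirna), len(rev)
    best = 0.0
    pair_score = params.pair_score
    gap = params.gap_cost
    for k in range(1, min(M, N) + 1):
        for mis in combinations(range(M), k):
            for wjs in combinations(range(N), k):
                score = 0.0
                for idx in range(k):
                    score += pair_score(mis[idx] + 1, mirna[mis[idx]], rev[wjs[idx]])
                    if idx:
                        score += gap(mis[idx] - mis[idx - 1] - 1)
                        score += gap(wjs[idx] - wjs[idx - 1] - 1)
                if score > best:
                    best = score
    return best
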