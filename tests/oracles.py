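"""Independent reference implementations used to validate the fast paths.

These deliberately avoid the production code's seeding/capping shortcuts:
a full affine-gap Smith-Waterman with traceback, an exhaustive two-segment
split-read decomposition over every diagonal, and a brute-force direct
repeat search.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**6)


@njit(cache=False)
def _sw_fill(q, t, match, mis, gopen, gext):
    m, n = len(q), len(t)
    H = np.zeros((m + 1, n + 1), np.int32)
    Mh = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    Me = np.zeros((m + 1, n + 1), np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    Mf = np.zeros((m + 1, n + 1), np.int32)
    ptrH = np.zeros((m + 1, n + 1), np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = np.zeros((m + 1, n + 1), np.uint8)  # 1 open, 0 extend
    ptrF = np.zeros((m + 1, n + 1), np.uint8)
    best = (0, 0, 0, 0)  # score, matches, i, j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # E: consume query base (gap in target)
            eo = H[i - 1, j] - gopen - gext
            ee = E[i - 1, j] - gext
            if eo > ee or (eo == ee and Mh[i - 1, j] >= Me[i - 1, j]):
                E[i, j] = eo
                Me[i, j] = Mh[i - 1, j]
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                Me[i, j] = Me[i - 1, j]
                ptrE[i, j] = 0
            # F: consume target base (gap in query)
            fo = H[i, j - 1] - gopen - gext
            fe = F[i, j - 1] - gext
            if fo > fe or (fo == fe and Mh[i, j - 1] >= Mf[i, j - 1]):
                F[i, j] = fo
                Mf[i, j] = Mh[i, j - 1]
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                Mf[i, j] = Mf[i, j - 1]
                ptrF[i, j] = 0
            is_match = q[i - 1] == t[j - 1] and q[i - 1] < 4
            s = match if is_match else mis
            diag = H[i - 1, j - 1] + s
            mdiag = Mh[i - 1, j - 1] + (1 if is_match else 0)
            # choose max by (score, matches); 0 restart last
            sc, mt, pt = 0, 0, 0
            if diag > sc or (diag == sc and mdiag > mt):
                sc, mt, pt = diag, mdiag, 1
            if E[i, j] > sc or (E[i, j] == sc and Me[i, j] > mt):
                sc, mt, pt = E[i, j], Me[i, j], 2
            if F[i, j] > sc or (F[i, j] == sc and Mf[i, j] > mt):
                sc, mt, pt = F[i, j], Mf[i, j], 3
            H[i, j] = sc
            Mh[i, j] = mt
            ptrH[i, j] = pt
            if sc > best[0] or (sc == best[0] and mt > best[1]):
                best = (sc, mt, i, j)
    return H, ptrH, ptrE, ptrF, best


def smith_waterman(q, t, match=1, mis=-2, gopen=5, gext=2):
    """Optimal local alignment stats: (score, matches, columns, query_span).

    Gap of length k costs gopen + gext*k.  Among co-optimal cells/paths the
    one with the most matches is preferred.  N never matches.
    """
    q = np.asarray(q, dtype=np.uint8)
    t = np.asarray(t, dtype=np.uint8)
    H, ptrH, ptrE, ptrF, best = _sw_fill(q, t, match, mis, gopen, gext)
    score, _, i, j = best
    if score <= 0:
        return 0, 0, 0, 0
    matches = cols = qspan = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            pt = ptrH[i, j]
            if pt == 0:
                break
            if pt == 1:
                cols += 1
                qspan += 1
                if q[i - 1] == t[j - 1] and q[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif pt == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = ptrE[i, j]
            cols += 1
            qspan += 1
            i -= 1
            state = 0 if opened else 1
        else:
            opened = ptrF[i, j]
            cols += 1
            j -= 1
            state = 0 if opened else 2
    return int(score), int(matches), int(cols), int(qspan)


def sw_decision(q, t, id_cut, len_cut, **kw):
    """Accept/reject under the stringency cutoffs from the optimal alignment."""
    score, matches, cols, qspan = smith_waterman(q, t, **kw)
    if cols == 0:
        return False
    return matches / cols >= id_cut and qspan / len(q) >= len_cut


def exhaustive_split(codes, doubled, L, min_segment=15, min_total_frac=0.85,
                     contiguous_max_mm=3):
    """Exhaustive two-segment decomposition over every diagonal.

    Same contract as the production caller (score-maximal segment ends,
    rightmost 5' / leftmost 3' tie-break, coverage b2 <= e1, both segments
    >= min_segment, total matches >= min_total_frac * read length), but
    considering every diagonal of the circle rather than seeded candidates.
    Returns (b5_0based, b3_0based, total_matches) or None.
    """
    rl = len(codes)
    diags = np.arange(L)
    win = doubled[diags[:, None] + np.arange(rl)[None, :]]
    match = (win == codes[None, :]) & (codes[None, :] < 4)
    if (rl - match.sum(1)).min() <= contiguous_max_mm:
        return None
    P = np.zeros((L, rl + 1), dtype=np.int64)
    np.cumsum(match, axis=1, out=P[:, 1:])
    e_idx = np.arange(rl + 1)
    prefix_score = 3 * P - 2 * e_idx[None, :]
    suffix_score = 3 * (P[:, -1:] - P) - 2 * (rl - e_idx)[None, :]
    e1 = rl - np.argmax(prefix_score[:, ::-1], axis=1)
    b2 = np.argmax(suffix_score, axis=1)
    A = P[np.arange(L), e1]
    B = P[:, -1] - P[np.arange(L), b2]
    ok5 = (e1 >= min_segment) & (e1 < rl)
    ok3 = (rl - b2 >= min_segment) & (b2 > 0)
    best = None
    order5 = np.flatnonzero(ok5)
    order3 = np.flatnonzero(ok3)
    if not len(order5) or not len(order3):
        return None
    # full pair scan (L x L is fine at 2 kb)
    for i in order5:
        for j in order3:
            if i == j or b2[j] > e1[i]:
                continue
            total = A[i] + B[j]
            key = (-total, -e1[i], b2[j], diags[i], diags[j])
            if best is None or key < best[0]:
                best = (key, i, j)
    if best is None:
        return None
    i, j = best[1], best[2]
    total = int(A[i] + B[j])
    if total < min_total_frac * rl:
        return None
    b5 = (int(diags[i]) + int(e1[i]) - 1) % L
    b3 = (int(diags[j]) + int(b2[j])) % L
    return b5, b3, total


def brute_force_repeat(seq: str, b5: int, b3: int, L: int, W: int = 40) -> int:
    """Total junction ambiguity of ...b5 | b3... by sliding the junction.

    Builds the local rearranged-molecule string for every alternative
    junction assignment (b5+k, b3+k) and counts how far the junction can
    slide in each direction while producing an identical molecule.  Only
    valid when the deleted span exceeds ``W`` and no N falls in the window.
    """

    def mol(k):
        # the rearranged molecule around the junction when it is assigned
        # at (b5+k, b3+k), written in fixed molecule coordinates
        left = "".join(seq[(b5 - W + i) % L] for i in range(W + k))  # .. b5+k
        right = "".join(seq[(b3 + k - 1 + i) % L] for i in range(W - k))
        return left + right

    ref = mol(0)
    right = 0
    while right < W - 1 and mol(right + 1) == ref:
        right += 1
    left = 0
    while left < W - 1 and mol(-left - 1) == ref:
        left += 1
    return left + right
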