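"""Numba kernels for affine-gap local alignment and exact-word seeding.

The dynamic program is Gotoh's three-state local alignment where a gap of
length k costs ``gap_open + k * gap_extend`` (BLAST-style accounting: the
first gapped base pays both the open and the extend cost).  Alignment start
coordinates are propagated through the DP so hits can be reported as
half-open query/reference intervals without a traceback matrix; score ties
are broken toward the lowest reference start, then the lowest query start.

The same recurrence serves the exact oracle (band covering the whole matrix),
the seeded banded extension, and a score-only variant used for pool-scale
read screening.  A banded run only ever removes alignment paths, so its score
is a true alignment score and never exceeds the full-DP optimum.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def gotoh_local(q, r, match, mismatch, gap_oe, gap_ext, dlo, dhi):
    """Banded local affine alignment with start tracking.

    ``q``/``r`` are uint8 base codes; the band admits cells with diagonal
    ``d = i - j`` in ``[dlo, dhi]`` (i: 1-based reference row, j: 1-based
    query column).  ``gap_oe`` is open+extend (cost of a length-1 gap).
    Returns ``(score, qs, qe, rs, re)`` with 0-based half-open intervals;
    score 0 means no positive-scoring local alignment inside the band.
    """
    n = r.shape[0]
    m = q.shape[0]

    H_prev = np.zeros(m + 1, np.int64)
    F_prev = np.full(m + 1, NEG, np.int64)
    oHr_prev = np.zeros(m + 1, np.int64)
    oHq_prev = np.zeros(m + 1, np.int64)
    oFr_prev = np.zeros(m + 1, np.int64)
    oFq_prev = np.zeros(m + 1, np.int64)
    H_cur = np.zeros(m + 1, np.int64)
    F_cur = np.full(m + 1, NEG, np.int64)
    oHr_cur = np.zeros(m + 1, np.int64)
    oHq_cur = np.zeros(m + 1, np.int64)
    oFr_cur = np.zeros(m + 1, np.int64)
    oFq_cur = np.zeros(m + 1, np.int64)

    best = 0
    bqs = 0
    bqe = 0
    brs = 0
    bre = 0

    for i in range(1, n + 1):
        jlo = i - dhi
        if jlo < 1:
            jlo = 1
        jhi = i - dlo
        if jhi > m:
            jhi = m
        if jlo > jhi:
            if i - dlo < 1:
                # band not yet entered; row is semantically all-zero, which
                # is exactly what the initial buffers hold
                continue
            break  # band exhausted
        H_cur[jlo - 1] = 0
        F_cur[jlo - 1] = NEG
        E = NEG
        eor = 0
        eoq = 0
        rc = r[i - 1]
        for j in range(jlo, jhi + 1):
            # E: gap consuming query bases (horizontal move)
            e_open = H_cur[j - 1] - gap_oe
            if H_cur[j - 1] == 0:
                cor = i
                coq = j - 1
            else:
                cor = oHr_cur[j - 1]
                coq = oHq_cur[j - 1]
            e_ext = E - gap_ext
            if e_open > e_ext or (e_open == e_ext and (cor < eor or (cor == eor and coq < eoq))):
                E = e_open
                eor = cor
                eoq = coq
            else:
                E = e_ext
            # F: gap consuming reference bases (vertical move)
            f_open = H_prev[j] - gap_oe
            if H_prev[j] == 0:
                cor = i - 1
                coq = j
            else:
                cor = oHr_prev[j]
                coq = oHq_prev[j]
            f_ext = F_prev[j] - gap_ext
            if f_open > f_ext or (
                f_open == f_ext and (cor < oFr_prev[j] or (cor == oFr_prev[j] and coq < oFq_prev[j]))
            ):
                F_cur[j] = f_open
                oFr_cur[j] = cor
                oFq_cur[j] = coq
            else:
                F_cur[j] = f_ext
                oFr_cur[j] = oFr_prev[j]
                oFq_cur[j] = oFq_prev[j]
            # H: best of restart, diagonal, E, F
            if q[j - 1] == rc:
                diag = H_prev[j - 1] + match
            else:
                diag = H_prev[j - 1] + mismatch
            if H_prev[j - 1] == 0:
                dor = i - 1
                doq = j - 1
            else:
                dor = oHr_prev[j - 1]
                doq = oHq_prev[j - 1]
            hv = 0
            hor = i
            hoq = j
            if diag > hv or (diag == hv and (dor < hor or (dor == hor and doq < hoq))):
                hv = diag
                hor = dor
                hoq = doq
            if E > hv or (E == hv and (eor < hor or (eor == hor and eoq < hoq))):
                hv = E
                hor = eor
                hoq = eoq
            if F_cur[j] > hv or (
                F_cur[j] == hv and (oFr_cur[j] < hor or (oFr_cur[j] == hor and oFq_cur[j] < hoq))
            ):
                hv = F_cur[j]
                hor = oFr_cur[j]
                hoq = oFq_cur[j]
            H_cur[j] = hv
            oHr_cur[j] = hor
            oHq_cur[j] = hoq
            if hv > best or (hv == best and hv > 0 and (hor < brs or (hor == brs and hoq < bqs))):
                best = hv
                brs = hor
                bqs = hoq
                bre = i
                bqe = j
        if jhi + 1 <= m:
            H_cur[jhi + 1] = 0
            F_cur[jhi + 1] = NEG
        # roll rows
        H_prev, H_cur = H_cur, H_prev
        F_prev, F_cur = F_cur, F_prev
        oHr_prev, oHr_cur = oHr_cur, oHr_prev
        oHq_prev, oHq_cur = oHq_cur, oHq_prev
        oFr_prev, oFr_cur = oFr_cur, oFr_prev
        oFq_prev, oFq_cur = oFq_cur, oFq_prev

    if best <= 0:
        return 0, 0, 0, 0, 0
    return best, bqs, bqe, brs, bre


@njit(cache=True)
def gotoh_score(q, r, match, mismatch, gap_oe, gap_ext, dlo, dhi):
    """Score-only banded local affine alignment (same band semantics)."""
    n = r.shape[0]
    m = q.shape[0]
    H_prev = np.zeros(m + 1, np.int64)
    F_prev = np.full(m + 1, NEG, np.int64)
    H_cur = np.zeros(m + 1, np.int64)
    F_cur = np.full(m + 1, NEG, np.int64)
    best = 0
    for i in range(1, n + 1):
        jlo = i - dhi
        if jlo < 1:
            jlo = 1
        jhi = i - dlo
        if jhi > m:
            jhi = m
        if jlo > jhi:
            if i - dlo < 1:
                continue
            break
        H_cur[jlo - 1] = 0
        F_cur[jlo - 1] = NEG
        E = NEG
        rc = r[i - 1]
        for j in range(jlo, jhi + 1):
            e_open = H_cur[j - 1] - gap_oe
            e_ext = E - gap_ext
            E = e_open if e_open > e_ext else e_ext
            f_open = H_prev[j] - gap_oe
            f_ext = F_prev[j] - gap_ext
            F_cur[j] = f_open if f_open > f_ext else f_ext
            if q[j - 1] == rc:
                hv = H_prev[j - 1] + match
            else:
                hv = H_prev[j - 1] + mismatch
            if E > hv:
                hv = E
            if F_cur[j] > hv:
                hv = F_cur[j]
            if hv < 0:
                hv = 0
            H_cur[j] = hv
            if hv > best:
                best = hv
        if jhi + 1 <= m:
            H_cur[jhi + 1] = 0
            F_cur[jhi + 1] = NEG
        H_prev, H_cur = H_cur, H_prev
        F_prev, F_cur = F_cur, F_prev
    return best


@njit(cache=True)
def kmer_codes(codes, k):
    """Rolling 2-bit codes of all k-mers of a base-code array."""
    n = codes.shape[0] - k + 1
    if n < 1:
        return np.empty(0, np.int64)
    out = np.empty(n, np.int64)
    mask = (1 << (2 * k)) - 1
    v = 0
    for t in range(k):
        v = ((v << 2) | codes[t]) & mask
    out[0] = v
    for t in range(1, n):
        v = ((v << 2) | codes[t + k - 1]) & mask
        out[t] = v
    return out


@njit(cache=True)
def seed_diagonals(q_kmers, ref_codes_sorted, ref_pos_sorted):
    """Diagonals (ref_pos - query_pos) of all exact k-mer matches."""
    m = q_kmers.shape[0]
    los = np.empty(m, np.int64)
    his = np.empty(m, np.int64)
    total = 0
    for t in range(m):
        lo = np.searchsorted(ref_codes_sorted, q_kmers[t], side="left")
        hi = np.searchsorted(ref_codes_sorted, q_kmers[t], side="right")
        los[t] = lo
        his[t] = hi
        total += hi - lo
    out = np.empty(total, np.int64)
    idx = 0
    for t in range(m):
        for u in range(los[t], his[t]):
            out[idx] = ref_pos_sorted[u] - t
            idx += 1
    return out


@njit(cache=True)
def assign_scores(
    q,
    q_kmers,
    csr_codes,
    csr_pos,
    csr_offsets,
    ref_codes,
    ref_offsets,
    match,
    mismatch,
    gap_oe,
    gap_ext,
    band,
    top_k,
):
    """Best banded alignment score of one read against each screened design.

    Designs are screened by their densest seed-diagonal window (width
    ``2 * band + 1``); the ``top_k`` designs by window seed count — plus every
    design tying the k-th count, so exact duplicates are never separated by
    the heuristic — are extended with a score-only banded DP centered on the
    densest window.  Returns an int64 array of scores, -1 for designs that
    were not extended (no seeds or below the screening cut).
    """
    n_designs = csr_offsets.shape[0] - 1
    m = q_kmers.shape[0]
    qlen = q.shape[0]
    max_ref = 0
    for d in range(n_designs):
        rl = ref_offsets[d + 1] - ref_offsets[d]
        if rl > max_ref:
            max_ref = rl
    nbins = qlen + max_ref + 2
    bins = np.zeros(nbins, np.int64)
    screen = np.zeros(n_designs, np.int64)
    center = np.zeros(n_designs, np.int64)
    w = 2 * band + 1
    for d in range(n_designs):
        lo_off = csr_offsets[d]
        hi_off = csr_offsets[d + 1]
        codes_d = csr_codes[lo_off:hi_off]
        pos_d = csr_pos[lo_off:hi_off]
        for b in range(nbins):
            bins[b] = 0
        any_seed = False
        for t in range(m):
            lo = np.searchsorted(codes_d, q_kmers[t], side="left")
            hi = np.searchsorted(codes_d, q_kmers[t], side="right")
            for u in range(lo, hi):
                bins[pos_d[u] - t + qlen] += 1
                any_seed = True
        if not any_seed:
            screen[d] = 0
            continue
        rl = ref_offsets[d + 1] - ref_offsets[d]
        span = qlen + rl  # valid diagonal bins: [0, span)
        run = 0
        for b in range(min(w, span)):
            run += bins[b]
        best_run = run
        best_b = 0
        for b in range(1, span - w + 1):
            run += bins[b + w - 1] - bins[b - 1]
            if run > best_run:
                best_run = run
                best_b = b
        screen[d] = best_run
        center[d] = best_b + band - qlen  # center diagonal of the window
    # screening cut: the top_k-th largest positive count (ties included)
    scores = np.full(n_designs, -1, np.int64)
    if n_designs > top_k:
        tmp = np.sort(screen)[::-1]
        cut = tmp[top_k - 1]
        if cut < 1:
            cut = 1
    else:
        cut = 1
    for d in range(n_designs):
        if screen[d] < cut:
            continue
        rseq = ref_codes[ref_offsets[d] : ref_offsets[d + 1]]
        rl = rseq.shape[0]
        if qlen + rl <= w:
            dlo = -qlen
            dhi = rl
        else:
            dlo = center[d] - band
            dhi = center[d] + band
        scores[d] = gotoh_score(q, rseq, match, mismatch, gap_oe, gap_ext, dlo, dhi)
    return scores
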