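"""Exact MFE folding under the reduced nearest-neighbour model.

A Zuker-style dynamic program over three tables:

* ``V[i, j]``  — minimum energy of the subsequence i..j given that (i, j)
  is a base pair (hairpin / stack / bulge / internal / multiloop case);
* ``WM[i, j]`` — minimum energy of i..j inside a multiloop, containing at
  least one branch (unpaired multiloop bases are free, branches cost the
  per-branch term);
* ``W[j]``     — minimum energy of the exterior prefix 0..j.

The DP reports the exact optimum for the model (interior loops capped at
``max_interior`` unpaired bases, pseudoknots excluded).  Backpointers are
stored so the optimal structure can be rebuilt without re-deriving the
recursion in Python.  The all-unpaired structure has energy 0, so the
reported MFE is never positive.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._seq import encode, to_rna
from .energy import EnergyModel, INF, default_model, structure_energy

__all__ = ["fold_mfe", "pair_table", "structure_energy"]


@njit(cache=True)
def _fold_dp(enc, pair_cls, stack, hpen, bpen, ipen, mclose, mbranch, minloop, maxint):
    n = enc.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    # backpointers for V: kind 0=hairpin, 1=interior(k,l), 2=multi(split k)
    bVk = np.full((n, n), -1, dtype=np.int16)
    bVl = np.full((n, n), -1, dtype=np.int16)
    bVkind = np.full((n, n), -1, dtype=np.int8)
    # WM: kind 0 -> (i+1,j), 1 -> (i,j-1), 2 -> pair(i,j), 3 -> split k
    bWMkind = np.full((n, n), -1, dtype=np.int8)
    bWMk = np.full((n, n), -1, dtype=np.int16)

    for span in range(minloop + 1, n):
        for i in range(0, n - span):
            j = i + span
            ci = enc[i]
            cj = enc[j]
            cij = -1
            if ci < 4 and cj < 4:
                cij = pair_cls[ci, cj]
            if cij >= 0:
                # hairpin
                best = hpen[j - i - 1]
                kind = 0
                bk = -1
                bl = -1
                # interior (stack / bulge / internal)
                kmax = j - 1
                for k in range(i + 1, kmax):
                    lu = k - i - 1
                    if lu > maxint:
                        break
                    for l in range(j - 1, k, -1):
                        ru = j - l - 1
                        if lu + ru > maxint:
                            break
                        vkl = V[k, l]
                        if vkl >= INF:
                            continue
                        ck = pair_cls[enc[k], enc[l]]
                        if lu == 0 and ru == 0:
                            cost = stack[cij, ck]
                        elif lu == 0 or ru == 0:
                            cost = bpen[lu + ru]
                        else:
                            cost = ipen[lu + ru]
                        cand = vkl + cost
                        if cand < best:
                            best = cand
                            kind = 1
                            bk = k
                            bl = l
                # multiloop: (i,j) closes two+ branch segments
                for k in range(i + 2, j - 1):
                    a = WM[i + 1, k - 1]
                    if a >= INF:
                        continue
                    b = WM[k, j - 1]
                    if b >= INF:
                        continue
                    cand = mclose + mbranch + a + b
                    if cand < best:
                        best = cand
                        kind = 2
                        bk = k
                        bl = -1
                if best < INF:
                    V[i, j] = best
                    bVkind[i, j] = kind
                    bVk[i, j] = bk
                    bVl[i, j] = bl
            # WM
            best = WM[i + 1, j] if i + 1 <= j else INF
            kind = 0
            bk = -1
            c = WM[i, j - 1] if j - 1 >= i else INF
            if c < best:
                best = c
                kind = 1
            if V[i, j] + mbranch < best:
                best = V[i, j] + mbranch
                kind = 2
            for k in range(i + 1, j + 1):
                a = WM[i, k - 1]
                if a >= INF:
                    continue
                b = V[k, j]
                if b >= INF:
                    continue
                cand = a + b + mbranch
                if cand < best:
                    best = cand
                    kind = 3
                    bk = k
            if best < INF:
                WM[i, j] = best
                bWMkind[i, j] = kind
                bWMk[i, j] = bk

    W = np.zeros(n)
    bW = np.full(n, -1, dtype=np.int16)  # -1: j unpaired; else i pairs j
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        bi = -1
        for i in range(0, j):
            v = V[i, j]
            if v >= INF:
                continue
            cand = (W[i - 1] if i > 0 else 0.0) + v
            if cand < best:
                best = cand
                bi = i
        W[j] = best
        bW[j] = bi
    return V, WM, W, bVkind, bVk, bVl, bWMkind, bWMk, bW


def _traceback(n, tables):
    V, WM, W, bVkind, bVk, bVl, bWMkind, bWMk, bW = tables
    pairs = []
    stack = []
    # exterior
    j = n - 1
    while j >= 0:
        i = bW[j]
        if i < 0:
            j -= 1
        else:
            stack.append(("V", i, j))
            j = i - 1
    while stack:
        state, i, j = stack.pop()
        if state == "V":
            pairs.append((i, j))
            kind = bVkind[i, j]
            if kind == 0:
                continue
            if kind == 1:
                stack.append(("V", int(bVk[i, j]), int(bVl[i, j])))
            else:
                k = int(bVk[i, j])
                stack.append(("WM", i + 1, k - 1))
                stack.append(("WM", k, j - 1))
        else:  # WM
            kind = bWMkind[i, j]
            if kind == 0:
                stack.append(("WM", i + 1, j))
            elif kind == 1:
                stack.append(("WM", i, j - 1))
            elif kind == 2:
                stack.append(("V", i, j))
            else:
                k = int(bWMk[i, j])
                stack.append(("WM", i, k - 1))
                stack.append(("V", k, j))
    return pairs


def pair_table(structure: str) -> dict[int, int]:
    """Dot-bracket -> {i: j, j: i} pair map."""
    out = {}
    st = []
    for i, c in enumerate(structure):
        if c == "(":
            st.append(i)
        elif c == ")":
            j = st.pop()
            out[i] = j
            out[j] = i
    if st:
        raise ValueError("unbalanced dot-bracket string")
    return out


def fold_mfe(seq: str, model: EnergyModel | None = None) -> tuple[str, float]:
    """Fold ``seq`` to its minimum-free-energy structure.

    Parameters
    ----------
    seq : nucleotide string (T is read as U).
    model : energy model; the shipped reduced table by default.

    Returns
    -------
    (structure, mfe) : dot-bracket string and energy in kcal/mol.  A
    sequence with no favourable pairing returns ``("." * len(seq), 0.0)``.
    """
    model = model or default_model()
    rna = to_rna(seq)
    if not rna or any(c not in "ACGU" for c in rna):
        raise ValueError("sequence must be non-empty over A/C/G/U (or T)")
    n = len(rna)
    if n < model.min_hairpin_loop + 2:
        return "." * n, 0.0
    enc = encode(rna)
    h, b, il = model.penalty_tables(n)
    tables = _fold_dp(
        enc, model.pair_class, model.stack.astype(np.float64), h, b, il,
        model.multi_close, model.multi_branch, model.min_hairpin_loop,
        model.max_interior,
    )
    mfe = float(tables[2][n - 1])
    if mfe >= 0.0:
        return "." * n, 0.0
    pairs = _traceback(n, tables)
    dots = ["."] * n
    for i, j in pairs:
        dots[i] = "("
        dots[j] = ")"
    return "".join(dots), mfe
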