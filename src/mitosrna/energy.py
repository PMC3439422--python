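"""Reduced nearest-neighbour energy model for RNA secondary structure.

The model assigns an energy (kcal/mol) to any pseudoknot-free structure as

    E = sum(stacking terms) + sum(loop penalties)

where every base pair closes exactly one loop (hairpin, stacked pair,
bulge, internal loop, or multiloop) and the exterior loop is free.
Stacking energies depend only on the classes of the two stacked pairs
(GU < AU < GC); loop penalties grow logarithmically with loop size.
Parameters ship in ``data/energy_model.yaml``.

:func:`structure_energy` scores an explicit structure under the model and
is the single source of truth for what a structure costs; the dynamic
program in :mod:`mitosrna.fold` minimises exactly this quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from ._seq import to_rna

INF = 1e9

#: nucleotide code (A0 C1 G2 U3) pair -> class index, or -1 if not pairable
_PAIR_CLASS = -np.ones((4, 4), dtype=np.int8)
for _ab, _cls in (("GU", 0), ("UG", 0), ("AU", 1), ("UA", 1), ("GC", 2), ("CG", 2)):
    _PAIR_CLASS["ACGU".index(_ab[0]), "ACGU".index(_ab[1])] = _cls


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the reduced nearest-neighbour model."""

    stack: np.ndarray                      # (3, 3) kcal/mol, class x class
    hairpin: tuple[float, float, int]      # (base, slope, ref)
    bulge: tuple[float, float, int]
    internal: tuple[float, float, int]
    multi_close: float
    multi_branch: float
    min_hairpin_loop: int = 3
    max_interior: int = 30
    pair_class: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "pair_class", _PAIR_CLASS)
        if not (self.stack < 0).all():
            raise ValueError("all stacking energies must be negative")

    # -- loop penalty formulas (size in unpaired nucleotides) -------------
    def hairpin_penalty(self, size: int) -> float:
        base, slope, ref = self.hairpin
        if size < self.min_hairpin_loop:
            return INF
        return base + slope * math.log(size / ref)

    def bulge_penalty(self, size: int) -> float:
        base, slope, ref = self.bulge
        return base + slope * math.log(size / ref)

    def internal_penalty(self, size: int) -> float:
        base, slope, ref = self.internal
        return base + slope * math.log(size / ref)

    def pair_ok(self, a: str, b: str) -> bool:
        ia, ib = "ACGU".index(a), "ACGU".index(b)
        return self.pair_class[ia, ib] >= 0

    def penalty_tables(self, n: int):
        """Precomputed hairpin/bulge/internal penalty arrays up to size n."""
        h = np.full(n + 1, INF)
        b = np.full(n + 1, INF)
        il = np.full(n + 1, INF)
        for s in range(self.min_hairpin_loop, n + 1):
            h[s] = self.hairpin_penalty(s)
        for s in range(1, min(n, self.max_interior) + 1):
            b[s] = self.bulge_penalty(s)
        for s in range(2, min(n, self.max_interior) + 1):
            il[s] = self.internal_penalty(s)
        return h, b, il


def load_energy_model(path=None) -> EnergyModel:
    """Load an :class:`EnergyModel` from YAML (the shipped table by default)."""
    if path is None:
        text = resources.files("mitosrna.data").joinpath("energy_model.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    cfg = yaml.safe_load(text)
    return EnergyModel(
        stack=np.asarray(cfg["stack"], dtype=float),
        hairpin=(cfg["hairpin"]["base"], cfg["hairpin"]["slope"], cfg["hairpin"]["ref"]),
        bulge=(cfg["bulge"]["base"], cfg["bulge"]["slope"], cfg["bulge"]["ref"]),
        internal=(cfg["internal"]["base"], cfg["internal"]["slope"], cfg["internal"]["ref"]),
        multi_close=cfg["multiloop"]["close"],
        multi_branch=cfg["multiloop"]["branch"],
        min_hairpin_loop=cfg["min_hairpin_loop"],
        max_interior=cfg["max_interior"],
    )


_default_model: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _default_model
    if _default_model is None:
        _default_model = load_energy_model()
    return _default_model


def structure_energy(seq: str, pairs, model: EnergyModel | None = None) -> float:
    """Energy of an explicit structure (iterable of (i, j) pairs, i < j).

    Performs the full loop decomposition: every pair closes a loop whose
    type is determined by the directly-nested pairs.  Returns ``INF`` for
    structures the model disallows (loop too small, interior loop larger
    than ``max_interior``, non-complementary or crossing pairs).
    """
    model = model or default_model()
    rna = to_rna(seq)
    n = len(rna)
    plist = sorted((min(i, j), max(i, j)) for i, j in pairs)
    seen = set()
    for i, j in plist:
        if not (0 <= i < j < n) or i in seen or j in seen:
            return INF
        seen.add(i)
        seen.add(j)
        if not model.pair_ok(rna[i], rna[j]):
            return INF
        if j - i - 1 < model.min_hairpin_loop:
            return INF
    # crossing check
    for a in range(len(plist)):
        for b in range(a + 1, len(plist)):
            i, j = plist[a]
            k, l = plist[b]
            if i < k < j < l:
                return INF

    def cls(i, j):
        return model.pair_class["ACGU".index(rna[i]), "ACGU".index(rna[j])]

    def children(lo, hi, pool):
        """Outermost pairs strictly inside (lo, hi)."""
        out = []
        inside = [(i, j) for i, j in pool if lo < i and j < hi]
        covered = -1
        for i, j in inside:  # pool is sorted by i; nested pairs have larger i
            if i > covered:
                out.append((i, j))
                covered = j
        return out, inside

    total = 0.0
    pool = plist

    def loop_energy(i, j, pool):
        nonlocal total
        kids, inside = children(i, j, pool)
        if not kids:
            total += model.hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            left = k - i - 1
            right = j - l - 1
            if left == 0 and right == 0:
                total += float(model.stack[cls(i, j), cls(k, l)])
            elif left + right > model.max_interior:
                total += INF
            elif left == 0 or right == 0:
                total += model.bulge_penalty(left + right)
            else:
                total += model.internal_penalty(left + right)
        else:
            total += model.multi_close + model.multi_branch * len(kids)
        for k, l in kids:
            sub = [(a, b) for a, b in inside if k < a and b < l]
            loop_energy(k, l, sub)

    # exterior: outermost pairs contribute no penalty
    exterior, _ = children(-1, n, plist)
    for i, j in exterior:
        sub = [(a, b) for a, b in plist if i < a and b < j]
        loop_energy(i, j, sub)
    return total if total < INF / 2 else INF
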