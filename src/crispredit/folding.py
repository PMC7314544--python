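"""Bundled hairpin-only minimum-free-energy estimator.

Scores the self-structure of short targeting sequences (DNA given, T
treated as U) with a deliberately small nearest-neighbor model: a single
helix of stacked Watson-Crick or GU-wobble pairs closing a terminal loop
of at least 3 nt. Energy = hairpin-loop initiation + sum of stack terms;
the minimum over all such structures, capped at 0.0, is reported in
kcal/mol. Stack and loop parameters are approximate Turner-style 37 C
values shipped as data below. An external folding backend can replace
this estimator and its free energy is then used verbatim.
"""

from __future__ import annotations

import math

from .seqio import AlphabetError

__all__ = ["hairpin_mfe", "STACK_ENERGY", "HAIRPIN_LOOP_INIT", "canonical_pair"]

# Stack free energies (kcal/mol): key = (outer pair, inner pair), where a
# pair "XY" means X pairs with Y and X is 5' of the inner pair on the top
# strand. Approximate Turner nearest-neighbor values, WC + GU wobble.
STACK_ENERGY: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.9, ("AU", "CG"): -2.2, ("AU", "GC"): -2.1,
    ("AU", "GU"): -0.6, ("AU", "UA"): -1.1, ("AU", "UG"): -1.4,
    ("CG", "AU"): -2.1, ("CG", "CG"): -3.3, ("CG", "GC"): -2.4,
    ("CG", "GU"): -1.4, ("CG", "UA"): -2.1, ("CG", "UG"): -2.1,
    ("GC", "AU"): -2.4, ("GC", "CG"): -3.4, ("GC", "GC"): -3.3,
    ("GC", "GU"): -1.5, ("GC", "UA"): -2.2, ("GC", "UG"): -2.5,
    ("GU", "AU"): -1.3, ("GU", "CG"): -2.5, ("GU", "GC"): -2.1,
    ("GU", "GU"): -0.5, ("GU", "UA"): -1.4, ("GU", "UG"): 1.3,
    ("UA", "AU"): -1.3, ("UA", "CG"): -2.4, ("UA", "GC"): -2.1,
    ("UA", "GU"): -1.0, ("UA", "UA"): -0.9, ("UA", "UG"): -1.3,
    ("UG", "AU"): -1.0, ("UG", "CG"): -1.5, ("UG", "GC"): -1.4,
    ("UG", "GU"): 0.3, ("UG", "UA"): -0.6, ("UG", "UG"): -0.5,
}

# Hairpin loop initiation penalties by loop size; larger loops get a
# logarithmic Jacobson-Stockmayer extrapolation from size 9.
HAIRPIN_LOOP_INIT: dict[int, float] = {
    3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4,
}
_RT = 0.616  # kcal/mol at 37 C
MIN_LOOP = 3

_PAIRABLE = frozenset({"AU", "UA", "CG", "GC", "GU", "UG"})


def _to_rna(seq: str) -> str:
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - set("ACGU")
    if bad:
        raise AlphabetError(f"invalid characters {sorted(bad)}")
    return rna


def canonical_pair(a: str, b: str) -> bool:
    """True for Watson-Crick or GU wobble base pairs (RNA letters)."""
    return a + b in _PAIRABLE


def loop_energy(size: int) -> float:
    if size < MIN_LOOP:
        raise ValueError(f"hairpin loop must be >= {MIN_LOOP} nt, got {size}")
    if size in HAIRPIN_LOOP_INIT:
        return HAIRPIN_LOOP_INIT[size]
    return HAIRPIN_LOOP_INIT[9] + 1.75 * _RT * math.log(size / 9)


def hairpin_mfe(seq: str) -> float:
    """Minimum free energy over all single-hairpin structures, capped at 0.

    Dynamic program over closing pairs: V(i, j) is the best energy of a
    structure closed by pair (i, j) -- either the terminal loop itself or
    one stack on top of V(i+1, j-1).
    """
    rna = _to_rna(seq)
    n = len(rna)
    if n < MIN_LOOP + 2:
        return 0.0
    INF = math.inf
    V = [[INF] * n for _ in range(n)]
    # Fill by increasing span so V(i+1, j-1) is ready before V(i, j).
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not canonical_pair(rna[i], rna[j]):
                continue
            best = loop_energy(j - i - 1)
            inner = V[i + 1][j - 1]
            if inner < INF and canonical_pair(rna[i + 1], rna[j - 1]):
                stacked = STACK_ENERGY[(rna[i] + rna[j], rna[i + 1] + rna[j - 1])] + inner
                if stacked < best:
                    best = stacked
            V[i][j] = best
    mfe = min((V[i][j] for i in range(n) for j in range(n) if V[i][j] < INF),
              default=0.0)
    return min(mfe, 0.0)
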