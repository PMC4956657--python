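"""RNA secondary-structure folding backends.

The built-in folder finds the maximum-score nested structure under a
stacking-aware scheme: Watson-Crick and G:U pairs score GC=3, AU=2, GU=1,
adjacent (stacked) pairs earn a +1 bonus, and hairpin loops hold at least
3 unpaired bases.  The dynamic programme is exact for this objective and the
traceback is deterministic.  Reported "energies" are the negated score, a
pseudo-energy clearly flagged on the result; the ViennaRNA backend (when its
Python bindings are importable) returns thermodynamic kcal/mol instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

MIN_LOOP = 3
STACK_BONUS = 1.0
_PAIR_SCORE = {
    ("G", "C"): 3.0, ("C", "G"): 3.0,
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}

BACKENDS = ("builtin", "vienna", "auto")


def _vienna_available() -> bool:
    try:
        import RNA  # noqa: F401
        return True
    except ImportError:  # pragma: no cover
        return False


class FoldError(ValueError):
    pass


@dataclass
class FoldResult:
    seq: str          # RNA alphabet, 5'->3'
    structure: str    # dot-bracket
    mfe: float        # <= 0; pseudo-energy unless energy_model == "thermodynamic"
    energy_model: str = "pseudo"

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.seq):
            raise FoldError("structure/sequence length mismatch")

    @property
    def pairs(self) -> List[Tuple[int, int]]:
        return structure_pairs(self.structure)


def pair_score(a: str, b: str) -> float:
    return _PAIR_SCORE.get((a, b), 0.0)


def structure_pairs(structure: str) -> List[Tuple[int, int]]:
    stack, pairs = [], []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise FoldError("unbalanced structure")
            pairs.append((stack.pop(), i))
    if stack:
        raise FoldError("unbalanced structure")
    return sorted(pairs)


def pair_table(structure: str) -> List[Optional[int]]:
    """partner index per position (None = unpaired)."""
    table: List[Optional[int]] = [None] * len(structure)
    for i, j in structure_pairs(structure):
        table[i], table[j] = j, i
    return table


def structure_score(seq_rna: str, structure: str) -> float:
    """Objective value of a given structure (pair scores + stacking bonuses)."""
    pairs = structure_pairs(structure)
    pset = set(pairs)
    score = 0.0
    for i, j in pairs:
        s = pair_score(seq_rna[i], seq_rna[j])
        if s == 0.0:
            raise FoldError(f"illegal pair {seq_rna[i]}:{seq_rna[j]} at {i},{j}")
        if j - i <= MIN_LOOP:
            raise FoldError(f"loop shorter than {MIN_LOOP} at {i},{j}")
        score += s
        if (i + 1, j - 1) in pset:
            score += STACK_BONUS
    return score


def _fold_builtin(seq_rna: str) -> Tuple[str, float]:
    n = len(seq_rna)
    if n == 0:
        return "", 0.0
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            P[i, j] = pair_score(seq_rna[i], seq_rna[j])

    NEG = -1e9
    M = np.zeros((n, n))
    C = np.full((n, n), NEG)
    for d in range(1, n):
        i = np.arange(0, n - d)
        j = i + d
        if d > MIN_LOOP:
            inner = np.maximum(M[i + 1, j - 1], C[i + 1, j - 1] + STACK_BONUS)
            pairable = P[i, j] > 0
            C[i, j] = np.where(pairable, P[i, j] + inner, NEG)
        best = np.maximum(M[i + 1, j], M[i, j - 1])
        best = np.maximum(best, C[i, j])
        for s in range(1, d):
            best = np.maximum(best, M[i, i + s] + M[i + s + 1, j])
        M[i, j] = best

    structure = ["."] * n

    def trace(i: int, j: int, paired: bool) -> None:
        stack = [(i, j, paired)]
        while stack:
            i, j, paired = stack.pop()
            if i >= j:
                continue
            if paired:
                structure[i], structure[j] = "(", ")"
                rest = C[i, j] - P[i, j]
                if (C[i + 1, j - 1] > NEG / 2
                        and rest == C[i + 1, j - 1] + STACK_BONUS):
                    stack.append((i + 1, j - 1, True))
                else:
                    stack.append((i + 1, j - 1, False))
                continue
            v = M[i, j]
            if v == 0:
                continue
            if C[i, j] > NEG / 2 and v == C[i, j]:
                stack.append((i, j, True))
            elif v == M[i + 1, j]:
                stack.append((i + 1, j, False))
            elif v == M[i, j - 1]:
                stack.append((i, j - 1, False))
            else:
                for s in range(1, j - i):
                    if v == M[i, i + s] + M[i + s + 1, j]:
                        stack.append((i, i + s, False))
                        stack.append((i + s + 1, j, False))
                        break
                else:  # pragma: no cover - DP guarantees a case matches
                    raise FoldError("traceback failed")

    trace(0, n - 1, False)
    return "".join(structure), float(M[0, n - 1])


def _fold_vienna(seq_rna: str) -> Tuple[str, float]:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise FoldError("ViennaRNA python bindings not available") from exc
    structure, mfe = RNA.fold(seq_rna)
    return structure, float(mfe)


def fold(seq: str, backend: str = "builtin") -> FoldResult:
    """Fold a sequence (DNA or RNA spelling accepted; N never pairs).

    ``backend="auto"`` picks the thermodynamic ViennaRNA folder when its
    Python bindings are importable and the scored built-in DP otherwise.
    """
    rna = seq.upper().replace("T", "U")
    bad = set(rna) - set("ACGUN")
    if bad:
        raise FoldError(f"invalid characters for folding: {sorted(bad)}")
    if backend == "auto":
        backend = "vienna" if _vienna_available() else "builtin"
    if backend == "builtin":
        structure, score = _fold_builtin(rna)
        return FoldResult(rna, structure, mfe=-score, energy_model="pseudo")
    if backend == "vienna":
        structure, mfe = _fold_vienna(rna)
        return FoldResult(rna, structure, mfe=min(mfe, 0.0),
                          energy_model="thermodynamic")
    raise FoldError(f"unknown folding backend {backend!r}")
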