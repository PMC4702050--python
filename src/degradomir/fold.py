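"""RNA secondary-structure prediction backends.

The pipeline needs the minimum-free-energy (MFE) structure of each precursor
candidate.  The preferred backend is ViennaRNA's ``RNA.fold``; a weighted
Nussinov base-pair-maximisation engine is provided as a dependency-free
fallback and as an alternative backend for testing.  Both return a
:class:`FoldResult` whose ``pairs`` table is a 0-based involution
(``pairs[i] == j`` iff i:j are paired, -1 if unpaired).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

try:  # ViennaRNA python bindings (conda package `viennarna`)
    import RNA as _vienna
except ImportError:  # pragma: no cover - exercised only without ViennaRNA
    _vienna = None


class FoldError(RuntimeError):
    """Raised when a folding backend fails for a sequence."""


@dataclass(frozen=True)
class FoldResult:
    structure: str
    mfe: float
    pairs: tuple[int, ...]

    def unpaired_fraction(self, start: int, end: int) -> float:
        """Fraction of positions in [start, end) that are unpaired."""
        if end <= start:
            return 1.0
        n = sum(1 for i in range(start, end) if self.pairs[i] < 0)
        return n / (end - start)


def pairs_from_dotbracket(structure: str) -> tuple[int, ...]:
    """Derive the pair table from a dot-bracket string."""
    pairs = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise FoldError(f"unbalanced structure: {structure}")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif ch != ".":
            raise FoldError(f"unexpected character {ch!r} in structure")
    if stack:
        raise FoldError(f"unbalanced structure: {structure}")
    return tuple(pairs)


_CAN_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_PAIR_SCORE = {("G", "C"): 3, ("C", "G"): 3, ("A", "T"): 2, ("T", "A"): 2,
               ("G", "T"): 1, ("T", "G"): 1}
_MIN_LOOP = 3


def fold_nussinov(sequence: str) -> FoldResult:
    """Weighted base-pair maximisation (Nussinov) with a 3-nt minimum loop.

    The pseudo-energy reported is minus the pair-weight sum (GC=3, AU=2,
    GU=1) so that more-paired structures score lower, mirroring the sign
    convention of a thermodynamic MFE.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if n == 0:
        return FoldResult("", 0.0, ())
    best = [[0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            val = best[i][j - 1]
            for k in range(i, j - _MIN_LOOP):
                w = _PAIR_SCORE.get((seq[k], seq[j]))
                if w is None:
                    continue
                left = best[i][k - 1] if k > i else 0
                cand = left + w + best[k + 1][j - 1]
                if cand > val:
                    val = cand
            best[i][j] = val
    pairs = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or best[i][j] == 0:
            continue
        if best[i][j] == best[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - _MIN_LOOP):
            w = _PAIR_SCORE.get((seq[k], seq[j]))
            if w is None:
                continue
            left = best[i][k - 1] if k > i else 0
            if left + w + best[k + 1][j - 1] == best[i][j]:
                pairs[k], pairs[j] = j, k
                stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    structure = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(pairs)
    )
    score = sum(
        _PAIR_SCORE[(seq[i], seq[p])] for i, p in enumerate(pairs) if p > i
    )
    return FoldResult(structure, -float(score), tuple(pairs))


def fold_vienna(sequence: str) -> FoldResult:
    """MFE fold via ViennaRNA."""
    if _vienna is None:  # pragma: no cover
        raise FoldError("ViennaRNA python bindings are not available")
    rna = sequence.upper().replace("T", "U")
    try:
        structure, mfe = _vienna.fold(rna)
    except Exception as exc:  # pragma: no cover
        raise FoldError(f"ViennaRNA failed on {sequence[:30]}...") from exc
    return FoldResult(structure, float(mfe), pairs_from_dotbracket(structure))


_BACKENDS = {"vienna": fold_vienna, "nussinov": fold_nussinov}


def fold(sequence: str, backend: str = "auto") -> FoldResult:
    """Fold a sequence with the selected backend.

    ``auto`` prefers the thermodynamic engine and falls back to the
    base-pair-maximisation engine with a warning.
    """
    if backend == "auto":
        if _vienna is not None:
            return fold_vienna(sequence)
        warnings.warn(
            "ViennaRNA not available; using the base-pair-maximisation backend",
            stacklevel=2,
        )
        return fold_nussinov(sequence)
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown fold backend {backend!r}") from None
    return fn(sequence)
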