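"""Internal minimum-free-energy RNA folding engine.

A deliberately small nearest-neighbour model, not a Turner-parameter
thermodynamic engine: it reproduces the comparative behaviour that matters
here (more G:C means lower energy; G:U wobble pairs allowed but weak) with
an energy function simple enough to publish in full and to cross-check by
exhaustive enumeration at small lengths.  Users wanting Turner energies
plug in an external folder through :func:`parse_external_fold`.

Energy model (kcal/mol), applied to a loop decomposition of the structure:

* pair strengths: G:C/C:G 3.0, A:U/U:A 2.0, G:U/U:G 1.0
* stack of adjacent pairs: -(strength_outer + strength_inner)/2
* each hairpin loop: +3.0; each internal loop or bulge: +2.0;
  each multiloop: +3.0; exterior bases: free
* hairpin loops have >= 3 unpaired bases; internal loops hold at most
  30 unpaired bases in total; no dangles, no coaxial terms

The temperature argument is accepted for interface parity with external
engines and logged; this model has no temperature dependence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: allowed pair strengths; every other combination cannot pair
PAIR_STRENGTH: dict[str, float] = {
    "GC": 3.0, "CG": 3.0,
    "AU": 2.0, "UA": 2.0,
    "GU": 1.0, "UG": 1.0,
}
HAIRPIN_PENALTY = 3.0
INTERNAL_PENALTY = 2.0
MULTI_PENALTY = 3.0
MIN_HAIRPIN = 3
MAX_INTERNAL = 30
MAX_LENGTH = 200

INF = float("inf")


class FoldError(ValueError):
    pass


def stack_energy(outer: str, inner: str) -> float:
    """Stacking term for pair ``inner`` directly inside pair ``outer``."""
    return -(PAIR_STRENGTH[outer] + PAIR_STRENGTH[inner]) / 2.0


def can_pair(a: str, b: str) -> bool:
    return a + b in PAIR_STRENGTH


def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise FoldError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise FoldError(f"illegal structure symbol {ch!r} at {idx}")
    if stack:
        raise FoldError(f"unclosed '(' at position {stack[-1]}")
    return sorted(pairs)


def dotbracket_from_pairs(n: int, pairs: list[tuple[int, int]]) -> str:
    out = ["."] * n
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def validate_structure(seq: str, structure: str) -> list[tuple[int, int]]:
    """Check pairing rules and the minimum hairpin size; return the pairs."""
    if len(seq) != len(structure):
        raise FoldError("sequence and structure lengths differ")
    pairs = pairs_from_dotbracket(structure)
    paired = {i for p in pairs for i in p}
    for i, j in pairs:
        if not can_pair(seq[i], seq[j]):
            raise FoldError(f"disallowed pair {seq[i]}:{seq[j]} at ({i},{j})")
        enclosed_pairs = [p for p in pairs if i < p[0] and p[1] < j]
        if not enclosed_pairs:
            loop = j - i - 1
            if loop < MIN_HAIRPIN:
                raise FoldError(
                    f"hairpin loop of {loop} < {MIN_HAIRPIN} bases at ({i},{j})"
                )
    del paired
    return pairs


def _children(pairs: list[tuple[int, int]]) -> dict[tuple[int, int] | None, list[tuple[int, int]]]:
    """Directly nested pairs per closing pair (None = exterior)."""
    tree: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in sorted(pairs):
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        tree.setdefault(parent, []).append(p)
        tree.setdefault(p, [])
        stack.append(p)
    return tree

def structure_energy(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Energy of a given structure under the published model.

    Decomposes into loops: a pair closing no pairs is a hairpin; closing one
    pair is a stack (if contiguous) or internal loop/bulge; closing two or
    more is a multiloop.
    """
    tree = _children(sorted(pairs))
    energy = 0.0
    for key, kids in tree.items():
        if key is None:
            continue
        i, j = key
        if not kids:
            energy += HAIRPIN_PENALTY
        elif len(kids) == 1:
            (k, l1) = kids[0]
            if k == i + 1 and l1 == j - 1:
                energy += stack_energy(seq[i] + seq[j], seq[k] + seq[l1])
            else:
                energy += INTERNAL_PENALTY
        else:
            energy += MULTI_PENALTY
    return energy


def fold_mfe(seq: str, temperature: float = 37.0) -> tuple[str, float]:
    """Minimum-free-energy structure and energy of one RNA sequence.

    Deterministic: among co-optimal structures the traceback resolves ties
    by a fixed preference order (stack, then hairpin, then internal loop,
    then multiloop; earliest/shortest branch first).
    """
    seq = seq.upper().replace("T", "U")
    if set(seq) - RNA_ALPHABET:
        raise FoldError(f"non-ACGU symbols: {sorted(set(seq) - RNA_ALPHABET)}")
    if len(seq) > MAX_LENGTH:
        raise FoldError(f"sequence longer than {MAX_LENGTH}")
    if temperature != 37.0:
        log.info("internal engine has no temperature dependence (T=%s)", temperature)
    n = len(seq)
    if n == 0:
        return "", 0.0

    pairable = np.zeros((n, n), dtype=bool)
    strength = {}
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            if can_pair(seq[i], seq[j]):
                pairable[i, j] = True
                strength[(i, j)] = PAIR_STRENGTH[seq[i] + seq[j]]

    V = np.full((n, n), INF)
    B1 = np.full((n + 1, n), INF)  # >=1 branch in [i..j]
    B2 = np.full((n + 1, n), INF)  # >=2 branches in [i..j]

    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            # --- V(i,j): structure closed by pair (i,j)
            if pairable[i, j]:
                best = HAIRPIN_PENALTY
                if pairable[i + 1, j - 1] and V[i + 1, j - 1] < INF:
                    e = stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1]) + V[i + 1, j - 1]
                    if e < best:
                        best = e
                # internal loops / bulges (>=1 unpaired, <= MAX_INTERNAL total)
                k_hi = min(i + MAX_INTERNAL + 1, j - 1)
                for k in range(i + 1, k_hi + 1):
                    left = k - i - 1
                    l_lo = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERNAL - left))
                    for l1 in range(l_lo, j):
                        if left + (j - l1 - 1) == 0:
                            continue  # that is the stack case
                        if V[k, l1] < INF:
                            e = INTERNAL_PENALTY + V[k, l1]
                            if e < best:
                                best = e
                if j - 1 >= i + 1 and B2[i + 1, j - 1] < INF:
                    e = MULTI_PENALTY + B2[i + 1, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # --- B1/B2 over [i..j]
            b1 = B1[i + 1, j]
            b2 = B2[i + 1, j]
            row = V[i, i + 1 : j + 1]
            for off, vik in enumerate(row):
                if vik >= INF:
                    continue
                k = i + 1 + off
                rest1 = B1[k + 1, j] if k + 1 <= j else INF
                cand1 = vik + min(0.0, rest1 if rest1 < INF else 0.0)
                if cand1 < b1:
                    b1 = cand1
                if rest1 < INF:
                    cand2 = vik + rest1
                    if cand2 < b2:
                        b2 = cand2
            B1[i, j] = b1
            B2[i, j] = b2
        # diagonal entries stay INF (no branch fits in one base)

    # exterior: W[i] = MFE of suffix i..n-1
    W = np.zeros(n + 1)
    for i in range(n - 1, -1, -1):
        best = W[i + 1]
        for k in range(i + MIN_HAIRPIN + 1, n):
            if V[i, k] < INF:
                e = V[i, k] + W[k + 1]
                if e < best:
                    best = e
        W[i] = best

    pairs: list[tuple[int, int]] = []

    def trace_V(i: int, j: int) -> None:
        pairs.append((i, j))
        target = V[i, j]
        if pairable[i + 1, j - 1] and V[i + 1, j - 1] < INF:
            e = stack_energy(seq[i] + seq[j], seq[i + 1] + seq[j - 1]) + V[i + 1, j - 1]
            if e == target:
                trace_V(i + 1, j - 1)
                return
        if target == HAIRPIN_PENALTY:
            return
        k_hi = min(i + MAX_INTERNAL + 1, j - 1)
        for k in range(i + 1, k_hi + 1):
            left = k - i - 1
            l_lo = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_INTERNAL - left))
            for l1 in range(l_lo, j):
                if left + (j - l1 - 1) == 0 or V[k, l1] >= INF:
                    continue
                if INTERNAL_PENALTY + V[k, l1] == target:
                    trace_V(k, l1)
                    return
        if j - 1 >= i + 1 and B2[i + 1, j - 1] < INF:
            if MULTI_PENALTY + B2[i + 1, j - 1] == target:
                trace_B(i + 1, j - 1, need_two=True)
                return
        raise AssertionError("traceback failed in closed structure")

    def trace_B(i: int, j: int, need_two: bool) -> None:
        target = (B2 if need_two else B1)[i, j]
        if i + 1 <= j and (B2 if need_two else B1)[i + 1, j] == target:
            trace_B(i + 1, j, need_two)
            return
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if V[i, k] >= INF:
                continue
            rest1 = B1[k + 1, j] if k + 1 <= j else INF
            if need_two:
                if rest1 < INF and V[i, k] + rest1 == target:
                    trace_V(i, k)
                    trace_B(k + 1, j, need_two=False)
                    return
            else:
                take_rest = rest1 if rest1 < INF else 0.0
                if V[i, k] + min(0.0, take_rest) == target:
                    trace_V(i, k)
                    if rest1 < INF and rest1 < 0.0:
                        trace_B(k + 1, j, need_two=False)
                    return
        raise AssertionError("traceback failed in multiloop decomposition")

    def trace_W(i: int) -> None:
        while i < n:
            if W[i] == W[i + 1]:
                i += 1
                continue
            for k in range(i + MIN_HAIRPIN + 1, n):
                if V[i, k] < INF and V[i, k] + W[k + 1] == W[i]:
                    trace_V(i, k)
                    i = k + 1
                    break
            else:
                raise AssertionError("traceback failed in exterior loop")

    trace_W(0)
    energy = structure_energy(seq, pairs) if pairs else 0.0
    if abs(energy - W[0]) > 1e-9:
        raise AssertionError(
            f"traceback energy {energy} != DP optimum {W[0]}"
        )
    if energy > 0:
        # the DP never chooses a positive-energy structure over the empty one
        raise AssertionError("positive-energy optimum should be empty")
    structure = dotbracket_from_pairs(n, pairs)
    return structure, float(energy)


_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def parse_external_fold(text: str) -> tuple[str, str, float]:
    """Parse an external folder's output: sequence line, then
    ``structure (energy)``.

    Returns (sequence, structure, energy); the structure is validated
    against the engine contract (allowed pairs, hairpin >= 3).
    """
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FoldError("expected a sequence line and a structure line")
    seq = lines[0].strip().upper().replace("T", "U")
    if seq.startswith(">"):
        if len(lines) < 3:
            raise FoldError("FASTA header present but no structure line (line 3)")
        seq = lines[1].strip().upper().replace("T", "U")
        struct_line = lines[2]
        struct_lineno = 3
    else:
        struct_line = lines[1]
        struct_lineno = 2
    m = _ENERGY_RE.search(struct_line)
    if not m:
        raise FoldError(f"line {struct_lineno}: no trailing '(energy)' found")
    energy = float(m.group(1).replace("−", "-"))
    structure = struct_line[: m.start()].strip()
    if set(seq) - RNA_ALPHABET:
        raise FoldError("line 1: sequence has non-ACGU symbols")
    try:
        validate_structure(seq, structure)
    except FoldError as err:
        raise FoldError(f"line {struct_lineno}: {err}") from err
    return seq, structure, energy


def serialize_fold(seq: str, structure: str, energy: float) -> str:
    return f"{seq}\n{structure} ({energy:.2f})\n"


@dataclass(frozen=True)
class InternalEngine:
    """Folding-engine contract wrapper for the internal model."""

    temperature: float = 37.0

    def __call__(self, seq: str) -> tuple[str, float]:
        return fold_mfe(seq, self.temperature)
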