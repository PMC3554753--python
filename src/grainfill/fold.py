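"""Shared nucleic-acid energy model.

A deliberately simple, fully documented nearest-neighbour *stacking* model is
used everywhere a free energy is needed (hairpin folding, miRNA:miRNA* duplex
metrics, miRNA:target hybridisation) so that every threshold comparison in
the pipeline uses one self-contained energy scale and tests can hand-compute
expected values.

Model constants
---------------
Each admissible base pair carries a "bond strength" in arbitrary kcal/mol
units::

    A:T (A:U)  2.0
    G:C        3.0
    G:T (G:U)  1.0   (wobble)

Energy is assigned only to *stacked* pairs: two pairs adjacent in a helix
contribute ``-(bond_1 + bond_2) / 2`` kcal/mol.  An isolated pair therefore
contributes nothing, and a helix of ``k`` pairs with bonds ``b_1..b_k`` has
energy ``-(b_1/2 + b_2 + ... + b_{k-1} + b_k/2)``.  Loops are penalty-free;
hairpin loops must span at least :data:`MIN_LOOP` unpaired bases.

An external thermodynamic folder can replace :func:`fold_window` behind the
same ``(structure, mfe)`` contract; the default keeps the test-suite
self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: minimum number of unpaired bases enclosed by a hairpin-closing pair
MIN_LOOP = 3

#: bond strength of each admissible pair (symmetric); absent key = no pair
PAIR_BOND = {
    ("A", "T"): 2.0,
    ("T", "A"): 2.0,
    ("G", "C"): 3.0,
    ("C", "G"): 3.0,
    ("G", "T"): 1.0,
    ("T", "G"): 1.0,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def normalize(seq: str) -> str:
    """Uppercase a sequence and normalise U to T (DNA alphabet internally)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement (input must already be normalised ACGT)."""
    return seq.translate(_COMPLEMENT)[::-1]


def pair_state(a: str, b: str) -> str:
    """Pairing state of two bases: ``"WC"``, ``"GU"`` or ``"MM"``."""
    if (a, b) in _WC:
        return "WC"
    if (a, b) in _GU:
        return "GU"
    return "MM"


@dataclass(frozen=True)
class FoldResult:
    """Secondary structure of a single strand under the stacking model."""

    structure: str  #: dot-bracket, same length as the folded sequence
    mfe: float  #: kcal/mol, <= 0

    @property
    def pair_table(self) -> list[int]:
        """Partner index per position (-1 for unpaired)."""
        table = [-1] * len(self.structure)
        stack: list[int] = []
        for i, c in enumerate(self.structure):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                table[i], table[j] = j, i
        return table


def _bond_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    bond = np.zeros((n, n))
    lut = np.zeros((256, 256))
    for (a, b), v in PAIR_BOND.items():
        lut[ord(a), ord(b)] = v
    bond[:, :] = lut[codes[:, None], codes[None, :]]
    return bond


def fold_window(seq: str) -> FoldResult:
    """Minimum-free-energy structure of ``seq`` under the stacking model.

    Dynamic programme over intervals (Nussinov recursion with stacking
    energies), vectorised per diagonal.  All energies are sums of halves of
    small integers, so float comparisons in the traceback are exact.
    """
    seq = normalize(seq)
    n = len(seq)
    if n == 0:
        return FoldResult("", 0.0)
    bond = _bond_matrix(seq)
    pairable = bond > 0

    INF = np.inf
    V = np.full((n, n), INF)  # MFE of [i, j] with (i, j) paired
    W = np.zeros((n, n))  # MFE of [i, j]

    for d in range(MIN_LOOP + 1, n):
        i = np.arange(0, n - d)
        j = i + d
        # paired case: either stack on an inner adjacent pair or not
        inner_w = W[i + 1, j - 1]
        stack = -(bond[i, j] + bond[i + 1, j - 1]) / 2.0
        with np.errstate(invalid="ignore"):
            v = np.minimum(inner_w, stack + V[i + 1, j - 1])
        v = np.where(pairable[i, j], v, INF)
        V[i, j] = v
        best = v.copy()
        for t in range(d):  # bifurcation / unpaired ends (W[i,i] == 0)
            best = np.minimum(best, W[i, i + t] + W[i + t + 1, j])
        W[i, j] = best

    structure = ["."] * n
    agenda: list[tuple[int, int, str]] = [(0, n - 1, "W")]
    while agenda:
        i, j, mode = agenda.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if mode == "W":
            w = W[i, j]
            if w == 0.0:
                continue
            if V[i, j] == w:
                agenda.append((i, j, "V"))
                continue
            for t in range(j - i):
                if W[i, i + t] + W[i + t + 1, j] == w:
                    agenda.append((i, i + t, "W"))
                    agenda.append((i + t + 1, j, "W"))
                    break
        else:  # V: (i, j) paired
            structure[i], structure[j] = "(", ")"
            stack = -(bond[i, j] + bond[i + 1, j - 1]) / 2.0
            if (
                pairable[i + 1, j - 1]
                and np.isfinite(V[i + 1, j - 1])
                and stack + V[i + 1, j - 1] == V[i, j]
            ):
                agenda.append((i + 1, j - 1, "V"))
            elif W[i + 1, j - 1] == V[i, j]:
                agenda.append((i + 1, j - 1, "W"))
    mfe = float(W[0, n - 1])
    return FoldResult("".join(structure), mfe)


def duplex_energy(strand_a: str, strand_b: str) -> float:
    """Hybridisation energy of two antiparallel strands, ungapped.

    ``strand_a`` is read 5'->3' and paired position-by-position against
    ``strand_b`` read 3'->5' (i.e. ``strand_a[i]`` vs ``strand_b[-1 - i]``).
    WC and G:U positions pair; adjacent paired positions stack and contribute
    ``-(bond_i + bond_{i+1}) / 2``; everything else contributes 0.
    """
    a = normalize(strand_a)
    b = normalize(strand_b)
    if len(a) != len(b):
        raise ValueError("duplex strands must have equal length")
    rb = b[::-1]
    bonds = [PAIR_BOND.get((x, y), 0.0) for x, y in zip(a, rb)]
    energy = 0.0
    for k in range(len(bonds) - 1):
        if bonds[k] > 0 and bonds[k + 1] > 0:
            energy -= (bonds[k] + bonds[k + 1]) / 2.0
    return energy
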