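"""RNA secondary structures with CT-file semantics.

A :class:`SecondaryStructure` is a pseudoknot-free pairing of an RNA
sequence, stored as a 1-based pair table (``partner[i]`` is the pairing
partner of position ``i``, or 0 when unpaired) exactly as in the body of a
CT file.  Structures are validated on construction: the pair table must be
an involution, pairs must be nested (no crossing pairs) and hairpin loops
must enclose at least three unpaired nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RNA_ALPHABET = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}

#: Canonical pairs (Watson-Crick plus wobble).
CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
                   ("G", "U"), ("U", "G")}

MIN_HAIRPIN = 3


class InvalidStructureError(ValueError):
    """Raised when a pair table violates the structure invariants."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an A/C/G/U string to an int8 array (A=0, C=1, G=2, U=3)."""
    seq = sequence.upper().replace("T", "U")
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message detail only
        raise ValueError(f"non-RNA character in sequence: {exc}") from exc


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure (CT semantics).

    Parameters
    ----------
    sequence : str
        RNA sequence over A/C/G/U.
    pair_table : numpy.ndarray
        1-based pair table of length ``len(sequence) + 1``; entry 0 is
        unused, ``pair_table[i] == j`` iff i pairs with j (0 = unpaired).
    """

    sequence: str
    pair_table: np.ndarray = field(repr=False)

    def __post_init__(self):
        pt = np.asarray(self.pair_table, dtype=np.int32)
        object.__setattr__(self, "pair_table", pt)
        n = len(self.sequence)
        if pt.shape != (n + 1,):
            raise InvalidStructureError(
                f"pair table length {pt.shape} does not match sequence ({n})")
        validate_pair_table(pt, n)
        pt.setflags(write=False)

    # -- constructors ------------------------------------------------------
    @classmethod
    def open_chain(cls, sequence: str) -> "SecondaryStructure":
        return cls(sequence, np.zeros(len(sequence) + 1, dtype=np.int32))

    @classmethod
    def from_pairs(cls, sequence: str, pairs) -> "SecondaryStructure":
        pt = np.zeros(len(sequence) + 1, dtype=np.int32)
        for i, j in pairs:
            pt[i], pt[j] = j, i
        return cls(sequence, pt)

    @classmethod
    def from_dotbracket(cls, sequence: str, db: str) -> "SecondaryStructure":
        if len(db) != len(sequence):
            raise InvalidStructureError("dot-bracket length mismatch")
        stack, pairs = [], []
        for pos, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise InvalidStructureError("unbalanced dot-bracket")
                pairs.append((stack.pop(), pos))
            elif ch != ".":
                raise InvalidStructureError(f"unsupported character {ch!r}")
        if stack:
            raise InvalidStructureError("unbalanced dot-bracket")
        return cls.from_pairs(sequence, pairs)

    # -- views -------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Sorted list of (i, j) pairs with i < j."""
        pt = self.pair_table
        return [(i, int(pt[i])) for i in range(1, len(self) + 1)
                if pt[i] > i]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def is_paired(self, i: int) -> bool:
        return self.pair_table[i] != 0

    def to_dotbracket(self) -> str:
        out = ["."] * len(self)
        for i, j in self.pairs:
            out[i - 1], out[j - 1] = "(", ")"
        return "".join(out)

    def __eq__(self, other) -> bool:
        return (isinstance(other, SecondaryStructure)
                and self.sequence == other.sequence
                and np.array_equal(self.pair_table, other.pair_table))

    def __hash__(self) -> int:
        return hash((self.sequence, self.pair_table.tobytes()))

    # -- loop context ------------------------------------------------------
    def context_codes(self) -> np.ndarray:
        """Per-position pairing context for probing-likelihood models.

        Returns an int8 array (1-based, entry 0 unused):
        0 = unpaired, 1 = paired at a helix end, 2 = paired stacked between
        two base pairs.  A paired nucleotide i (partner j) is *stacked* when
        both neighbouring pairings (i-1, j+1) and (i+1, j-1) exist; it is a
        helix end otherwise.
        """
        n = len(self)
        pt = self.pair_table
        codes = np.zeros(n + 1, dtype=np.int8)
        for i in range(1, n + 1):
            j = pt[i]
            if j == 0:
                continue
            inner = 1 <= i + 1 <= n and pt[i + 1] == j - 1 and j - 1 >= 1
            outer = i - 1 >= 1 and j + 1 <= n and pt[i - 1] == j + 1
            codes[i] = 2 if (inner and outer) else 1
        return codes


def validate_pair_table(pt: np.ndarray, n: int) -> None:
    """Check involution, nesting and minimum hairpin loop size."""
    for i in range(1, n + 1):
        j = int(pt[i])
        if j < 0 or j > n:
            raise InvalidStructureError(f"partner of {i} out of range: {j}")
        if j == 0:
            continue
        if j == i:
            raise InvalidStructureError(f"self-pairing at {i}")
        if pt[j] != i:
            raise InvalidStructureError(f"pair table is not an involution at {i}")
        if j > i and j - i - 1 < MIN_HAIRPIN:
            raise InvalidStructureError(
                f"hairpin loop of pair ({i},{j}) shorter than {MIN_HAIRPIN}")
    # nesting: a stack-based scan
    stack = []
    for i in range(1, n + 1):
        j = int(pt[i])
        if j > i:
            stack.append(j)
        elif 0 < j < i:
            if not stack or stack[-1] != i:
                raise InvalidStructureError("crossing pairs (pseudoknot)")
            stack.pop()


# ---------------------------------------------------------------------------
# CT file I/O (header count line, 6-column body)
# ---------------------------------------------------------------------------

def write_ct(structure: SecondaryStructure, path, title: str = "") -> None:
    n = len(structure)
    pt = structure.pair_table
    with open(path, "w") as fh:
        fh.write(f"{n} {title}\n")
        for i in range(1, n + 1):
            nxt = i + 1 if i < n else 0
            fh.write(f"{i} {structure.sequence[i-1]} {i-1} {nxt} "
                     f"{int(pt[i])} {i}\n")


def read_ct(path) -> SecondaryStructure:
    with open(path) as fh:
        header = fh.readline().split()
        n = int(header[0])
        bases, pt = [], np.zeros(n + 1, dtype=np.int32)
        for _ in range(n):
            parts = fh.readline().split()
            idx = int(parts[0])
            bases.append(parts[1])
            pt[idx] = int(parts[4])
    return SecondaryStructure("".join(bases), pt)
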