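"""Junction-anchored sequences and junction-relative mutation IDs.

A :class:`JunctionSequence` is an RNA spanning an exon-intron boundary;
``junction_offset`` is the 1-based index of the last exonic nucleotide.
Mutations are named relative to that boundary the way splicing work
reports them: ``+19C>G`` substitutes C with G at the 19th intronic
nucleotide, ``-6G>A`` at the 6th nucleotide counting backwards from the
exon end.  Compensatory double mutations join two substitutions with
``/`` (e.g. ``-3C>G/+14G>C``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .structure import SecondaryStructure

_SUB_RE = re.compile(r"^([+-]\d+)([ACGU])>([ACGU])$")


class MutationFormatError(ValueError):
    """Raised for malformed mutation IDs or reference-base mismatches."""


@dataclass(frozen=True)
class JunctionSequence:
    """An exon-intron junction region.

    Attributes
    ----------
    sequence : str
        RNA over A/C/G/U.
    junction_offset : int
        1-based index of the last exonic nucleotide; positions
        1..junction_offset are exonic, the rest intronic.
    true_structure : SecondaryStructure, optional
        Ground-truth structure for simulation fixtures.
    """

    sequence: str
    junction_offset: int
    true_structure: SecondaryStructure | None = field(default=None,
                                                      compare=False)

    def __post_init__(self):
        seq = self.sequence.upper().replace("T", "U")
        if set(seq) - set("ACGU"):
            raise ValueError("sequence must contain only A/C/G/U")
        if not (1 <= self.junction_offset < len(seq)):
            raise ValueError("junction offset must satisfy "
                             "1 <= offset < length")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def exon(self) -> str:
        return self.sequence[:self.junction_offset]

    @property
    def intron(self) -> str:
        return self.sequence[self.junction_offset:]

    def absolute_position(self, signed: int) -> int:
        """Map a junction-relative signed position to a 1-based index."""
        if signed == 0:
            raise MutationFormatError("position 0 is not defined")
        if signed > 0:
            idx = self.junction_offset + signed
        else:
            idx = self.junction_offset + 1 + signed
        if not (1 <= idx <= len(self)):
            raise MutationFormatError(
                f"position {signed:+d} falls outside the sequence")
        return idx

    def relative_position(self, index: int) -> int:
        """Inverse of :meth:`absolute_position`."""
        if not (1 <= index <= len(self)):
            raise ValueError("index out of range")
        if index > self.junction_offset:
            return index - self.junction_offset
        return index - self.junction_offset - 1


@dataclass(frozen=True)
class Substitution:
    position: int      # junction-relative signed position (never 0)
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.position:+d}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class MutationSpec:
    """One or more substitutions with a canonical junction-relative ID."""

    substitutions: tuple

    @property
    def id(self) -> str:
        return format_mutation(self)

    def positions(self, js: JunctionSequence) -> list[int]:
        return [js.absolute_position(s.position) for s in self.substitutions]


def parse_mutation(mutation_id: str) -> MutationSpec:
    """Parse ``+19C>G`` / ``-6G>A`` / compensatory ``a/b`` IDs."""
    subs = []
    for token in mutation_id.replace(" ", "").split("/"):
        m = _SUB_RE.match(token.replace("T", "U"))
        if not m:
            raise MutationFormatError(f"malformed mutation id: {token!r}")
        pos = int(m.group(1))
        if pos == 0:
            raise MutationFormatError("position 0 is not defined")
        subs.append(Substitution(pos, m.group(2), m.group(3)))
    if not subs:
        raise MutationFormatError("empty mutation id")
    return MutationSpec(tuple(subs))


def format_mutation(spec: MutationSpec) -> str:
    return "/".join(str(s) for s in spec.substitutions)


def apply_mutation(js: JunctionSequence, spec: MutationSpec,
                   profile=None):
    """Apply a mutation; optionally mask its sites in a probing profile.

    The wild-type profile restrains the mutant's structural space, except
    that each mutated site is set to the no-data sentinel.  Returns
    ``(mutant_sequence, masked_profile)``; the profile slot is ``None``
    when no profile is supplied.
    """
    seq = list(js.sequence)
    positions = []
    for sub in spec.substitutions:
        idx = js.absolute_position(sub.position)
        if seq[idx - 1] != sub.ref:
            raise MutationFormatError(
                f"reference base mismatch at {sub.position:+d}: wild type "
                f"has {seq[idx - 1]}, id says {sub.ref}")
        seq[idx - 1] = sub.alt
        positions.append(idx)
    mutant = "".join(seq)
    masked = profile.mask_positions(positions) if profile is not None else None
    return mutant, masked


def _translate(codon: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(codon.replace("U", "T")).translate())


def classify_substitution(js: JunctionSequence, sub: Substitution,
                          frame_offset: int = 0) -> str:
    """"intronic", "synonymous" or "non-synonymous" for one substitution.

    ``frame_offset`` is the 0-based position within its codon of the
    first exonic nucleotide of the junction sequence.
    """
    idx = js.absolute_position(sub.position)
    if idx > js.junction_offset:
        return "intronic"
    codon_start = idx - ((idx - 1 + frame_offset) % 3)
    wt_codon = js.sequence[codon_start - 1:codon_start + 2]
    if len(wt_codon) < 3 or codon_start < 1:
        return "synonymous"  # incomplete codon at the boundary: no aa change
    mut = list(wt_codon)
    mut[idx - codon_start] = sub.alt
    return ("synonymous" if _translate(wt_codon) == _translate("".join(mut))
            else "non-synonymous")


def category_flags(category: str) -> dict:
    """Indicator flags for the category-gated regression.

    Compensatory double mutations carry the flags of their component
    substitutions (non-synonymous dominating); WT-like variants carry no
    flags.
    """
    cat = category.lower().replace("_", "-")
    flags = {"is_non_synonymous": 0, "is_synonymous": 0, "is_intronic": 0}
    if cat in ("non-synonymous", "nonsynonymous"):
        flags["is_non_synonymous"] = 1
    elif cat == "synonymous":
        flags["is_synonymous"] = 1
    elif cat == "intronic":
        flags["is_intronic"] = 1
    elif cat == "compensatory":
        # components are scored individually by the pipeline; by default a
        # compensatory pair of synonymous/intronic changes gates the
        # structure block
        flags["is_synonymous"] = 1
    elif cat in ("wt-like", "wt"):
        pass
    else:
        raise ValueError(f"unknown category {category!r}")
    return flags


def classify_mutation(js: JunctionSequence, spec: MutationSpec,
                      frame_offset: int = 0) -> str:
    """Category of a (possibly compensatory) mutation."""
    kinds = [classify_substitution(js, s, frame_offset)
             for s in spec.substitutions]
    if len(kinds) > 1:
        return "compensatory"
    return kinds[0]
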