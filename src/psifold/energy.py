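"""Nearest-neighbor free-energy model and fixed-structure evaluation.

The model is a deliberately compact nearest-neighbor parameter set:

* a 6 x 6 stacking table over the six canonical pair types (kcal/mol for a
  pair stacked directly on an adjacent pair),
* logarithmic length penalties for hairpin and internal/bulge loops,
* an affine multibranch-loop penalty (offset + per-branch + per-unpaired,
  the closing pair counting as a branch),
* a terminal penalty for AU/GU pairs that delimit a loop (helix ends), and
* the temperature, with RT = 0.0019872 kcal/(mol K) x T.

The whole parameter set is plain data (TSV round-trip), so a measured
nearest-neighbor table can be dropped in without touching the engine.
Chemical-probing restraints enter as per-nucleotide pseudo-energies: a
paired nucleotide with reactivity r pays -RT ln[ P(r | paired) /
P(r | unpaired) ], zero for no-data positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .structure import (InvalidStructureError, SecondaryStructure,
                        encode_sequence)

R_GAS = 0.0019872  # kcal / (mol K)

#: pair-type order used by every table in the engine
PAIR_ORDER = ("CG", "GC", "AU", "UA", "GU", "UG")

#: 4x4 matrix base-index -> base-index -> pair type (-1 = not pairable)
PTYPE = np.full((4, 4), -1, dtype=np.int8)
for _t, _p in enumerate(PAIR_ORDER):
    _a, _b = ("ACGU".index(_p[0]), "ACGU".index(_p[1]))
    PTYPE[_a, _b] = _t

NO_DATA = -999.0


def _default_stack() -> np.ndarray:
    # stack energy = -(strength(outer) + strength(inner)); CG-on-CG -3.2,
    # AU-on-AU -1.8, GU-on-GU -0.9 -- the qualitative ordering of measured
    # nearest-neighbor tables in a 36-entry table.
    strength = {"CG": 1.6, "GC": 1.6, "AU": 0.9, "UA": 0.9,
                "GU": 0.45, "UG": 0.45}
    tab = np.zeros((6, 6))
    for i, p in enumerate(PAIR_ORDER):
        for j, q in enumerate(PAIR_ORDER):
            tab[i, j] = -(strength[p] + strength[q])
    return tab


@dataclass(frozen=True)
class EnergyModel:
    """Parameter set for the folding engine (all energies kcal/mol)."""

    stack: np.ndarray = field(default_factory=_default_stack)
    hairpin_base: float = 5.4       # hairpin loop of 3
    internal_base: float = 1.7      # internal/bulge loop of 1
    loop_log_coeff: float = 1.0786  # 1.75 RT at 310.15 K
    ml_offset: float = 3.4
    ml_branch: float = 0.4
    ml_unpaired: float = 0.1
    au_end_penalty: float = 0.5
    temperature: float = 310.15
    max_internal: int = 30          # internal-loop size cap in the DP

    @property
    def RT(self) -> float:
        return R_GAS * self.temperature

    def hairpin_penalty(self, loop_len: int) -> float:
        if loop_len < 3:
            return math.inf
        return self.hairpin_base + self.loop_log_coeff * math.log(loop_len / 3.0)

    def internal_penalty(self, loop_len: int) -> float:
        if loop_len < 1:
            raise ValueError("internal loop length must be >= 1")
        return self.internal_base + self.loop_log_coeff * math.log(loop_len)

    def au_penalty(self, ptype: int) -> float:
        """Terminal penalty for a loop-delimiting pair of the given type."""
        return 0.0 if ptype in (0, 1) else self.au_end_penalty

    # -- arrays for the DP kernels ----------------------------------------
    def au_array(self) -> np.ndarray:
        return np.array([self.au_penalty(t) for t in range(6)])

    def hairpin_array(self, n: int) -> np.ndarray:
        out = np.full(n + 1, np.inf)
        for L in range(3, n + 1):
            out[L] = self.hairpin_penalty(L)
        return out

    def internal_array(self, n: int) -> np.ndarray:
        out = np.full(n + 1, np.inf)
        for L in range(1, n + 1):
            out[L] = self.internal_penalty(L)
        return out

    def with_temperature(self, temperature: float) -> "EnergyModel":
        return replace(self, temperature=temperature)

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# psifold energy model v1\n")
            for key in ("hairpin_base", "internal_base", "loop_log_coeff",
                        "ml_offset", "ml_branch", "ml_unpaired",
                        "au_end_penalty", "temperature", "max_internal"):
                fh.write(f"{key}\t{getattr(self, key)}\n")
            fh.write("stack\t" + "\t".join(PAIR_ORDER) + "\n")
            for i, p in enumerate(PAIR_ORDER):
                row = "\t".join(f"{v:.4f}" for v in self.stack[i])
                fh.write(f"{p}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "EnergyModel":
        scalars: dict = {}
        stack = np.zeros((6, 6))
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()
                     and not ln.startswith("#")]
        it = iter(lines)
        for ln in it:
            parts = ln.split("\t")
            if parts[0] == "stack":
                for i in range(6):
                    row = next(it).split("\t")
                    stack[i] = [float(v) for v in row[1:7]]
                break
            scalars[parts[0]] = float(parts[1])
        scalars["max_internal"] = int(scalars.get("max_internal", 30))
        return cls(stack=stack, **scalars)


class PseudoEnergyModel:
    """Reactivity pseudo-energies from context likelihood distributions.

    Parameters
    ----------
    distributions : ContextDistributions
        Calibrated (or parametric) likelihoods for unpaired / helix-end /
        stacked reactivities, exposing ``logpdf(context, r)`` with contexts
        ``"unpaired"``, ``"helix_end"``, ``"stacked"`` and the count-weighted
        two-state mixture ``"paired"``.
    profile : ReactivityProfile, optional
        Profile whose reactivities generate the per-position penalties; may
        be bound later via :meth:`bind`.
    mode : {"two", "three"}
        ``"two"`` collapses helix-end and stacked into one paired state (the
        form used inside the partition-function DP); ``"three"`` scores a
        fixed structure with context-specific likelihoods.
    """

    def __init__(self, distributions, profile=None, mode: str = "two"):
        if mode not in ("two", "three"):
            raise ValueError("mode must be 'two' or 'three'")
        self.distributions = distributions
        self.profile = profile
        self.mode = mode

    def bind(self, profile) -> "PseudoEnergyModel":
        return PseudoEnergyModel(self.distributions, profile, self.mode)

    def _reactivities(self, n: int) -> np.ndarray:
        if self.profile is None:
            return np.full(n + 1, NO_DATA)
        return self.profile.reactivity_array(n)

    def penalty_array(self, n: int, model: EnergyModel) -> np.ndarray:
        """1-based per-position penalty added when the position is paired.

        Two-context form: -RT ln[ P(r | paired) / P(r | unpaired) ]; exactly
        0 for no-data positions.
        """
        r = self._reactivities(n)
        out = np.zeros(n + 1)
        d = self.distributions
        for i in range(1, n + 1):
            if r[i] == NO_DATA or np.isnan(r[i]):
                continue
            out[i] = -model.RT * (d.logpdf("paired", r[i])
                                  - d.logpdf("unpaired", r[i]))
        return out

    def context_penalty(self, context: int, r: float,
                        model: EnergyModel) -> float:
        """Three-context penalty for one nucleotide in a fixed structure."""
        if context == 0 or r == NO_DATA or np.isnan(r):
            return 0.0
        name = "helix_end" if context == 1 else "stacked"
        d = self.distributions
        return -model.RT * (d.logpdf(name, r) - d.logpdf("unpaired", r))


# ---------------------------------------------------------------------------
# Fixed-structure evaluation (loop decomposition)
# ---------------------------------------------------------------------------

def _loop_decomposition(structure: SecondaryStructure):
    """Yield loops of the structure.

    Each loop is ``(closing, branches, n_unpaired)`` where ``closing`` is
    the (i, j) pair closing the loop or ``None`` for the exterior loop and
    ``branches`` is the list of (k, l) pairs directly interior to it.
    """
    pt = structure.pair_table
    n = len(structure)

    def scan(lo: int, hi: int):
        branches, unpaired = [], 0
        k = lo
        while k <= hi:
            if pt[k] == 0:
                unpaired += 1
                k += 1
            else:
                branches.append((k, int(pt[k])))
                k = int(pt[k]) + 1
        return branches, unpaired

    exterior = scan(1, n)
    yield None, exterior[0], exterior[1]
    stack = list(exterior[0])
    while stack:
        i, j = stack.pop()
        branches, unpaired = scan(i + 1, j - 1)
        yield (i, j), branches, unpaired
        stack.extend(branches)


def evaluate_energy(structure: SecondaryStructure, model: EnergyModel,
                    pseudo: PseudoEnergyModel | None = None) -> float:
    """Free energy (kcal/mol) of a fixed structure under the model.

    The fully unpaired chain scores exactly 0 without pseudo terms.  Raises
    :class:`InvalidStructureError` for malformed pair tables (checked at
    structure construction).
    """
    seq = encode_sequence(structure.sequence)
    pt = structure.pair_table

    def ptype(i: int, j: int) -> int:
        t = PTYPE[seq[i - 1], seq[j - 1]]
        if t < 0:
            raise InvalidStructureError(
                f"non-canonical pair {structure.sequence[i-1]}-"
                f"{structure.sequence[j-1]} at ({i},{j})")
        return int(t)

    energy = 0.0
    for closing, branches, unpaired in _loop_decomposition(structure):
        if closing is None:  # exterior loop: only terminal penalties
            for k, l in branches:
                energy += model.au_penalty(ptype(k, l))
            continue
        i, j = closing
        if len(branches) == 0:
            energy += model.hairpin_penalty(unpaired)
            energy += model.au_penalty(ptype(i, j))
        elif len(branches) == 1:
            k, l = branches[0]
            if k == i + 1 and l == j - 1:  # helix continuation
                energy += model.stack[ptype(i, j), ptype(k, l)]
            else:
                energy += model.internal_penalty(unpaired)
                energy += model.au_penalty(ptype(i, j))
                energy += model.au_penalty(ptype(k, l))
        else:
            energy += (model.ml_offset
                       + model.ml_branch * (len(branches) + 1)
                       + model.ml_unpaired * unpaired)
            energy += model.au_penalty(ptype(i, j))
            for k, l in branches:
                energy += model.au_penalty(ptype(k, l))

    if pseudo is not None:
        n = len(structure)
        if pseudo.mode == "three":
            codes = structure.context_codes()
            r = pseudo._reactivities(n)
            for i in range(1, n + 1):
                energy += pseudo.context_penalty(int(codes[i]), r[i], model)
        else:
            pen = pseudo.penalty_array(n, model)
            for i in range(1, n + 1):
                if pt[i] != 0:
                    energy += pen[i]
    return energy
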