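"""Partition function, MFE folding, Boltzmann sampling and the
exhaustive enumeration oracle.

The engine folds a single RNA strand under the nearest-neighbor model of
:mod:`psifold.energy`, optionally restrained by chemical-probing
pseudo-energies.  ``partition_function`` runs a McCaskill-style O(n^3)
inside/outside recursion whose weights agree with ``evaluate_energy``
structure by structure; ``sample_structures`` draws independent samples by
stochastic traceback; ``enumerate_structures`` brute-forces every
pseudoknot-free structure of a short sequence and is the testing oracle
for all three.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _dp
from .energy import PTYPE, EnergyModel, PseudoEnergyModel, evaluate_energy
from .structure import SecondaryStructure, encode_sequence

MAX_ENUMERATION_LENGTH = 20


@dataclass(frozen=True)
class StructureEnsemble:
    """N structures sampled from the Boltzmann distribution."""

    sequence: str
    members: tuple
    seed: int
    profile_id: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, item):
        return self.members[item]

    def pair_matrix(self) -> np.ndarray:
        """(N, n+1) int matrix of 1-based pair tables."""
        return np.stack([m.pair_table for m in self.members])


def _kernel_args(sequence: str, model: EnergyModel,
                 pseudo: PseudoEnergyModel | None, profile):
    seq = encode_sequence(sequence)
    n = len(seq)
    if pseudo is not None and profile is not None:
        pseudo = pseudo.bind(profile)
    if pseudo is not None:
        dms = pseudo.penalty_array(n, model)[1:]
    else:
        dms = np.zeros(n)
    return (seq, PTYPE, model.stack, model.hairpin_array(n),
            model.internal_array(n), model.au_array(),
            model.ml_offset, model.ml_branch, model.ml_unpaired,
            dms, model.RT, model.max_internal)


def partition_function(sequence: str, model: EnergyModel | None = None,
                       pseudo: PseudoEnergyModel | None = None,
                       profile=None):
    """Boltzmann partition function and base-pair probability matrix.

    Returns
    -------
    log_z : float
        Natural log of the partition function (open chain has weight 1,
        so an unpairable sequence gives ``log_z == 0``).
    pair_prob : numpy.ndarray
        Symmetric (n+1, n+1) matrix of pair probabilities, 1-based (row
        and column 0 unused).  ``pair_prob.sum(axis=1)[i]`` is the
        probability that nucleotide i is paired.
    """
    model = model or EnergyModel()
    args = _kernel_args(sequence, model, pseudo, profile)
    n = len(sequence)
    if n < 5:
        return 0.0, np.zeros((n + 1, n + 1))
    B, M, M1, Qpre, Qsuf = _dp.inside(*args)
    log_z = float(Qpre[n])
    OB = _dp.outside(*args, B, M, M1, Qpre, Qsuf)
    P0 = _dp.pair_probabilities(B, OB, log_z)
    P = np.zeros((n + 1, n + 1))
    P[1:, 1:] = P0
    return log_z, P


def paired_probability(pair_prob: np.ndarray) -> np.ndarray:
    """Per-nucleotide paired probability (1-based) from the pair matrix."""
    return pair_prob.sum(axis=1)


def mfe_fold(sequence: str, model: EnergyModel | None = None,
             pseudo: PseudoEnergyModel | None = None,
             profile=None) -> SecondaryStructure:
    """Minimum free-energy structure.

    Ties are resolved toward fewer pairs; among equal-energy, equal-count
    co-optima the traceback picks a fixed decomposition order (hairpin,
    stack, internal by ascending (k, l), multibranch by ascending k), so
    the result is deterministic.
    """
    model = model or EnergyModel()
    n = len(sequence)
    if n < 5:
        return SecondaryStructure.open_chain(sequence)
    args = _kernel_args(sequence, model, pseudo, profile)
    tables = _dp.mfe_tables(*args)
    pt0 = _dp.mfe_traceback(*args, *tables)
    pt = np.zeros(n + 1, dtype=np.int32)
    for i in range(n):
        if pt0[i] >= 0:
            pt[i + 1] = pt0[i] + 1
    return SecondaryStructure(sequence, pt)


def sample_structures(sequence: str, model: EnergyModel | None = None,
                      pseudo: PseudoEnergyModel | None = None,
                      profile=None, n: int = 1000, seed: int = 0,
                      profile_id: str = "") -> StructureEnsemble:
    """Draw ``n`` independent Boltzmann samples by stochastic traceback."""
    model = model or EnergyModel()
    ln = len(sequence)
    if ln < 5:
        members = tuple(SecondaryStructure.open_chain(sequence)
                        for _ in range(n))
        return StructureEnsemble(sequence, members, seed, profile_id)
    args = _kernel_args(sequence, model, pseudo, profile)
    B, M, M1, Qpre, Qsuf = _dp.inside(*args)
    tables = _dp.sample_tracebacks(*args, B, M, M1, Qpre, Qsuf,
                                   n, np.uint64(seed & 0x7FFFFFFFFFFFFFFF))
    members = []
    for row in tables:
        pt = np.zeros(ln + 1, dtype=np.int32)
        for i in range(ln):
            if row[i] >= 0:
                pt[i + 1] = row[i] + 1
        members.append(SecondaryStructure(sequence, pt))
    return StructureEnsemble(sequence, tuple(members), seed, profile_id)


# ---------------------------------------------------------------------------
# Exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_structures(sequence: str, model: EnergyModel | None = None,
                         pseudo: PseudoEnergyModel | None = None):
    """All pseudoknot-free structures of a short sequence, with energies.

    Only canonical pairs and hairpin loops >= 3 are allowed, matching the
    engine.  Refuses sequences longer than ``MAX_ENUMERATION_LENGTH``.
    Returns a list of ``(SecondaryStructure, energy)`` pairs.
    """
    n = len(sequence)
    if n > MAX_ENUMERATION_LENGTH:
        raise ValueError(
            f"enumeration limited to {MAX_ENUMERATION_LENGTH} nt (got {n})")
    model = model or EnergyModel()
    seq = encode_sequence(sequence)

    @lru_cache(maxsize=None)
    def structs(i: int, j: int):
        """All pair-sets on 0-based closed interval [i, j]."""
        if j - i + 1 <= 4:
            if j < i:
                return (frozenset(),)
            return (frozenset(),)
        out = list(frozenset(s) for s in structs(i + 1, j))
        for k in range(i + 4, j + 1):
            if PTYPE[seq[i], seq[k]] >= 0:
                for inner in structs(i + 1, k - 1):
                    for rest in structs(k + 1, j):
                        out.append(inner | rest | {(i, k)})
        return tuple(out)

    results = []
    for pairset in structs(0, n - 1):
        s = SecondaryStructure.from_pairs(
            sequence, [(i + 1, j + 1) for i, j in pairset])
        results.append((s, evaluate_energy(s, model, pseudo)))
    return results


def count_structures(sequence: str) -> int:
    """Independent recursive count of pseudoknot-free structures.

    Uses a different recursion (split at the pairing partner of the LAST
    position) from :func:`enumerate_structures`, as a cross-check.
    """
    seq = encode_sequence(sequence)
    n = len(seq)

    @lru_cache(maxsize=None)
    def count(i: int, j: int) -> int:
        if j - i + 1 <= 4:
            return 1
        total = count(i, j - 1)  # j unpaired
        for k in range(i, j - 3):
            if PTYPE[seq[k], seq[j]] >= 0:
                total += count(i, k - 1) * count(k + 1, j - 1)
        return total

    return count(0, n - 1)
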