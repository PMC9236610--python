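"""Unfolding free energy of spliceosome-footprint regions.

The cost of presenting a stretch of pre-mRNA to the spliceosome is
modeled as the non-equilibrium unfolding free energy

    dG_unfold_cost = dG(region forced single-stranded) - dG(folded),

i.e. every base pair touching the region of interest is removed from a
fixed structure (no refolding) and both forms are scored with the same
energy model.  Footprint extents for the four spliceosome assembly
intermediates captured by cryo-EM (numbers of exonic/intronic
nucleotides enclosed around the donor site) are built in, and can be
re-derived from coordinate files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .energy import EnergyModel, PseudoEnergyModel, evaluate_energy
from .folding import StructureEnsemble, mfe_fold
from .junction import JunctionSequence
from .structure import SecondaryStructure

#: (exonic, intronic) nucleotides enclosed by each spliceosome complex
FOOTPRINTS = {
    "PreB": (2, 8),
    "B": (10, 17),
    "PreBact": (9, 20),
    "Bact": (12, 31),
}

#: the donor site read by U1 snRNA: last 3 exonic + first 6 intronic nt
SPLICE_SITE_EXTENT = (3, 6)


@dataclass(frozen=True)
class JunctionRegion:
    """A junction-anchored interval (extents in nucleotides)."""

    exonic_extent: int
    intronic_extent: int

    def __post_init__(self):
        if self.exonic_extent < 0 or self.intronic_extent < 0:
            raise ValueError("extents must be non-negative")

    @property
    def width(self) -> int:
        return self.exonic_extent + self.intronic_extent

    def resolve(self, js: JunctionSequence) -> tuple[int, int]:
        """1-based inclusive interval [start, end] on the sequence."""
        start = js.junction_offset - self.exonic_extent + 1
        end = js.junction_offset + self.intronic_extent
        if start < 1 or end > len(js):
            raise ValueError(
                f"region ({self.exonic_extent},{self.intronic_extent}) "
                f"overflows the sequence")
        return start, end


def footprint_region(stage: str, js: JunctionSequence | None = None
                     ) -> JunctionRegion:
    """Region for a named spliceosome stage (validated against ``js``)."""
    if stage not in FOOTPRINTS:
        raise KeyError(f"unknown spliceosome stage {stage!r}; "
                       f"choose from {sorted(FOOTPRINTS)}")
    region = JunctionRegion(*FOOTPRINTS[stage])
    if js is not None:
        region.resolve(js)  # raises on overflow
    return region


def splice_site_region() -> JunctionRegion:
    return JunctionRegion(*SPLICE_SITE_EXTENT)


# ---------------------------------------------------------------------------
# Unfolding
# ---------------------------------------------------------------------------

def unfold_region(structure: SecondaryStructure,
                  start: int, end: int) -> SecondaryStructure:
    """Force [start, end] (1-based, inclusive) single-stranded.

    Every pair with at least one endpoint inside the interval is removed
    (the CT-file operation of zeroing the partner column); all other
    pairs are untouched.
    """
    pt = structure.pair_table.copy()
    for i in range(1, len(structure) + 1):
        j = int(pt[i])
        if j and (start <= i <= end or start <= j <= end):
            pt[i] = 0
            pt[j] = 0
    return SecondaryStructure(structure.sequence, pt)


def delta_g_unfold(structure: SecondaryStructure,
                   region: JunctionRegion | tuple,
                   js: JunctionSequence,
                   model: EnergyModel,
                   pseudo: PseudoEnergyModel | None = None) -> float:
    """Unfolding cost dG(unfolded) - dG(folded) for one structure.

    Pseudo-energies, when given, are included in both evaluations, so
    they cancel for positions whose pairing state the unfolding does not
    change.  Zero when the region is already unpaired.
    """
    start, end = (region.resolve(js) if isinstance(region, JunctionRegion)
                  else region)
    opened = unfold_region(structure, start, end)
    e_folded = evaluate_energy(structure, model, pseudo)
    e_unfolded = evaluate_energy(opened, model, pseudo)
    return e_unfolded - e_folded


@dataclass(frozen=True)
class UnfoldingStats:
    """Moments of the unfolding cost over a Boltzmann ensemble."""

    mean: float
    sd: float
    skew: float
    kurtosis: float     # excess kurtosis; 0 for zero-variance ensembles
    mfe_delta_g: float  # unfolding cost of the single MFE structure
    n: int
    values: np.ndarray

    def as_features(self) -> dict:
        return {"mean_dg": self.mean, "sd_dg": self.sd,
                "skew_dg": self.skew, "kurt_dg": self.kurtosis,
                "mfe_dg": self.mfe_delta_g}


def ensemble_unfolding_stats(ensemble: StructureEnsemble,
                             region: JunctionRegion,
                             js: JunctionSequence,
                             model: EnergyModel,
                             pseudo: PseudoEnergyModel | None = None,
                             profile=None) -> UnfoldingStats:
    """Population moments of the unfolding cost across ensemble members.

    The MFE unfolding cost is recomputed from an MFE fold of the same
    sequence/restraints.  Skew and excess kurtosis are defined as 0 for
    zero-variance ensembles.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble is empty")
    start_end = region.resolve(js)
    values = np.array([
        delta_g_unfold(s, start_end, js, model, pseudo)
        for s in ensemble])
    mean = float(values.mean())
    sd = float(values.std())  # population SD
    if sd < 1e-12:
        skew = kurt = 0.0
    else:
        skew = float(_stats.skew(values, bias=True))
        kurt = float(_stats.kurtosis(values, bias=True))  # excess
    mfe = mfe_fold(ensemble.sequence, model, pseudo, profile)
    mfe_dg = delta_g_unfold(mfe, start_end, js, model, pseudo)
    return UnfoldingStats(mean, sd, skew, kurt, mfe_dg, len(ensemble), values)


# ---------------------------------------------------------------------------
# Footprints from coordinates
# ---------------------------------------------------------------------------

def count_footprint_from_coordinates(path, chain_id: str,
                                     junction_residue: int
                                     ) -> tuple[int, int]:
    """Count resolved pre-mRNA nucleotides up/downstream of the junction.

    Reads a PDB or mmCIF file; a residue counts when it has at least one
    atom record.  Residues with sequence number <= ``junction_residue``
    are exonic, the rest intronic.
    """
    import gemmi
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if all(len(mdl) == 0 for mdl in st):  # empty coordinate file
        return 0, 0
    for mdl in st:
        for chain in mdl:
            if chain.name != chain_id:
                continue
            n_ex = n_in = 0
            for res in chain:
                if len(res) == 0:
                    continue
                if res.seqid.num <= junction_residue:
                    n_ex += 1
                else:
                    n_in += 1
            return n_ex, n_in
    raise KeyError(f"chain {chain_id!r} not found in {path}")


# ---------------------------------------------------------------------------
# Exon-independence scan
# ---------------------------------------------------------------------------

def exon_independence_scan(js: JunctionSequence,
                           exon_interval: tuple[int, int],
                           profile=None,
                           model: EnergyModel | None = None,
                           pseudo: PseudoEnergyModel | None = None):
    """Refold successively longer 3' extensions of an exon.

    Starting from the exon alone and adding one downstream nucleotide at
    a time, each prefix is MFE-folded (restrained to the profile
    positions available for that prefix) and the fraction of base pairs
    with both ends inside the exon interval is recorded.  A fold with no
    pairs reports fraction 1.0 by convention and is flagged by
    ``n_pairs == 0``.

    Returns a DataFrame with columns ``extension``, ``length``,
    ``fraction_intra`` and ``n_pairs``.
    """
    import pandas as pd
    from .reactivity import ReactivityProfile

    model = model or EnergyModel()
    lo, hi = exon_interval
    if not (1 <= lo <= hi <= len(js)):
        raise ValueError("exon interval outside sequence")
    rows = []
    for end in range(hi, len(js) + 1):
        seq = js.sequence[:end]
        prof = None
        if profile is not None:
            keep = profile.position <= end
            prof = ReactivityProfile(profile.position[keep],
                                     profile.base[keep],
                                     profile.reactivity[keep],
                                     profile.se[keep])
        s = mfe_fold(seq, model, pseudo, prof)
        pairs = s.pairs
        intra = sum(1 for i, j in pairs if lo <= i <= hi and lo <= j <= hi)
        frac = intra / len(pairs) if pairs else 1.0
        rows.append({"extension": end - hi, "length": end,
                     "fraction_intra": frac, "n_pairs": len(pairs)})
    return pd.DataFrame(rows)
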