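"""Synthetic inputs for every stage of the pipeline.

Real inputs for this kind of analysis are probing experiments, curated
mutation panels and deposited cryo-EM coordinates; the generators here
emulate each of them so the full pipeline is exercisable and testable
offline:

* junction sequences with a planted hairpin straddling the exon-intron
  boundary (the study region is a 234-nt junction amplicon, the default
  fixture size);
* per-nucleotide reactivities drawn from context-dependent gamma
  distributions (unpaired mean 0.8 > helix-end 0.2 > stacked 0.05,
  shape 2) against a known structure;
* mutation-rate tables with binomial counting noise at a given read
  depth, whose raw-reactivity reduction recovers the simulated profile;
* mutation panels whose observed PSI follows a Beta distribution around
  an inverse-logit mean in the features the real pipeline computes; and
* minimal PDB coordinate fixtures for footprint counting.

Every generator takes an explicit seed and owns its RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .junction import JunctionSequence, MutationSpec, Substitution
from .reactivity import (ContextDistributions, MutationRateTable,
                         ReactivityProfile)
from .structure import SecondaryStructure

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
#: pair choices for planted helices, GC-biased for stability
_PAIR_CHOICES = ("GC", "CG", "GC", "CG", "AU", "UA")

STUDY_REGION_LENGTH = 234


@dataclass(frozen=True)
class ReactivitySimulationParams:
    """Context means (reactivity units), gamma shape and seed."""

    unpaired_mean: float = 0.8
    paired_mean: float = 0.05
    helix_end_mean: float = 0.2
    dispersion: float = 2.0     # gamma shape; larger = tighter
    seed: int = 0

    def __post_init__(self):
        if not (self.unpaired_mean > self.helix_end_mean
                > self.paired_mean > 0):
            raise ValueError("means must satisfy unpaired > helix_end "
                             "> paired > 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def distributions(self) -> ContextDistributions:
        return ContextDistributions.from_gamma(
            self.unpaired_mean, self.helix_end_mean, self.paired_mean,
            shape=self.dispersion)


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Ground truth for a simulated mutation panel.

    ``true_coefficients`` are the interactive-model coefficients on the
    logit scale (intercept, four structure terms gated on synonymous/
    intronic, three motif terms gated on non-synonymous).  When ``None``
    they are derived from the wild-type ensemble features with
    :func:`default_panel_coefficients`, which anchors the wild-type
    structural baseline at PSI 0.5.
    """

    true_coefficients: tuple | None = None
    precision_phi: float = 50.0
    n_mutations: int = 47
    category_mix: dict = field(default_factory=lambda: {
        "non-synonymous": 0.3, "synonymous": 0.3,
        "intronic": 0.3, "compensatory": 0.1})
    seed: int = 0

    def __post_init__(self):
        if self.precision_phi <= 0:
            raise ValueError("precision must be positive")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category proportions must sum to 1")


def gen_junction_sequence(length: int = STUDY_REGION_LENGTH,
                          junction_offset: int | None = None,
                          hairpin_arm: int = 10,
                          seed: int = 0) -> JunctionSequence:
    """Random junction sequence with one planted hairpin.

    The hairpin's 5' arm ends on the last exonic nucleotide and its
    4-nt loop opens the intron, so the helix straddles the boundary the
    way the study region's junction hairpin does.  Deterministic for a
    fixed seed.
    """
    if junction_offset is None:
        junction_offset = length * 2 // 5
    if length < 2 * hairpin_arm + 7:
        raise ValueError("length must be >= 2*arm + 7")
    if not (hairpin_arm <= junction_offset
            and junction_offset + 4 + hairpin_arm <= length):
        raise ValueError("junction must sit inside the hairpin span")
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGU"), size=length))
    left_start = junction_offset - hairpin_arm + 1   # 1-based
    loop_start = junction_offset + 1
    right_start = junction_offset + 5
    pairs = []
    for k in range(hairpin_arm):
        i = left_start + k
        j = right_start + (hairpin_arm - 1 - k)
        a, b = _PAIR_CHOICES[rng.integers(0, len(_PAIR_CHOICES))]
        seq[i - 1], seq[j - 1] = a, b
        pairs.append((i, j))
    # keep the loop reactive (unpaired-friendly A-rich)
    for p in range(loop_start, loop_start + 4):
        seq[p - 1] = rng.choice(list("AAC"))
    sequence = "".join(seq)
    structure = SecondaryStructure.from_pairs(sequence, pairs)
    return JunctionSequence(sequence, junction_offset, structure)


def simulate_reactivities(structure: SecondaryStructure,
                          params: ReactivitySimulationParams | None = None
                          ) -> ReactivityProfile:
    """Draw per-nucleotide reactivities from context gamma distributions.

    Unpaired, helix-end and stacked nucleotides get their own mean; the
    draws are non-negative by construction.
    """
    params = params or ReactivitySimulationParams()
    rng = np.random.default_rng(params.seed)
    codes = structure.context_codes()
    means = {0: params.unpaired_mean, 1: params.helix_end_mean,
             2: params.paired_mean}
    n = len(structure)
    react = np.empty(n)
    shape = params.dispersion
    for i in range(1, n + 1):
        mean = means[int(codes[i])]
        react[i - 1] = rng.gamma(shape, mean / shape)
    return ReactivityProfile(np.arange(1, n + 1),
                             np.array(list(structure.sequence)),
                             react, np.zeros(n))


def simulate_profile_table(profile: ReactivityProfile, depth: int = 10000,
                           background_rate: float = 0.005,
                           seed: int = 0) -> MutationRateTable:
    """Mutation-rate table whose raw reduction recovers the profile.

    Treated rate = background + reactivity (clipped to [0, 0.99]),
    untreated rate = background, with binomial counting noise at the
    given read depth.  ``depth=0`` returns the analytic (noise-free)
    rates.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0 <= background_rate < 1):
        raise ValueError("background rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    r = np.where(profile.mask, np.maximum(profile.reactivity, 0.0), 0.0)
    p_s = np.clip(background_rate + r, 0.0, 0.99)
    p_u = np.full(len(r), background_rate)
    if depth == 0:
        mutr_s, mutr_u = p_s, p_u
        d = np.ones(len(r), dtype=int)
    else:
        mutr_s = rng.binomial(depth, p_s) / depth
        mutr_u = rng.binomial(depth, p_u) / depth
        d = np.full(len(r), depth, dtype=int)
    return MutationRateTable(profile.position, profile.base,
                             mutr_s, mutr_u, d, d)


# ---------------------------------------------------------------------------
# Synthetic motif resources
# ---------------------------------------------------------------------------

def gen_hexamer_sets(seed: int = 0, n_per_category: int = 2,
                     cluster_size: int = 16) -> dict:
    """Synthetic enhancer/silencer hexamer clusters per SRE category.

    Each cluster is a random consensus hexamer plus single/double
    substitution variants, mimicking over-represented k-mer families
    from splicing-reporter screens.  Returns
    ``{category: [list of hexamer lists]}``.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    out = {}
    for cat in ("ESE", "ESS", "ISE", "ISS",
                "RBP-inclusion", "RBP-exclusion"):
        clusters = []
        for _ in range(n_per_category):
            consensus = "".join(rng.choice(bases, 6))
            members = {consensus}
            while len(members) < cluster_size:
                var = list(consensus)
                for _ in range(rng.integers(1, 3)):
                    var[rng.integers(0, 6)] = rng.choice(bases)
                members.add("".join(var))
            clusters.append(sorted(members))
        out[cat] = clusters
    return out


def default_motif_pwms(seed: int = 0):
    """(sre_pwms, rbp_pwms) built from synthetic hexamer clusters."""
    from .motifs import pwm_from_hexamers
    sets = gen_hexamer_sets(seed)
    sre, rbp = [], []
    for cat, clusters in sets.items():
        for k, hexamers in enumerate(clusters):
            pwm = pwm_from_hexamers(hexamers, cat, name=f"{cat}_{k + 1}")
            (rbp if cat.startswith("RBP") else sre).append(pwm)
    return sre, rbp


# ---------------------------------------------------------------------------
# Mutation panels
# ---------------------------------------------------------------------------

def _draw_mutation(rng, js: JunctionSequence, category: str,
                   frame_offset: int = 0) -> MutationSpec:
    from .junction import classify_substitution
    bases = "ACGU"
    for _ in range(2000):
        if category == "intronic":
            pos = int(rng.integers(1, len(js) - js.junction_offset + 1))
        elif category == "compensatory":
            s1 = _draw_mutation(rng, js, rng.choice(
                ["synonymous", "intronic"]), frame_offset)
            s2 = _draw_mutation(rng, js, rng.choice(
                ["synonymous", "intronic"]), frame_offset)
            if s1.substitutions[0].position == s2.substitutions[0].position:
                continue
            subs = tuple(sorted(s1.substitutions + s2.substitutions,
                                key=lambda s: s.position))
            return MutationSpec(subs)
        else:
            pos = -int(rng.integers(1, js.junction_offset + 1))
        idx = js.absolute_position(pos if category == "intronic" else pos)
        ref = js.sequence[idx - 1]
        alt = bases[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        sub = Substitution(pos if category == "intronic" else pos, ref, alt)
        if category in ("synonymous", "non-synonymous"):
            if classify_substitution(js, sub, frame_offset) != category:
                continue
        return MutationSpec((sub,))
    raise RuntimeError(f"could not draw a {category} mutation")


def derive_panel_coefficients(panel: pd.DataFrame) -> np.ndarray:
    """Generating truth for the interactive model, scaled to the panel.

    The interactive formula gates the absolute-scale unfolding-cost
    block to synonymous/intronic variants while sharing one intercept
    with the delta-scale motif block, so a coherent truth must keep the
    structure block centred near zero on the rows it gates.  Slopes for
    SD/skew/kurtosis are set per unit of their variation across the
    gated rows (standardized effects 0.8, 0.5 and 0.35 on the logit
    scale); the mean-cost slope is then solved from the linear
    constraint that the block's average contribution on gated rows
    vanishes.  With zero intercept a typical variant sits near PSI 0.5
    and the linear predictor stays within a physiological range for
    every seed, while motif slopes (enhancer +0.6, silencer -0.6, donor
    +0.5 per unit delta) drive the non-synonymous rows.
    """
    gated = panel[(panel["is_synonymous"] == 1)
                  | (panel["is_intronic"] == 1)]
    if len(gated) < 4:
        raise ValueError("panel needs synonymous/intronic rows")
    target = {"sd_dg": 0.8, "skew_dg": 0.5, "kurt_dg": 0.35}
    slopes = {}
    for feat, c in target.items():
        s = float(gated[feat].std())
        slopes[feat] = c / s if s > 1e-9 else 0.0
    m_mean = float(gated["mean_dg"].mean())
    resid = sum(slopes[f] * float(gated[f].mean()) for f in target)
    slopes["mean_dg"] = -resid / m_mean if abs(m_mean) > 1e-9 else 0.0
    return np.array([0.0, slopes["mean_dg"], slopes["sd_dg"],
                     slopes["skew_dg"], slopes["kurt_dg"],
                     0.6, -0.6, 0.5])


def simulate_mutation_panel(spec: SyntheticPanelSpec,
                            wild_type: JunctionSequence,
                            config=None,
                            n_samples: int = 200) -> pd.DataFrame:
    """Mutation panel with pipeline-computed features and Beta PSI.

    Each synthetic mutation's features are computed by the real variant
    pipeline on the wild-type fixture; its mean PSI is the inverse logit
    of the interactive-model linear predictor under the true
    coefficients, and the observed PSI is drawn Beta(mu*phi,
    (1-mu)*phi).  Complete splicing outcomes are clamped to 0.02/0.98
    (the boundary squeeze keeps the Beta support open).
    """
    from .pipeline import PipelineConfig, compute_features
    from .psi_model import design_matrix

    rng = np.random.default_rng(spec.seed)
    if config is None:
        config = PipelineConfig.for_synthetic(
            wild_type, seed=spec.seed, n_samples=n_samples)
    cats, counts = zip(*spec.category_mix.items())
    n_per = np.floor(np.asarray(counts) * spec.n_mutations).astype(int)
    while n_per.sum() < spec.n_mutations:
        n_per[int(np.argmax(np.asarray(counts) * spec.n_mutations
                            - n_per))] += 1
    rows = []
    seen = set()
    for cat, cnt in zip(cats, n_per):
        for _ in range(cnt):
            for _ in range(200):
                spec_m = _draw_mutation(rng, wild_type, cat,
                                        config.frame_offset)
                if spec_m.id not in seen:
                    seen.add(spec_m.id)
                    break
            feats = compute_features(config, spec_m, category=cat)
            rows.append(feats)
    panel = pd.DataFrame(rows)
    beta_true = (derive_panel_coefficients(panel)
                 if spec.true_coefficients is None
                 else np.asarray(spec.true_coefficients, float))
    mat, _ = design_matrix(panel, "interactive")
    if mat.shape[1] != len(beta_true):
        raise ValueError(f"expected {mat.shape[1]} true coefficients")
    mu = 1.0 / (1.0 + np.exp(-(mat @ beta_true)))
    psi = rng.beta(mu * spec.precision_phi, (1 - mu) * spec.precision_phi)
    panel["true_mean_psi"] = mu
    # Beta draws are strictly inside (0,1); complete splicing outcomes
    # entered as exact 0/1 (e.g. from gels) are represented as 0.02/0.98
    panel["psi"] = np.where(psi <= 0.0, 0.02, np.where(psi >= 1.0, 0.98, psi))
    panel.attrs["true_coefficients"] = beta_true
    return panel


def simulate_feature_table(n: int = 200, phi: float = 50.0,
                           true_coefficients=None,
                           seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Fast feature-level panel (no folding) for model-recovery studies.

    Features are drawn from plausible marginal distributions (unfolding
    cost moments on the kcal/mol scale, motif deltas around 0) and PSI
    from the interactive-model Beta law.  Returns (panel, true_beta).
    """
    from .psi_model import design_matrix

    rng = np.random.default_rng(seed)
    beta = (np.asarray(true_coefficients, float)
            if true_coefficients is not None
            else np.array([0.4, -0.25, 0.3, 0.2, -0.15, 0.5, -0.6, 0.35]))
    cat = rng.choice(["synonymous", "intronic", "non-synonymous"], n)
    panel = pd.DataFrame({
        "id": [f"m{k}" for k in range(n)],
        "category": cat,
        "mean_dg": rng.normal(10, 3, n),
        "sd_dg": np.abs(rng.normal(2, 0.5, n)),
        "skew_dg": rng.normal(0, 1, n),
        "kurt_dg": rng.normal(0, 1, n),
        "mfe_dg": rng.normal(12, 4, n),
        "enhancer": rng.normal(0, 1, n),
        "silencer": rng.normal(0, 1, n),
        "delta_ss": rng.normal(0, 2, n),
        "rbp_ex": rng.normal(0, 1, n),
        "rbp_in": rng.normal(0, 1, n),
    })
    for flag, name in (("is_synonymous", "synonymous"),
                       ("is_intronic", "intronic"),
                       ("is_non_synonymous", "non-synonymous")):
        panel[flag] = (cat == name).astype(int)
    mat, _ = design_matrix(panel, "interactive")
    mu = 1.0 / (1.0 + np.exp(-(mat @ beta)))
    panel["true_mean_psi"] = mu
    panel["psi"] = rng.beta(mu * phi, (1 - mu) * phi)
    return panel, beta


# ---------------------------------------------------------------------------
# Coordinate fixtures
# ---------------------------------------------------------------------------

def make_synthetic_coordinates(n_exonic: int, n_intronic: int, path,
                               chain_id: str = "R") -> None:
    """Write a minimal synthetic PDB file with one pre-mRNA chain.

    Residues 1..n_exonic sit upstream of the junction (the junction
    residue is ``n_exonic``), residues n_exonic+1.. downstream; each
    residue carries a single phosphorus atom, which is all the footprint
    counter requires.
    """
    if n_exonic < 0 or n_intronic < 0:
        raise ValueError("residue counts must be >= 0")
    import gemmi
    st = gemmi.Structure()
    st.name = "synthetic junction fixture"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    total = n_exonic + n_intronic
    for num in range(1, total + 1):
        res = gemmi.Residue()
        res.name = "A"
        res.seqid = gemmi.SeqId(num, " ")
        atom = gemmi.Atom()
        atom.name = "P"
        atom.element = gemmi.Element("P")
        atom.pos = gemmi.Position(float(num) * 6.0, 0.0, 0.0)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
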