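"""End-to-end variant-to-PSI prediction.

For every variant the pipeline: applies the substitution(s) to the
wild-type junction sequence; restrains folding with the wild-type
probing profile, masking the mutated sites as no-data; samples a
Boltzmann ensemble; computes the unfolding-cost moments of the
configured spliceosome footprint plus the MFE unfolding cost; scores
donor-site and SRE/RBP motif strength changes against wild type; and
assembles the feature vector for the beta-regression models.  Seeds are
derived per variant from the run seed, so whole runs are reproducible
byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energetics import (JunctionRegion, ensemble_unfolding_stats,
                         footprint_region)
from .energy import EnergyModel, PseudoEnergyModel
from .folding import sample_structures
from .junction import (JunctionSequence, MutationSpec, apply_mutation,
                       category_flags, classify_mutation, parse_mutation)
from .motifs import SpliceSiteModel, delta_strength
from .reactivity import ReactivityProfile


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a variant run needs.

    ``footprint`` names the spliceosome stage whose enclosed region is
    unfolded (the late-assembly Bact footprint predicts splicing outcome
    best and is the default); ``n_samples`` is the Boltzmann ensemble
    size per variant.
    """

    wild_type: JunctionSequence
    profile: ReactivityProfile | None = None
    model: EnergyModel = field(default_factory=EnergyModel)
    pseudo: PseudoEnergyModel | None = None
    sre_pwms: tuple = ()
    rbp_pwms: tuple = ()
    splice_site_model: SpliceSiteModel = field(
        default_factory=SpliceSiteModel)
    footprint: str = "Bact"
    n_samples: int = 1000
    seed: int = 0
    frame_offset: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("ensemble size must be >= 1")
        footprint_region(self.footprint, self.wild_type)  # validates

    @property
    def region(self) -> JunctionRegion:
        return footprint_region(self.footprint)

    def variant_seed(self, index: int) -> int:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(index,))
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)

    @classmethod
    def for_synthetic(cls, wild_type: JunctionSequence, seed: int = 0,
                      n_samples: int = 200, footprint: str = "Bact",
                      **kwargs) -> "PipelineConfig":
        """Config with simulated probing data and synthetic motif sets.

        Reactivities are simulated from the fixture's true structure,
        pushed through a finite-depth mutation-rate table and the raw/
        normalize/prepare reduction, then used both as the folding
        restraint and (through the parametric context distributions) as
        the pseudo-energy model.
        """
        from .reactivity import (compute_raw_reactivity, normalize_per_base,
                                 prepare_for_folding)
        from .synthetic import (ReactivitySimulationParams,
                                default_motif_pwms, simulate_profile_table,
                                simulate_reactivities)
        if wild_type.true_structure is None:
            raise ValueError("synthetic config needs a true structure")
        params = ReactivitySimulationParams(seed=seed)
        raw_profile = simulate_reactivities(wild_type.true_structure, params)
        table = simulate_profile_table(
            raw_profile.with_reactivity(raw_profile.reactivity * 0.05),
            depth=20000, seed=seed + 1)
        raw = compute_raw_reactivity(table)
        normed = normalize_per_base(raw)
        folding_profile = prepare_for_folding(normed)
        # the parametric context likelihoods match the generating law of
        # the normalized data only approximately; they provide the
        # restraint direction (low reactivity -> pairing bonus)
        pseudo = PseudoEnergyModel(params.distributions())
        sre, rbp = default_motif_pwms(seed)
        return cls(wild_type=wild_type, profile=folding_profile,
                   pseudo=pseudo, sre_pwms=tuple(sre), rbp_pwms=tuple(rbp),
                   footprint=footprint, n_samples=n_samples, seed=seed,
                   **kwargs)


def compute_features(config: PipelineConfig,
                     spec: MutationSpec | str,
                     category: str | None = None,
                     variant_index: int = 0) -> dict:
    """Feature vector for one variant (or the WT when spec is None)."""
    if isinstance(spec, str):
        spec = parse_mutation(spec)
    js = config.wild_type
    if spec is None:
        mutant, masked = js.sequence, config.profile
        mut_id = "WT"
    else:
        mutant, masked = apply_mutation(js, spec, config.profile)
        mut_id = spec.id
    if category is None:
        category = ("wt-like" if spec is None
                    else classify_mutation(js, spec, config.frame_offset))
    seed = config.variant_seed(variant_index)
    ensemble = sample_structures(mutant, config.model, config.pseudo,
                                 masked, n=config.n_samples, seed=seed,
                                 profile_id=mut_id)
    mutant_js = JunctionSequence(mutant, js.junction_offset)
    stats = ensemble_unfolding_stats(ensemble, config.region, mutant_js,
                                     config.model, config.pseudo, masked)
    deltas = delta_strength(config.sre_pwms, js, mutant,
                            splice_model=config.splice_site_model,
                            rbp_pwms=config.rbp_pwms)
    feats = {"id": mut_id, "category": category}
    feats.update(stats.as_features())
    feats.update(deltas.as_features())
    feats.update(category_flags(category))
    return feats


def run_variant_prediction(config: PipelineConfig, panel,
                           formula: str = "interactive",
                           fit: bool = True,
                           output_dir=None) -> dict:
    """Compute features for a panel, optionally fit and predict.

    ``panel`` is either a DataFrame with ``id`` (and optionally
    ``category`` and ``psi``) columns, or an iterable of mutation IDs /
    :class:`MutationSpec`.  Per-variant failures are recorded and the
    run continues.  Returns a dict with ``features`` (DataFrame),
    ``fit`` (BetaRegression or None), ``predictions`` and ``errors``.
    """
    from .psi_model import fit_beta_regression

    if isinstance(panel, pd.DataFrame):
        ids = panel["id"].tolist()
        cats = (panel["category"].tolist() if "category" in panel
                else [None] * len(ids))
        psis = (panel["psi"].tolist() if "psi" in panel
                else [None] * len(ids))
    else:
        ids = [m.id if isinstance(m, MutationSpec) else str(m)
               for m in panel]
        cats = [None] * len(ids)
        psis = [None] * len(ids)

    rows, errors = [], []
    for k, (mid, cat, psi) in enumerate(zip(ids, cats, psis)):
        try:
            spec = None if mid in ("WT", "") else parse_mutation(mid)
            feats = compute_features(config, spec, category=cat,
                                     variant_index=k)
            if psi is not None and not (isinstance(psi, float)
                                        and np.isnan(psi)):
                feats["psi"] = float(psi)
            rows.append(feats)
        except Exception as exc:  # per-variant failure: record, continue
            errors.append({"id": mid, "error": str(exc)})
    features = pd.DataFrame(rows)
    model_fit = None
    predictions = None
    if fit and "psi" in features.columns and features["psi"].notna().all() \
            and len(features) > 0:
        model_fit = fit_beta_regression(features, formula)
        predictions = features[["id", "category", "psi"]].copy()
        predictions["predicted_psi"] = model_fit.predict(features)
    elif len(features) > 0:
        predictions = features[["id", "category"]].copy()
    if output_dir is not None:
        import pathlib
        out = pathlib.Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        if predictions is not None:
            predictions.to_csv(out / "predictions.csv", index=False)
        if model_fit is not None:
            (out / "fit.json").write_text(
                json.dumps(model_fit.to_dict(), indent=2))
    return {"features": features, "fit": model_fit,
            "predictions": predictions, "errors": errors}


def saturation_specs(js: JunctionSequence,
                     window: JunctionRegion) -> list[MutationSpec]:
    """All single substitutions in a junction-anchored window (3 per
    position, no duplicates)."""
    from .junction import Substitution
    start, end = window.resolve(js)
    specs = []
    for idx in range(start, end + 1):
        ref = js.sequence[idx - 1]
        rel = js.relative_position(idx)
        for alt in "ACGU":
            if alt != ref:
                specs.append(MutationSpec((Substitution(rel, ref, alt),)))
    return specs


def saturation_mutagenesis(config: PipelineConfig,
                           window: JunctionRegion,
                           fit_model=None,
                           formula: str = "interactive") -> dict:
    """Predict PSI for every possible substitution in a window.

    Requires a fitted model (or fits one is not provided here — pass
    ``fit_model`` from a panel run).  Returns per-variant predictions
    plus per-position mean PSI and mean unfolding-cost change versus
    wild type.
    """
    specs = saturation_specs(config.wild_type, window)
    result = run_variant_prediction(config, [s.id for s in specs],
                                    formula=formula, fit=False)
    features = result["features"]
    wt_feats = compute_features(config, None, variant_index=len(specs) + 1)
    if fit_model is not None:
        features = features.copy()
        features["predicted_psi"] = fit_model.predict(features)
    features["position"] = [
        parse_mutation(m).substitutions[0].position
        for m in features["id"]]
    features["ddg_mean_vs_wt"] = features["mean_dg"] - wt_feats["mean_dg"]
    agg = {"ddg_mean_vs_wt": "mean"}
    if "predicted_psi" in features:
        agg["predicted_psi"] = "mean"
    per_position = (features.groupby("position").agg(agg)
                    .rename(columns={"predicted_psi": "mean_psi",
                                     "ddg_mean_vs_wt": "mean_ddg"}))
    return {"variants": features, "per_position": per_position,
            "wild_type": wt_feats, "errors": result["errors"]}


# ---------------------------------------------------------------------------
# Gel quantification
# ---------------------------------------------------------------------------

def gel_psi(bands: pd.DataFrame) -> tuple[float, float]:
    """Mean PSI and standard error from replicate gel band intensities.

    ``bands`` carries one row per replicate with columns
    ``intensity_4r`` (exon-included isoform) and ``intensity_3r``;
    per-replicate PSI is 4R / (4R + 3R).
    """
    i4 = bands["intensity_4r"].to_numpy(float)
    i3 = bands["intensity_3r"].to_numpy(float)
    if np.any((i4 < 0) | (i3 < 0)):
        raise ValueError("band intensities must be non-negative")
    tot = i4 + i3
    if np.any(tot == 0):
        raise ValueError("PSI undefined: a replicate has both bands zero")
    psi = i4 / tot
    mean = float(psi.mean())
    se = float(psi.std(ddof=1) / np.sqrt(len(psi))) if len(psi) > 1 else 0.0
    return mean, se
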