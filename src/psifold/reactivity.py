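"""Chemical-probing reactivity profiles.

Mutational-profiling experiments report per-nucleotide mutation rates for
a reagent-treated sample and an untreated control; the raw reactivity of
nucleotide i is the rate difference ``R_i = mutr_S - mutr_U``.  Profiles
are normalized per nucleotide type by the mean of the top decile of
reactivities after the most reactive 2% are removed, and prepared for
folding by masking G/U (the reagent reads out A/C), capping at 5 and
flooring negatives.  ``-999`` is the universal no-data sentinel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .structure import SecondaryStructure

NO_DATA = -999.0
REACTIVITY_CAP = 5.0


class MalformedTableError(ValueError):
    """Raised when a mutation-rate table violates its invariants."""


@dataclass(frozen=True)
class MutationRateTable:
    """Per-nucleotide mutation rates from a mutational-profiling run."""

    position: np.ndarray       # 1-based, contiguous, strictly increasing
    base: np.ndarray           # A/C/G/U per position
    mutr_s: np.ndarray         # treated mutation rate (fraction)
    mutr_u: np.ndarray         # untreated mutation rate (fraction)
    depth_s: np.ndarray
    depth_u: np.ndarray

    def __post_init__(self):
        arrays = [np.asarray(a) for a in
                  (self.position, self.base, self.mutr_s, self.mutr_u,
                   self.depth_s, self.depth_u)]
        lengths = {a.shape[0] for a in arrays}
        if len(lengths) != 1:
            raise MalformedTableError("column length mismatch")
        pos = arrays[0].astype(int)
        if len(pos) and not np.all(np.diff(pos) == 1):
            raise MalformedTableError("positions must be contiguous ascending")
        for rates in (arrays[2], arrays[3]):
            r = rates.astype(float)
            if np.any((r < 0) | (r > 1)):
                raise MalformedTableError("rates must lie in [0, 1]")
        for name, arr in zip(
                ("position", "base", "mutr_s", "mutr_u", "depth_s", "depth_u"),
                arrays):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.position)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": self.position, "base": self.base,
            "mutr_s": self.mutr_s, "mutr_u": self.mutr_u,
            "depth_s": self.depth_s, "depth_u": self.depth_u})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MutationRateTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df["position"].to_numpy(), df["base"].to_numpy(),
                   df["mutr_s"].to_numpy(float), df["mutr_u"].to_numpy(float),
                   df["depth_s"].to_numpy(), df["depth_u"].to_numpy())


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-nucleotide reactivities with standard errors.

    ``reactivity == -999`` marks no-data positions; their SE is NaN.
    """

    position: np.ndarray
    base: np.ndarray
    reactivity: np.ndarray
    se: np.ndarray = field(default=None)

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=int)
        base = np.asarray(self.base)
        react = np.asarray(self.reactivity, dtype=float)
        se = (np.full(len(react), np.nan) if self.se is None
              else np.asarray(self.se, dtype=float))
        se = np.where(react == NO_DATA, np.nan, se)
        for name, arr in zip(("position", "base", "reactivity", "se"),
                             (pos, base, react, se)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.position)

    @property
    def mask(self) -> np.ndarray:
        """True where data is present."""
        return self.reactivity != NO_DATA

    def reactivity_array(self, n: int) -> np.ndarray:
        """1-based dense array of length n+1, sentinel where absent."""
        out = np.full(n + 1, NO_DATA)
        inside = (self.position >= 1) & (self.position <= n)
        out[self.position[inside]] = self.reactivity[inside]
        return out

    def with_reactivity(self, reactivity: np.ndarray,
                        se=None) -> "ReactivityProfile":
        return ReactivityProfile(self.position, self.base,
                                 reactivity, self.se if se is None else se)

    def mask_positions(self, positions) -> "ReactivityProfile":
        """Copy with the given 1-based positions set to the sentinel."""
        react = self.reactivity.copy()
        react[np.isin(self.position, list(positions))] = NO_DATA
        return self.with_reactivity(react)

    # -- .map I/O (position, reactivity, SE, base) ------------------------
    def to_map(self, path) -> None:
        with open(path, "w") as fh:
            for p, b, r, s in zip(self.position, self.base,
                                  self.reactivity, self.se):
                s_out = 0.0 if (np.isnan(s) if s is not None else True) else s
                fh.write(f"{p}\t{r:.6f}\t{s_out:.6f}\t{b}\n")

    @classmethod
    def from_map(cls, path) -> "ReactivityProfile":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["position", "reactivity", "se", "base"])
        return cls(df["position"].to_numpy(), df["base"].to_numpy(),
                   df["reactivity"].to_numpy(float), df["se"].to_numpy(float))


# ---------------------------------------------------------------------------
# Raw reactivity and normalization
# ---------------------------------------------------------------------------

def compute_raw_reactivity(table: MutationRateTable) -> ReactivityProfile:
    """R_i = mutr_S - mutr_U, negatives retained.

    The SE is propagated from the binomial standard errors of both rates
    (square root of the summed variances).
    """
    r = np.asarray(table.mutr_s, float) - np.asarray(table.mutr_u, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_s = table.mutr_s * (1 - table.mutr_s) / np.maximum(table.depth_s, 1)
        var_u = table.mutr_u * (1 - table.mutr_u) / np.maximum(table.depth_u, 1)
    se = np.sqrt(var_s + var_u)
    return ReactivityProfile(table.position, table.base, r, se)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def normalization_factor(values: np.ndarray) -> float:
    """Mean of the top decile after dropping the most reactive 2%.

    Counts are taken on the supplied (non-sentinel) values, rounded half
    up; at least one value is always retained in the decile.
    """
    v = np.sort(np.asarray(values, float))[::-1]
    n = len(v)
    n_excl = _round_half_up(0.02 * n)
    n_top = max(_round_half_up(0.10 * n), 1)
    kept = v[n_excl:n_excl + n_top]
    return float(kept.mean())


def normalize_per_base(raw: ReactivityProfile,
                       visualization_mode: bool = False,
                       min_values: int = 10) -> ReactivityProfile:
    """Per-nucleotide-type normalization of a raw profile.

    Each base type is divided by its own factor (top-decile mean after 2%
    exclusion).  Types with fewer than ``min_values`` informative entries
    are emitted as sentinel with a warning.  In visualization mode the G
    and U entries are rescaled so their maximum is 0.1.
    """
    react = raw.reactivity.copy()
    se = raw.se.copy()
    for b in "ACGU":
        sel = (raw.base == b) & raw.mask
        if not sel.any():
            continue
        if sel.sum() < min_values:
            warnings.warn(f"too few values to normalize base type {b}; "
                          "emitting no-data", stacklevel=2)
            react[sel] = NO_DATA
            se[sel] = np.nan
            continue
        factor = normalization_factor(react[sel])
        react[sel] = react[sel] / factor
        se[sel] = se[sel] / abs(factor)
    if visualization_mode:
        sel = np.isin(raw.base, ["G", "U"]) & (react != NO_DATA)
        if sel.any():
            peak = react[sel].max()
            if peak > 0:
                scale = 0.1 / peak
                react[sel] *= scale
                se[sel] *= scale
    return ReactivityProfile(raw.position, raw.base, react, se)


def prepare_for_folding(profile: ReactivityProfile,
                        cap: float = REACTIVITY_CAP) -> ReactivityProfile:
    """Mask G/U as no-data, cap at ``cap`` and floor negatives at 0."""
    react = profile.reactivity.copy()
    gu = np.isin(profile.base, ["G", "U"])
    react[gu] = NO_DATA
    present = react != NO_DATA
    react[present] = np.clip(react[present], 0.0, cap)
    return profile.with_reactivity(react)


# ---------------------------------------------------------------------------
# Context likelihood distributions
# ---------------------------------------------------------------------------

CONTEXT_NAMES = ("unpaired", "helix_end", "stacked")


class ContextDistributions:
    """Reactivity likelihoods for unpaired / helix-end / stacked contexts.

    Backed either by reflected, truncated kernel-density estimates fitted
    to observed reactivities (:meth:`from_observations`) or by gamma
    densities with per-context means (:meth:`from_gamma`).  All densities
    live on [0, cap]; queries outside are clamped.  ``"paired"`` queries
    the count-weighted helix-end/stacked mixture used by the two-context
    partition-function restraint.
    """

    def __init__(self, logpdf_funcs: dict, weights: dict,
                 means: dict, cap: float = REACTIVITY_CAP,
                 merged_paired: bool = False):
        self._logpdf = logpdf_funcs
        self.weights = weights
        self.means = means
        self.cap = cap
        self.merged_paired = merged_paired

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_gamma(cls, unpaired_mean: float = 0.8,
                   helix_end_mean: float = 0.2, stacked_mean: float = 0.05,
                   shape: float = 2.0, cap: float = REACTIVITY_CAP,
                   helix_end_weight: float = 0.5) -> "ContextDistributions":
        from scipy.stats import gamma as gamma_dist
        means = {"unpaired": unpaired_mean, "helix_end": helix_end_mean,
                 "stacked": stacked_mean}
        funcs = {}
        for name, mean in means.items():
            scale = mean / shape
            norm = gamma_dist.cdf(cap, shape, scale=scale)
            funcs[name] = _GammaLogPdf(shape, scale, math.log(norm))
        weights = {"helix_end": helix_end_weight,
                   "stacked": 1.0 - helix_end_weight}
        return cls(funcs, weights, means, cap)

    @classmethod
    def from_observations(cls, by_context: dict, cap: float = REACTIVITY_CAP,
                          min_per_class: int = 20) -> "ContextDistributions":
        """Fit reflected/truncated KDEs from per-context reactivity arrays.

        When helix-end or stacked has fewer than ``min_per_class``
        observations the two are merged into a single paired class (the
        result is flagged via ``merged_paired``).
        """
        obs = {k: np.clip(np.asarray(v, float), 0.0, cap)
               for k, v in by_context.items()}
        merged = (len(obs.get("helix_end", ())) < min_per_class
                  or len(obs.get("stacked", ())) < min_per_class)
        if len(obs.get("unpaired", ())) < min_per_class:
            raise ValueError("too few unpaired observations to calibrate")
        if merged:
            pooled = np.concatenate([obs.get("helix_end", np.empty(0)),
                                     obs.get("stacked", np.empty(0))])
            if len(pooled) < min_per_class:
                raise ValueError("too few paired observations to calibrate")
            obs = {"unpaired": obs["unpaired"],
                   "helix_end": pooled, "stacked": pooled}
        funcs, means = {}, {}
        for name in CONTEXT_NAMES:
            funcs[name] = _ReflectedKde(obs[name], cap)
            means[name] = float(np.mean(obs[name]))
        n_he, n_st = len(obs["helix_end"]), len(obs["stacked"])
        weights = {"helix_end": n_he / (n_he + n_st),
                   "stacked": n_st / (n_he + n_st)}
        if merged:
            weights = {"helix_end": 0.5, "stacked": 0.5}
        return cls(funcs, weights, means, cap, merged_paired=merged)

    # -- queries -----------------------------------------------------------
    def logpdf(self, context: str, r: float) -> float:
        r = float(np.clip(r, 0.0, self.cap))
        if context == "paired":
            w = self.weights
            a = self._logpdf["helix_end"](r) + math.log(w["helix_end"])
            b = self._logpdf["stacked"](r) + math.log(w["stacked"])
            hi, lo = max(a, b), min(a, b)
            return hi + math.log1p(math.exp(lo - hi))
        return self._logpdf[context](r)

    def pdf(self, context: str, r: float) -> float:
        return math.exp(self.logpdf(context, r))


class _GammaLogPdf:
    def __init__(self, shape, scale, log_norm):
        self.shape, self.scale, self.log_norm = shape, scale, log_norm

    def __call__(self, r: float) -> float:
        from scipy.stats import gamma as gamma_dist
        r = max(r, 1e-9)
        return float(gamma_dist.logpdf(r, self.shape, scale=self.scale)
                     - self.log_norm)


class _ReflectedKde:
    """Gaussian KDE with reflection at 0, truncated and renormalized on
    [0, cap] (Silverman bandwidth)."""

    def __init__(self, values: np.ndarray, cap: float):
        values = np.asarray(values, float)
        if np.ptp(values) < 1e-12:
            values = values + np.random.default_rng(0).normal(
                0, max(1e-3, abs(values.mean()) * 0.05), len(values))
        self._kde = gaussian_kde(values, bw_method="silverman")
        self.cap = cap
        grid = np.linspace(0, cap, 2001)
        dens = self._raw(grid)
        self._log_norm = math.log(np.trapezoid(dens, grid))

    def _raw(self, x):
        return self._kde(x) + self._kde(-np.asarray(x, float))

    def __call__(self, r: float) -> float:
        d = float(self._raw([r])[0])
        return math.log(max(d, 1e-300)) - self._log_norm


def classify_contexts(reference: SecondaryStructure) -> np.ndarray:
    """0 = unpaired, 1 = helix end, 2 = stacked (1-based array)."""
    return reference.context_codes()


def calibrate_context_distributions(
        profile: ReactivityProfile, reference: SecondaryStructure,
        cap: float = REACTIVITY_CAP) -> ContextDistributions:
    """Fit context likelihoods against a reference structure.

    Only A/C positions with data contribute; reactivities are capped at
    ``cap`` before fitting.
    """
    codes = classify_contexts(reference)
    by_context = {name: [] for name in CONTEXT_NAMES}
    for p, b, r in zip(profile.position, profile.base, profile.reactivity):
        if r == NO_DATA or b not in ("A", "C"):
            continue
        if p < 1 or p > len(reference):
            raise ValueError(f"profile position {p} outside reference")
        by_context[CONTEXT_NAMES[codes[p]]].append(min(max(r, 0.0), cap))
    return ContextDistributions.from_observations(by_context, cap)


def reactivity_auc(profile: ReactivityProfile,
                   reference: SecondaryStructure) -> float:
    """AUC of reactivity as a classifier of "unpaired", A/C positions only.

    Computed as the Mann-Whitney rank statistic; raises ``ValueError``
    when the reference provides only one class.
    """
    from sklearn.metrics import roc_auc_score
    labels, scores = [], []
    for p, b, r in zip(profile.position, profile.base, profile.reactivity):
        if r == NO_DATA or b not in ("A", "C"):
            continue
        labels.append(0 if reference.is_paired(int(p)) else 1)
        scores.append(r)
    if len(set(labels)) < 2:
        raise ValueError("reference contains a single pairing class; "
                         "AUC undefined")
    return float(roc_auc_score(labels, scores))
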