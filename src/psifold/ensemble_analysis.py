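"""Ensemble digitization, embedding, representatives and feature maps.

Every structure is flattened into an element string — one code per
nucleotide for the structural element it sits in: 5' exterior ``f``, 3'
exterior ``t``, stem ``s``, hairpin loop ``h`` and (any other) loop
``m`` — digitized as f,t -> 0, s -> 1, h -> 2, m -> 3.  Digitized
ensembles from several variants are stacked, embedded in 2-D with t-SNE
and clustered with k-means; a cluster's representative is the member
closest (Hamming) to the per-position plurality consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import SecondaryStructure

ELEMENT_CODES = {"f": 0, "t": 0, "s": 1, "h": 2, "m": 3}


def element_string(structure: SecondaryStructure) -> str:
    """Per-nucleotide element annotation (f/t/s/h/m).

    Paired positions are stems; unpaired positions in a branch-free loop
    are hairpins; exterior unpaired positions are ``f`` before the first
    pair and ``t`` after the last (midpoint split for the open chain);
    all other loops (internal, bulge, multibranch, exterior segments
    between helices) are ``m``.
    """
    n = len(structure)
    pt = structure.pair_table
    out = ["m"] * n
    paired_pos = [i for i in range(1, n + 1) if pt[i]]
    if not paired_pos:
        half = n // 2
        return "f" * half + "t" * (n - half)
    first, last = paired_pos[0], paired_pos[-1]
    for i in range(1, n + 1):
        if pt[i]:
            out[i - 1] = "s"
        elif i < first:
            out[i - 1] = "f"
        elif i > last:
            out[i - 1] = "t"
    # hairpin loops: unpaired run directly enclosed by a pair with no
    # branches inside
    for i in range(1, n + 1):
        j = int(pt[i])
        if j > i and all(pt[k] == 0 for k in range(i + 1, j)):
            for k in range(i + 1, j):
                out[k - 1] = "h"
    return "".join(out)


def digitize(element_str: str) -> np.ndarray:
    return np.array([ELEMENT_CODES[c] for c in element_str], dtype=np.int8)


def digitize_ensemble(members) -> np.ndarray:
    """(N, L) digitized matrix for a list/ensemble of structures."""
    return np.stack([digitize(element_string(s)) for s in members])


@dataclass(frozen=True)
class EnsembleEmbedding:
    """2-D embedding of pooled ensembles with k-means labels."""

    coordinates: pd.DataFrame   # columns x, y, variant, cluster
    occupancy: pd.DataFrame     # variants x clusters, rows sum to 1
    k: int
    seed: int

    def to_csv(self, path) -> None:
        self.coordinates.to_csv(path, index=False)


def embed_and_cluster(ensembles: dict, k: int = 5, seed: int = 0,
                      perplexity: float = 30.0) -> EnsembleEmbedding:
    """t-SNE embed and k-means cluster pooled digitized ensembles.

    Parameters
    ----------
    ensembles : dict
        Mapping variant label -> StructureEnsemble (or list of
        structures); all must share the sequence length.
    """
    from sklearn.cluster import KMeans
    from sklearn.manifold import TSNE

    labels, blocks = [], []
    for name, ens in ensembles.items():
        mat = digitize_ensemble(list(ens))
        blocks.append(mat)
        labels.extend([name] * mat.shape[0])
    lengths = {b.shape[1] for b in blocks}
    if len(lengths) != 1:
        raise ValueError("ensembles must share sequence length")
    matrix = np.vstack(blocks).astype(float)
    n = matrix.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} structures, got {n}")
    perp = min(perplexity, max(2.0, (n - 1) / 3.0))
    if np.ptp(matrix, axis=0).max() == 0:
        # every structure identical: all points co-located at the origin
        coords = np.zeros((n, 2))
        cluster = np.ones(n, dtype=int)
    else:
        coords = TSNE(n_components=2, random_state=seed,
                      perplexity=perp, init="pca").fit_transform(matrix)
        km = KMeans(n_clusters=k, random_state=seed, n_init=10)
        cluster = km.fit_predict(coords) + 1  # clusters numbered 1..k
    df = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                       "variant": labels, "cluster": cluster})
    occ = (df.groupby("variant")["cluster"]
             .value_counts(normalize=True).unstack(fill_value=0.0)
             .reindex(columns=range(1, k + 1), fill_value=0.0))
    return EnsembleEmbedding(df, occ, k, seed)


def representative_structure(members) -> SecondaryStructure:
    """Member closest to the per-position plurality element consensus.

    Ties in the consensus go to the lower digit; ties in distance to the
    earliest member.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member list")
    mat = digitize_ensemble(members)
    consensus = np.zeros(mat.shape[1], dtype=np.int8)
    for p in range(mat.shape[1]):
        counts = np.bincount(mat[:, p], minlength=4)
        consensus[p] = int(np.argmax(counts))  # argmax takes lowest on ties
    dists = (mat != consensus[None, :]).sum(axis=1)
    return members[int(np.argmin(dists))]


# ---------------------------------------------------------------------------
# Feature normalization and support categories
# ---------------------------------------------------------------------------

HEATMAP_FEATURES = ("delta_ss", "silencer", "enhancer", "mean_dg")
#: features whose sign is inverted so 1 always means "promotes inclusion"
INVERTED_FEATURES = ("silencer", "mean_dg")


def _normalize_column(values: np.ndarray, invert: bool) -> np.ndarray:
    """Clip non-zero values at their 5th/95th percentiles, scale by the
    max absolute value, optionally invert, and map onto [0, 1] around
    0.5 (exact zeros stay at 0.5)."""
    v = np.asarray(values, float).copy()
    nz = v != 0
    if not nz.any():
        return np.full(len(v), 0.5)
    lo, hi = np.percentile(v[nz], [5, 95])
    v[nz] = np.clip(v[nz], lo, hi)
    peak = np.abs(v).max()
    if peak > 0:
        v = v / peak
    if invert:
        v = -v
    return 0.5 + 0.5 * v


def normalize_and_categorize_features(panel: pd.DataFrame,
                                      wt_mean_dg: float = 0.0
                                      ) -> pd.DataFrame:
    """Normalized feature heatmap table with support categories.

    All features are treated as changes against wild type; the motif
    deltas already are, and the ensemble unfolding cost is centred by
    subtracting ``wt_mean_dg`` (the wild-type ensemble mean).

    For each mutation the four heatmap features are scaled to [0, 1]
    with 0.5 = no change and 1 = promotes inclusion (silencer and mean
    unfolding cost are inverted).  Rows are ordered by hierarchical
    clustering (average linkage, Euclidean): first on the changed/
    unchanged flags (six clusters), then within each cluster on the
    normalized values.  The support category records which feature
    groups agree in direction with the observed PSI (strictly above or
    below 0.5): ``both``, ``SRE``, ``structure`` or ``neither``.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    out = pd.DataFrame({"id": panel["id"].to_numpy()})
    flags = {}
    for feat in HEATMAP_FEATURES:
        raw = panel[feat].to_numpy(float)
        if feat == "mean_dg":
            raw = raw - wt_mean_dg
        out[f"norm_{feat}"] = _normalize_column(
            raw, invert=feat in INVERTED_FEATURES)
        flags[feat] = (raw != 0).astype(int)
        out[f"changed_{feat}"] = flags[feat]
    out["psi"] = panel["psi"].to_numpy(float)

    def side(x):
        return np.where(x > 0.5, 1, np.where(x < 0.5, -1, 0))

    psi_side = side(out["psi"].to_numpy())
    struct_side = side(out["norm_mean_dg"].to_numpy())
    sre_sides = np.stack([side(out[f"norm_{f}"].to_numpy())
                          for f in ("delta_ss", "enhancer", "silencer")])
    struct_support = (struct_side == psi_side) & (psi_side != 0)
    sre_support = ((sre_sides == psi_side[None, :])
                   & (psi_side[None, :] != 0)).any(axis=0)
    cat = np.where(struct_support & sre_support, "both",
                   np.where(sre_support, "SRE",
                            np.where(struct_support, "structure",
                                     "neither")))
    out["support"] = cat

    # two-stage hierarchical ordering
    flag_mat = np.column_stack(list(flags.values()))
    norm_mat = out[[f"norm_{f}" for f in HEATMAP_FEATURES]].to_numpy()
    n = len(out)
    if n >= 3:
        coarse = fcluster(linkage(flag_mat, method="average",
                                  metric="euclidean"),
                          t=min(6, n), criterion="maxclust")
        order = []
        for c in np.unique(coarse):
            idx = np.flatnonzero(coarse == c)
            if len(idx) > 2:
                sub = linkage(norm_mat[idx], method="average",
                              metric="euclidean")
                from scipy.cluster.hierarchy import leaves_list
                idx = idx[leaves_list(sub)]
            order.extend(idx.tolist())
        out = out.iloc[order].reset_index(drop=True)
        out["cluster"] = coarse[order]
    else:
        out["cluster"] = 1
    return out
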