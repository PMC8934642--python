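"""Kinetic clustering of modelled time profiles.

Two clustering routes are provided.  The *pattern* route labels each feature
by the sign pattern of the consecutive differences of its fitted profile
(one symbol per interval in {-, 0, +}), so features rising then falling land
together regardless of magnitude.  The *block-PLS* route computes successive
latent components maximizing the summed covariance between each omics
block's score and a consensus score; each feature joins the cluster indexed
by (component of its largest absolute loading, sign of that loading), giving
at most 2 * ncomp clusters.  Cluster count is selected by maximizing the
average silhouette coefficient under the correlation distance
d(i, j) = 1 - r(i, j), so profiles cluster by shape rather than magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .profiles import ModeledProfileSet

#: Width of the zero band for pattern symbols, as a fraction of profile range.
DEFAULT_ZERO_BAND = 0.01


class ClusteringError(ValueError):
    pass


@dataclass
class KineticClustering:
    """Feature -> kinetic cluster assignment with selection metadata."""

    labels: pd.Series  # feature id -> integer cluster (1-based)
    k: int
    method: str  # "pattern" | "block_pls"
    silhouette: Optional[float] = None
    loadings: Optional[pd.DataFrame] = None  # features x components
    feature_block: Optional[pd.Series] = None
    patterns: Optional[pd.Series] = None
    cluster_meta: dict = field(default_factory=dict)
    signature: Optional[dict] = None  # cluster -> retained feature ids

    def members(self, cluster: int) -> list:
        return sorted(self.labels.index[self.labels == cluster])

    def clusters(self) -> list:
        return sorted(set(self.labels))


# -- pattern clustering -------------------------------------------------------


def pattern_cluster(
    mset: ModeledProfileSet, zero_band: float = DEFAULT_ZERO_BAND
) -> KineticClustering:
    """Cluster by the sign pattern of consecutive fitted differences.

    A difference whose magnitude is below ``zero_band`` times the profile's
    range maps to the symbol ``0``; this makes labels invariant under
    positive affine transforms of a profile.
    """
    fitted = mset.fitted.loc[mset.kept_ids()]
    if fitted.shape[1] < 2:
        raise ClusteringError("need >=2 grid points for pattern clustering")
    patterns = {}
    for feat, row in fitted.iterrows():
        prof = row.to_numpy(dtype=float)
        eps = zero_band * (prof.max() - prof.min())
        symbols = []
        for d in np.diff(prof):
            symbols.append("+" if d > eps else ("-" if d < -eps else "0"))
        patterns[feat] = "".join(symbols)
    pat = pd.Series(patterns).loc[fitted.index]
    distinct = sorted(set(pat))
    label_of = {p: i + 1 for i, p in enumerate(distinct)}
    labels = pat.map(label_of)
    return KineticClustering(
        labels=labels,
        k=len(distinct),
        method="pattern",
        patterns=pat,
        cluster_meta={label_of[p]: {"pattern": p} for p in distinct},
    )


# -- multi-block PLS ----------------------------------------------------------


def _consensus_component(Xs, max_iter, tol, comp_index):
    """One consensus-score alternating-least-squares step across blocks."""
    # One alternating step is t <- sum_b X_b (X_b' t), normalized: block
    # weights w_b = X_b' t, block scores t_b = X_b w_b, consensus score the
    # normalized sum -- maximizing sum_b cov(t_b, t)^2.  The composite map is
    # applied through the (small) time x time cross-product matrix.
    M = np.zeros((Xs[0].shape[0], Xs[0].shape[0]))
    for X in Xs:
        M += X @ X.T
    t = M.sum(axis=0)
    nt0 = np.linalg.norm(t)
    t = t / nt0 if nt0 > 0 else np.full(M.shape[0], 1.0 / np.sqrt(M.shape[0]))
    for _ in range(max_iter):
        t_new = M @ t
        nt = np.linalg.norm(t_new)
        if nt == 0:
            raise ClusteringError(f"component {comp_index}: degenerate consensus score")
        t_new = t_new / nt
        if np.linalg.norm(t_new - t) < tol or np.linalg.norm(t_new + t) < tol:
            t = t_new
            break
        t = t_new
    else:
        raise ClusteringError(f"component {comp_index} did not converge in {max_iter} iterations")
    # fix the sign deterministically: largest-|entry| coordinate positive
    pivot = int(np.argmax(np.abs(t)))
    if t[pivot] < 0:
        t = -t
    return t


def block_pls_cluster(
    blocks: Sequence[pd.DataFrame],
    ncomp: int,
    max_iter: int = 20_000,
    tol: float = 1e-10,
    block_names: Optional[Sequence[str]] = None,
) -> KineticClustering:
    """Cluster features of several blocks by multi-block PLS loadings.

    ``blocks`` are scaled profile matrices (features x shared time grid).
    ``ncomp`` successive latent components are extracted by an alternating
    algorithm maximizing the summed covariance between each block's score
    and a consensus score, with deflation between components.  A feature's
    cluster is (component of max |loading|, sign of that loading).
    """
    if ncomp < 1:
        raise ClusteringError("ncomp must be >= 1")
    names = list(block_names) if block_names is not None else [f"block{i}" for i in range(len(blocks))]
    feats, blk = [], []
    for name, b in zip(names, blocks):
        feats.extend(b.index)
        blk.extend([name] * len(b.index))
    if len(set(feats)) != len(feats):
        raise ClusteringError("duplicate feature ids across blocks")
    Xs = [b.to_numpy(dtype=float).T for b in blocks]  # time x features
    n_time = Xs[0].shape[0]
    if any(X.shape[0] != n_time for X in Xs):
        raise ClusteringError("blocks must share the time grid")
    loadings = []
    for c in range(ncomp):
        t = _consensus_component(Xs, max_iter, tol, c + 1)
        comp_load = np.concatenate([X.T @ t for X in Xs])
        loadings.append(comp_load)
        Xs = [X - np.outer(t, t @ X) for X in Xs]
    L = np.column_stack(loadings)  # features x ncomp
    load_df = pd.DataFrame(L, index=feats, columns=[f"comp{c+1}" for c in range(ncomp)])
    labels, meta = _assign_from_loadings(load_df)
    return KineticClustering(
        labels=labels,
        k=len(set(labels)),
        method="block_pls",
        loadings=load_df,
        feature_block=pd.Series(blk, index=feats),
        cluster_meta=meta,
    )


def _assign_from_loadings(load_df: pd.DataFrame):
    """Map each feature to cluster (argmax |loading| component, loading sign).

    Clusters are numbered 1..k in (component, +/-) order; only realized
    combinations get a number.
    """
    L = load_df.to_numpy(dtype=float)
    comp = np.argmax(np.abs(L), axis=1)
    sign = np.sign(L[np.arange(len(L)), comp])
    sign[sign == 0] = 1.0
    keys = list(zip(comp.tolist(), sign.tolist()))
    realized = sorted(set(keys), key=lambda cs: (cs[0], -cs[1]))
    label_of = {cs: i + 1 for i, cs in enumerate(realized)}
    labels = pd.Series([label_of[k] for k in keys], index=load_df.index)
    meta = {label_of[(c, s)]: {"component": c + 1, "sign": int(s)} for c, s in realized}
    return labels, meta


# -- silhouette ---------------------------------------------------------------


def correlation_distance(profiles: pd.DataFrame) -> np.ndarray:
    """Pairwise d(i, j) = 1 - Pearson correlation of profile rows."""
    X = profiles.to_numpy(dtype=float)
    D = 1.0 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def silhouette_score(
    profiles: pd.DataFrame, labels: Union[pd.Series, Sequence[int]]
) -> float:
    """Average silhouette s(i) = (b - a) / max(a, b) under correlation distance.

    Features in singleton clusters contribute s(i) = 0.  Raises if all
    features share one cluster.
    """
    if isinstance(labels, pd.Series):
        labels = labels.loc[profiles.index]
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if len(uniq) < 2:
        raise ClusteringError("silhouette needs >=2 clusters")
    D = correlation_distance(profiles)
    n = len(lab)
    s = np.zeros(n)
    masks = {c: lab == c for c in uniq}
    for i in range(n):
        own = masks[lab[i]]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != lab[i])
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(s.mean())


# -- model selection and sparse signatures ------------------------------------


def choose_k(
    blocks: Sequence[pd.DataFrame],
    ncomp_grid: Sequence[int],
    block_names: Optional[Sequence[str]] = None,
    **pls_kwargs,
) -> KineticClustering:
    """Run block-PLS over candidate component counts and keep the clustering
    with the highest average silhouette; ties break toward fewer clusters."""
    if not ncomp_grid:
        raise ClusteringError("empty ncomp grid")
    concat = pd.concat(list(blocks), axis=0)
    best = None
    for ncomp in sorted(set(int(c) for c in ncomp_grid)):
        clustering = block_pls_cluster(blocks, ncomp, block_names=block_names, **pls_kwargs)
        if clustering.k < 2:
            sil = -np.inf
        else:
            sil = silhouette_score(concat, clustering.labels)
        clustering.silhouette = None if sil == -np.inf else float(sil)
        if best is None:
            best = clustering
        elif sil > (best.silhouette if best.silhouette is not None else -np.inf) + 1e-12:
            best = clustering
        elif (
            best.silhouette is not None
            and abs(sil - best.silhouette) <= 1e-12
            and clustering.k < best.k
        ):
            best = clustering
    if best.silhouette is None and best.k >= 2:
        best.silhouette = float(silhouette_score(concat, best.labels))
    return best


def sparse_signature(
    clustering: KineticClustering, keepX: Union[int, Sequence[int]]
) -> KineticClustering:
    """Soft-threshold loadings to a per-block, per-component ``keepX`` and
    recompute assignments; the signature is the retained features per cluster.

    ``keepX`` may be a single count applied to every component or one count
    per component.
    """
    if clustering.loadings is None or clustering.feature_block is None:
        raise ClusteringError("sparse signatures require a block-PLS clustering")
    L = clustering.loadings.copy()
    ncomp = L.shape[1]
    if np.isscalar(keepX):
        keep_per_comp = [int(keepX)] * ncomp
    else:
        keep_per_comp = [int(k) for k in keepX]
        if len(keep_per_comp) != ncomp:
            raise ClusteringError(f"keepX needs 1 or {ncomp} entries")
    blocks = clustering.feature_block
    for ci, col in enumerate(L.columns):
        for block in sorted(set(blocks)):
            idx = blocks.index[blocks == block]
            vals = L.loc[idx, col].abs().sort_values(ascending=False)
            cutoff_rank = min(keep_per_comp[ci], len(vals))
            dropped = vals.index[cutoff_rank:]
            L.loc[dropped, col] = 0.0
    retained = L.index[(L != 0).any(axis=1)]
    # reassign retained features on the thresholded loadings, mapping each
    # (component, sign) combination back to the original cluster numbering
    combo_of_cluster = {
        c: (m["component"] - 1, float(m["sign"])) for c, m in clustering.cluster_meta.items()
    }
    cluster_of_combo = {combo: c for c, combo in combo_of_cluster.items()}
    Lr = L.loc[retained].to_numpy(dtype=float)
    comp = np.argmax(np.abs(Lr), axis=1)
    sign = np.sign(Lr[np.arange(len(Lr)), comp])
    sign[sign == 0] = 1.0
    next_id = (max(cluster_of_combo.values()) if cluster_of_combo else 0) + 1
    signature: dict = {}
    for feat, c, s in zip(retained, comp.tolist(), sign.tolist()):
        combo = (c, s)
        if combo not in cluster_of_combo:
            cluster_of_combo[combo] = next_id
            next_id += 1
        signature.setdefault(int(cluster_of_combo[combo]), []).append(feat)
    signature = {c: sorted(members) for c, members in signature.items()}
    out = KineticClustering(
        labels=clustering.labels,
        k=clustering.k,
        method=clustering.method,
        silhouette=clustering.silhouette,
        loadings=clustering.loadings,
        feature_block=clustering.feature_block,
        patterns=clustering.patterns,
        cluster_meta=clustering.cluster_meta,
        signature=signature,
    )
    return out
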