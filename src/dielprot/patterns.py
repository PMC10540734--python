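"""Temporal pattern analysis: PCA, hierarchical clustering with a dynamic
hybrid tree cut, peak-phase distributions, protein/phospho-motif pairing,
and generic category enrichment (Fisher exact on partitions, KS on PCA
loadings)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .rhythm import bh_adjust


@dataclass
class PCAResult:
    scores: pd.DataFrame      # features x PCs
    loadings: pd.DataFrame    # ZT x PCs
    variance_fraction: pd.Series

    def reconstruct(self) -> pd.DataFrame:
        """scores @ loadings.T reproduces the centred matrix."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(rec, index=self.scores.index, columns=self.loadings.index)


def pca_profiles(mean_profiles: pd.DataFrame) -> PCAResult:
    """SVD-based PCA of mean temporal profiles.

    Rows (features) are observations, ZT columns are variables; profiles
    are zero-centred per feature.  The sign of each component is fixed so
    that its largest-magnitude loading is positive, making the output
    deterministic.
    """
    if mean_profiles.shape[1] < 3:
        raise ValueError("PCA needs >=3 timepoint columns")
    x = mean_profiles.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)  # per-feature centering
    if np.allclose(x, 0):
        raise ValueError("constant profiles: no variance to decompose")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign convention
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2
    pcs = [f"PC{i+1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=mean_profiles.index, columns=pcs),
        loadings=pd.DataFrame(vt.T, index=mean_profiles.columns, columns=pcs),
        variance_fraction=pd.Series(var / var.sum(), index=pcs),
    )


def _branch_height(node) -> float:
    return 0.0 if node.is_leaf() else node.dist


def _hybrid_branches(node, cut_height: float, min_size: int, gap: float) -> list[list[int]]:
    """Branch-wise evaluation of the dynamic hybrid cut.

    Merges above ``cut_height`` are always split.  Below it, a node is
    split only where the joining height stands clear of both subbranches'
    internal heights (max child height <= (1 - gap) * node height), the
    signature of two genuinely separated branches rather than smooth
    within-cluster agglomeration.  When a split is indicated, subbranches
    smaller than ``min_size`` cannot form clusters of their own and are
    returned as singleton groups to be marked unassigned later.
    """
    if node.is_leaf():
        return [[node.id]]
    forced = node.dist > cut_height
    inner = max(_branch_height(node.left), _branch_height(node.right))
    indicated = inner <= (1.0 - gap) * node.dist
    if not (forced or indicated):
        return [node.pre_order(lambda leaf: leaf.id)]
    return _hybrid_branches(node.left, cut_height, min_size, gap) + _hybrid_branches(
        node.right, cut_height, min_size, gap
    )


def cluster_profiles(
    mean_profiles: pd.DataFrame,
    cut_height: float = 100.0,
    min_cluster_size: int = 20,
    split_gap: float = 0.5,
    label_prefix: str = "P",
) -> pd.Series:
    """Hierarchical clustering with a dynamic hybrid tree cut.

    Profiles are z-scaled per feature; the distance is 1 - Pearson r and
    linkage is Ward.  Following the hybrid tree-cut idea, a static cut at
    ``cut_height`` (raw dendrogram height scale; a value above the tree
    height leaves the whole tree eligible) is combined with branch-wise
    evaluation: a join is split where its height stands well clear
    (``split_gap`` fraction) of the internal heights of both subbranches,
    and resulting branches smaller than ``min_cluster_size`` are left
    ``unassigned`` (no PAM-style reassignment).  Surviving clusters are
    labelled by decreasing size (P1, P2, ...).
    """
    n = len(mean_profiles)
    if n < min_cluster_size:
        import warnings

        warnings.warn("fewer features than min_cluster_size; everything unassigned")
        return pd.Series("unassigned", index=mean_profiles.index, name="cluster")
    x = mean_profiles.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    d = pdist(z, metric="correlation")  # 1 - Pearson r
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    link = hierarchy.linkage(d, method="ward")
    tree = hierarchy.to_tree(link)
    branches = _hybrid_branches(tree, cut_height, min_cluster_size, split_gap)
    clusters = [b for b in branches if len(b) >= min_cluster_size]
    clusters.sort(key=lambda b: (-len(b), min(b)))
    out = pd.Series("unassigned", index=mean_profiles.index, name="cluster")
    for i, members in enumerate(clusters):
        out.iloc[sorted(members)] = f"{label_prefix}{i+1}"
    return out


def peak_phase_distribution(
    results: pd.DataFrame, restrict_rhythmic: bool = True
) -> pd.DataFrame:
    """Histogram of peak ZTs over the sampled timepoints.

    ``results`` is a rhythm-results frame with ``peak_zt`` and ``rhythmic``
    columns.  Returns a frame with counts and fractions per ZT; fractions
    sum to 1.
    """
    f = results
    if restrict_rhythmic:
        f = f[f["rhythmic"]]
    if len(f) == 0:
        raise ValueError("no rhythmic features to tabulate")
    counts = f["peak_zt"].value_counts().sort_index()
    out = pd.DataFrame({"count": counts})
    out["fraction"] = out["count"] / out["count"].sum()
    out.index.name = "peak_zt"
    return out


def pair_protein_phospho(
    protein_results: pd.DataFrame, motif_results: pd.DataFrame, motif_locus: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Pair each phospho-motif's peak time with its cognate protein's.

    Joins on protein locus (protein results indexed by locus, motif results
    by motif id with ``motif_locus`` giving motif -> locus).  Returns the
    per-pair table and the summary fraction of motifs peaking at a
    different timepoint from their protein.
    """
    rows = []
    for mid, locus in motif_locus.items():
        if mid not in motif_results.index or locus not in protein_results.index:
            continue
        pp = float(protein_results.loc[locus, "peak_zt"])
        mp = float(motif_results.loc[mid, "peak_zt"])
        rows.append({"motif_id": mid, "locus": locus, "protein_peak_zt": pp,
                     "motif_peak_zt": mp, "differs": pp != mp})
    if not rows:
        raise ValueError("no protein/motif pairs share a locus")
    pairs = pd.DataFrame(rows).set_index("motif_id")
    return pairs, float(pairs["differs"].mean())


def category_enrichment(
    members: set,
    background: set,
    annotation: dict[str, set],
    mode: str = "fisher",
    loadings: pd.Series | None = None,
) -> pd.DataFrame:
    """Flat term-to-feature category enrichment.

    ``fisher`` mode tests the 2x2 partition (in members x in term) of the
    background with a two-sided Fisher exact test.  ``ks_on_loadings`` mode
    compares |loading| of term vs. non-term features with a two-sample KS
    test (terms with stronger contributions to a principal component rank
    first).  BH adjustment is applied across terms.
    """
    if not set(members) <= set(background):
        raise ValueError("members must be a subset of background")
    rows = []
    for term, feats in sorted(annotation.items()):
        feats = set(feats) & set(background)
        if not feats:
            import warnings

            warnings.warn(f"term {term!r} has no background members; skipped")
            continue
        if mode == "fisher":
            a = len(feats & set(members))
            b = len(set(members)) - a
            c = len(feats) - a
            d = len(set(background)) - len(set(members)) - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            stat = a
        elif mode == "ks_on_loadings":
            if loadings is None:
                raise ValueError("ks_on_loadings mode needs per-feature loadings")
            in_term = loadings.loc[loadings.index.intersection(feats)].abs()
            out_term = loadings.loc[loadings.index.difference(feats)].abs()
            if len(in_term) == 0 or len(out_term) == 0:
                continue
            stat, p = stats.ks_2samp(in_term, out_term)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"term": term, "stat": float(stat), "p": float(p)})
    out = pd.DataFrame(rows).set_index("term")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values("p")
    return out
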