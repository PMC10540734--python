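"""Normalization, variance-stabilizing transform, outlier replicates, rollup.

Order of operations: mean-normalize sample columns, roll peptides up to
proteins on the normalized-untransformed scale, arcsinh-transform before
any statistics that assume normality, and screen replicates against the
per-timepoint median profile (Pearson r^2 < 0.8 flags a degraded run).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import QuantTable, SampleKey


def mean_normalize(table: QuantTable) -> QuantTable:
    """Scale every sample column so all column means equal the grand mean.

    The scale factor for a column is (mean of all sample means)/(its own
    mean), computed over available (non-missing) values.
    """
    means = table.data.mean(axis=0, skipna=True)
    if (means == 0).any():
        bad = means.index[means == 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")
    grand = means.mean()
    factors = grand / means
    out = table.copy(data=table.data * factors, normalized=True)
    out.scale_factors = factors  # type: ignore[attr-defined]
    return out


def arcsinh_transform(table: QuantTable) -> QuantTable:
    """Apply x -> ln(x + sqrt(x^2+1)).  Guarded against double application."""
    if table.transformed:
        raise ValueError("table is already arcsinh-transformed")
    return table.copy(data=np.arcsinh(table.data), transformed=True)


@dataclass
class OutlierReport:
    correlations: pd.Series  # Pearson r of each replicate vs. timepoint median
    flagged: list[SampleKey]
    threshold: float
    pca_scores: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "threshold_r2": self.threshold,
            "flagged": [k.label for k in self.flagged],
            "r": {k: float(v) for k, v in self.correlations.items()},
        }


def detect_outlier_replicates(
    table: QuantTable, r2_threshold: float = 0.8, with_pca: bool = True
) -> OutlierReport:
    """Flag replicates poorly correlated with their timepoint's median profile.

    For each sample, Pearson r is computed between its feature vector and the
    per-feature median over all replicates of the same (condition, zt);
    features missing in any replicate of that timepoint are skipped for that
    timepoint.  Samples with r^2 below ``r2_threshold`` are flagged.  A PCA
    of replicate profiles accompanies the report for visual QC.
    """
    groups = table.timepoint_columns()
    if min(len(c) for c in groups.values()) < 3:
        raise ValueError("outlier screening needs >=3 replicates per timepoint")
    corr = {}
    flagged = []
    for (cond, zt), cols in sorted(groups.items()):
        block = table.data[cols].dropna(axis=0, how="any")
        med = block.median(axis=1)
        if float(med.std()) == 0:
            raise ValueError(f"median profile at ({cond}, ZT{zt:g}) is constant")
        for c in cols:
            r = float(np.corrcoef(block[c], med)[0, 1])
            corr[c] = r
            if r * r < r2_threshold:
                flagged.append(SampleKey.parse(c))
    pca_scores = None
    if with_pca:
        filled = table.data.dropna(axis=0, how="any")
        x = filled.to_numpy(dtype=float).T  # samples x features
        x = x - x.mean(axis=0, keepdims=True)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        k = min(3, len(s))
        pca_scores = pd.DataFrame(
            u[:, :k] * s[:k], index=filled.columns, columns=[f"PC{i+1}" for i in range(k)]
        )
    return OutlierReport(
        correlations=pd.Series(corr), flagged=flagged, threshold=r2_threshold, pca_scores=pca_scores
    )


@dataclass
class RollupReport:
    n_proteins: int = 0
    dropped: dict[str, int] = field(default_factory=dict)  # locus -> n peptides
    n_shared_excluded: int = 0


def rollup_protein(
    table: QuantTable,
    mapping: pd.Series | dict | None = None,
    min_peptides: int = 2,
) -> tuple[QuantTable, RollupReport]:
    """Sum unique peptides per protein locus; drop under-supported proteins.

    ``mapping`` maps peptide feature id -> locus (defaults to the table's own
    locus column).  Peptides shared between loci (mapping value containing
    ';') are excluded from every protein.  Proteins with fewer than
    ``min_peptides`` quantifying peptides are dropped and reported.
    """
    if mapping is None:
        mapping = table.locus
    if mapping is None or len(mapping) == 0:
        raise ValueError("empty peptide->locus mapping")
    mapping = pd.Series(mapping).reindex(table.feature_ids)
    shared = mapping.astype(str).str.contains(";")
    usable = table.data.loc[~shared & mapping.notna()]
    loci = mapping.loc[usable.index]
    counts = loci.value_counts()
    keep = counts.index[counts >= min_peptides]
    report = RollupReport(
        n_proteins=len(keep),
        dropped={loc: int(counts[loc]) for loc in counts.index if counts[loc] < min_peptides},
        n_shared_excluded=int(shared.sum()),
    )
    summed = usable.groupby(loci.loc[usable.index]).sum(min_count=1)
    summed = summed.loc[keep.sort_values()]
    summed.index.name = "locus"
    return QuantTable(summed, normalized=table.normalized), report
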