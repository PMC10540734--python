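"""Diel rhythmicity and equivalence statistics.

A feature is scored rhythmic by ordinary least squares of its
arcsinh-transformed replicate observations on a cubic polynomial in
Zeitgeber time, value ~ 1 + t + t^2 + t^3.  The cubic can represent one
peak and one trough inside a single 24 h window, which is the expected
shape of a diel profile sampled over one cycle; the F-test compares the
cubic against the intercept-only model (df 3, n-4).  P-values are
Benjamini--Hochberg adjusted across features, and a feature is called
rhythmic when q < fdr AND its peak/trough fold change (computed on the
normalized-untransformed scale) exceeds the fold gate.

Statistical *equivalence* (evidence for absence of change) is assessed by
exhaustive pairwise two one-sided tests (TOST) over all timepoint pairs:
the reported p is the largest pair p, so equivalence requires every pair of
timepoints to differ by less than the margin epsilon on the transformed
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import QuantTable
from .preprocess import arcsinh_transform

__all__ = [
    "polynomial_rhythm_test",
    "bh_adjust",
    "assign_peak_trough",
    "tost_equivalence",
    "DielRhythmModel",
    "DielRhythmResults",
    "EquivalenceResults",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini--Hochberg step-up adjusted p-values (monotonicity enforced,
    stable under input reordering)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def polynomial_rhythm_test(
    values, times, null: str = "intercept"
) -> tuple[float, np.ndarray]:
    """Cubic-polynomial F-test for one feature.

    Parameters
    ----------
    values, times
        Replicate observations (transformed scale) and their numeric ZT
        hours, flattened over replicates.
    null
        Reference model for the F-test: ``intercept`` (default) or
        ``linear``.

    Returns ``(p, coefficients)`` with coefficients in increasing order
    (intercept, t, t^2, t^3).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    mask = np.isfinite(y)
    y, t = y[mask], t[mask]
    n = y.size
    if n < 5:
        raise ValueError(f"need >=5 observations for a cubic fit, got {n}")
    X = np.vander(t, 4, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if null == "intercept":
        rss0 = float(((y - y.mean()) ** 2).sum())
        df_num = 3
    elif null == "linear":
        X0 = np.vander(t, 2, increasing=True)
        b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
        r0 = y - X0 @ b0
        rss0 = float(r0 @ r0)
        df_num = 2
    else:
        raise ValueError(f"unknown null model {null!r}")
    if rss0 <= 0:
        return 1.0, beta  # zero variance: nothing to explain
    df_den = n - 4
    if rss <= 0:
        return 0.0, beta  # exact fit
    f = ((rss0 - rss) / df_num) / (rss / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return p, beta


def _rhythm_test_matrix(Y: np.ndarray, t: np.ndarray, null: str = "intercept"):
    """Vectorized cubic F-test for a (n_obs x n_features) matrix with a
    shared time covariate and no missing values."""
    X = np.vander(t, 4, increasing=True)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    if null == "intercept":
        rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        df_num = 3
    else:
        X0 = np.vander(t, 2, increasing=True)
        b0, _, _, _ = np.linalg.lstsq(X0, Y, rcond=None)
        rss0 = ((Y - X0 @ b0) ** 2).sum(axis=0)
        df_num = 2
    df_den = len(t) - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss) / df_num) / (rss / df_den)
    p = stats.f.sf(f, df_num, df_den)
    p = np.where(rss0 <= 0, 1.0, np.where(rss <= 0, 0.0, p))
    return np.asarray(p, dtype=float), beta


def assign_peak_trough(means: pd.Series) -> tuple[float, float, float, str]:
    """Peak/trough ZT and fold from within-timepoint means.

    The peak (trough) time is the timepoint with the maximum (minimum) mean;
    ties break toward the earlier ZT.  Fold = max mean / min mean on the
    normalized-untransformed scale.  Returns ``(peak_zt, trough_zt, fold,
    flag)`` where flag is '' / 'flat' / 'zero_min'.
    """
    m = means.dropna()
    if m.empty:
        raise ValueError("no timepoint means available")
    m = m.sort_index()
    vals = m.to_numpy(dtype=float)
    if np.allclose(vals, vals[0]):
        zt0 = float(m.index[0])
        return zt0, zt0, 1.0, "flat"
    peak = float(m.index[int(np.argmax(vals))])
    trough = float(m.index[int(np.argmin(vals))])
    vmin = vals.min()
    if vmin == 0:
        return peak, trough, float("inf"), "zero_min"
    return peak, trough, float(vals.max() / vmin), ""


def tost_equivalence(
    groups: list[np.ndarray], epsilon: float = 0.3, welch: bool = False
) -> float:
    """Exhaustive pairwise TOST over timepoint groups.

    For every pair of timepoints, two one-sided t-tests assess whether the
    mean difference lies within (-epsilon, +epsilon); the pair p is the
    larger of the two one-sided p-values, and the returned p is the maximum
    over all pairs (the hardest pair decides).  Pooled-variance t by
    default; Welch behind a flag.
    """
    if epsilon <= 0:
        raise ValueError("equivalence margin must be positive")
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("TOST needs >=2 replicates per timepoint")
    worst = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            na, nb = len(a), len(b)
            d = a.mean() - b.mean()
            if welch:
                va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
                se = np.sqrt(va + vb)
                df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1)) if se > 0 else na + nb - 2
            else:
                sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
                se = np.sqrt(sp2 * (1 / na + 1 / nb))
                df = na + nb - 2
            if se == 0:
                pair_p = 0.0 if abs(d) < epsilon else 1.0
            else:
                p_lower = float(stats.t.sf((d + epsilon) / se, df))  # H0: d <= -eps
                p_upper = float(stats.t.cdf((d - epsilon) / se, df))  # H0: d >= +eps
                pair_p = max(p_lower, p_upper)
            worst = max(worst, pair_p)
    return worst


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass
class EquivalenceResults:
    """Per-feature equivalence calls from exhaustive pairwise TOST."""

    frame: pd.DataFrame  # columns: p_equiv, equivalent
    epsilon: float
    alpha: float

    def summary(self) -> str:
        n = len(self.frame)
        k = int(self.frame["equivalent"].sum())
        return (
            f"Equivalence (pairwise TOST, eps={self.epsilon}, alpha={self.alpha})\n"
            f"  features tested : {n}\n"
            f"  equivalent      : {k} ({100 * k / max(n, 1):.1f}%)\n"
        )


class DielRhythmResults:
    """Estimates and calls from :meth:`DielRhythmModel.fit`.

    Attributes
    ----------
    frame
        Per-feature table with columns ``p``, ``q``, ``fold``, ``peak_zt``,
        ``trough_zt``, ``rhythmic``, ``flag`` and the cubic coefficients
        ``b0..b3``.
    """

    def __init__(self, frame: pd.DataFrame, model: "DielRhythmModel"):
        self.frame = frame
        self.model = model

    @property
    def rhythmic_ids(self) -> pd.Index:
        return self.frame.index[self.frame["rhythmic"]]

    @property
    def n_rhythmic(self) -> int:
        return int(self.frame["rhythmic"].sum())

    def summary(self) -> str:
        f = self.frame
        n = len(f)
        lines = [
            "Diel rhythm analysis (cubic polynomial OLS, F-test vs "
            f"{self.model.null} null)",
            f"  features tested     : {n}",
            f"  FDR threshold (BH q): {self.model.fdr}",
            f"  fold-change gate    : >{self.model.fold_gate}",
            f"  rhythmic            : {self.n_rhythmic} ({100 * self.n_rhythmic / max(n, 1):.1f}%)",
        ]
        if self.n_rhythmic:
            peaks = f.loc[f["rhythmic"], "peak_zt"].value_counts().sort_index()
            dist = ", ".join(f"ZT{int(z)}: {c}" for z, c in peaks.items())
            lines.append(f"  peak distribution   : {dist}")
        return "\n".join(lines) + "\n"

    def peak_phase_distribution(self) -> pd.DataFrame:
        from .patterns import peak_phase_distribution

        return peak_phase_distribution(self.frame)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


class DielRhythmModel:
    """Per-feature diel rhythmicity model for a replicated ZT time course.

    Parameters
    ----------
    table
        Normalized :class:`QuantTable`.  P-values are computed on the
        arcsinh-transformed scale (applied internally unless the table is
        already transformed); fold changes use the normalized-untransformed
        means when available.
    fdr, fold_gate
        BH q-value threshold and peak/trough fold gate that jointly define
        the ``rhythmic`` call.
    null
        Reference model for the F-test (``intercept`` or ``linear``).
    """

    def __init__(
        self,
        table: QuantTable,
        fdr: float = 0.05,
        fold_gate: float = 1.5,
        null: str = "intercept",
    ):
        self.fdr = fdr
        self.fold_gate = fold_gate
        self.null = null
        if table.transformed:
            self.transformed = table
            self.raw = None  # folds will fall back to transformed means
        else:
            self.raw = table
            self.transformed = arcsinh_transform(table)
        keys = self.transformed.sample_keys
        self.times = np.array([k.zt for k in keys], dtype=float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "DielRhythmModel":
        """Build from a plain DataFrame (features x `<cond>_ZT<zt>_<rep>` columns)."""
        return cls(QuantTable(data), **kwargs)

    def fit(self) -> DielRhythmResults:
        tdata = self.transformed.data
        complete = ~tdata.isna().any(axis=1).to_numpy()
        p = np.full(len(tdata), np.nan)
        betas = np.full((len(tdata), 4), np.nan)
        if complete.any():
            Y = tdata.to_numpy(dtype=float)[complete].T  # obs x features
            p_c, beta_c = _rhythm_test_matrix(Y, self.times, null=self.null)
            p[complete] = p_c
            betas[complete] = beta_c.T
        # features with missing cells: per-feature fit on available obs
        for i in np.flatnonzero(~complete):
            row = tdata.iloc[i].to_numpy(dtype=float)
            ok = np.isfinite(row)
            if ok.sum() >= 5:
                p[i], betas[i] = polynomial_rhythm_test(row[ok], self.times[ok], null=self.null)

        q = np.full_like(p, np.nan)
        tested = np.isfinite(p)
        if tested.any():
            q[tested] = bh_adjust(p[tested])

        fold_table = self.raw if self.raw is not None else self.transformed
        means = fold_table.timepoint_means()
        rows = []
        for fid in tdata.index:
            peak, trough, fold, flag = assign_peak_trough(means.loc[fid])
            rows.append((peak, trough, fold, flag))
        pt = pd.DataFrame(rows, columns=["peak_zt", "trough_zt", "fold", "flag"], index=tdata.index)

        frame = pd.DataFrame({"p": p, "q": q}, index=tdata.index).join(pt)
        frame["rhythmic"] = (frame["q"] < self.fdr) & (frame["fold"] > self.fold_gate)
        frame["rhythmic"] = frame["rhythmic"].fillna(False).astype(bool)
        for k in range(4):
            frame[f"b{k}"] = betas[:, k]
        frame.index.name = "feature_id"
        return DielRhythmResults(frame, self)

    def equivalence(
        self, epsilon: float = 0.3, alpha: float = 0.05, welch: bool = False
    ) -> EquivalenceResults:
        """Exhaustive pairwise TOST per feature on the transformed scale."""
        tdata = self.transformed.data
        groups_cols = [cols for _, cols in sorted(self.transformed.timepoint_columns().items())]
        recs = {}
        for fid in tdata.index:
            groups = [tdata.loc[fid, cols].to_numpy(dtype=float) for cols in groups_cols]
            try:
                p_eq = tost_equivalence(groups, epsilon=epsilon, welch=welch)
            except ValueError:
                p_eq = np.nan
            recs[fid] = p_eq
        frame = pd.DataFrame({"p_equiv": pd.Series(recs)})
        frame["equivalent"] = frame["p_equiv"] < alpha
        frame.index.name = "feature_id"
        return EquivalenceResults(frame, epsilon=epsilon, alpha=alpha)
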