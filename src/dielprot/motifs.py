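"""Position-specific phospho-motif enrichment (binomial sequence-logo
statistics) and phase-specific kinase-consensus enrichment.

Each phospho-site is represented by the 15-residue window (+-7) around the
phosphorylated residue, padded with ``_`` at protein termini.  For every
window position (excluding 0, the phospho-residue itself, which is
conditioned on rather than tested) and residue, over-/under-representation
in a foreground set relative to background per-position frequencies is
scored with exact binomial tails, displayed as signed -log10 p heights.
The Bonferroni significance line for 20 residues x 15 positions at alpha
0.05 is -log10(0.05/300) = 3.78.

Kinase-consensus classes are declarative window patterns: proline-directed
[pS/pT]P (CMGC family), the stricter CDK consensus [pS/pT]PXX[K/R],
acid-directed sites with D/E just C-terminal of the phospho-residue
(CK2-like), and hydrophobic residues at -5/+4 (SnRK/AMPK-like).  These
regex-style stand-ins approximate consensus sets that full kinase-target
predictors derive per site, and outputs are labelled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rhythm import bh_adjust

PAD = "_"
WINDOW_HALF = 7
WINDOW_LEN = 2 * WINDOW_HALF + 1
RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
HYDROPHOBIC = frozenset("AILMFV")
P_FLOOR = 1e-300


def significance_threshold(alpha: float = 0.05, n_tests: int = 20 * 15) -> float:
    """Bonferroni logo significance line, rounded to 2 decimals."""
    return round(-np.log10(alpha / n_tests), 2)


@dataclass(frozen=True)
class SiteWindow:
    """A +-7 residue window around one phospho-site (position 1-based)."""

    locus: str
    position: int
    window: str

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW_LEN:
            raise ValueError(f"window must have {WINDOW_LEN} residues, got {len(self.window)}")
        if self.window[WINDOW_HALF] not in "STY":
            raise ValueError(
                f"centre residue {self.window[WINDOW_HALF]!r} at {self.locus}:{self.position} "
                "is not S/T/Y"
            )

    def residue_at(self, offset: int) -> str:
        """Residue at window offset in [-7, +7]; ``_`` marks padding."""
        return self.window[offset + WINDOW_HALF]


def extract_windows(
    sites: Sequence[tuple[str, int]], sequences: dict[str, str]
) -> list[SiteWindow]:
    """Extract +-7 windows for (locus, 1-based position) phospho-sites."""
    out = []
    for locus, pos in sites:
        if locus not in sequences:
            raise KeyError(f"no sequence for locus {locus!r}")
        seq = sequences[locus]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} outside {locus} (length {len(seq)})")
        i = pos - 1
        left = seq[max(0, i - WINDOW_HALF): i]
        right = seq[i + 1: i + 1 + WINDOW_HALF]
        window = PAD * (WINDOW_HALF - len(left)) + left + seq[i] + right + PAD * (WINDOW_HALF - len(right))
        out.append(SiteWindow(locus=locus, position=pos, window=window))
    return out


def _position_counts(windows: Sequence[SiteWindow]):
    """Residue counts per offset, pads excluded.  Returns (counts, totals)
    where counts[offset][residue] and totals[offset] ignore pad characters."""
    counts: dict[int, dict[str, int]] = {}
    totals: dict[int, int] = {}
    offsets = [o for o in range(-WINDOW_HALF, WINDOW_HALF + 1) if o != 0]
    for off in offsets:
        c: dict[str, int] = {}
        tot = 0
        for w in windows:
            r = w.residue_at(off)
            if r == PAD:
                continue
            c[r] = c.get(r, 0) + 1
            tot += 1
        counts[off] = c
        totals[off] = tot
    return counts, totals


def binomial_tail_pvalues(k: int, n: int, p: float) -> tuple[float, float]:
    """Exact binomial tails: (P(X >= k), P(X <= k)) for X ~ Binomial(n, p)."""
    p_over = float(stats.binom.sf(k - 1, n, p))
    p_under = float(stats.binom.cdf(k, n, p))
    return p_over, p_under


@dataclass
class LogoResult:
    """Signed -log10 binomial heights per (offset, residue)."""

    frame: pd.DataFrame  # columns: offset, residue, k, n, p_bg, p_value, height, significant
    threshold: float

    def height_matrix(self) -> pd.DataFrame:
        return self.frame.pivot(index="residue", columns="offset", values="height")


def binomial_logo(
    foreground: Sequence[SiteWindow], background: Sequence[SiteWindow]
) -> LogoResult:
    """Position-specific residue enrichment of foreground windows against
    background per-position frequencies.

    For offset o and residue r: k = foreground windows with r at o, n =
    foreground windows with any real residue at o, p = background frequency
    of r at o.  Height is -log10 P(X >= k) when the foreground rate exceeds
    p (over-representation, drawn upward) and +log10 P(X <= k) otherwise
    (under-representation, drawn downward); p-values are floored at 1e-300
    so heights stay finite.
    """
    if not foreground:
        raise ValueError("empty foreground")
    fg_counts, fg_totals = _position_counts(foreground)
    bg_counts, bg_totals = _position_counts(background)
    thr = significance_threshold()
    rows = []
    for off in sorted(fg_counts):
        n = fg_totals[off]
        bg_n = bg_totals[off]
        for res in RESIDUES:
            k = fg_counts[off].get(res, 0)
            if n == 0 or bg_n == 0:
                rows.append({"offset": off, "residue": res, "k": k, "n": n,
                             "p_bg": np.nan, "p_value": np.nan, "height": 0.0,
                             "significant": False, "flag": "no_data"})
                continue
            p_bg = bg_counts[off].get(res, 0) / bg_n
            p_over, p_under = binomial_tail_pvalues(k, n, p_bg)
            if k / n > p_bg:
                pv = max(p_over, P_FLOOR)
                height = -np.log10(pv)
            else:
                pv = max(p_under, P_FLOOR)
                height = np.log10(pv)  # negative: under-represented
            rows.append({"offset": off, "residue": res, "k": k, "n": n,
                         "p_bg": p_bg, "p_value": pv, "height": float(height),
                         "significant": bool(abs(height) >= thr), "flag": ""})
    return LogoResult(frame=pd.DataFrame(rows), threshold=thr)


def grouped_binomial(
    foreground: Sequence[SiteWindow],
    background: Sequence[SiteWindow],
    group: set[str],
    positions: Sequence[int],
) -> dict:
    """Binomial enrichment of a residue *group* at a *set* of positions.

    Success for a window = any group residue at any listed offset.  The
    event probability is the background rate of that event; the p-value is
    the exact over-representation tail (or the under tail when depleted).
    """
    if not group:
        raise ValueError("empty residue group")
    for pos in positions:
        if not -WINDOW_HALF <= pos <= WINDOW_HALF or pos == 0:
            raise ValueError(f"offset {pos} outside -7..+7 (0 excluded)")

    def hits(ws):
        return sum(any(w.residue_at(o) in group for o in positions) for w in ws)

    k, n = hits(foreground), len(foreground)
    bg_k, bg_n = hits(background), len(background)
    if bg_n == 0:
        raise ValueError("empty background")
    p = bg_k / bg_n
    p_over, p_under = binomial_tail_pvalues(k, n, p)
    enriched = n > 0 and k / n > p
    return {
        "k": k,
        "n": n,
        "p_event": p,
        "p_value": p_over if enriched else p_under,
        "direction": "over" if enriched else "under",
    }


# ---------------------------------------------------------------------------
# kinase-consensus classes and phase-specific enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifClass:
    """A declarative kinase-consensus pattern over window offsets."""

    name: str
    predicate: Callable[[SiteWindow], bool]
    note: str = "consensus approximation"

    def matches(self, w: SiteWindow) -> bool:
        return bool(self.predicate(w))


def default_motif_classes() -> list[MotifClass]:
    return [
        MotifClass(
            "proline_directed",
            lambda w: w.window[WINDOW_HALF] in "ST" and w.residue_at(1) == "P",
            "[pS/pT]P, CMGC-family consensus",
        ),
        MotifClass(
            "cdk_like",
            lambda w: w.window[WINDOW_HALF] in "ST"
            and w.residue_at(1) == "P"
            and w.residue_at(4) in "KR",
            "[pS/pT]PXX[K/R], CDK consensus",
        ),
        MotifClass(
            "acid_directed",
            lambda w: any(w.residue_at(o) in "DE" for o in (1, 2, 3)),
            "D/E at +1..+3, CK2-like consensus approximation",
        ),
        MotifClass(
            "hydrophobic_directed",
            lambda w: w.residue_at(-5) in HYDROPHOBIC and w.residue_at(4) in HYDROPHOBIC,
            "hydrophobic at -5 and +4, SnRK/AMPK-like",
        ),
    ]


def phase_motif_enrichment(
    rhythm_results: pd.DataFrame,
    windows: dict[str, SiteWindow],
    background: Sequence[SiteWindow],
    classes: Sequence[MotifClass] | None = None,
) -> pd.DataFrame:
    """Kinase-consensus enrichment per peak-phase bin.

    ``rhythm_results`` must carry ``peak_zt`` and ``rhythmic`` per motif id;
    ``windows`` maps motif id -> SiteWindow.  For each (peak ZT, class)
    cell, the count of rhythmic motifs matching the class is tested against
    the class rate among *all detected* windows (the background guards
    against detection bias), with exact binomial tails and BH adjustment
    across cells.
    """
    classes = list(classes) if classes is not None else default_motif_classes()
    rhythmic = rhythm_results[rhythm_results["rhythmic"]]
    bg_n = len(background)
    if bg_n == 0:
        raise ValueError("empty background window set")
    rows = []
    for zt, sub in rhythmic.groupby("peak_zt"):
        ws = [windows[m] for m in sub.index if m in windows]
        if not ws:
            import warnings

            warnings.warn(f"no windows for rhythmic motifs peaking at ZT{zt:g}; skipped")
            continue
        for cls in classes:
            k = sum(cls.matches(w) for w in ws)
            n = len(ws)
            p_bg = sum(cls.matches(w) for w in background) / bg_n
            p_over, p_under = binomial_tail_pvalues(k, n, p_bg)
            enriched = k / n > p_bg
            with np.errstate(divide="ignore"):
                fold = (k / n) / p_bg if p_bg > 0 else np.inf
            rows.append({
                "peak_zt": float(zt), "motif_class": cls.name, "k": k, "n": n,
                "bg_rate": p_bg, "fold_enrichment": float(fold),
                "p_value": p_over if enriched else p_under,
                "direction": "over" if enriched else "under",
                "note": cls.note,
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p_value"].to_numpy())
    return out
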