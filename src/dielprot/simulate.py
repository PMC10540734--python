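"""Synthetic data emulating a 6-timepoint x 5-replicate diel LC-MS design.

The generators reproduce the statistical structure the analysis assumes:
cosine-shaped diel profiles with multiplicative lognormal noise and
per-sample loading factors, technical phosphopeptide redundancy (charge
states 2-4, missed cleavages, oxidation/acetylation co-modifications),
a degraded outlier replicate, a 4-point dark-adaptation decay series, and
partial 15N incorporation courses.  Every generator is a pure function of
its specification plus seed, so identical inputs give identical output.

Baseline abundances are drawn log-uniformly over four decades to emulate
the dynamic range of label-free intensity data; noise is multiplicative
lognormal because such intensities are right-skewed (the reason the
analysis arcsinh-transforms before testing).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import PhosphoVariant, QuantTable, SampleKey

LD_ZTS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
DA_ZTS = (24.0, 48.0, 72.0, 96.0)
REPLICATES = ("A", "B", "C", "D", "E")

_AA = "ACDEFGHIKLMNPQRSTVWY"
# Amino-acid background roughly matching average proteome composition
_AA_FREQ = np.array(
    [0.083, 0.014, 0.054, 0.067, 0.039, 0.071, 0.022, 0.059, 0.058, 0.097,
     0.024, 0.040, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069, 0.011, 0.032]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


@dataclass(frozen=True)
class SimSpec:
    """Conditions for one simulated LD dataset.

    Defaults mirror the study design: five biological replicates harvested at
    six Zeitgeber times across one light--dark cycle, 855 protein-level
    features, with a controllable rhythmic fraction of cosine-like profiles.
    """

    n_features: int = 855
    frac_rhythmic: float = 0.095
    fold_range: tuple[float, float] = (1.5, 5.0)
    noise_cv: float = 0.1
    loading_spread: float = 0.05
    seed: int = 0
    zts: tuple[float, ...] = LD_ZTS
    replicates: tuple[str, ...] = REPLICATES
    condition: str = "LD"
    phase_choices: tuple[float, ...] | None = None  # None = uniform over [0, 24)
    baseline_decades: float = 4.0
    feature_prefix: str = "feat"

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise ValueError(f"frac_rhythmic must be in [0,1], got {self.frac_rhythmic}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


def motif_simspec(**overrides) -> SimSpec:
    """A SimSpec sized like the phosphopeptide-motif dataset (1472 features,
    58% rhythmic, amplitudes reaching 20-fold)."""
    kw = dict(n_features=1472, frac_rhythmic=0.58, fold_range=(1.5, 20.0), feature_prefix="motif")
    kw.update(overrides)
    return SimSpec(**kw)


def _amplitude_for_fold(fold: np.ndarray, phase: np.ndarray, zts: Sequence[float]) -> np.ndarray:
    """Relative amplitude A such that max/min of 1 + A cos(2pi (zt-phase)/24)
    over the sampled ZT grid equals the requested peak/trough fold exactly."""
    t = np.asarray(zts, dtype=float)
    c = np.cos(2 * np.pi * (t[None, :] - phase[:, None]) / 24.0)
    cmax, cmin = c.max(axis=1), c.min(axis=1)
    return (fold - 1.0) / (cmax - fold * cmin)


def generate_ld_dataset(spec: SimSpec) -> tuple[QuantTable, pd.DataFrame]:
    """Generate one LD quantification table plus its ground truth.

    Abundance model per feature i and sample (zt, rep):

        baseline_i * (1 + A_i cos(2 pi (zt - phi_i)/24)) * LN(cv) * loading

    Non-rhythmic features have A = 0.  Returns ``(table, truth)`` where the
    truth frame carries per-feature ``rhythmic``, ``phase`` and ``fold``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_features
    ids = [f"{spec.feature_prefix}{i:05d}" for i in range(n)]
    n_r = int(round(spec.frac_rhythmic * n))
    rhythmic = np.zeros(n, dtype=bool)
    rhythmic[rng.choice(n, size=n_r, replace=False)] = True

    if spec.phase_choices is not None:
        phase = rng.choice(np.asarray(spec.phase_choices, dtype=float), size=n)
    else:
        phase = rng.uniform(0.0, 24.0, size=n)
    lo, hi = spec.fold_range
    fold = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    fold = np.where(rhythmic, fold, 1.0)
    amp = np.where(rhythmic, _amplitude_for_fold(fold, phase, spec.zts), 0.0)
    baseline = 10.0 ** rng.uniform(2.0, 2.0 + spec.baseline_decades, size=n)

    cols, colkeys = [], []
    for zt in spec.zts:
        for rep in spec.replicates:
            colkeys.append(SampleKey(spec.condition, zt, rep))
            cols.append(colkeys[-1].label)
    loading = np.exp(rng.normal(0.0, spec.loading_spread, size=len(cols)))

    sigma = np.sqrt(np.log1p(spec.noise_cv**2))
    data = np.empty((n, len(cols)))
    for j, key in enumerate(colkeys):
        mean = baseline * (1.0 + amp * np.cos(2 * np.pi * (key.zt - phase) / 24.0))
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n)) if sigma > 0 else 1.0
        data[:, j] = mean * noise * loading[j]

    table = QuantTable(pd.DataFrame(data, index=pd.Index(ids, name="feature_id"), columns=cols))
    truth = pd.DataFrame(
        {"rhythmic": rhythmic, "phase": phase, "fold": fold, "amplitude": amp, "baseline": baseline},
        index=pd.Index(ids, name="feature_id"),
    )
    truth.attrs["loading"] = pd.Series(loading, index=cols)
    return table, truth


def noise_free_means(spec: SimSpec) -> pd.DataFrame:
    """Expected (noise- and loading-free) within-timepoint means per feature."""
    table, truth = generate_ld_dataset(spec)
    t = np.asarray(spec.zts)
    mean = truth["baseline"].to_numpy()[:, None] * (
        1.0
        + truth["amplitude"].to_numpy()[:, None]
        * np.cos(2 * np.pi * (t[None, :] - truth["phase"].to_numpy()[:, None]) / 24.0)
    )
    return pd.DataFrame(mean, index=table.feature_ids, columns=t)


# ---------------------------------------------------------------------------
# phosphopeptide technical redundancy
# ---------------------------------------------------------------------------

_CO_MODS = ("Oxidation (M)", "Acetyl (N-term)")


def generate_phospho_variants(
    motif_table: QuantTable,
    max_variants: int = 6,
    ambiguous_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[PhosphoVariant], list[dict]]:
    """Explode each motif into 1-6 technical variants whose abundances are a
    Dirichlet split of the motif abundance (so summing them recovers the
    motif exactly).

    Motif feature ids must follow the ``locus@pos[+pos...]`` convention.  A
    fraction of variants is given a deliberately shifted site assignment plus
    a matching entry in the returned alternative-prediction list (keyed by
    sequence, charge and co-modification count), emulating ambiguous site
    localization resolved by cross-referencing against a second search
    engine's most-probable-site predictions.
    """
    if motif_table.n_features == 0:
        raise ValueError("empty motif table")
    rng = np.random.default_rng(seed)
    variants: list[PhosphoVariant] = []
    predictions: list[dict] = []
    vid = 0
    for fid in motif_table.feature_ids:
        locus, _, postxt = fid.partition("@")
        positions = tuple(int(p) for p in postxt.split("+"))
        abundance = motif_table.data.loc[fid]
        n_var = int(rng.integers(1, max_variants + 1))
        weights = rng.dirichlet(np.ones(n_var))
        # one tryptic peptide per motif; variants share it
        pep_len = int(rng.integers(10, 21))
        site_local = sorted(rng.choice(pep_len - 2, size=len(positions), replace=False) + 1)
        seq = rng.choice(list(_AA), size=pep_len, p=_AA_FREQ)
        residues = rng.choice(["S", "T", "Y"], size=len(positions), p=[0.6, 0.35, 0.05])
        for p_local, res in zip(site_local, residues):
            seq[p_local] = res
        seq = "".join(seq)
        for v in range(n_var):
            charge = int(rng.integers(2, 5))
            mc = int(rng.integers(0, 3))
            mods = frozenset(m for m in _CO_MODS if rng.random() < 0.25)
            reported = positions
            if rng.random() < ambiguous_fraction:
                # shift the first site by one residue; the prediction record
                # holds the true assignment
                reported = tuple(sorted([positions[0] + 1, *positions[1:]]))
                predictions.append(
                    {
                        "sequence": seq,
                        "charge": charge,
                        "n_mods": len(mods),
                        "positions": positions,
                        "confidence": float(rng.uniform(0.8, 1.0)),
                    }
                )
            variants.append(
                PhosphoVariant(
                    feature_id=f"var{vid:06d}",
                    locus=locus,
                    sequence=seq,
                    charge=charge,
                    missed_cleavages=mc,
                    modifications=mods,
                    phospho_positions=reported,
                    abundance=abundance * weights[v],
                )
            )
            vid += 1
    return variants, predictions


# ---------------------------------------------------------------------------
# 15N incorporation courses and dark adaptation
# ---------------------------------------------------------------------------


def generate_labeling_course(
    k_degs: Sequence[float] | pd.Series,
    efficiency: float = 0.93,
    times: Sequence[float] = (6.0, 12.0, 24.0, 48.0, 72.0),
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Partial 15N incorporation: labelled fraction f(t) = E(1 - exp(-k t)).

    Multiplicative lognormal noise (CV ``noise_cv``) is applied and the
    result clipped to [0, 1].  Returns a locus x time DataFrame.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or len(times) == 0:
        raise ValueError("time grid must be non-empty and non-negative")
    if isinstance(k_degs, pd.Series):
        loci, rates = k_degs.index, k_degs.to_numpy(dtype=float)
    else:
        rates = np.asarray(k_degs, dtype=float)
        loci = pd.Index([f"prot{i:04d}" for i in range(len(rates))], name="locus")
    if np.any(rates <= 0):
        raise ValueError("degradation rates must be positive")
    rng = np.random.default_rng(seed)
    f = efficiency * (1.0 - np.exp(-rates[:, None] * times[None, :]))
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        f = f * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=f.shape))
    return pd.DataFrame(np.clip(f, 0.0, 1.0), index=loci, columns=times)


def generate_da_dataset(
    k_degs: pd.Series,
    baselines: pd.Series | None = None,
    noise_cv: float = 0.1,
    seed: int = 0,
    zts: Sequence[float] = DA_ZTS,
    replicates: Sequence[str] = REPLICATES,
) -> QuantTable:
    """Dark-adaptation series: exponential decay per protein from its level at
    the start of prolonged darkness (ZT24) at the protein's degradation rate.

    Synthesis is assumed halted in extended darkness, so level(t) =
    level(ZT24) * exp(-k_deg (t - 24)).
    """
    rng = np.random.default_rng(seed)
    loci = k_degs.index
    if baselines is None:
        baselines = pd.Series(10.0 ** rng.uniform(2.0, 6.0, size=len(loci)), index=loci)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    cols, vals = [], []
    for zt in zts:
        decay = baselines.to_numpy() * np.exp(-k_degs.to_numpy() * (zt - zts[0]))
        for rep in replicates:
            cols.append(SampleKey("DA", float(zt), rep).label)
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(loci))) if sigma > 0 else 1.0
            vals.append(decay * noise)
    data = pd.DataFrame(np.column_stack(vals), index=loci, columns=cols)
    return QuantTable(data)


# ---------------------------------------------------------------------------
# outlier replicate
# ---------------------------------------------------------------------------


def inject_outlier_replicate(
    table: QuantTable, sample: SampleKey, severity: float = 1.0, seed: int = 0
) -> QuantTable:
    """Degrade one replicate so that its correlation to the per-timepoint
    median collapses (r^2 < 0.8 at severity >= 1).

    A fraction ``severity`` of that sample's values is permuted across
    features, destroying the feature-wise structure while keeping the
    marginal intensity distribution intact.
    """
    label = sample.label
    if label not in table.data.columns:
        raise KeyError(f"sample {label!r} not in table")
    if severity == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    col = out.data[label].to_numpy().copy()
    if np.nanstd(col) == 0:
        raise ValueError("constant sample column: outlier undetectable by correlation")
    n = len(col)
    k = int(round(min(max(severity, 0.0), 1.0) * n))
    idx = rng.choice(n, size=k, replace=False)
    col[np.sort(idx)] = col[rng.permutation(idx)]
    out.data[label] = col
    return out


# ---------------------------------------------------------------------------
# protein sequences with designated phospho-sites
# ---------------------------------------------------------------------------


@dataclass
class PlantedMotifs:
    """Planting rates for kinase-consensus context around designated sites."""

    proline_rate: float = 0.0      # P at +1 ([pS/pT]P, CMGC-family consensus)
    acidic_rate: float = 0.0       # D/E at each of +1..+3 (CK2-style)
    basic_plus4_rate: float = 0.0  # K/R at +4 (completes the CDK consensus)


def generate_protein_sequences(
    n: int,
    mean_length: int = 300,
    sites_per_protein: int = 2,
    planted: PlantedMotifs | None = None,
    seed: int = 0,
) -> tuple[dict[str, str], list[tuple[str, int]]]:
    """Random protein sequences plus designated S/T/Y phospho-sites.

    Residues are drawn from an average proteome background; around each
    designated site, kinase-consensus residues are planted at the stated
    rates.  Returns ``(sequences, sites)`` with sites as (locus, 1-based
    position) pairs.  Lengths below 15 are rejected because window
    extraction needs +-7 context.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_length < 15:
        raise ValueError("sequence length < 15 cannot host a +-7 window")
    planted = planted or PlantedMotifs()
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    sites: list[tuple[str, int]] = []
    for i in range(n):
        length = max(int(rng.normal(mean_length, mean_length / 5)), 30)
        seq = rng.choice(list(_AA), size=length, p=_AA_FREQ)
        locus = f"prot{i:04d}"
        n_sites = max(1, min(sites_per_protein, length - 16))
        pos_pool = rng.choice(np.arange(8, length - 7), size=n_sites, replace=False)
        for p0 in np.sort(pos_pool):
            res = rng.choice(["S", "T", "Y"], p=[0.6, 0.35, 0.05])
            seq[p0] = res
            if res in "ST":
                if rng.random() < planted.proline_rate:
                    seq[p0 + 1] = "P"
                    if rng.random() < planted.basic_plus4_rate:
                        seq[p0 + 4] = rng.choice(["K", "R"])
                elif rng.random() < planted.acidic_rate:
                    for off in (1, 2, 3):
                        seq[p0 + off] = rng.choice(["D", "E"])
            sites.append((locus, int(p0) + 1))  # 1-based
        seqs[locus] = "".join(seq)
    return seqs, sites
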