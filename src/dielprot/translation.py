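"""Light-gated translation model of diel protein dynamics.

Protein level P(t) for an mRNA peaking at phase phi follows

    dP/dt = ((k_syn - 1) L(t) + 1) m(t) - k_deg P(t)
    m(t)  = cos(2 pi (t - phi)/24) + 1

where L(t) = 1 during the light interval of each 24 h cycle (lights on at
ZT0 for ``photoperiod`` hours) and 0 at night, k_syn is the light/dark
protein synthesis ratio and k_deg the first-order degradation rate.  With
k_syn = 1 the model reduces to a linear first-order system whose steady
state peaks atan(omega/k_deg)/omega hours after the mRNA — about 4.6 h at
k_deg = 0.1 /h; with light-stimulated synthesis the peaks crowd into the
light interval regardless of mRNA phase.

Because the right-hand side is linear in P with a piecewise-constant gate,
the default integrator propagates the exact analytic solution between
light switches (machine precision; no discontinuity smoothing).  A stiff
numerical route through scipy's solve_ivp is provided for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OMEGA = 2.0 * np.pi / 24.0
SAMPLED_ZTS = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
DAYTIME_ZTS = (4.0, 8.0, 12.0)


@dataclass(frozen=True)
class TranslationParams:
    """Model constants.

    k_deg (per hour) and k_syn (dimensionless light/dark synthesis ratio)
    default to the measured values for this organism; ``settle`` hours of
    simulation precede the reported cycle so the dynamics are periodic.
    ``dilution`` adds an optional constant growth-dilution rate to the
    effective decay (off by default: it is small relative to k_deg).
    """

    k_deg: float = 0.1
    k_syn: float = 4.0
    photoperiod: float = 12.0
    settle: float = 240.0
    phi_step: float = 0.1
    dilution: float = 0.0

    def __post_init__(self) -> None:
        if self.k_deg <= 0:
            raise ValueError("k_deg must be positive")
        if self.k_syn < 1:
            raise ValueError("k_syn must be >= 1 (light/dark synthesis ratio)")
        if not 0 < self.photoperiod < 24:
            raise ValueError("photoperiod must lie in (0, 24)")

    @property
    def k_eff(self) -> float:
        return self.k_deg + self.dilution


def _particular(t, phi, a, k):
    """Particular (periodic) solution for P' = a (cos(w(t-phi)) + 1) - k P."""
    return a / k + a * (k * np.cos(OMEGA * (t - phi)) + OMEGA * np.sin(OMEGA * (t - phi))) / (
        k**2 + OMEGA**2
    )


def _propagate(P0, t0, t1, phi, a, k):
    """Exact solution over a segment with constant synthesis multiplier a."""
    return (P0 - _particular(t0, phi, a, k)) * np.exp(-k * (t1 - t0)) + _particular(t1, phi, a, k)


def _switch_segments(t_end: float, photoperiod: float):
    """Yield (start, stop, is_light) covering [0, t_end] split at the light
    switches; light spans [0, photoperiod) within each 24 h cycle."""
    edges = [0.0]
    c = 0.0
    while c < t_end:
        for e in (c + photoperiod, c + 24.0):
            if 0.0 < e < t_end:
                edges.append(e)
        c += 24.0
    edges.append(t_end)
    edges = sorted(set(edges))
    for a, b in zip(edges[:-1], edges[1:]):
        yield a, b, (a % 24.0) < photoperiod


def simulate_protein(
    params: TranslationParams,
    phi: float,
    dt: float = 0.01,
    method: str = "analytic",
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Simulate one protein and locate its steady-state peak and trough.

    Returns ``(t, P, peak_zt, trough_zt)`` where ``t`` spans the final 24 h
    (Zeitgeber time 0-24 sampled every ``dt`` hours) after ``settle`` hours
    of settling, and peak/trough are located on that grid.
    """
    k = params.k_eff
    if method == "analytic":
        P = 0.0
        for a, b, light in _switch_segments(params.settle, params.photoperiod):
            mult = params.k_syn if light else 1.0
            P = _propagate(P, a, b, phi, mult, k)
        ts = np.arange(0.0, 24.0 + dt / 2, dt)
        out = np.empty_like(ts)
        Pseg = P
        for a, b, light in _switch_segments(24.0, params.photoperiod):
            mult = params.k_syn if light else 1.0
            sel = (ts >= a - 1e-12) & (ts <= b + 1e-12)
            tt = ts[sel]
            out[sel] = (Pseg - _particular(params.settle + a, phi, mult, k)) * np.exp(
                -k * (params.settle + tt - (params.settle + a))
            ) + _particular(params.settle + tt, phi, mult, k)
            Pseg = _propagate(Pseg, params.settle + a, params.settle + b, phi, mult, k)
    elif method == "ode":
        from scipy.integrate import solve_ivp

        def rhs(t, y, mult):
            m = np.cos(OMEGA * (t - phi)) + 1.0
            return [mult * m - k * y[0]]

        P = 0.0
        horizon = params.settle + 24.0
        ts = np.arange(0.0, 24.0 + dt / 2, dt)
        out = np.full_like(ts, np.nan)
        for a, b, light in _switch_segments(horizon, params.photoperiod):
            mult = params.k_syn if light else 1.0
            sel = None
            t_eval = np.array([b])
            if b > params.settle:
                sel = (ts + params.settle >= a - 1e-9) & (ts + params.settle <= b + 1e-9)
                t_eval = np.union1d(np.clip(ts[sel] + params.settle, a, b), [b])
            sol = solve_ivp(
                rhs, (a, b), [P], args=(mult,), method="LSODA",
                rtol=1e-9, atol=1e-12, t_eval=t_eval,
            )
            if not sol.success:
                raise RuntimeError(f"ODE integration failed on [{a},{b}]: {sol.message}")
            if sel is not None:
                pos = np.searchsorted(sol.t, np.clip(ts[sel] + params.settle, a, b))
                out[sel] = sol.y[0][pos]
            P = float(sol.y[0, -1])
    else:
        raise ValueError(f"unknown method {method!r}")
    peak = float(ts[int(np.argmax(out))] % 24.0)
    trough = float(ts[int(np.argmin(out))] % 24.0)
    return ts, out, peak, trough


def bin_to_sampled_zt(time: float, zts=SAMPLED_ZTS) -> float:
    """Nearest sampled ZT on the 24 h circle; ties break to the earlier ZT."""
    zts = np.asarray(zts, dtype=float)
    d = np.abs((time - zts + 12.0) % 24.0 - 12.0)
    return float(zts[int(np.argmin(d))])


@dataclass
class TranslationSimResult:
    """Peak/trough times across the mRNA phase grid, with ZT-binned summary."""

    params: TranslationParams
    table: pd.DataFrame          # index phi; columns peak_zt, trough_zt, peak_bin
    histogram: pd.Series         # fraction of peaks per sampled ZT
    daytime_fraction: float      # share of peaks binned to daytime ZTs
    daytime_definition: str = "binned"

    def summary(self) -> str:
        h = ", ".join(f"ZT{int(z)}: {v:.3f}" for z, v in self.histogram.items())
        return (
            "Light-gated translation simulation\n"
            f"  k_deg = {self.params.k_deg} /h, k_syn = {self.params.k_syn}, "
            f"photoperiod = {self.params.photoperiod} h\n"
            f"  mRNA phases  : {len(self.table)} on a {self.params.phi_step} h grid\n"
            f"  peak fraction: {h}\n"
            f"  daytime (ZT4-12) share of protein peaks: "
            f"{100 * self.daytime_fraction:.1f}%\n"
        )


class TranslationModel:
    """Forward simulator over a uniform grid of mRNA peak phases."""

    def __init__(self, params: TranslationParams | None = None):
        self.params = params or TranslationParams()

    def simulate(self, phi: float, dt: float = 0.01, method: str = "analytic"):
        return simulate_protein(self.params, phi, dt=dt, method=method)

    def peak_time_distribution(
        self, dt: float = 0.01, daytime: str = "binned"
    ) -> TranslationSimResult:
        """Distribution of protein peak times for mRNA phases uniform on
        [0, 24) at ``phi_step`` intervals.

        ``daytime`` selects the operationalization of "daytime peaks":
        ``binned`` (default) counts peaks whose nearest sampled ZT is 4, 8
        or 12; ``continuous`` counts peaks falling in the light interval
        (0, photoperiod].
        """
        phis = np.arange(0.0, 24.0, self.params.phi_step)
        if len(phis) == 0:
            raise ValueError("empty phase grid")
        rows = []
        for phi in phis:
            _, _, peak, trough = simulate_protein(self.params, float(phi), dt=dt)
            rows.append({"phi": float(phi), "peak_zt": peak, "trough_zt": trough,
                         "peak_bin": bin_to_sampled_zt(peak)})
        table = pd.DataFrame(rows).set_index("phi")
        hist = (
            table["peak_bin"].value_counts().reindex(list(SAMPLED_ZTS), fill_value=0)
            / len(table)
        )
        hist.index.name = "zt"
        if daytime == "binned":
            frac = float(table["peak_bin"].isin(DAYTIME_ZTS).mean())
        elif daytime == "continuous":
            frac = float(
                ((table["peak_zt"] > 0) & (table["peak_zt"] <= self.params.photoperiod)).mean()
            )
        else:
            raise ValueError(f"unknown daytime definition {daytime!r}")
        return TranslationSimResult(
            params=self.params, table=table, histogram=hist,
            daytime_fraction=frac, daytime_definition=daytime,
        )


def peak_time_distribution(
    params: TranslationParams | None = None, **kwargs
) -> TranslationSimResult:
    """Functional wrapper around :meth:`TranslationModel.peak_time_distribution`."""
    return TranslationModel(params).peak_time_distribution(**kwargs)
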