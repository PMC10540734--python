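from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from dielprot.motifs import (
    SiteWindow,
    binomial_logo,
    binomial_tail_pvalues,
    default_motif_classes,
    extract_windows,
    grouped_binomial,
    phase_motif_enrichment,
    significance_threshold,
)
from dielprot.simulate import PlantedMotifs, generate_protein_sequences


def exact_binomial_upper_tail(k, n, p):
    """Independent exact enumeration of P(X >= k)."""
    pf = Fraction(p).limit_denominator(10**6)
    return float(sum(comb(n, j) * pf**j * (1 - pf) ** (n - j) for j in range(k, n + 1)))


def _window(centre="S", fill="A", at=None):
    res = [fill] * 15
    res[7] = centre
    for off, aa in (at or {}).items():
        res[off + 7] = aa
    return SiteWindow("L", 8, "".join(res))


class TestExtractWindows:
    def test_interior_site_full_window(self):
        seqs = {"L": "ACDEFGHSKLMNPQRSTVWY"}
        (w,) = extract_windows([("L", 8)], seqs)
        assert w.window == seqs["L"][0:15]
        assert w.residue_at(0) == "S"

    def test_terminal_site_padded(self):
        seqs = {"L": "AASAAAAAAAAAAAAAAAAA"}
        (w,) = extract_windows([("L", 3)], seqs)
        assert w.window.startswith("_____")
        assert len(w.window) == 15
        assert w.window[7] == "S"

    def test_position_beyond_length_names_site(self):
        with pytest.raises(ValueError, match="L:99|99"):
            extract_windows([("L", 99)], {"L": "AAASAAA"})

    def test_generated_sites_are_centred_sty(self):
        seqs, sites = generate_protein_sequences(30, seed=2)
        for w in extract_windows(sites, seqs):
            assert w.window[7] in "STY"

    def test_non_sty_centre_rejected(self):
        with pytest.raises(ValueError, match="S/T/Y"):
            SiteWindow("L", 8, "A" * 15)


class TestBinomialLogo:
    def test_exact_tail_example(self):
        p_over, _ = binomial_tail_pvalues(5, 10, 0.2)
        assert p_over == pytest.approx(0.0328, abs=5e-5)
        assert p_over == pytest.approx(exact_binomial_upper_tail(5, 10, 0.2), rel=1e-9)
        assert -np.log10(p_over) == pytest.approx(1.48, abs=0.01)

    def test_threshold_matches_bonferroni_line(self):
        assert significance_threshold() == pytest.approx(3.78)

    def test_heights_signed_by_direction(self):
        fg = [_window(at={1: "P"})] * 10
        bg = fg + [_window(at={1: "G"})] * 30
        res = binomial_logo(fg, bg)
        f = res.frame.set_index(["offset", "residue"])
        assert f.loc[(1, "P"), "height"] > 0   # enriched in foreground
        assert f.loc[(1, "G"), "height"] < 0   # depleted
        assert res.threshold == pytest.approx(3.78)

    def test_matches_exact_enumeration_small_n(self):
        rng = np.random.default_rng(3)
        fg = [_window(fill=rng.choice(list("AGPDE"))) for _ in range(20)]
        bg = fg + [_window(fill=rng.choice(list("AGPDE"))) for _ in range(40)]
        res = binomial_logo(fg, bg)
        for _, row in res.frame.sample(30, random_state=1).iterrows():
            if row["n"] == 0 or not np.isfinite(row["p_bg"]):
                continue
            k, n, p = int(row["k"]), int(row["n"]), float(row["p_bg"])
            if k / n > p:
                expected = exact_binomial_upper_tail(k, n, p)
                assert row["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_null_foreground_rarely_significant(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 40
        for s in range(n_sim):
            seqs, sites = generate_protein_sequences(60, seed=100 + s)
            windows = extract_windows(sites, seqs)
            fg = [windows[i] for i in rng.choice(len(windows), 25, replace=False)]
            res = binomial_logo(fg, windows)
            if (res.frame["height"].abs() >= res.threshold).any():
                hits += 1
        assert hits <= int(0.05 * n_sim) + 2

    def test_pads_never_counted(self):
        fg = [SiteWindow("L", 1, "_______SAAAAAAA")] * 5
        res = binomial_logo(fg, fg)
        left = res.frame[res.frame["offset"] < 0]
        assert (left["n"] == 0).all()
        assert (left["height"] == 0).all()

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            binomial_logo([], [_window()])


class TestGroupedBinomial:
    def test_exact_tail_for_acidic_group(self):
        fg = [_window(at={1: "D"})] * 40 + [_window()] * 20
        bg = [_window(at={1: "D"})] * 30 + [_window()] * 70
        out = grouped_binomial(fg, bg, group={"D", "E"}, positions=[1, 2, 3])
        assert out["k"] == 40 and out["n"] == 60
        assert out["p_event"] == pytest.approx(0.3)
        assert out["p_value"] == pytest.approx(exact_binomial_upper_tail(40, 60, 0.3), rel=1e-9)

    def test_saturated_group_p_one(self):
        fg = [_window()] * 10
        out = grouped_binomial(fg, fg, group=set("ACDEFGHIKLMNPQRSTVWY"), positions=[1])
        assert out["p_event"] == 1.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_planted_motif_underflows(self):
        fg = [_window(at={1: "E"})] * 200
        bg = fg + [_window(at={1: "G"})] * 800
        out = grouped_binomial(fg, bg, group={"D", "E"}, positions=[1])
        assert out["p_value"] < 1e-100

    def test_position_zero_rejected(self):
        with pytest.raises(ValueError):
            grouped_binomial([_window()], [_window()], group={"P"}, positions=[0])


class TestPhaseEnrichment:
    def _setup(self, rng):
        seqs, sites = generate_protein_sequences(
            120, planted=PlantedMotifs(proline_rate=0.0), seed=7
        )
        windows = extract_windows(sites, seqs)
        ids = [f"m{i}" for i in range(len(windows))]
        return dict(zip(ids, windows)), ids

    def test_planted_proline_cell_is_minimum_p(self):
        # build foreground where ZT16 motifs are all proline-directed
        base = _window()
        pro = _window(at={1: "P"})
        windows = {f"m{i}": (pro if i < 30 else base) for i in range(90)}
        peaks = [16.0] * 30 + [0.0] * 30 + [8.0] * 30
        rr = pd.DataFrame({"peak_zt": peaks, "rhythmic": True}, index=list(windows))
        bg = list(windows.values()) + [base] * 60
        out = phase_motif_enrichment(rr, windows, bg)
        pro_rows = out[out["motif_class"] == "proline_directed"]
        best = pro_rows.loc[pro_rows["p_value"].idxmin()]
        assert best["peak_zt"] == 16.0 and best["direction"] == "over"

    def test_counts_partition_rhythmic_motifs(self):
        windows, ids = self._setup(np.random.default_rng(8))
        rng = np.random.default_rng(9)
        rr = pd.DataFrame(
            {"peak_zt": rng.choice([0.0, 8.0, 16.0], len(ids)), "rhythmic": True}, index=ids
        )
        out = phase_motif_enrichment(rr, windows, list(windows.values()))
        per_class = out.groupby("motif_class")["n"].sum()
        assert (per_class == len(ids)).all()

    def test_null_rarely_significant_after_bh(self):
        windows, ids = self._setup(np.random.default_rng(10))
        sig = 0
        n_sim = 25
        for s in range(n_sim):
            rng = np.random.default_rng(200 + s)
            rr = pd.DataFrame(
                {"peak_zt": rng.choice([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], len(ids)),
                 "rhythmic": True},
                index=ids,
            )
            out = phase_motif_enrichment(rr, windows, list(windows.values()))
            if (out["q"] < 0.05).any():
                sig += 1
        assert sig <= int(0.05 * n_sim) + 2

    def test_default_classes_cover_known_consensus(self):
        names = {c.name for c in default_motif_classes()}
        assert {"proline_directed", "cdk_like", "acid_directed", "hydrophobic_directed"} <= names
        w_cdk = _window(at={1: "P", 4: "K"})
        matches = {c.name for c in default_motif_classes() if c.matches(w_cdk)}
        assert {"proline_directed", "cdk_like"} <= matches
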