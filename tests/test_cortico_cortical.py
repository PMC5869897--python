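"""Cortico-cortical fitting, mapping and laminar disaggregation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import ndtr

from cortimap import cortico_cortical as cc
from cortimap import synthetic
from cortimap.errors import InsufficientDataError, InvalidStateError
from cortimap.synthetic import GroundTruth


def _long(rows):
    return pd.DataFrame(rows, columns=["injection", "target", "source", "fln", "sln"])


def _identity_overlap(areas):
    return pd.DataFrame(np.eye(len(areas)), index=areas, columns=areas)


class TestMapFln:
    def test_identity_overlap_preserves_values(self):
        areas = ["A", "B", "C"]
        raw = _long([(0, "A", "B", 0.02, np.nan), (0, "A", "C", 0.05, np.nan)])
        out = cc.map_fln(raw, _identity_overlap(areas))
        assert np.isclose(out.at["A", "B"], 0.02)
        assert np.isclose(out.at["A", "C"], 0.05)

    def test_split_source_halves_fln(self):
        # one beta source overlaps two model areas half-half
        overlap = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0]],
            index=["B1", "B2"],
            columns=["beta", "other"],
        )
        raw = pd.DataFrame(
            [(0, "B1", "beta", 0.04, np.nan)],
            columns=["injection", "target", "source", "fln", "sln"],
        )
        out = cc.map_fln(raw, overlap)
        assert np.isclose(out.at["B1", "B1"], 0.02)
        assert np.isclose(out.at["B1", "B2"], 0.02)

    def test_repeat_injections_averaged(self):
        areas = ["A", "B"]
        raw = _long([(0, "A", "B", 0.02, np.nan), (1, "A", "B", 0.04, np.nan)])
        out = cc.map_fln(raw, _identity_overlap(areas))
        assert np.isclose(out.at["A", "B"], 0.03)


class TestMapSln:
    def test_identity_overlap(self):
        areas = ["A", "B"]
        raw = _long([(0, "A", "B", 0.02, 0.7)])
        out = cc.map_sln(raw, _identity_overlap(areas))
        assert np.isclose(out.at["A", "B"], 0.7)

    def test_fln_weighted_mean(self):
        # model area B overlaps two beta areas with equal overlap; FLN weights
        overlap = pd.DataFrame(
            [[0.5, 0.5]], index=["B"], columns=["b1", "b2"]
        )
        overlap.loc["A"] = [0.0, 0.0]
        overlap.at["A", "b1"] = 1.0  # keep rows stochastic
        raw = _long([(0, "A", "b1", 0.03, 0.2), (0, "A", "b2", 0.03, 0.8)])
        out = cc.map_sln(raw, overlap.loc[["B", "A"]])
        assert np.isclose(out.at["A", "B"], 0.5)

    def test_weighted_mean_arithmetic(self):
        overlap = pd.DataFrame([[0.5, 0.5], [1.0, 0.0]], index=["B", "A"], columns=["b1", "b2"])
        raw = _long([(0, "A", "b1", 0.03, 0.2), (0, "A", "b2", 0.01, 0.8)])
        out = cc.map_sln(raw, overlap)
        # weights within B's row: 0.5*0.03 : 0.5*0.01 = 0.75 : 0.25
        assert np.isclose(out.at["A", "B"], 0.75 * 0.2 + 0.25 * 0.8)


class TestFitEdr:
    def test_noiseless_recovery(self, arch32, dist32):
        truth = GroundTruth(fln_noise_sd=0.0, phi=0.0, seed=2)
        tr = synthetic.make_tracing(arch32, dist32, truth, 10, fln_row_total=None)
        fit = cc.fit_edr(tr.fln, dist32)
        assert np.isclose(fit.lambda_decay, truth.lambda_decay, rtol=1e-9)
        assert np.isclose(fit.c_scale, truth.c_scale, rtol=1e-9)

    def test_constant_fln_gives_zero_decay(self, dist32):
        f = pd.DataFrame(0.01, index=dist32.index, columns=dist32.columns)
        np.fill_diagonal(f.values, np.nan)
        fit = cc.fit_edr(f, dist32)
        assert fit.lambda_decay == 0.0

    def test_matches_independent_ols(self, tracing32, dist32):
        fit = cc.fit_edr(tracing32.fln, dist32)
        f = tracing32.fln.to_numpy()
        d = dist32.to_numpy()
        ok = np.isfinite(f) & (f > 0)
        ols = sm.OLS(np.log10(f[ok]), sm.add_constant(d[ok])).fit()
        assert np.isclose(fit.lambda_decay, -ols.params[1] * np.log(10), atol=1e-10)
        assert np.isclose(fit.c_scale, 10 ** ols.params[0], rtol=1e-10)
        assert np.isclose(fit.p_value, ols.pvalues[1], atol=1e-10)

    def test_insufficient_data(self, dist32):
        f = pd.DataFrame(np.nan, index=dist32.index, columns=dist32.columns)
        f.iloc[0, 1] = 0.01
        with pytest.raises(InsufficientDataError):
            cc.fit_edr(f, dist32)


class TestFillAndNormalize:
    def test_row_totals_exact(self, tracing32, dist32):
        fit = cc.fit_edr(tracing32.fln, dist32)
        fln, ext = cc.fill_and_normalize_fln(
            tracing32.fln, fit, tracing32.binary, 0.79, 0.013, dist32,
            tracing32.nonmodeled_distances,
        )
        totals = fln.sum(axis=1) + ext.sum(axis=1)
        np.testing.assert_allclose(totals, 1 - 0.79 - 0.013, atol=1e-12)

    def test_absent_connections_stay_zero(self, tracing32, dist32):
        fit = cc.fit_edr(tracing32.fln, dist32)
        fln, _ = cc.fill_and_normalize_fln(
            tracing32.fln, fit, tracing32.binary, 0.79, 0.013, dist32,
            tracing32.nonmodeled_distances,
        )
        absent = (tracing32.binary.to_numpy() == 0) & ~(
            np.nan_to_num(tracing32.fln.to_numpy()) > 0
        )
        assert (fln.to_numpy()[absent] == 0).all()

    def test_no_missing_entries_only_rescales(self):
        areas = ["A", "B", "C"]
        fln = pd.DataFrame(
            [[0, 0.02, 0.04], [0.01, 0, 0.03], [0.02, 0.02, 0]],
            index=areas, columns=areas, dtype=float,
        )
        binary = (fln > 0).astype(int)
        dist = pd.DataFrame(10.0, index=areas, columns=areas)
        fit = cc.EDRFit(0.045, 0.11, 0.0, 10, -0.9)
        out, _ = cc.fill_and_normalize_fln(fln, fit, binary, 0.79, 0.013, dist, None)
        ratio = out.to_numpy()[fln.to_numpy() > 0] / fln.to_numpy()[fln.to_numpy() > 0]
        row_ratio = np.repeat(0.197 / fln.sum(axis=1).to_numpy(), 2)
        np.testing.assert_allclose(ratio, row_ratio, rtol=1e-12)


class TestFitSln:
    def test_low_dispersion_recovery_within_2se(self):
        rng = np.random.default_rng(11)
        n = 150
        ell = rng.uniform(-1.2, 1.2, n)
        a0_true, a1_true = 0.0, -1.5
        mu = ndtr(a0_true + a1_true * ell)
        total = np.full(n, 150)
        supra = rng.binomial(total, mu)  # phi -> 0 limit
        fit = cc.fit_sln(supra, total, ell)
        assert abs(fit.a0 - a0_true) < 2 * fit.se_a0
        assert abs(fit.a1 - a1_true) < 2 * fit.se_a1
        assert fit.phi < 0.05

    def test_flat_link_predicts_half(self):
        fit = cc.SLNFit(0.0, -1.0, 0.1, "probit", 0.0, 0.1, 0.1, 0.1, 10)
        assert np.isclose(cc.predict_sln(fit, 0.0), 0.5)

    def test_probit_and_logit_agree(self):
        rng = np.random.default_rng(3)
        n = 200
        ell = rng.uniform(-1.0, 1.0, n)
        mu = ndtr(-0.15 - 1.5 * ell)
        p = rng.beta(mu * 4, (1 - mu) * 4)
        total = np.full(n, 100)
        supra = rng.binomial(total, p)
        f_p = cc.fit_sln(supra, total, ell, link="probit")
        f_l = cc.fit_sln(supra, total, ell, link="logit")
        xs = np.linspace(-1.5, 1.5, 100)
        assert np.max(np.abs(cc.predict_sln(f_p, xs) - cc.predict_sln(f_l, xs))) < 0.05


class TestPredictSln:
    def test_link_limits(self):
        fit = cc.SLNFit(-0.152, -1.534, 0.2, "probit", 0, 0, 0, 0, 10)
        assert cc.predict_sln(fit, -30.0) > 0.999
        assert cc.predict_sln(fit, 30.0) < 0.001

    def test_standard_normal_cdf_at_intercept(self):
        fit = cc.SLNFit(-0.152, -1.534, 0.2, "probit", 0, 0, 0, 0, 10)
        assert np.isclose(cc.predict_sln(fit, 0.0), ndtr(-0.152))
        assert abs(cc.predict_sln(fit, 0.0) - 0.44) < 0.01

    def test_monotone_decreasing(self):
        fit = cc.SLNFit(-0.152, -1.534, 0.2, "probit", 0, 0, 0, 0, 10)
        xs = np.linspace(-2, 2, 50)
        ys = cc.predict_sln(fit, xs)
        assert (np.diff(ys) < 0).all()


class TestSourceLayerFractions:
    def test_equal_split(self):
        X = cc.source_layer_fractions(0.6, 100.0, 100.0)
        assert np.isclose(X["23E"], 0.6)
        assert np.isclose(X["5E"], 0.2)
        assert np.isclose(X["6E"], 0.2)

    def test_boundary_all_supragranular(self):
        X = cc.source_layer_fractions(1.0, 50.0, 70.0)
        assert np.isclose(X["23E"], 1.0)

    def test_ordinal_orders_of_magnitude(self):
        X = cc.source_layer_fractions(0.4, 1.0, 1.0, {"5": 3, "6": 1})
        assert np.isclose(X["5E"], 0.6 * 100 / 101)
        assert np.isclose(X["6E"], 0.6 / 101)

    def test_excluded_supragranular_layer(self):
        X = cc.source_layer_fractions(0.4, 1.0, 1.0, {"23": 0, "5": 1, "6": 1})
        assert X["23E"] == 0.0
        assert np.isclose(sum(X.values()), 1.0)


class TestTargetLayerFractions:
    FRACS = {"1": 0.1, "23": 0.3, "4": 0.2, "5": 0.2, "6": 0.2}

    def test_feedforward_terminates_in_l4(self):
        Y = cc.target_layer_fractions(0.8, self.FRACS)
        assert np.isclose(Y["4"], 1.0)

    def test_feedback_thickness_proportional(self):
        fracs = {"1": 0.1, "23": 0.3, "4": 0.2, "5": 0.2, "6": 0.2}
        Y = cc.target_layer_fractions(0.2, fracs)
        np.testing.assert_allclose(
            [Y["1"], Y["23"], Y["5"], Y["6"]], [0.125, 0.375, 0.25, 0.25]
        )
        assert Y["4"] == 0.0

    def test_lateral_uses_all_layers(self):
        Y = cc.target_layer_fractions(0.5, self.FRACS)
        assert all(Y[v] > 0 for v in self.FRACS)
        np.testing.assert_allclose(sum(Y.values()), 1.0)

    def test_agranular_feedforward_fallback(self):
        fracs = {"1": 0.12, "23": 0.4, "4": 0.0, "5": 0.2, "6": 0.28}
        Y = cc.target_layer_fractions(0.9, fracs)
        assert Y["4"] == 0.0
        assert np.isclose(sum(Y.values()), 1.0)


class TestSynapseToCellbody:
    def test_columns_sum_to_one(self, celltypes):
        occ = {"23E": 0.25, "23I": 0.07, "4E": 0.25, "4I": 0.06,
               "5E": 0.08, "5I": 0.02, "6E": 0.2, "6I": 0.07}
        P = cc.synapse_to_cellbody(celltypes, occ)
        sums = P.sum(axis=0, skipna=True)
        for v, s in sums.items():
            if P[v].notna().any():
                assert np.isclose(s, 1.0, atol=1e-9)

    def test_two_type_toy_matches_bruteforce(self):
        # two cell types, two layers: enumerate the joint table by hand
        ct = pd.DataFrame(
            {
                "cell_type": ["x", "y"],
                "population": ["23E", "5E"],
                "occurrence": [0.6, 0.4],
                "nsyn_1": [0.0, 0.0],
                "nsyn_23": [100.0, 50.0],
                "nsyn_4": [0.0, 0.0],
                "nsyn_5": [0.0, 200.0],
                "nsyn_6": [0.0, 0.0],
                "pcc_1": [0.0, 0.0],
                "pcc_23": [0.5, 0.2],
                "pcc_4": [0.0, 0.0],
                "pcc_5": [0.0, 0.1],
                "pcc_6": [0.0, 0.0],
            }
        )
        occ = {"23E": 0.5, "5E": 0.5}
        P = cc.synapse_to_cellbody(ct, occ)
        # brute force: joint(v, c) = pcc * nsyn * occ_rescaled
        joint_23 = {"x": 0.5 * 100 * 0.5, "y": 0.2 * 50 * 0.5}
        cond_23E = joint_23["x"] / (joint_23["x"] + joint_23["y"])
        assert np.isclose(P.at["23E", "23"], cond_23E, atol=1e-12)
        assert np.isclose(P.at["5E", "5"], 1.0)

    def test_layer_without_cc_synapses_marked_undefined(self):
        ct = pd.DataFrame(
            {
                "cell_type": ["x"],
                "population": ["23E"],
                "occurrence": [1.0],
                "nsyn_1": [0.0], "nsyn_23": [100.0], "nsyn_4": [0.0],
                "nsyn_5": [0.0], "nsyn_6": [0.0],
                "pcc_1": [0.0], "pcc_23": [0.5], "pcc_4": [0.0],
                "pcc_5": [0.0], "pcc_6": [0.0],
            }
        )
        P = cc.synapse_to_cellbody(ct, {"23E": 1.0})
        assert P["4"].isna().all()
        assert np.isclose(P.at["23E", "23"], 1.0)


class TestRedistribution:
    def test_exact_excitatory_share_with_conservation(self):
        mass = pd.Series({"23E": 0.5, "23I": 0.1, "4E": 0.3, "4I": 0.1})
        out = cc.redistribute_ei(mass, 0.93)
        assert np.isclose(out.sum(), mass.sum(), atol=1e-12)
        e_share = out[out.index.str.endswith("E")].sum() / out.sum()
        assert np.isclose(e_share, 0.93, atol=1e-12)

    def test_no_inhibitory_mass_left_unchanged(self):
        mass = pd.Series({"23E": 0.7, "5E": 0.3})
        out = cc.redistribute_ei(mass, 0.93)
        pd.testing.assert_series_equal(out, mass)

    def test_zero_excitatory_rejected(self):
        with pytest.raises(InvalidStateError):
            cc.redistribute_ei(pd.Series({"23I": 1.0}), 0.93)


class TestAssembleTypeIII:
    def test_mass_conservation_and_oracle(self, tiny_arch, celltypes):
        from cortimap import architecture as am

        pops = am.population_sizes(tiny_arch, 0.5642)
        occ = {p.split("-")[1]: n for p, n in pops.df.loc[pops.df["area"] == "V1x", "N"].items()}
        tot = sum(occ.values())
        occ = {k: v / tot for k, v in occ.items()}
        p_cond = cc.synapse_to_cellbody(celltypes, occ)
        areas = list(tiny_arch.index)
        nsyn_cc = pd.DataFrame(0.0, index=areas, columns=areas)
        nsyn_cc.at["V1x", "V2x"] = 1e6
        nsyn_cc.at["V2x", "V1x"] = 2e6
        sln = pd.DataFrame(np.nan, index=areas, columns=areas)
        sln.at["V1x", "V2x"] = 0.2   # feedback
        sln.at["V2x", "V1x"] = 0.8   # feedforward
        t3 = cc.assemble_type_iii(nsyn_cc, sln, tiny_arch, pops, p_cond)
        by_pair = t3.groupby(["target_area", "source_area"])["synapses"].sum()
        assert np.isclose(by_pair[("V1x", "V2x")], 1e6, rtol=1e-9)
        assert np.isclose(by_pair[("V2x", "V1x")], 2e6, rtol=1e-9)
        # excitatory share after redistribution
        for (ta, sa), grp in t3.groupby(["target_area", "source_area"]):
            e = grp[grp["target_pop"].str.endswith("E")]["synapses"].sum()
            assert np.isclose(e / grp["synapses"].sum(), 0.93, atol=1e-9)
        # brute-force oracle for one projection: X_j * sum_v Y_v * P(i|v) * Z_i
        grp = t3[(t3["target_area"] == "V1x") & (t3["source_area"] == "V2x")]
        s = 0.2
        n5e, n6e = pops.df.at["V2x-5E", "N"], pops.df.at["V2x-6E", "N"]
        X = {"23E": s, "5E": (1 - s) * n5e / (n5e + n6e), "6E": (1 - s) * n6e / (n5e + n6e)}
        fracs = {v: tiny_arch.at["V1x", f"frac_{v}"] for v in synthetic.FRAC_LAYERS}
        layers = ["1", "23", "5", "6"]
        wsum = sum(fracs[v] for v in layers)
        mass = {}
        for p in [q.split("-")[1] for q in pops.area_populations("V1x")]:
            mass[p] = sum(fracs[v] / wsum * p_cond.at[p, v] for v in layers if np.isfinite(p_cond.at[p, v]))
        tot = sum(mass.values())
        mass = {k: v / tot for k, v in mass.items()}
        e_share = sum(v for k, v in mass.items() if k.endswith("E"))
        z = {k: (0.93 / e_share if k.endswith("E") else 0.07 / (1 - e_share)) for k in mass}
        for row in grp.itertuples():
            j = row.source_pop.split("-")[1]
            i = row.target_pop.split("-")[1]
            expected = 1e6 * X[j] * mass[i] * z[i]
            assert np.isclose(row.synapses, expected, rtol=1e-9)

    def test_absent_connection_produces_no_synapses(self, tiny_arch, celltypes):
        from cortimap import architecture as am

        pops = am.population_sizes(tiny_arch, 0.5642)
        p_cond = cc.synapse_to_cellbody(
            celltypes, {"23E": 0.3, "23I": 0.08, "4E": 0.2, "4I": 0.05,
                        "5E": 0.1, "5I": 0.02, "6E": 0.2, "6I": 0.05}
        )
        areas = list(tiny_arch.index)
        nsyn_cc = pd.DataFrame(0.0, index=areas, columns=areas)
        nsyn_cc.at["V1x", "V2x"] = 1e5
        sln = pd.DataFrame(0.5, index=areas, columns=areas)
        t3 = cc.assemble_type_iii(nsyn_cc, sln, tiny_arch, pops, p_cond)
        pairs = set(zip(t3["target_area"], t3["source_area"]))
        assert pairs == {("V1x", "V2x")}

    def test_agranular_target_l4_mass_reassigned(self, tiny_arch, celltypes):
        from cortimap import architecture as am

        pops = am.population_sizes(tiny_arch, 0.5642)
        p_cond = cc.synapse_to_cellbody(
            celltypes, {"23E": 0.3, "23I": 0.08, "4E": 0.2, "4I": 0.05,
                        "5E": 0.1, "5I": 0.02, "6E": 0.2, "6I": 0.05}
        )
        areas = list(tiny_arch.index)
        nsyn_cc = pd.DataFrame(0.0, index=areas, columns=areas)
        nsyn_cc.at["THx", "V1x"] = 1e5
        sln = pd.DataFrame(0.5, index=areas, columns=areas)
        t3 = cc.assemble_type_iii(nsyn_cc, sln, tiny_arch, pops, p_cond)
        assert not t3["target_pop"].str.contains("-4").any()
        assert np.isclose(t3["synapses"].sum(), 1e5, rtol=1e-9)
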