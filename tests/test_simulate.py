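import numpy as np
import pandas as pd
import pytest

from fermnet.pls import fit_pls
from fermnet.rates import compute_mu, phenotype_at, relative_abundance
from fermnet.simulate import (
    FermentationParams,
    SimulationDesign,
    make_pathway_library,
    simulate_fermentation,
    simulate_metabolome,
)
from fermnet.tables import PhenotypeVector


class TestSimulateFermentation:
    def test_zero_growth_gives_constant_od(self):
        params = FermentationParams(mu_phases=(0.0, 0.0, 0.0, 0.0))
        tc = simulate_fermentation(params, seed=1)
        assert np.allclose(tc.column("od600"), params.od0)

    def test_butanol_low_before_acid_peak(self):
        tc = simulate_fermentation(seed=1)
        pre = tc.data[tc.data["time_h"] < FermentationParams().acid_peak_h]
        assert (pre["butanol_g_l"] <= 0.1).all()
        assert tc.data["butanol_g_l"].iloc[-1] > 5.0

    def test_pure_exponential_phase_recovers_mu(self):
        params = FermentationParams(mu_phases=(0.07, 0.07, 0.07, 0.07))
        tc = simulate_fermentation(params, seed=0)
        mu = compute_mu(tc)
        assert np.allclose(mu.to_numpy(), 0.07, atol=1e-6)

    def test_acids_rise_then_fall(self):
        tc = simulate_fermentation(seed=0)
        ace = tc.data.set_index("time_h")["acetate_g_l"]
        peak_t = ace.idxmax()
        assert 25 < peak_t < 40
        assert ace.iloc[-1] < ace.max()

    def test_ph_falls_bumps_falls(self):
        tc = simulate_fermentation(seed=0)
        ph = tc.data.set_index("time_h")["ph"]
        assert ph.loc[0.0] > ph.loc[12.0]       # initial fall
        assert ph.loc[20.0] > ph.loc[12.0]      # bump
        assert ph.iloc[-1] < ph.loc[20.0]       # final drift down

    def test_nonnegative_concentrations(self):
        tc = simulate_fermentation(FermentationParams(noise_sd=0.05), seed=3)
        for col in ("butanol_g_l", "acetate_g_l", "butyrate_g_l", "glucose_g_l"):
            assert (tc.data[col] >= 0).all()

    def test_bad_phase_bounds_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate_fermentation(FermentationParams(phase_bounds_h=(0, 45, 12, 63, 84)))

    def test_deterministic(self):
        a = simulate_fermentation(FermentationParams(noise_sd=0.02), seed=9)
        b = simulate_fermentation(FermentationParams(noise_sd=0.02), seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_dcw_is_fixed_multiple_of_od(self):
        tc = simulate_fermentation(seed=0)
        assert np.allclose(tc.column("dcw_g_l"), 0.3 * tc.column("od600"))


def simple_phenotype():
    return PhenotypeVector(
        time_h=[24.0, 48.0, 60.0, 80.0],
        mu=[0.0708, 0.0053, 0.0010, 0.0031],
        q=[0.0041, 0.0524, 0.0724, 0.0004],
        dcw_g_l=[0.7, 1.2, 1.3, 1.25],
    )


class TestSimulateMetabolome:
    def test_row_count(self):
        design = SimulationDesign(n_metabolites=10, seed=0)
        table, _ = simulate_metabolome(simple_phenotype(), design)
        assert len(table.data) == 20  # 4 times x 5 replicates
        assert len(table.metabolites) == 10

    def test_null_model_near_constant(self):
        design = SimulationDesign(n_metabolites=5, noise_sd=1e-9, seed=0)
        table, _ = simulate_metabolome(simple_phenotype(), design)
        a_r = relative_abundance(table, table.data["time_h"].map(
            dict(zip([24.0, 48.0, 60.0, 80.0], [0.7, 1.2, 1.3, 1.25]))).to_numpy())
        rel_spread = a_r.std(axis=0, ddof=1) / a_r.mean(axis=0)
        assert (rel_spread < 1e-3).all()

    def test_positive_peak_areas(self):
        design = SimulationDesign(n_metabolites=20, seed=2)
        table, _ = simulate_metabolome(simple_phenotype(), design)
        assert (table.areas().to_numpy() > 0).all()
        assert (table.internal_standard_areas() > 0).all()

    def test_planted_positive_effect_correlates_with_mu(self):
        # Monte-Carlo: positive beta_g at 3x noise SD gives positive sample
        # correlation of A_r with mu in >= 95/100 seeds
        wins = 0
        phen = simple_phenotype()
        mu_by_time = dict(zip(phen.time_h, phen.mu))
        for s in range(100):
            design = SimulationDesign(
                n_metabolites=3, planted_effects=[(0, 0.45, 0.0)], noise_sd=0.15, seed=s
            )
            table, _ = simulate_metabolome(phen, design)
            dcw = table.data["time_h"].map(dict(zip(phen.time_h, phen.dcw_g_l))).to_numpy()
            a_r = relative_abundance(table, dcw)
            y = table.data["time_h"].map(mu_by_time).to_numpy()
            if np.corrcoef(a_r.iloc[:, 0], y)[0, 1] > 0:
                wins += 1
        assert wins >= 95

    def test_normalization_recovers_planted_matrix(self):
        # A_i = A_r * DCW * A_s by construction, so relative_abundance is exact
        design = SimulationDesign(n_metabolites=4, seed=5)
        phen = simple_phenotype()
        table, _ = simulate_metabolome(phen, design)
        dcw = table.data["time_h"].map(dict(zip(phen.time_h, phen.dcw_g_l))).to_numpy()
        a_r = relative_abundance(table, dcw).to_numpy()
        manual = table.areas().to_numpy() / (dcw * table.internal_standard_areas())[:, None]
        assert np.allclose(a_r, manual, rtol=1e-12)

    def test_determinism_and_substream_stability(self):
        phen = simple_phenotype()
        d_small = SimulationDesign(n_metabolites=5, seed=7)
        d_big = SimulationDesign(n_metabolites=8, seed=7)
        t1, _ = simulate_metabolome(phen, d_small)
        t2, _ = simulate_metabolome(phen, d_small)
        t3, _ = simulate_metabolome(phen, d_big)
        pd.testing.assert_frame_equal(t1.data, t2.data)
        # adding metabolites must not reshuffle existing columns
        for m in t1.metabolites:
            assert np.allclose(t1.data[m], t3.data[m])

    def test_single_sampling_time_rejected(self):
        phen = PhenotypeVector(time_h=[24.0], mu=[0.07], q=[0.004])
        design = SimulationDesign(sample_times_h=(24.0,), n_metabolites=3)
        with pytest.raises(ValueError, match="distinct sampling times"):
            simulate_metabolome(phen, design)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            SimulationDesign(n_replicates=1).validate()
        with pytest.raises(ValueError, match="noise_sd"):
            SimulationDesign(noise_sd=0.0).validate()
        with pytest.raises(ValueError, match="out of range"):
            SimulationDesign(n_metabolites=5, planted_effects=[(5, 1.0, 0.0)]).validate()

    def test_ground_truth_signs(self):
        design = SimulationDesign(
            n_metabolites=4, planted_effects=[(0, 0.5, 0.0), (1, 0.0, -0.5)], seed=0
        )
        _, truth = simulate_metabolome(simple_phenotype(), design)
        assert truth.effects["sign_g"].tolist() == [1, 0, 0, 0]
        assert truth.effects["sign_b"].tolist() == [0, -1, 0, 0]

    def test_effect_size_monotone_in_coefficient(self):
        # larger |beta| never decreases the mean |PLS coefficient| downstream
        phen = simple_phenotype()
        mu_by_time = dict(zip(phen.time_h, phen.mu))
        means = []
        for effect in (0.15, 0.45, 1.35):
            coefs = []
            for s in range(40):
                design = SimulationDesign(
                    n_metabolites=10, planted_effects=[(0, effect, 0.0)], noise_sd=0.15, seed=s
                )
                table, _ = simulate_metabolome(phen, design)
                a_r = relative_abundance(table, 1.0)
                y = table.data["time_h"].map(mu_by_time).to_numpy()
                model = fit_pls(a_r.to_numpy(), y, n_components=2)
                coefs.append(abs(model.coef_[0]))
            means.append(np.mean(coefs))
        assert means[0] <= means[1] <= means[2]


class TestMakePathwayLibrary:
    def setup_method(self):
        self.background = [f"C{i:05d}" for i in range(40)]
        self.pools = {"g+": self.background[:12], "b-": self.background[12:24]}

    def test_chain_graph_out_degrees(self):
        lib, _ = make_pathway_library({}, self.background, 1, size_range=(3, 3),
                                      graph_kind="chain", seed=0)
        degs = sorted(d for _, d in lib.pathways[0].graph.out_degree())
        assert degs == [0, 1, 1]

    def test_roundtrip(self, tmp_path):
        lib, _ = make_pathway_library(self.pools, self.background, 6,
                                      planted_type_assignment={0: "g+", 2: "b-"}, seed=4)
        lib.write_gmt(tmp_path / "x.gmt")
        lib.write_sif(tmp_path / "x.sif")
        from fermnet.pathways import PathwayLibrary

        back = PathwayLibrary.read(tmp_path / "x.gmt", tmp_path / "x.sif")
        for a, b in zip(lib, back):
            assert a.compounds == b.compounds and set(a.graph.edges) == set(b.graph.edges)

    def test_planted_fraction_honored(self):
        lib, planted = make_pathway_library(
            self.pools, self.background, 4, size_range=(5, 10),
            planted_type_assignment={0: "g+"}, seed=1
        )
        assert planted["path_000"] == "g+"
        p = lib.pathways[0]
        frac = len(p.compounds & set(self.pools["g+"])) / len(p.compounds)
        assert frac >= 0.6

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError, match="only"):
            make_pathway_library({"tiny": self.background[:2]}, self.background, 1,
                                 size_range=(10, 10), planted_type_assignment={0: "tiny"}, seed=0)

    def test_sizes_validated(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_pathway_library({}, self.background, 1, size_range=(1, 3))

    def test_dags_are_acyclic(self):
        import networkx as nx

        lib, _ = make_pathway_library({}, self.background, 8, seed=11)
        for p in lib:
            assert nx.is_directed_acyclic_graph(p.graph)

    def test_planted_fisher_example(self):
        # 8 hits from a size-10 pathway, query 20, background 97 -> p < 0.1
        from fermnet.pathways import ora_fisher

        assert ora_fisher(8, 20, 10, 97) < 0.1


def test_phenotype_roundtrip_tsv(tmp_path):
    phen = simple_phenotype()
    phen.to_tsv(tmp_path / "p.tsv")
    back = PhenotypeVector.from_tsv(tmp_path / "p.tsv")
    assert np.allclose(back.mu, phen.mu) and np.allclose(back.q, phen.q)
    assert np.allclose(back.dcw_g_l, phen.dcw_g_l)


def test_phenotype_at_reads_off_grid_times():
    tc = simulate_fermentation(seed=0)
    phen = phenotype_at(tc, [24.0, 48.0, 60.0, 80.0])
    assert phen.mu[0] > phen.mu[1] > 0  # log phase fastest
    assert phen.q[1] > phen.q[0]        # solventogenesis after onset
    with pytest.raises(ValueError, match="not on the time-course grid"):
        phenotype_at(tc, [24.5])
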