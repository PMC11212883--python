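"""Column construction, connectome rules, and the surrogate simulation."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from m1beta.config import (ConditionFlags, ConnectivityRule, CylinderGeometry,
                           E_POPULATIONS, default_config)
from m1beta.network import (border_correction_factor, connect, delay_ms,
                            place_neurons, population_counts, simulate)

DESK = default_config(scale=0.04)


@pytest.fixture(scope="module")
def desk_column():
    import warnings
    neurons = place_neurons(DESK, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # border correction may clamp p at 1
        edges = connect(neurons, DESK.rules, DESK.geometry, seed=2)
    return neurons, edges


class TestPlacement:
    def test_full_scale_total_count(self):
        counts = population_counts(default_config())
        assert counts["count"].sum() == 10_073

    def test_scale_proportionality(self):
        full = population_counts(default_config())["count"].sum()
        tenth = population_counts(default_config(scale=0.1))["count"].sum()
        assert tenth == pytest.approx(0.1 * full, rel=0.02)

    def test_zero_density_layer_is_empty(self):
        cfg = default_config()
        cfg.layers = {k: (replace(v, density_per_mm3=1e-9) if k == "L4" else v)
                      for k, v in cfg.layers.items()}
        counts = population_counts(cfg)
        assert "IT4" not in set(counts["population"])

    def test_positions_inside_cylinder_slices(self):
        cfg = default_config(scale=0.05)
        neurons = place_neurons(cfg, seed=3)
        rho = np.hypot(neurons["x_um"], neurons["z_um"])
        assert (rho <= cfg.geometry.radius_um + 1e-9).all()
        for layer, grp in neurons.groupby("layer"):
            lo, hi = cfg.geometry.layer_bounds_um[layer]
            assert grp["y_um"].between(lo, hi).all()

    def test_ratio_rules(self):
        counts = population_counts(default_config()).set_index("population")["count"]
        assert abs(counts["IT5B"] - counts["PT5B"]) <= 1
        assert abs(counts["IT6"] - counts["CT6"]) <= 1
        for pv, som in [("PV2/3", "SOM2/3"), ("PV5B", "SOM5B"), ("PV6", "SOM6")]:
            assert counts[pv] == pytest.approx(2 * counts[som], abs=2)

    def test_bad_boundaries_rejected(self):
        geo = CylinderGeometry(layer_bounds_um={"L1": (0.0, 100.0),
                                                "L2/3": (200.0, 1350.0)})
        with pytest.raises(ValueError, match="partition"):
            geo.validate()


class TestDelay:
    @pytest.mark.parametrize("d,expected", [(0.0, 2.0), (250.0, 2.5),
                                            (1000.0, 4.0)])
    def test_delay_formula(self, d, expected):
        assert delay_ms(d) == expected

    def test_all_edge_delays_follow_formula(self, desk_column):
        neurons, edges = desk_column
        pos = neurons.set_index("neuron_id")[["x_um", "y_um", "z_um"]]
        d = np.linalg.norm(pos.loc[edges["pre_id"]].to_numpy()
                           - pos.loc[edges["post_id"]].to_numpy(), axis=1)
        assert np.allclose(edges["delay_ms"], 2.0 + d / 500.0)
        assert (edges["delay_ms"] >= 2.0).all()


class TestConnect:
    def test_kernel_at_zero_distance_is_pcon(self):
        """Co-located pairs accepted at pcon (no correction)."""
        n = 4000
        neurons = pd.DataFrame({
            "neuron_id": np.arange(n), "population": ["A"] * (n // 2) + ["B"] * (n // 2),
            "layer": "L", "x_um": 0.0, "y_um": 0.0, "z_um": 0.0})
        rules = [ConnectivityRule("A", "B", 0.3, 0.5)]
        edges = connect(neurons, rules, CylinderGeometry(), seed=4,
                        apply_border_correction=False)
        rate = len(edges) / (n // 2) ** 2
        assert rate == pytest.approx(0.3, abs=0.01)

    def test_length_constant_recovered(self):
        """log-acceptance regression recovers lambda within 10%."""
        rng = np.random.default_rng(0)
        n = 340  # ~1.1e5 ordered candidate pairs
        neurons = pd.DataFrame({
            "neuron_id": np.arange(n), "population": "P", "layer": "L",
            "x_um": rng.uniform(-75, 75, n), "y_um": rng.uniform(0, 600, n),
            "z_um": rng.uniform(-75, 75, n)})
        edges = connect(neurons, [ConnectivityRule("P", "P", 0.8, 0.5)],
                        CylinderGeometry(), seed=1,
                        apply_border_correction=False)
        pos = neurons[["x_um", "y_um", "z_um"]].to_numpy()
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        accepted = np.zeros((n, n), bool)
        accepted[edges["pre_id"], edges["post_id"]] = True
        np.fill_diagonal(d, np.nan)
        ok = np.isfinite(d.ravel())
        bins = np.arange(0, 400, 25)
        idx = np.digitize(d.ravel()[ok], bins)
        acc = accepted.ravel()[ok]
        centers, rates = [], []
        for b in range(1, len(bins)):
            sel = idx == b
            if sel.sum() > 200 and acc[sel].mean() > 0:
                centers.append((bins[b - 1] + bins[b]) / 2)
                rates.append(acc[sel].mean())
        slope = np.polyfit(centers, np.log(rates), 1)[0]
        assert -1 / slope == pytest.approx(100.0, rel=0.10)

    def test_border_correction_at_wall_exceeds_center(self):
        geo = CylinderGeometry()
        tab = pd.DataFrame({"x_um": [0.0, geo.radius_um],
                            "z_um": [0.0, 0.0]})
        c = border_correction_factor(tab, geo, 100.0)
        assert c[1] > c[0] >= 1.0

    def test_dale_sign_of_projections(self, desk_column):
        """Excitatory populations emit only depolarizing projections,
        inhibitory only hyperpolarizing ones."""
        neurons, edges = desk_column
        pop_of = neurons.set_index("neuron_id")["population"]
        pre_pop = pop_of.loc[edges["pre_id"]].to_numpy()
        is_e = np.isin(pre_pop, E_POPULATIONS)
        assert set(edges.loc[is_e, "projection"]) <= {"exc"}
        assert set(edges.loc[~is_e, "projection"]) <= \
            {"pv", "som_e", "som_i"}


class TestSimulate:
    def test_zero_drive_zero_spikes(self, desk_column):
        neurons, edges = desk_column
        cfg = default_config(scale=0.04)
        cfg.drives = [replace(d, rate_range_hz=(0.0, 0.0)) for d in cfg.drives]
        res = simulate(cfg, 0.5, ConditionFlags(), seed=5,
                       neurons=neurons, edges=edges)
        assert res.spikes.n_spikes == 0

    def test_fixed_seed_identical_raster(self, desk_column):
        neurons, edges = desk_column
        a = simulate(DESK, 0.6, ConditionFlags(), seed=6,
                     neurons=neurons, edges=edges)
        b = simulate(DESK, 0.6, ConditionFlags(), seed=6,
                     neurons=neurons, edges=edges)
        assert np.array_equal(a.spikes.spike_times, b.spikes.spike_times)
        assert np.array_equal(a.spikes.spike_neuron_ids,
                              b.spikes.spike_neuron_ids)
        assert np.array_equal(a.currents_na, b.currents_na)

    def test_activated_state_raises_pt5b_rate(self, desk_column):
        """Doubling motor-thalamic drive (rest -> activated) increases the
        PT5B population rate on matched seeds."""
        from m1beta.metrics import firing_rates
        neurons, edges = desk_column
        rest = simulate(DESK, 1.5, ConditionFlags(activated=False), seed=7,
                        neurons=neurons, edges=edges)
        act = simulate(DESK, 1.5, ConditionFlags(activated=True), seed=7,
                       neurons=neurons, edges=edges)
        r = firing_rates(rest.spikes).set_index("population")["mean_rate"]
        a = firing_rates(act.spikes).set_index("population")["mean_rate"]
        assert a["PT5B"] > r["PT5B"]

    def test_emits_current_traces(self, desk_column):
        neurons, edges = desk_column
        res = simulate(DESK, 0.5, ConditionFlags(), seed=8,
                       neurons=neurons, edges=edges)
        assert res.currents_na.shape == (len(neurons), 500)
        assert np.isfinite(res.currents_na).all()
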