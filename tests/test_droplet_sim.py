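"""Generator behaviour: encapsulation, growth, transcription, readout."""

import numpy as np
import pytest
from scipy import stats

import emulsim as es
from emulsim.droplet_sim import encapsulate, grow, transcribe, ground_truth_frame
from emulsim.errors import ConfigError


def _single_cells(cfg, rng):
    cols = [c for c in encapsulate(cfg, rng) if c.founding_cells == 1]
    transcribe(cols, cfg, rng)
    return cols


class TestEncapsulate:
    def test_poisson_occupancy(self):
        cfg = es.SimConfig(seed=1, n_droplets=100_000)
        counts = np.array([c.founding_cells for c in encapsulate(cfg)])
        # empty fraction ~ exp(-0.1) = 0.9048
        assert np.mean(counts == 0) == pytest.approx(np.exp(-0.1), abs=0.005)
        # among occupied droplets, >=2 cells ~ 4.84% (conditional Poisson)
        occupied = counts[counts > 0]
        expected = (1 - np.exp(-0.1) - 0.1 * np.exp(-0.1)) / (1 - np.exp(-0.1))
        assert np.mean(occupied >= 2) == pytest.approx(expected, abs=0.01)

    def test_poisson_gof_chi2(self):
        # occupancy histogram passes a chi-square GOF against Poisson(0.1)
        # at alpha=0.01 for the large-droplet-count regime
        passes = 0
        for seed in range(5):
            cfg = es.SimConfig(seed=seed, n_droplets=20_000)
            counts = np.array([c.founding_cells for c in encapsulate(cfg)])
            obs = np.bincount(np.minimum(counts, 2), minlength=3)
            pmf = stats.poisson(0.1).pmf([0, 1])
            exp = np.array([pmf[0], pmf[1], 1 - pmf.sum()]) * counts.size
            p = stats.chisquare(obs, exp).pvalue
            passes += p > 0.01
        assert passes >= 4

    def test_zero_mean_all_empty(self):
        cfg = es.SimConfig(seed=2, n_droplets=500, mean_cells_per_droplet=0.0)
        assert all(c.founding_cells == 0 for c in encapsulate(cfg))

    def test_invalid_droplet_count(self):
        with pytest.raises(ConfigError):
            es.SimConfig(seed=0, n_droplets=-5)
        cfg = es.SimConfig(seed=0, n_droplets=0)
        with pytest.raises(ConfigError):
            encapsulate(cfg)


class TestEffectiveConcentration:
    @pytest.mark.parametrize(
        "volume_nl, cells, expected",
        [
            (5.9, 1, 169_491.5),   # the published ~170,000 cells/ml droplet
            (1.0, 1, 1_000_000.0),
            (11.4, 1, 87_719.3),
            (3.4, 1, 294_117.6),
        ],
    )
    def test_values(self, volume_nl, cells, expected):
        assert es.effective_concentration(volume_nl, cells) == pytest.approx(expected, rel=1e-4)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            es.effective_concentration(0.0)


class TestGrow:
    def test_deterministic_doubling(self):
        cfg = es.SimConfig(seed=3, n_droplets=1, mean_cells_per_droplet=0.0,
                           doubling_time_h=24.0, division_cv=0.0,
                           capacity_cells_per_nl=1e9)
        col = es.DropletColony(0, 1, 0, 1, ["a+/b-"], [False], _division_times=[24.0])
        rng = np.random.default_rng(0)
        grow([col], cfg, rng)
        grow([col], cfg, rng)
        assert col.cell_count == 4

    def test_divisions_per_founder_in_range(self):
        # 5.9 nl defaults: 2-4 divisions per founding cell by days 2-3
        cfg = es.SimConfig(seed=4, n_droplets=3000, days=3)
        rng = np.random.default_rng(4)
        cols = [c for c in encapsulate(cfg, rng) if c.founding_cells == 1]
        for day in (1, 2, 3):
            grow(cols, cfg, rng)
            if day >= 2:
                div = np.log2([c.cell_count for c in cols if c.cell_count > 0])
                assert 2.0 <= np.median(div) <= 4.0

    def test_capacity_forces_decline(self):
        # small droplet with capacity < 8 cells: day-3 count drops below day-2
        cfg = es.SimConfig(seed=5, n_droplets=1500, droplet_volume_nl=3.4,
                           capacity_cells_per_nl=1.1)
        rng = np.random.default_rng(5)
        cols = encapsulate(cfg, rng)
        totals = []
        for _ in range(3):
            grow(cols, cfg, rng)
            totals.append(sum(c.cell_count for c in cols))
        assert totals[2] < totals[1]
        assert any(not c.viable for c in cols if c.founding_cells > 0)

    def test_empty_droplets_pass_through(self):
        cfg = es.SimConfig(seed=6, n_droplets=10, mean_cells_per_droplet=0.0)
        cols = encapsulate(cfg)
        grow(cols, cfg)
        assert all(c.cell_count == 0 and c.day == 1 for c in cols)


class TestTranscribe:
    def test_exclusive_bursting_single_cells(self):
        # day-0 single cells: dominant variant carries >90% of hTERT molecules
        # in >=90% of hTERT-positive cells; under 25% of cells are burst-on
        cfg = es.SimConfig(seed=7, n_droplets=30_000)
        cols = _single_cells(cfg, np.random.default_rng(7))
        frac_on = np.mean([c.per_cell_bursting[0] for c in cols])
        assert frac_on < 0.25
        dominant_ok = total = 0
        for c in cols:
            mols = np.array([c.molecule_counts[v] for v in es.VARIANTS])
            if mols.sum() == 0:
                continue
            total += 1
            dominant_ok += mols.max() / mols.sum() > 0.9
        assert dominant_ok / total >= 0.9

    def test_at_most_one_variant_bursting(self):
        # with zero baseline every expressing cell carries a single variant
        cfg = es.SimConfig(seed=8, n_droplets=20_000, baseline_mean=0.0)
        for c in _single_cells(cfg, np.random.default_rng(8)):
            mols = np.array([c.molecule_counts[v] for v in es.VARIANTS])
            assert np.count_nonzero(mols) <= 1

    def test_no_burst_null_is_unimodal(self, target_map):
        # burst rates all zero: per-cell-normalised abundance of expressing
        # colonies stays at baseline leakage and the dip test does not reject
        # in >=90% of runs
        from conftest import simulate_gated
        from emulsim.abundance_stats import total_htert

        rates = dict.fromkeys(es.VARIANTS, 0.0)
        hits = 0
        for seed in range(10):
            cfg = es.SimConfig(seed=seed, n_droplets=2500, baseline_mean=0.5,
                               variant_burst_rates=rates)
            gated, _ = simulate_gated(cfg, [0], target_map)
            x = total_htert(gated).to_numpy()
            x = x[x > 0]
            hits += es.dip_test(x, b=200, rng=seed).p_value > 0.05
        assert hits >= 9

    def test_htr_variance_shrinks_with_colony_size(self, target_map):
        # per-cell hTR averages over more cells in larger colonies, so the
        # across-colony variance falls monotonically with size bin (sizes
        # span 1 to 4-8 cells across harvest days 0-2)
        cfg = es.SimConfig(seed=9, n_droplets=9000, days=2)
        _, truth = es.simulate_experiment(cfg, target_map, [0, 1, 2])
        truth = truth[truth["cell_count"] > 0]
        norm = truth["mol_hTR"] / truth["cell_count"]
        variances = []
        for lo, hi in ((1, 1), (2, 3), (4, 16)):
            sel = (truth["cell_count"] >= lo) & (truth["cell_count"] <= hi)
            assert sel.sum() > 50
            variances.append(norm[sel].var())
        assert variances[0] > variances[1] > variances[2]


class TestReadout:
    def test_zero_molecules_no_peak(self, target_map):
        cfg = es.SimConfig(seed=10, n_droplets=1)
        col = es.DropletColony(0, 1, 0, 1, ["a+/b-"], [False],
                               molecule_counts=dict.fromkeys(es.TARGETS, 0))
        peaks = es.readout([col], cfg, target_map)
        assert set(peaks["target"]) == {"size-standard"}

    def test_noiseless_area_scaling(self, target_map):
        cfg = es.SimConfig(seed=11, n_droplets=1, detection_prob=1.0,
                           area_noise_cv=0.0, area_per_molecule=100.0)
        counts = dict.fromkeys(es.TARGETS, 0)
        counts["a+/b-"] = 10
        col = es.DropletColony(0, 1, 0, 1, ["a+/b-"], [True], molecule_counts=counts)
        peaks = es.readout([col], cfg, target_map)
        row = peaks[peaks["target"] == "a+/b-"].iloc[0]
        assert row["area"] == pytest.approx(1000.0)

    def test_binomial_thinning_identity(self, target_map):
        # P(positive) = 1 - exp(-lambda d p_det) under Poisson input thinned
        # by the detection probability
        lam_d, p_det = 3.0, 0.4
        rng = np.random.default_rng(12)
        cfg = es.SimConfig(seed=12, n_droplets=1, detection_prob=p_det)
        hits = 0
        n_rep = 4000
        for _ in range(n_rep):
            mol = rng.poisson(lam_d)
            hits += rng.binomial(mol, p_det) > 0 if mol else 0
        expected = 1 - np.exp(-lam_d * p_det)
        assert hits / n_rep == pytest.approx(expected, abs=0.02)


class TestDilutionSeries:
    def test_zero_lambda_all_negative(self):
        s = es.simulate_dilution_series(0.0, [1, 0.5, 0.25], 18, rng=0)
        assert np.all(s.k == 0)

    @pytest.mark.parametrize("lam", [12.5, 0.16])
    def test_expected_positive_counts(self, lam):
        # mean positives over replicates ~ N(1 - exp(-lambda)) at d=1
        rng = np.random.default_rng(13)
        ks = [es.simulate_dilution_series(lam, [1.0], 18, rng).k[0] for _ in range(400)]
        expected = 18 * (1 - np.exp(-lam))
        assert np.mean(ks) == pytest.approx(expected, rel=0.05)

    def test_empty_dilutions_rejected(self):
        with pytest.raises(ConfigError):
            es.simulate_dilution_series(1.0, [], 18)
        with pytest.raises(ConfigError):
            es.simulate_dilution_series(1.0, [0.0, 1.0], 18)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self, target_map):
        cfg = dict(seed=42, n_droplets=400, days=2)
        p1, t1 = es.simulate_experiment(es.SimConfig(**cfg), target_map)
        p2, t2 = es.simulate_experiment(es.SimConfig(**cfg), target_map)
        assert p1.to_csv() == p2.to_csv()
        assert t1.to_csv() == t2.to_csv()
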