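import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cfmix import (
    call_diploid,
    component_calls,
    deconvolve,
    maf_spectrum,
    simulate_cfdna_mixture,
    simulate_mixture_reads,
    simulate_pedigree,
    split_major_minor,
)

# ---------------------------------------------------------------------------
# independent oracle: pure-python per-locus enumeration of all 3^k configs


def _log_binom(k, n, p):
    if p <= 0.0:
        return 0.0 if k == 0 else -math.inf
    if p >= 1.0:
        return 0.0 if k == n else -math.inf
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        + k * math.log(p) + (n - k) * math.log(1 - p)
    )


def _oracle_posterior(alt, n, weights, af, eps):
    """Posterior over genotype configs by direct enumeration with log-sum-exp."""
    hwe = [(1 - af) ** 2, 2 * af * (1 - af), af**2]
    logs = []
    for cfg in itertools.product((0, 1, 2), repeat=len(weights)):
        q = sum(w * g for w, g in zip(weights, cfg)) / 2.0
        p = q * (1 - eps) + (1 - q) * eps
        lp = _log_binom(alt, n, p) + sum(math.log(hwe[g]) for g in cfg)
        logs.append(lp)
    m = max(logs)
    norm = m + math.log(sum(math.exp(x - m) for x in logs))
    return [math.exp(x - norm) for x in logs]


def _fixture_depths(panel, weights, seed, depth=2500):
    ped = simulate_pedigree(panel, seed=seed)
    rows = ["bm_donor", "mother", "fetus"][: len(weights)]
    if len(weights) == 2:
        g = ped.genotypes.loc[["mother", "fetus"]]
    else:
        g = ped.genotypes.loc[rows]
    d = simulate_mixture_reads(g, weights, depth=depth, eps=0.005, seed=seed + 1)
    return ped, d


class TestOracleEquivalence:
    @pytest.mark.parametrize("weights", [(0.9064, 0.0936), (0.7264, 0.18, 0.0936)])
    def test_posterior_matches_enumeration_on_100_loci(self, default_panel, weights):
        ped, depths = _fixture_depths(default_panel, weights, seed=42)
        depths = depths.iloc[:100]
        af = default_panel.pop_af
        res = deconvolve(depths, weights, af, eps=0.005)
        for i, rid in enumerate(res.region_ids):
            alt = int(depths["alt_count"].iloc[i])
            n = alt + int(depths["ref_count"].iloc[i])
            expected = _oracle_posterior(alt, n, weights, float(af[rid]), 0.005)
            assert np.allclose(res.posterior[i], expected, atol=1e-9)
            assert res.map_index[i] == int(np.argmax(expected))

    def test_zero_alt_zero_eps_calls_all_reference(self, default_panel):
        d = pd.DataFrame(
            {"ref_count": [2500], "alt_count": [0]},
            index=pd.Index([default_panel.snp_ids[0]], name="region_id"),
        )
        res = deconvolve(d, (0.9064, 0.0936), default_panel.pop_af, eps=0.0)
        assert tuple(res.map_configs[0]) == (0, 0)

    def test_low_alt_fraction_assigns_alt_to_minor(self, default_panel):
        # 117/2500 = 0.047 sits at the q of a het minor component (0.0936/2)
        rid = default_panel.snp_ids[0]
        d = pd.DataFrame(
            {"ref_count": [2500 - 117], "alt_count": [117]},
            index=pd.Index([rid], name="region_id"),
        )
        af = pd.Series({rid: 0.3})
        res = deconvolve(d, (0.9064, 0.0936), af, eps=0.005)
        expected = _oracle_posterior(117, 2500, (0.9064, 0.0936), 0.3, 0.005)
        assert res.map_index[0] == int(np.argmax(expected))
        assert tuple(res.map_configs[0]) == (0, 1)


class TestContracts:
    def test_zero_weight_component_rejected(self, default_panel):
        d = pd.DataFrame({"ref_count": [10], "alt_count": [0]},
                         index=pd.Index([default_panel.snp_ids[0]], name="region_id"))
        with pytest.raises(ValueError, match="unidentifiable"):
            deconvolve(d, (1.0, 0.0), default_panel.pop_af)

    def test_zero_coverage_emitted_as_missing(self, default_panel):
        ids = default_panel.snp_ids[:2]
        d = pd.DataFrame({"ref_count": [0, 100], "alt_count": [0, 5]},
                         index=pd.Index(ids, name="region_id"))
        res = deconvolve(d, (0.9, 0.1), default_panel.pop_af)
        assert res.map_index[0] == -1
        assert np.isnan(res.posterior[0]).all()
        assert res.map_index[1] >= 0

    def test_posterior_rows_sum_to_one(self, default_panel):
        ped, depths = _fixture_depths(default_panel, (0.7264, 0.18, 0.0936), seed=3)
        res = deconvolve(depths, (0.7264, 0.18, 0.0936), default_panel.pop_af)
        ok = res.map_index >= 0
        assert np.allclose(res.posterior[ok].sum(axis=1), 1.0, atol=1e-9)


class TestMajorMinorSplit:
    def test_equal_weights_rejected(self, default_panel):
        ped, depths = _fixture_depths(default_panel, (0.5, 0.5), seed=5)
        res = deconvolve(depths, (0.5, 0.5), default_panel.pop_af)
        with pytest.raises(ValueError, match="equal weight"):
            split_major_minor(res, "s")

    def test_major_labels_larger_component(self, default_panel):
        ped, depths = _fixture_depths(default_panel, (0.18, 0.82), seed=6, depth=100_000)
        res = deconvolve(depths, (0.18, 0.82), default_panel.pop_af, eps=0.005)
        rows = split_major_minor(res, "W004", posterior_floor=0.9)
        assert list(rows.index) == ["W004major", "W004minor"]
        # the 0.82 component is the fetus row of the fixture
        fetus = ped.genotypes.loc["fetus"]
        called = rows.loc["W004major"].notna()
        assert (rows.loc["W004major"][called] == fetus[called]).mean() > 0.99

    def test_noiseless_deep_split_recovers_sources(self, default_panel):
        ped = simulate_pedigree(default_panel, seed=7)
        g = ped.genotypes.loc[["mother", "fetus"]]
        d = simulate_mixture_reads(g, (0.9, 0.1), depth=100_000, eps=0.0, seed=8)
        res = deconvolve(d, (0.9, 0.1), default_panel.pop_af, eps=0.0)
        rows = split_major_minor(res, "s", posterior_floor=0.9)
        maj, mino = rows.loc["smajor"], rows.loc["sminor"]
        called = maj.notna()
        assert called.mean() > 0.95
        assert (maj[called] == ped.genotypes.loc["mother"][called]).all()
        assert (mino[called] == ped.genotypes.loc["fetus"][called]).all()

    def test_ptg_degenerate_case_reproduces_maternal_genotype(self, default_panel):
        # standard pregnancy (no transplant): major calls = maternal genome
        ped = simulate_pedigree(default_panel, seed=9)
        g = ped.genotypes.loc[["mother", "fetus"]]
        f = 0.0936
        d = simulate_mixture_reads(g, (1 - f, f), depth=2500, eps=0.005, seed=10)
        res = deconvolve(d, (1 - f, f), default_panel.pop_af, eps=0.005)
        rows = split_major_minor(res, "s", posterior_floor=0.9)
        maj = rows.loc["smajor"]
        called = maj.notna()
        assert (maj[called] == ped.genotypes.loc["mother"][called]).mean() > 0.99

    def test_all_below_floor_gives_all_missing(self, default_panel):
        ids = default_panel.snp_ids[:3]
        d = pd.DataFrame({"ref_count": [0, 0, 0], "alt_count": [0, 0, 0]},
                         index=pd.Index(ids, name="region_id"))
        res = deconvolve(d, (0.9, 0.1), default_panel.pop_af)
        rows = split_major_minor(res, "s")
        assert rows.isna().all().all()


class TestThreeComponentConcordance:
    def test_major_component_beats_minor_and_depth_monotonicity(self, default_panel):
        w = (0.7264, 0.18, 0.0936)
        conc = {2500: [], 500: [], 100: []}
        conc_c = []
        for seed in range(5):
            ped = simulate_pedigree(default_panel, seed=seed)
            truth = ped.genotypes.loc[["bm_donor", "mother", "fetus"]].to_numpy()
            for depth in conc:
                d = simulate_cfdna_mixture(ped, w, depth=depth, eps=0.005,
                                           seed=seed + depth)
                res = deconvolve(d, w, default_panel.pop_af, eps=0.005)
                ok = res.map_index >= 0
                cfg = res.map_configs
                a = (cfg[ok, 0] == truth[0, ok]).mean()
                if depth == 2500:
                    conc_c.append((cfg[ok, 2] == truth[2, ok]).mean())
                conc[depth].append(a)
        means = {d: np.mean(v) for d, v in conc.items()}
        assert means[2500] > 0.95
        assert means[2500] >= means[500] >= means[100]
        # identifiability decreases with component fraction: A beats C
        assert means[2500] > np.mean(conc_c)

    def test_component_calls_rows(self, default_panel):
        ped, depths = _fixture_depths(default_panel, (0.7264, 0.18, 0.0936), seed=11)
        res = deconvolve(depths, (0.7264, 0.18, 0.0936), default_panel.pop_af)
        rows = component_calls(res, "p", posterior_floor=0.9)
        assert list(rows.index) == ["p.c1", "p.c2", "p.c3"]
        called = rows.loc["p.c1"].notna()
        donor = ped.genotypes.loc["bm_donor"]
        assert (rows.loc["p.c1"][called] == donor[called]).mean() > 0.99


class TestDiploidCalling:
    def test_calls_match_truth_at_depth(self, default_panel):
        ped = simulate_pedigree(default_panel, seed=12)
        from cfmix import simulate_gdna_reads

        d = simulate_gdna_reads(ped.genotypes.loc["father"], depth=2500,
                                eps=0.005, seed=13)
        calls = call_diploid(d, default_panel.pop_af, eps=0.005)
        called = calls.notna()
        assert called.mean() > 0.99
        assert (calls[called] == ped.genotypes.loc["father"][called]).all()


class TestMAFSpectrum:
    def test_single_genome_stays_in_bands(self, default_panel):
        ped = simulate_pedigree(default_panel, seed=14)
        from cfmix import simulate_gdna_reads

        d = simulate_gdna_reads(ped.genotypes.loc["fetus"], depth=2500,
                                eps=0.005, seed=15)
        sp = maf_spectrum(d, min_depth=100, delta=0.1)
        assert sp.band_deviation < 0.01

    def test_three_way_mixture_leaves_bands(self, default_panel):
        ped = simulate_pedigree(default_panel, seed=16)
        d = simulate_cfdna_mixture(ped, (0.7264, 0.18, 0.0936), depth=2500,
                                   eps=0.005, seed=17)
        sp = maf_spectrum(d, min_depth=100, delta=0.1)
        assert sp.band_deviation > 0.1

    def test_wide_bands_cover_everything(self, default_panel):
        ped = simulate_pedigree(default_panel, seed=18)
        d = simulate_cfdna_mixture(ped, (0.7264, 0.18, 0.0936), depth=2500,
                                   eps=0.005, seed=19)
        sp = maf_spectrum(d, min_depth=100, delta=0.2499)
        assert sp.band_deviation < 0.01

    def test_no_covered_locus_is_an_error(self, default_panel):
        ids = default_panel.snp_ids[:2]
        d = pd.DataFrame({"ref_count": [1, 2], "alt_count": [0, 1]},
                         index=pd.Index(ids, name="region_id"))
        with pytest.raises(ValueError, match="min_depth"):
            maf_spectrum(d, min_depth=100)
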