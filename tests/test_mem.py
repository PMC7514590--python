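import numpy as np
import pytest

from gazemem import (
    ApEnParams,
    DataError,
    EMSeries,
    MemSpec,
    MultilevelEntropyMap,
    apen_auto,
    average_mems,
    build_mem,
    render_mem,
    value_band,
)
from oracles import mean_sd_bruteforce

SMALL = MemSpec(nemr=256, nss=64, levels=3)


def _noise_map(rng, spec=SMALL, **kwargs):
    return build_mem(rng.normal(size=spec.nemr), spec, **kwargs)


class TestMemSpec:
    def test_default_level_geometry(self):
        spec = MemSpec()
        assert [spec.n_segments(l) for l in range(1, 7)] == [32, 16, 8, 4, 2, 1]
        assert [spec.segment_size(l) for l in range(1, 7)] == [
            64, 128, 256, 512, 1024, 2048,
        ]
        assert spec.total_cells == 63

    def test_incoherent_spec_rejected(self):
        with pytest.raises(DataError):
            MemSpec(nemr=2048, nss=64, levels=5)

    def test_level_for_size(self):
        assert MemSpec().level_for_size(256) == 3
        with pytest.raises(DataError):
            MemSpec().level_for_size(100)


class TestBuildMem:
    def test_constant_series_all_zero_and_degenerate(self):
        mem = build_mem(np.zeros(SMALL.nemr), SMALL)
        for level in range(SMALL.levels):
            assert not mem.values[level].any()
            assert mem.degenerate[level].all()

    def test_cells_equal_apen_of_slices(self, rng):
        v = rng.normal(size=SMALL.nemr)
        params = ApEnParams()
        mem = build_mem(v, SMALL, params)
        for level in range(1, SMALL.levels + 1):
            w = SMALL.segment_size(level)
            for seg in range(1, SMALL.n_segments(level) + 1):
                expected, _ = apen_auto(v[(seg - 1) * w : seg * w], params)
                assert mem.cell(level, seg) == expected

    def test_global_policy_uses_full_series_sd(self, rng):
        v = rng.normal(size=SMALL.nemr)
        params = ApEnParams(r_policy="global")
        mem = build_mem(v, SMALL, params)
        sd = np.std(v, ddof=1)
        expected, _ = apen_auto(v[:64], params, global_sd=sd)
        assert mem.cell(1, 1) == expected

    def test_deterministic_bit_identical(self, rng):
        v = rng.normal(size=SMALL.nemr)
        m1, m2 = build_mem(v, SMALL), build_mem(v, SMALL)
        for a, b in zip(m1.values, m2.values):
            np.testing.assert_array_equal(a, b)

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(DataError, match="length"):
            build_mem(rng.normal(size=100), SMALL)

    def test_provenance_from_em_series(self, rng):
        s = EMSeries("p01", "s1", 4, rng.normal(size=SMALL.nemr), 1000.0)
        mem = build_mem(s, SMALL)
        assert mem.provenance == {
            "participant_id": "p01", "session_id": "s1", "stimulus_index": 4,
        }

    def test_dyadic_nesting_of_windows(self):
        df = build_mem(np.random.default_rng(0).normal(size=SMALL.nemr), SMALL).to_dataframe()
        for level in range(1, SMALL.levels):
            fine = df[df.level == level].reset_index(drop=True)
            coarse = df[df.level == level + 1].reset_index(drop=True)
            for _, row in coarse.iterrows():
                children = fine[
                    (fine.start_sample >= row.start_sample)
                    & (fine.end_sample <= row.end_sample)
                ]
                assert len(children) == 2
                assert children.start_sample.min() == row.start_sample
                assert children.end_sample.max() == row.end_sample


class TestAverageMems:
    def test_identical_maps_mean_equals_input_sd_zero(self, rng):
        m = _noise_map(rng)
        mean, sd = average_mems([m, m])
        for level in range(SMALL.levels):
            np.testing.assert_array_equal(mean.values[level], m.values[level])
            np.testing.assert_array_equal(sd.values[level], 0.0 * sd.values[level])

    def test_two_cell_values_average_arithmetically(self):
        spec = MemSpec(nemr=128, nss=64, levels=2)
        def with_first_cell(x):
            values = [np.array([x, 0.5]), np.array([0.6])]
            flags = [np.zeros(2, bool), np.zeros(1, bool)]
            return MultilevelEntropyMap(spec, values, flags)
        mean, _ = average_mems([with_first_cell(0.2), with_first_cell(0.4)])
        assert mean.cell(1, 1) == pytest.approx(0.3)

    def test_matches_accumulation_oracle(self, rng):
        maps = [_noise_map(rng) for _ in range(12)]
        mean, sd = average_mems(maps)
        for level in range(SMALL.levels):
            means, sds = mean_sd_bruteforce([m.values[level].tolist() for m in maps])
            np.testing.assert_allclose(mean.values[level], means, atol=1e-12)
            np.testing.assert_allclose(sd.values[level], sds, atol=1e-12)

    def test_mixed_specs_and_empty_list_rejected(self, rng):
        a = _noise_map(rng)
        b = build_mem(rng.normal(size=128), MemSpec(nemr=128, nss=64, levels=2))
        with pytest.raises(DataError):
            average_mems([a, b])
        with pytest.raises(DataError):
            average_mems([])

    def test_exclude_degenerate_option(self):
        spec = MemSpec(nemr=128, nss=64, levels=2)
        degen = MultilevelEntropyMap(
            spec,
            [np.array([0.0, 0.4]), np.array([0.6])],
            [np.array([True, False]), np.array([False])],
        )
        live = MultilevelEntropyMap(
            spec,
            [np.array([0.8, 0.4]), np.array([0.6])],
            [np.zeros(2, bool), np.zeros(1, bool)],
        )
        mean_incl, _ = average_mems([degen, live])
        mean_excl, _ = average_mems([degen, live], exclude_degenerate=True)
        assert mean_incl.cell(1, 1) == pytest.approx(0.4)
        assert mean_excl.cell(1, 1) == pytest.approx(0.8)


class TestSerializationAndRendering:
    def test_json_roundtrip(self, rng, tmp_path):
        m = _noise_map(rng)
        path = tmp_path / "m.json"
        m.save_json(path)
        back = MultilevelEntropyMap.load_json(path)
        assert back.spec == m.spec
        for a, b in zip(back.values, m.values):
            np.testing.assert_array_equal(a, b)
        assert back.provenance == m.provenance

    @pytest.mark.parametrize(
        "value,band",
        [
            (0.35, "green"),
            (0.4, "brown"),       # bands are left-closed
            (0.55, "blue"),
            (0.65, "light violet"),
            (0.75, "light burgundy"),
            (0.85, "light gray"),
            (0.95, "dark gray"),
            (1.0, "red"),
            (1.2, "red"),
        ],
    )
    def test_value_bands(self, value, band):
        assert value_band(value) == band

    def test_render_writes_figure_and_numeric_map(self, rng, tmp_path):
        m = _noise_map(rng)
        out = tmp_path / "map.png"
        render_mem(m, out)
        assert out.exists()
        assert (tmp_path / "map.csv").exists()
        assert (tmp_path / "map.json").exists()
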