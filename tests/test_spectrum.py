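import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import simulate_sample
from lesionmux.extract import PASS, extract_observations
from lesionmux.simulate import PRESETS
from lesionmux.spectrum import SpectrumResult, aggregate, miscoding, pileup


@pytest.fixture(scope="module")
def clean_sample(tmp_path_factory, txg_lesion_mix):
    """Error-free, well-formed sample: pileup should be pure template."""
    td = tmp_path_factory.mktemp("clean")
    _, run = simulate_sample(txg_lesion_mix, td, n_read_pairs=500, seed=13,
                             substitution_error_rate=0.0,
                             malformed_insert_fraction=0.0)
    layouts = [l for l, _, _ in txg_lesion_mix]
    obs = extract_observations(run.r1_path, run.r2_path, layouts)
    return obs, layouts[0]


class TestPileup:
    def test_depth_equals_pass_at_covered_positions(self, clean_sample):
        obs, layout = clean_sample
        table = pileup(obs, layout)
        n_pass = int((obs["status"] == PASS).sum())
        assert n_pass == 500
        assert (table["depth"] == n_pass).all()
        # covered ROI positions = insert positions inside the ROI
        lo, hi = layout.region_of_interest
        expected = set(range(max(lo, layout.insert_start),
                             min(hi, layout.insert_end) + 1))
        assert set(table.index.get_level_values("coordinate")) == expected

    def test_non_lesion_positions_are_pure_template(self, clean_sample):
        obs, layout = clean_sample
        table = pileup(obs, layout)
        tmpl = layout.insert_template
        for (_, coord), row in table.iterrows():
            if coord == layout.lesion_coordinate:
                continue
            base = tmpl[coord - layout.insert_start]
            assert row[base] == row["depth"]

    def test_lesion_column_counts(self, clean_sample):
        obs, layout = clean_sample
        # overwrite lesion bases to a known 97 T / 3 A composition
        obs = obs.copy()
        idx = obs.index[obs["status"] == PASS][:100]
        li = layout.lesion_insert_index
        for rank, i in enumerate(idx):
            base = "A" if rank < 3 else "T"
            s = obs.at[i, "insert_seq"]
            obs.at[i, "insert_seq"] = s[:li] + base + s[li + 1:]
        table = pileup(obs.loc[idx], layout)
        at = table.xs(layout.lesion_coordinate, level="coordinate").iloc[0]
        assert (at["A"], at["C"], at["G"], at["T"]) == (3, 0, 0, 97)

    def test_empty_observations_warn_not_fail(self, clean_sample):
        obs, layout = clean_sample
        with pytest.warns(UserWarning, match="no PASS"):
            table = pileup(obs.iloc[0:0], layout)
        assert table.empty

    def test_sequencing_error_rate_recovered(self, txg_lesion_mix,
                                             tmp_path):
        """Pooled non-template fraction at non-lesion 16-mer positions
        matches the configured substitution rate (the overlap consensus
        passes R1 through at constant quality, so R1's error rate is what
        survives)."""
        rate = 0.001
        _, run = simulate_sample(txg_lesion_mix, tmp_path,
                                 n_read_pairs=20_000, seed=37,
                                 substitution_error_rate=rate,
                                 malformed_insert_fraction=0.0)
        layouts = [l for l, _, _ in txg_lesion_mix]
        obs = extract_observations(run.r1_path, run.r2_path, layouts)
        layout = layouts[0]
        table = pileup(obs, layout)
        tmpl = layout.insert_template
        non_tmpl = 0
        total = 0
        for (_, coord), row in table.iterrows():
            if coord == layout.lesion_coordinate:
                continue
            if coord < layout.insert_start + 18:
                continue  # barcode region: errors there were demux-rejected
            base = tmpl[coord - layout.insert_start]
            non_tmpl += row["depth"] - row[base]
            total += row["depth"]
        p_hat = non_tmpl / total
        se = np.sqrt(rate * (1 - rate) / total)
        assert abs(p_hat - rate) <= 3 * se


class TestMiscoding:
    def test_mostly_mutant_counts(self):
        s = SpectrumResult(counts={"A": 3, "T": 97}, lesion="oxoeA")
        assert s.mutation_frequency == pytest.approx(0.97)
        assert s.mutant_shares["T"] == pytest.approx(1.0)
        assert sum(s.fractions.values()) == pytest.approx(1.0)
        assert sum(s.mutant_shares.values()) == pytest.approx(1.0)

    def test_all_reference_is_zero_frequency(self):
        s = SpectrumResult(counts={"A": 50})
        assert s.mutation_frequency == 0.0
        assert s.mutant_shares == {}

    def test_zero_depth_flagged_not_fatal(self, clean_sample):
        obs, layout = clean_sample
        table = pileup(obs, layout)
        with pytest.warns(UserWarning, match="no coverage"):
            s = miscoding(table, layout.lesion_coordinate,
                          construct_id="not_present")
        assert s.no_coverage
        assert s.mutation_frequency is None

    def test_miscoding_from_pileup(self, clean_sample):
        obs, layout = clean_sample
        table = pileup(obs, layout)
        s = miscoding(table, layout.lesion_coordinate,
                      construct_id=layout.construct_id, lesion="oxoeA",
                      context=layout.context)
        assert s.depth == 500
        assert s.mutation_frequency is not None


class TestAggregate:
    def test_two_replicates_pool_depth_weighted(self):
        r1 = SpectrumResult(counts={"A": 3, "T": 97}, lesion="oxoeA")
        r2 = SpectrumResult(counts={"A": 5, "T": 95}, lesion="oxoeA")
        pooled = aggregate([r1, r2])
        assert pooled.fractions["T"] == pytest.approx(0.96)
        assert pooled.depth == 200

    def test_single_group_identity(self):
        r = SpectrumResult(counts={"A": 3, "T": 97}, lesion="oxoeA")
        pooled = aggregate([r])
        assert pooled.counts == r.counts
        assert pooled.fractions == r.fractions

    def test_mixed_lesion_identities_refused(self):
        r1 = SpectrumResult(counts={"A": 90, "T": 10}, lesion="A")
        r2 = SpectrumResult(counts={"A": 3, "T": 97}, lesion="oxoeA")
        with pytest.raises(ValueError, match="lesion identities"):
            aggregate([r1, r2])
        pooled = aggregate([r1, r2], allow_mixed_lesion=True)
        assert pooled.depth == 200

    @given(tables=st.lists(
        st.tuples(st.integers(0, 500), st.integers(0, 500),
                  st.integers(0, 500), st.integers(1, 500)),
        min_size=2, max_size=6))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_pooling_is_order_independent_and_associative(self, tables):
        spectra = [SpectrumResult(counts=dict(zip("ACGT", t)),
                                  lesion="oxoeA") for t in tables]
        direct = aggregate(spectra)
        reversed_ = aggregate(list(reversed(spectra)))
        nested = aggregate([aggregate(spectra[:1]),
                            aggregate(spectra[1:])])
        for other in (reversed_, nested):
            assert other.counts == direct.counts
            assert other.fractions == direct.fractions

    def test_pool_mixture_closed_form(self):
        """Pooling the 16-context presets at equal depth reproduces the
        analytic mixture: lesion->T share among mutants ~ 0.986."""
        depth = 1_000_000
        gxn = {"GXC", "GXG", "GXT"}
        contexts = [a + "X" + b for a in "ACGT" for b in "ACGT"]
        spectra = []
        p_default = PRESETS["oxoeA_pool_default"].probs
        p_gxn = PRESETS["oxoeA_pool_GXC_GXG_GXT"].probs
        for ctx in contexts:
            p = p_gxn if ctx in gxn else p_default
            spectra.append(SpectrumResult(
                counts=dict(zip("ACGT", p * depth)), lesion="oxoeA",
                context=ctx))
        pooled = aggregate(spectra)
        expected_ft = (13 * p_default[3] + 3 * p_gxn[3]) / 16
        expected_fa = (13 * p_default[0] + 3 * p_gxn[0]) / 16
        expected_share = expected_ft / (1 - expected_fa)
        share = pooled.mutant_shares["T"]
        assert share == pytest.approx(expected_share, abs=1e-12)
        assert share == pytest.approx(0.9859, abs=5e-4)
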