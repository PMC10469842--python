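"""Unit and property tests of the density-shift -> AFE estimation chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualqsip import (
    CARBON_13,
    NITROGEN_15,
    FractionRecord,
    atom_fraction_excess,
    estimate_afe_table,
    filter_enriched,
    gc_from_wad,
    molecular_weights,
    normalize_afe,
    weighted_abundance,
    weighted_average_density,
)
from dualqsip.qsip import AfeEstimate, validate_sample


class TestWeightedAbundance:
    @pytest.mark.parametrize(
        "counts,total,conc,expected",
        [
            (50, 100, 2.0, 1.0),
            (0, 100, 2.0, 0.0),
            (30, 120, 0.8, 0.2),  # direct arithmetic: 0.25 * 0.8
            (0, 0, 1.5, 0.0),  # empty fraction contributes nothing
        ],
    )
    def test_values(self, counts, total, conc, expected):
        assert weighted_abundance(counts, total, conc) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weighted_abundance(-1, 100, 1.0)
        with pytest.raises(ValueError):
            weighted_abundance(1, 100, -1.0)


class TestWad:
    @pytest.mark.parametrize(
        "dens,y,expected",
        [
            ((1.70, 1.72, 1.74), (1, 2, 1), 1.72),
            ((1.70, 1.74), (1, 0), 1.70),
            ((1.70, 1.72, 1.74), (1, 1, 2), 1.725),  # hand-evaluated weighted mean
        ],
    )
    def test_values(self, dens, y, expected):
        assert weighted_average_density(np.array(y), np.array(dens)) == pytest.approx(
            expected
        )

    def test_all_zero_profile_has_no_wad(self):
        with pytest.raises(ValueError, match="no WAD"):
            weighted_average_density(np.zeros(3), np.array([1.70, 1.72, 1.74]))

    @settings(deadline=None)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        y=st.lists(st.floats(min_value=0, max_value=10), min_size=3, max_size=9),
    )
    def test_invariant_to_uniform_rescaling(self, scale, y):
        y = np.array(y)
        if y.sum() == 0:
            return
        dens = np.linspace(1.67, 1.78, y.size)
        assert weighted_average_density(y, dens) == pytest.approx(
            weighted_average_density(scale * y, dens), rel=1e-9
        )

    def test_wad_bounded_by_density_range(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            y = rng.random(9)
            dens = np.linspace(1.665, 1.784, 9)
            wad = weighted_average_density(y, dens)
            assert dens[0] <= wad <= dens[-1]


class TestGcFromWad:
    @pytest.mark.parametrize(
        "wad,expected",
        [
            (1.709, 0.5),
            (1.66, 0.0),
            (1.7257, 0.670408163265307),  # direct formula evaluation
        ],
    )
    def test_values(self, wad, expected):
        gc, clamped = gc_from_wad(wad, CARBON_13)
        assert gc == pytest.approx(expected)
        assert not clamped

    def test_inverse_of_schildkraut_map(self):
        for gc_true in np.linspace(0.0, 1.0, 11):
            wad = 1.66 + 0.098 * gc_true
            gc, _ = gc_from_wad(wad, CARBON_13)
            assert gc == pytest.approx(gc_true, abs=1e-12)

    def test_out_of_range_clamped_and_flagged(self):
        gc, clamped = gc_from_wad(1.63, CARBON_13)
        assert gc == 0.0 and clamped
        gc, clamped = gc_from_wad(1.80, CARBON_13)
        assert gc == 1.0 and clamped


class TestMolecularWeights:
    def test_light_weight(self):
        m_light, _ = molecular_weights(0.5, CARBON_13)
        assert m_light == pytest.approx(307.939)

    def test_heavy_max_13c(self):
        # step-by-step: 307.939 + 9.974564 - 0.4987282 * 0.5
        _, m_heavy = molecular_weights(0.5, CARBON_13)
        assert m_heavy == pytest.approx(317.6641999)

    def test_heavy_max_15n(self):
        # step-by-step: 307.691 + 3.517396 at GC 0
        _, m_heavy = molecular_weights(0.0, NITROGEN_15)
        assert m_heavy == pytest.approx(311.208396)

    def test_gc_out_of_range(self):
        with pytest.raises(ValueError):
            molecular_weights(1.2, CARBON_13)


class TestAtomFractionExcess:
    def test_zero_shift_is_zero(self):
        assert atom_fraction_excess(1.709, 1.709, CARBON_13) == 0.0

    def test_full_labeling_limit(self):
        # labeled WAD placed so m_lab = m_heavymax -> AFE = 1 - a
        m_light, m_heavy = molecular_weights(0.5, CARBON_13)
        wad_lab = 1.709 * m_heavy / m_light
        afe = atom_fraction_excess(1.709, wad_lab, CARBON_13)
        assert afe == pytest.approx(1.0 - 0.01111233)
        assert afe == pytest.approx(0.98889, abs=1e-5)

    def test_known_shift(self):
        # gc 0.5, density shift +0.018 g/mL, 13C; closed-form chain
        # evaluated step by step: 0.32979461681797995
        afe = atom_fraction_excess(1.709, 1.727, CARBON_13)
        assert afe == pytest.approx(0.32979461681797995, abs=1e-12)

    @settings(deadline=None)
    @given(shifts=st.lists(st.floats(min_value=0, max_value=0.05), min_size=2, max_size=6))
    def test_strictly_increasing_in_labeled_wad(self, shifts):
        # quantize so successive shifts are resolvable in float64 densities
        shifts = sorted({round(s, 6) for s in shifts})
        if len(shifts) < 2:
            return
        afes = [atom_fraction_excess(1.709, 1.709 + s, CARBON_13) for s in shifts]
        assert all(b > a for a, b in zip(afes, afes[1:]))


class TestNormalizeAndFilter:
    @pytest.mark.parametrize(
        "raw,expected", [(1.02, 0.99), (0.50, 0.50), (-0.01, -0.01)]
    )
    def test_cap_binds_only_above(self, raw, expected):
        assert normalize_afe(raw, CARBON_13) == expected

    def test_filter_threshold(self):
        def est(v):
            return AfeEstimate("x", "13C", v, v, v > 0.10, 0.5, 1.709, 1.72)

        kept = filter_enriched([est(0.05), est(0.101), est(0.40)], CARBON_13)
        assert len(kept) == 2
        assert filter_enriched([est(0.10)], CARBON_13) == []  # strict inequality
        assert filter_enriched([], CARBON_13) == []


def _records(sample_id, counts_by_fraction, densities, conc=2.0):
    return [
        FractionRecord(sample_id, i + 1, d, conc, c)
        for i, (d, c) in enumerate(zip(densities, counts_by_fraction))
    ]


class TestEstimateAfeTable:
    densities = [1.68, 1.70, 1.72, 1.74, 1.76]

    def test_self_comparison_null(self):
        """A table compared against itself yields zero AFE, zero retained."""
        rng = np.random.default_rng(0)
        counts = [
            {f"t{j}": int(rng.integers(0, 500)) for j in range(5)} for _ in range(5)
        ]
        lab = _records("s1", counts, self.densities)
        unl = _records("s2", counts, self.densities)
        estimates, _ = estimate_afe_table(lab, unl, CARBON_13)
        assert len(estimates) == 5
        assert all(abs(e.afe_raw) < 1e-12 for e in estimates)
        assert not any(e.retained for e in estimates)

    def test_one_sided_taxon_goes_to_skip_report(self):
        lab = _records("s1", [{"a": 10, "b": 5}, {"a": 3}], [1.70, 1.72])
        unl = _records("s2", [{"a": 8}, {"a": 6}], [1.70, 1.72])
        estimates, skips = estimate_afe_table(lab, unl, CARBON_13)
        assert [e.taxon_id for e in estimates] == ["a"]
        assert ("b", "present in labeled sample only") in skips.rows

    def test_no_overlap_gives_empty_result(self):
        lab = _records("s1", [{"a": 10}], [1.70])
        unl = _records("s2", [{"b": 10}], [1.70])
        estimates, skips = estimate_afe_table(lab, unl, CARBON_13)
        assert estimates == []
        assert len(skips.rows) == 2

    def test_density_monotonicity_enforced(self):
        recs = _records("s1", [{"a": 1}, {"a": 1}], [1.72, 1.70])
        with pytest.raises(ValueError, match="strictly increasing"):
            validate_sample(recs)
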