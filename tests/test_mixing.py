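import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rhizotransfer.mixing import (
    CLIPPED_HIGH,
    CLIPPED_LOW,
    DegenerateEndMembersError,
    EndMemberEstimator,
    TransferProfileEstimator,
    delta_depo,
    estimate_end_members,
    prop_depo_concentration,
    prop_depo_isotope,
    prop_transfer,
)


class TestElementaryOperations:
    @pytest.mark.parametrize(
        "n_rs, n_nrs, expected, degenerate",
        [
            (0.15, 0.15, 0.0, True),
            (0.20, 0.10, 0.5, False),
            (0.25, 0.20, pytest.approx(0.2), False),
        ],
    )
    def test_prop_depo_concentration(self, n_rs, n_nrs, expected, degenerate):
        frac, flag = prop_depo_concentration(n_rs, n_nrs)
        assert frac == expected
        assert flag is degenerate

    def test_prop_depo_concentration_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            prop_depo_concentration(0.0, 0.1)

    def test_delta_depo_examples(self):
        # no isotopic contrast: deposition indistinguishable from background
        assert delta_depo(2.0, 2.0, 0.2, 0.1) == 2.0
        # hand evaluation: (-2.5)(0.20)/(0.10) + 2.0 = -3.0
        assert delta_depo(-0.5, 2.0, 0.20, 0.10) == pytest.approx(-3.0)
        # n_nrs -> 0: all rhizosphere N is deposition, result -> d_rs
        assert delta_depo(-0.5, 2.0, 0.20, 1e-9) == pytest.approx(-0.5, abs=1e-6)

    def test_delta_depo_degenerate(self):
        with pytest.raises(DegenerateEndMembersError):
            delta_depo(1.0, 2.0, 0.10, 0.20)

    def test_prop_depo_isotope_examples(self):
        assert prop_depo_isotope(2.0, 2.0, -3.0) == 0.0
        assert prop_depo_isotope(-3.0, 2.0, -3.0) == 1.0
        assert prop_depo_isotope(-0.5, 2.0, -3.0) == pytest.approx(0.5)
        with pytest.raises(DegenerateEndMembersError):
            prop_depo_isotope(1.0, 2.0, 2.0)

    def test_prop_transfer_examples(self):
        raw, clipped, flags = prop_transfer(4.0, 4.0, -3.0)
        assert raw == 0.0 and clipped == 0.0 and not flags
        raw, clipped, flags = prop_transfer(-3.0, 4.0, -3.0)
        assert raw == 1.0 and clipped == 1.0 and not flags
        raw, _, _ = prop_transfer(1.0, 4.0, -3.0)
        assert raw == pytest.approx(3 / 7)

    def test_prop_transfer_clipping_flags(self):
        raw, clipped, flags = prop_transfer(5.0, 4.0, -3.0)  # more enriched than ref
        assert raw < 0 and clipped == 0.0 and flags == {CLIPPED_LOW}
        raw, clipped, flags = prop_transfer(-4.0, 4.0, -3.0)
        assert raw > 1 and clipped == 1.0 and flags == {CLIPPED_HIGH}
        with pytest.raises(DegenerateEndMembersError):
            prop_transfer(1.0, 4.0, 4.0)


@given(
    n_nrs=st.floats(0.01, 1.0),
    enrich=st.floats(0.01, 2.0),
    d_rs=st.floats(-10, 10),
    d_nrs=st.floats(-10, 10),
)
@settings(max_examples=300, deadline=None)
def test_concentration_isotope_consistency(n_nrs, enrich, d_rs, d_nrs):
    """The derived deposition signature makes the isotope mixing model
    return exactly the concentration-based fraction (the algebraic
    identity that defines d_depo)."""
    n_rs = n_nrs * (1 + enrich)
    d_dep = delta_depo(d_rs, d_nrs, n_rs, n_nrs)
    if d_dep == d_nrs:  # zero isotopic contrast edge
        return
    p_conc, _ = prop_depo_concentration(n_rs, n_nrs)
    p_iso = prop_depo_isotope(d_rs, d_nrs, d_dep)
    assert p_iso == pytest.approx(p_conc, rel=1e-12, abs=1e-12)


@given(
    d_ref=st.floats(-5, 8),
    d_depo=st.floats(-8, 5),
    m1=st.floats(-8, 8),
    m2=st.floats(-8, 8),
)
@settings(max_examples=200, deadline=None)
def test_prop_transfer_affine_monotone(d_ref, d_depo, m1, m2):
    """Raw fraction is affine in d_mix with slope 1/(d_depo - d_ref)."""
    if abs(d_depo - d_ref) < 1e-6:
        return
    r1, _, _ = prop_transfer(m1, d_ref, d_depo)
    r2, _, _ = prop_transfer(m2, d_ref, d_depo)
    slope = 1.0 / (d_depo - d_ref)
    assert r2 - r1 == pytest.approx(slope * (m2 - m1), rel=1e-9, abs=1e-9)
    if d_depo < d_ref and m1 < m2:
        assert r1 >= r2


def _soil_table(n_rs, n_nrs, d_rs, d_nrs, blocks=6):
    rows = []
    for b in range(1, blocks + 1):
        rows.append({"compartment": "RS", "block": b, "n_pct": n_rs, "d15n": d_rs})
        rows.append({"compartment": "NRS", "block": b, "n_pct": n_nrs, "d15n": d_nrs})
    return pd.DataFrame(rows)


class TestEndMemberEstimator:
    def test_zero_variance_blocks_give_closed_form_and_zero_width(self):
        soil = _soil_table(0.20, 0.10, -0.5, 2.0)
        em = estimate_end_members(soil, rng_seed=0, n_boot=200)
        assert em.d_depo == pytest.approx(-3.0)
        assert em.p_depo_soil == pytest.approx(0.5)
        lo, hi = em.d_depo_interval()
        assert lo == hi == pytest.approx(-3.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        soil = _soil_table(0.20, 0.10, -0.5, 2.0)
        soil["d15n"] += rng.normal(0, 0.2, len(soil))
        a = estimate_end_members(soil, rng_seed=123, n_boot=500)
        b = estimate_end_members(soil, rng_seed=123, n_boot=500)
        assert np.array_equal(a.boot_d_depo, b.boot_d_depo, equal_nan=True)
        assert a.d_depo_interval() == b.d_depo_interval()

    def test_degenerate_draws_dropped_and_counted(self):
        # block-level enrichment straddles zero -> some draws degenerate
        soil = _soil_table(0.16, 0.15, -0.5, 2.0)
        rng = np.random.default_rng(3)
        soil.loc[soil["compartment"] == "RS", "n_pct"] += rng.normal(0, 0.02, 6)
        em = estimate_end_members(soil, rng_seed=5, n_boot=500)
        kept = np.isfinite(em.boot_d_depo).sum()
        assert kept + em.n_degenerate_draws == 500
        assert em.n_degenerate_draws > 0

    def test_insufficient_blocks_rejected(self):
        soil = _soil_table(0.2, 0.1, -0.5, 2.0, blocks=1)
        with pytest.raises(ValueError, match="2 blocks"):
            estimate_end_members(soil)

    def test_mean_degenerate_end_members_error(self):
        soil = _soil_table(0.10, 0.20, -0.5, 2.0)
        with pytest.raises(DegenerateEndMembersError):
            estimate_end_members(soil, n_boot=10)


class TestTransferProfileEstimator:
    def test_noise_free_recovery(self, noisefree_tables):
        plant, soil, truth = noisefree_tables
        em = EndMemberEstimator(n_boot=50, random_state=0).fit(soil)
        est = TransferProfileEstimator(end_members=em).fit(plant).estimates_
        tr = truth.set_index(["species", "distance"])["p_true"]
        for r in est.itertuples():
            assert r.p_transfer_raw == pytest.approx(tr.loc[(r.species, r.distance)], abs=1e-10)
        # no clipping on exact data
        assert (est["flags"] == "").all()

    def test_n_used_reflects_missing_cells(self, noisefree_tables):
        plant, soil, _ = noisefree_tables
        em = EndMemberEstimator(n_boot=20, random_state=0).fit(soil)
        est = TransferProfileEstimator(end_members=em).fit(plant).estimates_
        n = est.set_index(["species", "distance"])["n_used"]
        assert n.loc[("LC", 0)] == 5
        assert n.loc[("LC", 500)] == 4
        assert n.loc[("AS", 20)] == 4
        assert n.loc[("SG", 100)] == 6

    def test_missing_ref_raises_naming_species(self, noisefree_tables):
        plant, soil, _ = noisefree_tables
        em = EndMemberEstimator(n_boot=20, random_state=0).fit(soil)
        broken = plant[~((plant["species"] == "SG") & (plant["distance"] == "REF"))]
        with pytest.raises(ValueError, match="SG"):
            TransferProfileEstimator(end_members=em).fit(broken)

    def test_ci_bounds_ordered_and_contain_point_on_noisy_data(self, noisy_tables):
        plant, soil, _ = noisy_tables
        em = EndMemberEstimator(n_boot=300, random_state=1).fit(soil)
        est = TransferProfileEstimator(end_members=em).fit(plant).estimates_
        assert (est["ci_low"] <= est["ci_high"]).all()
        assert ((est["p_transfer"] >= 0) & (est["p_transfer"] <= 1)).all()
        unclipped = est["flags"] == ""
        assert (est.loc[unclipped, "p_transfer"] == est.loc[unclipped, "p_transfer_raw"]).all()

    def test_sklearn_params_round_trip(self):
        t = TransferProfileEstimator(ci=0.9, per_block=True)
        assert t.get_params()["ci"] == 0.9
        t.set_params(ci=0.8)
        assert t.ci == 0.8


def test_per_block_option_matches_pooled_on_noise_free_data(noisefree_tables):
    """Averaging per-block mixing ratios equals mixing the cell means when
    there is no within-cell variation."""
    plant, soil, truth = noisefree_tables
    em = EndMemberEstimator(n_boot=20, random_state=0).fit(soil)
    pooled = TransferProfileEstimator(end_members=em).fit(plant).estimates_
    perblk = TransferProfileEstimator(end_members=em, per_block=True).fit(plant).estimates_
    merged = pooled.merge(perblk, on=["species", "distance"], suffixes=("_pool", "_blk"))
    assert np.allclose(merged["p_transfer_raw_pool"], merged["p_transfer_raw_blk"], atol=1e-10)
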