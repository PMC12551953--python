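import numpy as np
import pytest

from indelfold.alleles import AllelePair, IndelSpec
from indelfold.errors import (
    DegenerateAffinityError,
    NoSharedSiteError,
    SkipRegion,
)
from indelfold.sitefinder import (
    AffinityTable,
    BindingRegion,
    effective_kd,
    identify_site,
    occupancy_profile,
    shift_control_region,
)
from indelfold.synthetic_data import site_recovery_cases, synthetic_affinity_table

from conftest import sparse_table

U7 = "UUUUUUU"


def test_affinity_table_validation():
    with pytest.raises(ValueError):
        AffinityTable({"AAAAAAA": 1.0})  # incomplete
    tbl = sparse_table({U7: 2.0})
    with pytest.raises(ValueError):
        tbl.rescaled(-1.0)  # negative scores rejected on construction


def test_zero_affinity_kmer_has_zero_occupancy():
    # single-window sequence whose 7-mer scores zero
    prof = occupancy_profile("AAAAAAA", sparse_table({U7: 1.0}), c=1.0)
    assert prof.probabilities.tolist() == [0.0]


def test_occupancy_half_at_effective_kd():
    # U7 alone: no pairing partners, accessibility 1, single window
    tbl = sparse_table({U7: 2.0})
    kd = effective_kd(U7, tbl)
    assert kd == pytest.approx(0.5)
    prof = occupancy_profile(U7, tbl, c=kd)
    assert prof.probabilities[0] == pytest.approx(0.5)


def test_effective_kd_sums_association_constants():
    # two isolated unit-affinity windows, no possible pairs -> sum K = 2
    tbl = sparse_table({U7: 1.0})
    assert effective_kd(U7 + "C" + U7, tbl) == pytest.approx(0.5)


def test_effective_kd_degenerate_input():
    with pytest.raises(DegenerateAffinityError):
        effective_kd("ACACACACAC", sparse_table({U7: 1.0}))


def test_occupancy_saturates_at_high_concentration():
    tbl = sparse_table({U7: 1.0})
    seq = U7 + "C" + U7
    low = occupancy_profile(seq, tbl, c=0.1).probabilities
    high = occupancy_profile(seq, tbl, c=1e9).probabilities
    mask = low > 0
    assert (high[mask] >= low[mask]).all()
    assert high[mask] == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        occupancy_profile(seq, tbl, c=-1.0)


def test_identify_site_finds_planted_element():
    table = synthetic_affinity_table(beta=1.0, seed=5)
    for pair, region, planted in site_recovery_cases(5, seed=31):
        assert identify_site(pair, region, table, "toy").l_start == planted


def test_identify_site_tie_breaks_to_five_prime():
    # two identical U7 windows in an otherwise unpairable all-C sequence:
    # equal scores, so the 5'-most start must win
    l_seq = "CCCCC" + U7 + "CCCC" + U7 + "CCCC"
    pair = AllelePair.from_deletion(l_seq, IndelSpec(0, 2))
    region = BindingRegion("t", 3, len(l_seq))
    site = identify_site(pair, region, sparse_table({U7: 1.0}), "toy")
    assert site.l_start == 5


def test_truncated_high_affinity_site_excluded():
    table = synthetic_affinity_table(beta=1.0, seed=5)
    for pair, region, planted in site_recovery_cases(5, seed=32, truncate=True):
        try:
            site = identify_site(pair, region, table, "toy")
        except NoSharedSiteError:
            continue
        assert site.l_start != planted
        assert site.s_start is not None


def test_identify_site_no_shared_kmer():
    l_seq = "CCCCC" + U7 + "CCCCC"
    pair = AllelePair.from_deletion(l_seq, IndelSpec(4, 9))
    region = BindingRegion("t", 5, 12)  # exactly the deleted 7-mer
    with pytest.raises(NoSharedSiteError):
        identify_site(pair, region, sparse_table({U7: 1.0, "C" * 7: 0.1}), "toy")


def test_identify_site_region_off_fragment_skipped():
    pair = AllelePair.from_deletion("C" * 30 + U7 + "C" * 3, IndelSpec(0, 1))
    with pytest.raises(SkipRegion):
        identify_site(
            pair,
            BindingRegion("t", 36, 61),  # only 4 nt left on the fragment
            sparse_table({U7: 1.0}),
            "toy",
        )


def test_identify_site_invariant_to_table_rescaling():
    table = synthetic_affinity_table(beta=1.0, seed=5)
    scaled = table.rescaled(7.25)
    pair, region, planted = site_recovery_cases(1, seed=33)[0]
    assert (
        identify_site(pair, region, table, "toy").l_start
        == identify_site(pair, region, scaled, "toy").l_start
    )
    # the invariance is exact: c rescales inversely, so c*K and hence every
    # occupancy probability is unchanged
    p1 = occupancy_profile(pair.l_seq, table, None, "toy").probabilities
    p2 = occupancy_profile(pair.l_seq, scaled, None, "toy").probabilities
    np.testing.assert_allclose(p1, p2, rtol=1e-12)


def test_occupancy_probabilities_in_unit_interval():
    table = synthetic_affinity_table(beta=1.0, seed=5)
    pair, _, _ = site_recovery_cases(1, seed=34)[0]
    p = occupancy_profile(pair.l_seq, table, None, "toy").probabilities
    assert ((p >= 0) & (p <= 1)).all()


def test_shift_control_region():
    region = BindingRegion("tx", 1000, 1025)
    shifted = shift_control_region(region)
    assert (shifted.start, shifted.end) == (700, 725)
    assert shifted.length == region.length
    same = shift_control_region(region, offset=0)
    assert (same.start, same.end) == (1000, 1025)
    with pytest.raises(SkipRegion):
        shift_control_region(BindingRegion("tx", 100, 125))


def test_affinity_table_tsv_round_trip(tmp_path):
    table = synthetic_affinity_table(beta=0.5, noise_sd=0.1, seed=2)
    path = tmp_path / "affinity.tsv"
    table.to_tsv(path)
    back = AffinityTable.from_tsv(path)
    for kmer in ("UUUUUUU", "AAAAAAA", "ACGUACG"):
        assert back[kmer] == pytest.approx(table[kmer], rel=1e-12)
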