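import math

import numpy as np
import pytest

from indelfold.constants import KT_KCAL_MOL
from indelfold.errors import ConfigError, GuardError
from indelfold.folding import (
    CountingEngine,
    FoldConstraint,
    ToyEngine,
    ToyModelParams,
    binding_delta_g,
    enumerate_structures,
    enumeration_free_energy,
    get_engine,
    partition_free_energy,
)
from indelfold.alleles import AllelePair, IndelSpec
from indelfold.preference import sweep_sites

from conftest import random_rna

P616 = ToyModelParams(kT=0.616)


def test_thermal_energy_constant():
    assert abs(KT_KCAL_MOL - 0.616) < 5e-4


def test_unpairable_sequence_has_zero_free_energy():
    assert partition_free_energy("AAAAA", engine="toy").g == 0.0
    assert partition_free_energy("ACCCA", engine="toy").g == 0.0


def test_gaaac_matches_two_structure_closed_form():
    # ensemble = {empty, (G1,C5)}: Z = 1 + e^{1/kT}
    expected = -0.616 * math.log(1.0 + math.exp(1.0 / 0.616))
    g = ToyEngine(P616).free_energy("GAAAC")
    assert g == pytest.approx(expected, abs=1e-12)
    assert g == pytest.approx(-1.111, abs=1e-3)


def test_fully_constrained_sequence_is_unfolded():
    g = ToyEngine(P616).free_energy("GAAAC", FoldConstraint(0, 5))
    assert g == 0.0


def test_enumeration_counts():
    assert len(enumerate_structures("GAAAC")) == 2
    assert len(enumerate_structures("AAAA")) == 1
    with pytest.raises(GuardError):
        enumerate_structures("A" * 21)


def test_enumeration_guard_allows_twenty():
    enumerate_structures("AC" * 10)


def _count_structures_dp(seq: str, min_hairpin: int = 3) -> int:
    """Independent pair-counting DP: number of valid structures (the
    epsilon -> 0 limit of the partition function)."""
    code = {"A": 0, "C": 1, "G": 2, "U": 3}
    s = [code[c] for c in seq]
    n = len(s)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def count(i, j):  # half-open [i, j)
        if j - i <= 0:
            return 1
        total = count(i + 1, j)
        for k in range(i + min_hairpin + 1, j):
            if (s[i] + s[k]) in (3, 5):
                total += count(i + 1, k) * count(k + 1, j)
        return total

    return count(0, n)


@pytest.mark.parametrize("seq", ["GGAAACC", "GCGCAAAAGCGC", "GAAACAAAGAAAC"])
def test_structure_count_matches_counting_dp(seq):
    assert len(enumerate_structures(seq)) == _count_structures_dp(seq)


def test_toy_partition_epsilon_limit_counts_structures():
    # With a vanishing pair energy every structure has weight ~1, so
    # exp(-G/kT) approaches the integer structure count.
    params = ToyModelParams(pair_energy=-1e-12)
    for seq in ("GGAAACC", "GCAAAGAAAC"):
        z = math.exp(-ToyEngine(params).free_energy(seq) / params.kT)
        assert z == pytest.approx(len(enumerate_structures(seq, params=params)), abs=1e-6)


def test_toy_dp_matches_enumeration_oracle():
    rng = np.random.default_rng(42)
    engine = ToyEngine()
    for _ in range(60):
        n = int(rng.integers(8, 15))
        seq = random_rna(rng, n)
        constraint = None
        if rng.random() < 0.7:
            start = int(rng.integers(0, n - 1))
            length = int(rng.integers(1, n - start + 1))
            constraint = FoldConstraint(start, length)
        assert engine.free_energy(seq, constraint) == pytest.approx(
            enumeration_free_energy(seq, constraint), abs=1e-9
        )


@pytest.mark.parametrize("engine_name", ["toy", "nearest_neighbor"])
def test_constraint_monotonicity(engine_name):
    # Constraining more positions removes structures from the ensemble, so
    # the free energy can only go up.
    rng = np.random.default_rng(7)
    engine = get_engine(engine_name)
    n_cases = 20 if engine_name == "toy" else 5
    for _ in range(n_cases):
        seq = random_rna(rng, int(rng.integers(20, 60)))
        start = int(rng.integers(0, len(seq) - 10))
        prev = engine.free_energy(seq, None)
        for length in (3, 6, 9):
            g = engine.free_energy(seq, FoldConstraint(start, length))
            assert g >= prev - 1e-6
            prev = g


@pytest.mark.parametrize("engine_name", ["toy", "nearest_neighbor"])
def test_binding_delta_g_non_negative(engine_name):
    rng = np.random.default_rng(11)
    engine = get_engine(engine_name)
    n_cases = 40 if engine_name == "toy" else 8
    for _ in range(n_cases):
        seq = random_rna(rng, int(rng.integers(30, 151)))
        site = int(rng.integers(0, len(seq) - 6))
        assert binding_delta_g(seq, site, 7, engine) >= -1e-6


def test_engines_deterministic():
    seq = random_rna(np.random.default_rng(3), 80)
    for name in ("toy", "nearest_neighbor"):
        engine = get_engine(name)
        g1 = engine.free_energy(seq, FoldConstraint(10, 7))
        g2 = engine.free_energy(seq, FoldConstraint(10, 7))
        assert g1 == g2


def test_unknown_engine_rejected():
    with pytest.raises(ConfigError):
        get_engine("mfe")


def test_g_none_cached_once_per_allele_in_sweep():
    pair = AllelePair.from_deletion(
        random_rna(np.random.default_rng(5), 150), IndelSpec(97, 3)
    )
    counting = CountingEngine(ToyEngine())
    results = sweep_sites(pair, engine=counting)
    # one unconstrained fold per allele plus one constrained fold per allele
    # per site: 2 + 2*44, not 4*44
    assert len(results) == 44
    assert counting.calls == 2 + 2 * len(results)
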