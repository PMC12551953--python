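import math

import numpy as np
import pytest

from indelfold.io import read_bed, read_fasta, read_indels
from indelfold.sitefinder import AffinityTable
from indelfold.synthetic_data import (
    GeneratorConfig,
    SelectionModel,
    make_fixtures,
    random_fragment,
    random_fragments,
    simulate_selection,
    synthetic_affinity_table,
    synthetic_indel_fig1,
)


def test_fragment_defaults_and_determinism():
    cfg = GeneratorConfig(seed=42)
    frag = random_fragment(cfg)
    assert frag.length == 150
    assert set(frag.sequence) <= set("ACGU")
    assert random_fragment(cfg).sequence == frag.sequence
    assert random_fragment(GeneratorConfig(seed=43)).sequence != frag.sequence


def test_pooled_base_frequencies_uniform():
    # 4000 fragments x 150 nt = 600,000 i.i.d. draws; each base frequency
    # should sit within a tight binomial bound of 1/4
    frags = random_fragments(GeneratorConfig(seed=7))
    pooled = "".join(f.sequence for f in frags)
    for base in "ACGU":
        assert pooled.count(base) / len(pooled) == pytest.approx(0.25, abs=0.005)


def test_fragment_length_guard():
    with pytest.raises(ValueError):
        GeneratorConfig(fragment_length=100)
    with pytest.raises(ValueError):
        GeneratorConfig(base_probs=(0.5, 0.5, 0.25, 0.25))


@pytest.mark.parametrize("size,expected_del", [(5, (95, 100)), (1, (99, 100))])
def test_fig1_deletion_interval(size, expected_del):
    frag = random_fragment(GeneratorConfig(seed=1))
    pair = synthetic_indel_fig1(frag, size)
    start, end = expected_del
    assert (pair.indel.l_start, pair.indel.junction) == (start, end)
    assert pair.s_seq == frag.sequence[:start] + frag.sequence[end:]
    assert len(pair.s_seq) == 150 - size


def test_fig1_sizes_share_junction():
    frag = random_fragment(GeneratorConfig(seed=1))
    junctions = {synthetic_indel_fig1(frag, s).indel.junction for s in range(1, 6)}
    assert junctions == {100}


def test_fig1_longer_fragment_keeps_downstream_flank():
    frag = random_fragment(GeneratorConfig(seed=1, fragment_length=250))
    pair = synthetic_indel_fig1(frag, 3)
    assert pair.indel.junction == 100
    assert len(pair.l_seq) - pair.indel.junction >= 100


def test_fig1_size_out_of_range():
    frag = random_fragment(GeneratorConfig(seed=1))
    with pytest.raises(ValueError):
        synthetic_indel_fig1(frag, 51)


def test_affinity_table_closed_forms():
    flat = synthetic_affinity_table(beta=0.0, noise_sd=0.0)
    assert flat["AAAAAAA"] == flat["UUUUUUU"] == flat["ACGUACG"]
    biased = synthetic_affinity_table(beta=1.0, noise_sd=0.0)
    assert biased["UUUUUUU"] / biased["AAAAAAA"] == pytest.approx(math.exp(7))
    assert max(("UUUUUUU", "AAAAAAA", "UUUAUUU"), key=lambda m: biased[m]) == "UUUUUUU"


def test_selection_hard_filter():
    rng = np.random.default_rng(0)
    ddgs = rng.normal(0, 1, size=500)
    model = SelectionModel(threshold=0.616, retention=0.0)
    retained = simulate_selection(list(ddgs), ddgs, model, seed=1)
    assert all(abs(d) <= 0.616 for d in retained)
    assert np.std(retained, ddof=1) < np.std(ddgs, ddof=1)


def test_selection_full_retention_is_identity():
    ddgs = [0.0, 5.0, -3.0]
    model = SelectionModel(threshold=0.1, retention=1.0)
    assert simulate_selection(["a", "b", "c"], ddgs, model, seed=1) == ["a", "b", "c"]


def test_selection_deterministic_given_seed():
    rng = np.random.default_rng(3)
    ddgs = rng.normal(0, 1, size=200)
    model = SelectionModel(threshold=0.5, retention=0.3)
    first = simulate_selection(list(range(200)), ddgs, model, seed=9)
    second = simulate_selection(list(range(200)), ddgs, model, seed=9)
    assert first == second


def test_make_fixtures_round_trip(tmp_path):
    cfg = GeneratorConfig(seed=5)
    paths = make_fixtures(tmp_path / "fx", cfg, n_transcripts=10)
    transcripts = read_fasta(paths["fasta"])
    assert len(transcripts) == 10
    assert all(len(s) == 600 and set(s) <= set("ACGU") for s in transcripts.values())
    variants = read_indels(paths["vcf"])
    assert len(variants) == 10
    assert all(1 <= v.size <= 5 for v in variants)
    # REF matches the transcript at the stated position
    for v in variants:
        t = transcripts[v.transcript_id]
        assert t[v.pos - 1 : v.pos - 1 + len(v.ref)] == v.ref.replace("T", "U")
    regions = read_bed(paths["bed"])
    assert all(r.length == 25 for r in regions)
    assert all(r.end <= 600 for r in regions)
    # every region contains its planted U7
    for r in regions:
        assert "U" * 7 in transcripts[r.transcript_id][r.start : r.end]
    AffinityTable.from_tsv(paths["affinity"])  # validates completeness


def test_make_fixtures_pure_function_of_seed(tmp_path):
    cfg = GeneratorConfig(seed=11)
    p1 = make_fixtures(tmp_path / "a", cfg, n_transcripts=4)
    p2 = make_fixtures(tmp_path / "b", cfg, n_transcripts=4)
    for kind in ("fasta", "vcf", "bed"):
        assert p1[kind].read_bytes() == p2[kind].read_bytes()
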