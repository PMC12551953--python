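"""Generators for every input the pipeline consumes.

Real runs of this analysis use dbSNP indels, Ensembl transcripts, CLIP-
derived binding regions and an RNAcompete affinity table. This module
produces structurally faithful synthetic stand-ins for all of them —
uniform-random 150-nt fragments, centrally placed deletions of sizes 1-5,
anchor-base VCF records, ~25-nt binding regions with a planted U7 element,
and a U-biased 7-mer affinity table — plus a simple purifying-selection
simulator used for parameter-recovery tests.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, TypeVar

import numpy as np

from .alleles import AllelePair, IndelSpec, TranscriptFragment
from .sitefinder import AffinityTable, BindingRegion, KMER_LEN

logger = logging.getLogger(__name__)

BASES = "ACGU"
T = TypeVar("T")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic cohorts.

    Defaults follow the headline analysis: 4000 fragments of 150 nt with
    uniform base composition and deletions of sizes 1-5.
    """

    seed: int = 0
    n_fragments: int = 4000
    fragment_length: int = 150
    base_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    indel_sizes: Tuple[int, ...] = (1, 2, 3, 4, 5)

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-12:
            raise ValueError("base_probs must sum to 1")
        if self.fragment_length < 107:
            raise ValueError(
                "fragment_length must be >= 107 to leave room for the "
                "deletion window, the sweep window and a 5' flank"
            )


@dataclass(frozen=True)
class SelectionModel:
    """Hard-threshold purifying selection on the magnitude of ddG: a variant
    with |ddG| <= threshold at the reference site is always retained; larger
    effects survive with probability ``retention``."""

    threshold: float
    retention: float = 0.0
    reference_distance: int = 0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if not 0.0 <= self.retention <= 1.0:
            raise ValueError("retention must be in [0, 1]")


def _rng_for(cfg_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg_seed, spawn_key=tuple(key))
    )


def random_fragment(
    cfg: GeneratorConfig, index: int = 0, origin: str = "random"
) -> TranscriptFragment:
    """One fragment with i.i.d. bases; deterministic in (cfg.seed, index)."""
    rng = _rng_for(cfg.seed, 0, index)
    seq = "".join(
        rng.choice(list(BASES), size=cfg.fragment_length, p=list(cfg.base_probs))
    )
    return TranscriptFragment(id=f"{origin}_frag_{index}", sequence=seq, origin=origin)


def random_fragments(
    cfg: GeneratorConfig, n: Optional[int] = None, origin: str = "random"
) -> List[TranscriptFragment]:
    n = cfg.n_fragments if n is None else n
    return [random_fragment(cfg, i, origin) for i in range(n)]


def fig1_junction(fragment_length: int) -> int:
    """0-based junction (first position after the deleted interval) of the
    synthetic-indel construction. At 150 nt this is position 100: deletions
    remove the 3' end of the central 50-nt window (1-based 51-100) and sites
    sweep the adjacent downstream 50 nt (101-150). Longer fragments keep the
    junction at 100, leaving extra 3' flank beyond the sweep window."""
    return min(100, fragment_length - 50)


def synthetic_indel_fig1(fragment: TranscriptFragment, size: int) -> AllelePair:
    """Deletion of ``size`` nt ending at the fixed junction, so all sizes
    share the same 3' junction and indel-site distances align across
    sizes."""
    if not 1 <= size <= 50:
        raise ValueError(f"indel size must be in 1..50, got {size}")
    junction = fig1_junction(fragment.length)
    indel = IndelSpec(
        l_start=junction - size, size=size, provenance="synthetic"
    )
    return AllelePair.from_deletion(fragment.sequence, indel)


def synthetic_affinity_table(
    beta: float = 1.0, noise_sd: float = 0.0, seed: int = 0
) -> AffinityTable:
    """U-biased 7-mer table emulating single-stranded U-rich binders:
    s(m) = exp(beta * countU(m) + eps_m), eps_m ~ N(0, noise_sd^2)."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(seed)
    kmers = ["".join(p) for p in itertools.product(BASES, repeat=KMER_LEN)]
    u_counts = np.array([m.count("U") for m in kmers], dtype=float)
    eps = rng.normal(0.0, noise_sd, size=len(kmers)) if noise_sd > 0 else 0.0
    scores = np.exp(beta * u_counts + eps)
    return AffinityTable(
        dict(zip(kmers, scores.tolist())),
        description=f"synthetic U-biased table (beta={beta}, noise_sd={noise_sd})",
    )


def simulate_selection(
    items: Sequence[T],
    ddgs: Sequence[float],
    model: SelectionModel,
    seed: int = 0,
) -> List[T]:
    """Apply the purifying-selection filter to items scored by ddG at the
    model's reference site; returns the retained items."""
    if len(items) != len(ddgs):
        raise ValueError("items and ddgs must have equal length")
    rng = np.random.default_rng(seed)
    retained: List[T] = []
    for item, ddg in zip(items, ddgs):
        if abs(ddg) <= model.threshold or rng.random() < model.retention:
            retained.append(item)
    return retained


# ---------------------------------------------------------------------------
# Binding-region fixtures with a planted ground-truth site
# ---------------------------------------------------------------------------

REGION_LEN = 25

#: Base composition of binding-region fixtures: U/C-rich and purine-poor,
#: emulating the weakly structured AU/U-rich 3'UTR context in which
#: single-stranded U-rich binders operate. Low purine content matters for the
#: ground truth: every A/G is a pairing partner for the planted U run, and a
#: strongly structured context would bury the planted element by
#: construction.
FIXTURE_BASE_PROBS = (0.05, 0.55, 0.05, 0.35)  # A, C, G, U


def _planted_region_sequence(
    rng: np.random.Generator,
    length: int,
    region_start: int,
    planted_offset: int,
    region_len: int = REGION_LEN,
) -> str:
    """U/C-rich background; the binding-region flanks are C so the planted
    U7 is the region's unique affinity and pairing signal."""
    seq = list(rng.choice(list(BASES), size=length, p=list(FIXTURE_BASE_PROBS)))
    seq[region_start : region_start + region_len] = "C" * region_len
    p = region_start + planted_offset
    seq[p : p + KMER_LEN] = "U" * KMER_LEN
    return "".join(seq)


def site_recovery_cases(
    n: int,
    seed: int = 0,
    truncate: bool = False,
    fragment_length: int = 150,
) -> List[Tuple[AllelePair, BindingRegion, int]]:
    """(pair, region, planted_start) triples for site-identification tests.

    Each 150-nt fragment carries a 25-nt binding region with a planted U7
    element at a random in-region offset and a deletion of size 1-5. With
    ``truncate=False`` the deletion lies 5' of the region; with
    ``truncate=True`` it removes part of the planted U7 itself, so the
    planted start must be excluded by the coordinate map."""
    cases = []
    for i in range(n):
        rng = _rng_for(seed, 1, i, int(truncate))
        region_start = int(rng.integers(60, 90))
        planted_offset = int(rng.integers(0, REGION_LEN - KMER_LEN + 1))
        planted_start = region_start + planted_offset
        size = int(rng.integers(1, 6))
        seq = _planted_region_sequence(
            rng, fragment_length, region_start, planted_offset
        )
        if truncate:
            # deletion starting inside the planted 7-mer
            l_start = planted_start + int(rng.integers(1, KMER_LEN - 1))
        else:
            l_start = int(rng.integers(10, 40))  # well 5' of the region
        indel = IndelSpec(l_start=l_start, size=size, provenance="synthetic")
        pair = AllelePair.from_deletion(seq, indel)
        region = BindingRegion(
            transcript_id=f"fixture_{i}",
            start=region_start,
            end=region_start + REGION_LEN,
            name=f"region_{i}",
        )
        cases.append((pair, region, planted_start))
    return cases


# ---------------------------------------------------------------------------
# File fixtures emulating the dbSNP / transcript / binding-region inputs
# ---------------------------------------------------------------------------

TRANSCRIPT_LEN = 600
#: Transcript layout: deletion junction and binding region placed so the
#: 150-nt centered fragment contains the full region, and the region start
#: clears the 300-nt control shift.
_JUNCTION = 375
_REGION_START = 400


def make_fixtures(
    out_dir,
    cfg: GeneratorConfig,
    n_transcripts: Optional[int] = None,
    transcript_length: int = TRANSCRIPT_LEN,
    beta: float = 1.0,
    noise_sd: float = 0.0,
) -> Dict[str, Path]:
    """Write a self-consistent fixture set: transcripts FASTA, dbSNP-style
    VCF of anchor-base deletions (sizes from cfg.indel_sizes, all < 6 nt),
    binding-region BED with planted U7 elements, and an affinity TSV.

    Every transcript carries one deletion whose junction sits 75 nt left of
    a binding region, so 150-nt indel-centered fragments contain the whole
    region and regions clear the 300-nt upstream control shift.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = cfg.n_fragments if n_transcripts is None else n_transcripts
    sizes = list(cfg.indel_sizes)

    fasta_path = out / "transcripts.fasta"
    vcf_path = out / "indels.vcf"
    bed_path = out / "regions.bed"
    affinity_path = out / "affinity.tsv"

    fasta_lines: List[str] = []
    bed_lines: List[str] = []
    vcf_records: List[str] = []
    contigs: List[str] = []

    for i in range(n):
        rng = _rng_for(cfg.seed, 2, i)
        tid = f"TX{i:05d}"
        planted_offset = int(rng.integers(0, REGION_LEN - KMER_LEN + 1))
        seq = _planted_region_sequence(
            rng, transcript_length, _REGION_START, planted_offset
        )
        size = sizes[i % len(sizes)]
        # deletion [junction-size, junction); VCF anchor base sits just 5'
        del_start = _JUNCTION - size
        anchor_pos0 = del_start - 1
        ref = seq[anchor_pos0 : anchor_pos0 + 1 + size].replace("U", "T")
        alt = ref[0]
        vcf_records.append(
            f"{tid}\t{anchor_pos0 + 1}\trs{900000 + i}\t{ref}\t{alt}\t.\tPASS\t."
        )
        contigs.append(f"##contig=<ID={tid},length={transcript_length}>")
        fasta_lines.append(f">{tid}")
        fasta_lines.extend(
            seq[j : j + 70] for j in range(0, len(seq), 70)
        )
        bed_lines.append(
            f"{tid}\t{_REGION_START}\t{_REGION_START + REGION_LEN}\tregion_{i}"
        )

    fasta_path.write_text("\n".join(fasta_lines) + "\n")
    bed_path.write_text("\n".join(bed_lines) + "\n")
    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=.,Number=0,Type=Flag,Description="placeholder">',
        *contigs,
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    vcf_path.write_text("\n".join(header + vcf_records) + "\n")
    synthetic_affinity_table(beta=beta, noise_sd=noise_sd, seed=cfg.seed).to_tsv(
        affinity_path
    )
    logger.info("wrote fixture set (%d transcripts) to %s", n, out)
    return {
        "fasta": fasta_path,
        "vcf": vcf_path,
        "bed": bed_path,
        "affinity": affinity_path,
    }
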