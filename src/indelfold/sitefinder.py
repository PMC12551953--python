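"""Locating the probable 7-nt binding site inside a ~25-nt binding region.

CLIP-style experiments resolve protein binding to ~25-nt regions that
contain, somewhere, the true 7-nt element. To pinpoint it we rank every
7-mer in the region by an affinity-weighted, structure-corrected occupancy:

    accessibility  a_i = exp(-dG_i / kT)          (dG_i from binding_delta_g)
    association    K_i = s(m_i) * a_i             (s from an affinity table)
    occupancy      p_i = c*K_i / (1 + c*K_i)      (single-site isotherm)

with the protein concentration c set to the effective dissociation constant
of the whole input RNA, defined here as 1 / sum_i K_i. Occupancies of the
two alleles are summed over the 7-mers they share; 7-mers destroyed by the
indel are excluded; the maximum wins (5'-most on ties).

Control regions are generated by shifting real regions 300 nt towards the
5' end of the transcript.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .alleles import ABSENT, AllelePair, SiteWindow, map_site_to_s
from .constants import KT_KCAL_MOL
from .errors import (
    DegenerateAffinityError,
    NoSharedSiteError,
    SkipRegion,
)
from .folding import binding_delta_g, get_engine

logger = logging.getLogger(__name__)

KMER_LEN = 7
N_KMERS = 4**KMER_LEN  # 16384
SHIFT_OFFSET = 300  # nt, towards the 5' end


class AffinityTable:
    """Relative binding preference s(m) >= 0 for every 7-mer (RNAcompete-
    like). Complete over all 4^7 keys; at least one score positive."""

    def __init__(self, scores: Dict[str, float], description: str = ""):
        if len(scores) != N_KMERS:
            raise ValueError(
                f"affinity table must cover all {N_KMERS} 7-mers, got "
                f"{len(scores)}"
            )
        vals = np.fromiter(scores.values(), dtype=float, count=N_KMERS)
        if (vals < 0).any():
            raise ValueError("affinity scores must be >= 0")
        if not (vals > 0).any():
            raise ValueError("at least one affinity score must be positive")
        self._scores = dict(scores)
        self.description = description

    def __getitem__(self, kmer: str) -> float:
        return self._scores[kmer]

    def __len__(self) -> int:
        return N_KMERS

    def rescaled(self, factor: float) -> "AffinityTable":
        return AffinityTable(
            {k: v * factor for k, v in self._scores.items()},
            description=self.description,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"kmer": list(self._scores), "score": list(self._scores.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, description: str = "") -> "AffinityTable":
        df = pd.read_csv(path, sep="\t", dtype={"kmer": str, "score": float})
        return cls(dict(zip(df["kmer"], df["score"])), description=description)


@dataclass(frozen=True)
class BindingRegion:
    """~25-nt experimentally resolved binding locus, 0-based half-open in
    transcript coordinates."""

    transcript_id: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start < KMER_LEN:
            raise ValueError(
                f"binding region [{self.start}, {self.end}) shorter than a "
                f"{KMER_LEN}-mer"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-7-mer-start binding probabilities for one sequence."""

    probabilities: np.ndarray  # p_i in [0,1], index = 7-mer start
    concentration: float  # c used in the isotherm
    effective_kd: float


def _association_constants(seq: str, table: AffinityTable, engine) -> np.ndarray:
    """K_i = s(m_i) * exp(-dG_i/kT) for every 7-mer start; the unconstrained
    fold is computed once for the whole sequence."""
    eng = get_engine(engine)
    n_sites = len(seq) - KMER_LEN + 1
    if n_sites < 1:
        raise ValueError("sequence shorter than one 7-mer")
    g_none = eng.free_energy(seq, None)
    out = np.empty(n_sites)
    for i in range(n_sites):
        s = table[seq[i : i + KMER_LEN]]
        if s == 0.0:
            out[i] = 0.0
            continue
        dg = binding_delta_g(seq, i, KMER_LEN, eng, g_none=g_none)
        out[i] = s * np.exp(-dg / KT_KCAL_MOL)
    return out


def effective_kd(seq: str, table: AffinityTable, engine="toy") -> float:
    """Effective dissociation constant of protein vs the whole RNA: the
    inverse of the summed single-site association constants."""
    total = _association_constants(seq, table, engine).sum()
    if total <= 0.0:
        raise DegenerateAffinityError(
            "no 7-mer with positive affinity-weighted accessibility"
        )
    return 1.0 / total


def occupancy_profile(
    seq: str,
    table: AffinityTable,
    c: Optional[float] = None,
    engine="toy",
) -> OccupancyProfile:
    """Binding probability at every 7-mer start. When ``c`` is omitted it is
    set to the sequence's own effective Kd (so sum-level occupancy is 1/2 in
    the single-molecule sense)."""
    k = _association_constants(seq, table, engine)
    total = k.sum()
    if c is None:
        if total <= 0.0:
            raise DegenerateAffinityError(
                "no 7-mer with positive affinity-weighted accessibility"
            )
        c = 1.0 / total
    elif c <= 0.0:
        raise ValueError(f"concentration must be positive, got {c}")
    ck = c * k
    return OccupancyProfile(
        probabilities=ck / (1.0 + ck),
        concentration=c,
        effective_kd=(1.0 / total) if total > 0 else np.inf,
    )


def identify_site(
    pair: AllelePair,
    region: BindingRegion,
    table: AffinityTable,
    engine="toy",
) -> SiteWindow:
    """The 7-mer within the binding region with the maximum summed l+s
    occupancy, each allele evaluated at its own effective Kd; 7-mers absent
    from the s-allele are excluded; ties break to the 5'-most start."""
    n = len(pair.l_seq)
    start = max(region.start, 0)
    end = min(region.end, n)
    if end - start < KMER_LEN:
        raise SkipRegion(
            f"region [{region.start}, {region.end}) leaves fewer than "
            f"{KMER_LEN} nt on the fragment"
        )
    prof_l = occupancy_profile(pair.l_seq, table, None, engine)
    prof_s = occupancy_profile(pair.s_seq, table, None, engine)
    best_start = None
    best_score = -np.inf
    for l_start in range(start, end - KMER_LEN + 1):
        s_start = map_site_to_s(l_start, pair.indel, KMER_LEN)
        if s_start is ABSENT:
            continue
        score = (
            prof_l.probabilities[l_start] + prof_s.probabilities[s_start]
        )
        if score > best_score:  # strict: keeps the 5'-most on ties
            best_score = score
            best_start = l_start
    if best_start is None:
        raise NoSharedSiteError(
            f"all 7-mers in region [{start}, {end}) overlap the deleted "
            "interval"
        )
    return SiteWindow.on_pair(pair, best_start, KMER_LEN)


def shift_control_region(
    region: BindingRegion, offset: int = SHIFT_OFFSET
) -> BindingRegion:
    """Same-length control region shifted ``offset`` nt towards the 5' end;
    regions too close to the transcript start are skipped."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if region.start < offset:
        raise SkipRegion(
            f"region start {region.start} < shift offset {offset}"
        )
    return BindingRegion(
        transcript_id=region.transcript_id,
        start=region.start - offset,
        end=region.end - offset,
        name=f"{region.name}_shifted" if region.name else "",
    )
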