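"""Allele pairs, indels, and coordinate bookkeeping.

An *indel* is always represented as a deletion relative to the longer of the
two observed sequences: the l-allele carries the extra nucleotides, the
s-allele lacks them. An insertion polymorphism is handled upstream by
swapping which observed allele is called "l", so a single deletion-shaped
representation covers both.

All coordinates here are 0-based, half-open. 1-based closed coordinates
appear only in file IO and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import AlphabetError, BoundsError, OverlapError

RNA_ALPHABET = frozenset("ACGU")

#: Sentinel-free convention: a site absent from the s-allele maps to None.
ABSENT = None

ORIGIN_VALUES = ("random", "human", "human_near_site")
PROVENANCE_VALUES = ("synthetic", "natural")


def validate_rna(seq: str) -> str:
    """Check that *seq* is a string over {A, C, G, U}; return it unchanged."""
    if not RNA_ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise AlphabetError(f"non-ACGU characters in sequence: {bad}")
    return seq


@dataclass(frozen=True)
class TranscriptFragment:
    """A (typically 150-nt) RNA fragment on which allele pairs are built."""

    id: str
    sequence: str
    origin: str = "random"

    def __post_init__(self) -> None:
        validate_rna(self.sequence)
        if self.origin not in ORIGIN_VALUES:
            raise ValueError(f"origin must be one of {ORIGIN_VALUES}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class IndelSpec:
    """A deletion of ``size`` nucleotides starting at ``l_start`` on the
    l-allele. ``junction`` is the 0-based index of the first l-allele
    position after the deleted interval; it is the reference point for
    indel-site distances on the 3' side."""

    l_start: int
    size: int
    provenance: str = "synthetic"
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"indel size must be >= 1, got {self.size}")
        if self.l_start < 0:
            raise BoundsError(f"l_start must be >= 0, got {self.l_start}")
        if self.provenance not in PROVENANCE_VALUES:
            raise ValueError(f"provenance must be one of {PROVENANCE_VALUES}")

    @property
    def junction(self) -> int:
        return self.l_start + self.size

    def check_within(self, l_seq: str) -> None:
        if self.junction > len(l_seq):
            raise BoundsError(
                f"deletion [{self.l_start}, {self.junction}) exceeds "
                f"l-allele length {len(l_seq)}"
            )


def apply_deletion(l_seq: str, indel: IndelSpec) -> str:
    """Return the s-allele: *l_seq* with the deleted interval spliced out."""
    validate_rna(l_seq)
    indel.check_within(l_seq)
    return l_seq[: indel.l_start] + l_seq[indel.junction :]


@dataclass(frozen=True)
class AllelePair:
    """A long and a short allele differing by exactly one deletion."""

    l_seq: str
    s_seq: str
    indel: IndelSpec

    def __post_init__(self) -> None:
        validate_rna(self.l_seq)
        validate_rna(self.s_seq)
        if len(self.l_seq) - len(self.s_seq) != self.indel.size:
            raise ValueError(
                "l/s length difference does not match the indel size"
            )
        if apply_deletion(self.l_seq, self.indel) != self.s_seq:
            raise ValueError("s_seq is not l_seq with the indel removed")

    @classmethod
    def from_deletion(cls, l_seq: str, indel: IndelSpec) -> "AllelePair":
        return cls(l_seq=l_seq, s_seq=apply_deletion(l_seq, indel), indel=indel)


def map_site_to_s(
    site_l_start: int, indel: IndelSpec, site_len: int = 7
) -> Optional[int]:
    """Map a site start from l-allele to s-allele coordinates.

    Returns the s-allele start index, or :data:`ABSENT` (None) when the site
    overlaps the deleted interval and therefore has no counterpart on the
    s-allele (such sites are excluded from allele comparisons).
    """
    if site_l_start < 0:
        raise BoundsError(f"negative site start {site_l_start}")
    site_end = site_l_start + site_len
    if site_end <= indel.l_start:  # entirely 5' of the deletion
        return site_l_start
    if site_l_start >= indel.junction:  # entirely 3' of the deletion
        return site_l_start - indel.size
    return ABSENT


def indel_site_distance(
    indel: IndelSpec, site_l_start: int, site_len: int = 7
) -> int:
    """Number of l-allele nucleotides strictly between the deletion and the
    site, so a site immediately adjacent to the deleted interval is at
    distance 0. Symmetric for sites 5' (upstream) and 3' (downstream) of
    the indel."""
    site_end = site_l_start + site_len
    if site_l_start >= indel.junction:  # downstream (3') site
        return site_l_start - indel.junction
    if site_end <= indel.l_start:  # upstream (5') site
        return indel.l_start - site_end
    raise OverlapError(
        f"site [{site_l_start}, {site_end}) overlaps deleted interval "
        f"[{indel.l_start}, {indel.junction})"
    )


@dataclass(frozen=True)
class SiteWindow:
    """A candidate binding site of ``length`` nt, located on the l-allele at
    ``l_start`` and (when not destroyed by the indel) at ``s_start`` on the
    s-allele."""

    l_start: int
    length: int = 7
    s_start: Optional[int] = field(default=ABSENT)

    @classmethod
    def on_pair(
        cls, pair: AllelePair, l_start: int, length: int = 7
    ) -> "SiteWindow":
        """Build a site window with the s-allele start filled in by the
        coordinate map (ABSENT when the indel destroys the site)."""
        if l_start < 0 or l_start + length > len(pair.l_seq):
            raise BoundsError(
                f"site [{l_start}, {l_start + length}) outside l-allele of "
                f"length {len(pair.l_seq)}"
            )
        s_start = map_site_to_s(l_start, pair.indel, length)
        return cls(l_start=l_start, length=length, s_start=s_start)
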