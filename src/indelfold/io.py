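"""Readers, writers, fragment extraction, and candidate export.

Formats: transcripts as FASTA (T is normalized to U on read), variants as a
VCF v4 subset in transcript coordinates (CHROM = transcript id, 1-based POS,
anchor-base REF/ALT), binding regions as BED (0-based half-open), affinity
tables and result curves as TSV. Genomic-to-transcript projection and
genome-build conversion are out of scope: variants must arrive already in
transcript space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import IndelSpec, TranscriptFragment
from .constants import KT_KCAL_MOL
from .errors import ParseError, SkipRegion
from .sitefinder import BindingRegion
from .stats import CurvePoint, curve_frame

logger = logging.getLogger(__name__)

#: Indels of this size or larger are excluded from the analysis.
MAX_INDEL_SIZE = 6


@dataclass(frozen=True)
class VariantRecord:
    """One VCF record in transcript coordinates (1-based anchor POS)."""

    transcript_id: str
    pos: int
    variant_id: str
    ref: str
    alt: str

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def size(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def read_fasta(path) -> Dict[str, str]:
    """id -> RNA sequence (uppercased, T converted to U)."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_indels(path, max_size: int = MAX_INDEL_SIZE) -> List[VariantRecord]:
    """Parse a VCF and keep only small indels (length difference in
    1..max_size-1); SNPs and indels of size >= max_size are dropped, with
    kept/dropped counts logged."""
    import pysam

    kept: List[VariantRecord] = []
    n_snp = n_large = n_other = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: cannot open VCF: {exc}") from exc
    try:
        for i, rec in enumerate(vcf):
            alts = rec.alts or ()
            if len(alts) != 1 or rec.ref is None:
                n_other += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            size = abs(len(ref) - len(alt))
            if size == 0:
                n_snp += 1
                continue
            if size >= max_size:
                n_large += 1
                continue
            kept.append(
                VariantRecord(
                    transcript_id=rec.chrom,
                    pos=rec.pos,
                    variant_id=rec.id or f"record_{i}",
                    ref=ref,
                    alt=alt,
                )
            )
    except (ValueError, OSError) as exc:
        raise ParseError(
            f"{path}: malformed VCF near record {len(kept) + n_snp + n_large + n_other + 1}: {exc}"
        ) from exc
    logger.info(
        "read_indels(%s): kept=%d dropped_snp=%d dropped_size_ge_%d=%d "
        "dropped_other=%d",
        path,
        len(kept),
        n_snp,
        max_size,
        n_large,
        n_other,
    )
    return kept


def _rna(allele: str) -> str:
    return allele.upper().replace("T", "U")


def _deletion_on_l(
    transcript: str, variant: VariantRecord
) -> Tuple[str, int, int]:
    """Resolve a variant to (l-allele transcript, deletion start, size).

    A deletion keeps the transcript as the l-allele; an insertion is handled
    by splicing the extra bases in, so the insertion-carrying sequence
    becomes the l-allele and the variant is again a deletion relative to it.
    """
    ref, alt = _rna(variant.ref), _rna(variant.alt)
    pos0 = variant.pos - 1
    if pos0 < 0 or pos0 + len(ref) > len(transcript):
        raise ParseError(
            f"{variant.variant_id}: REF outside transcript "
            f"{variant.transcript_id}"
        )
    if transcript[pos0 : pos0 + len(ref)] != ref:
        raise ParseError(
            f"{variant.variant_id}: REF does not match transcript "
            f"{variant.transcript_id} at position {variant.pos}"
        )
    if len(ref) > len(alt) and ref.startswith(alt):
        # deletion: the anchor prefix is a VCF artifact, not deleted sequence
        return transcript, pos0 + len(alt), len(ref) - len(alt)
    if len(alt) > len(ref) and alt.startswith(ref):
        extra = alt[len(ref) :]
        insert_at = pos0 + len(ref)
        l_transcript = transcript[:insert_at] + extra + transcript[insert_at:]
        return l_transcript, insert_at, len(extra)
    raise ParseError(
        f"{variant.variant_id}: unsupported allele pair {variant.ref}>"
        f"{variant.alt} (not a left-anchored indel)"
    )


def extract_fragment_centered(
    transcript: str,
    variant: VariantRecord,
    length: int = 150,
    origin: str = "human",
) -> Tuple[TranscriptFragment, IndelSpec]:
    """150-nt (by default) l-allele fragment with the deletion junction at
    the fragment midpoint (floor(length/2), 0-based), plus the fragment-local
    deletion spec. Variants without enough flanking sequence raise
    :class:`SkipRegion`."""
    l_transcript, del_start, size = _deletion_on_l(_rna(transcript), variant)
    junction = del_start + size
    frag_start = junction - length // 2
    if frag_start < 0 or frag_start + length > len(l_transcript):
        raise SkipRegion(
            f"{variant.variant_id}: insufficient flank for a {length}-nt "
            "centered fragment"
        )
    if del_start < frag_start:
        raise SkipRegion(
            f"{variant.variant_id}: deletion of size {size} does not fit "
            f"inside the {length}-nt fragment"
        )
    fragment = TranscriptFragment(
        id=f"{variant.transcript_id}:{variant.variant_id}",
        sequence=l_transcript[frag_start : frag_start + length],
        origin=origin,
    )
    indel = IndelSpec(
        l_start=del_start - frag_start,
        size=size,
        provenance="natural",
        variant_id=variant.variant_id,
    )
    return fragment, indel


def read_bed(path) -> List[BindingRegion]:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name"],
        usecols=[0, 1, 2, 3],
    )
    return [
        BindingRegion(
            transcript_id=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            name="" if pd.isna(r.name) else str(r.name),
        )
        for r in df.itertuples()
    ]


def write_bed(regions: Sequence[BindingRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# Candidate export
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "transcript",
    "indel_coordinate",
    "dbSNP_ID",
    "ref_allele",
    "alt_allele",
    "binding_site_locus",
    "binding_region_locus",
    "delta_delta_G",
    "transcript_ids",
]


@dataclass(frozen=True)
class CandidateRow:
    """One exported candidate: a natural indel whose predicted effect on
    binding affinity at the identified site exceeds thermal energy."""

    transcript: str
    indel_coordinate: int  # 1-based position of the first variant nucleotide
    dbSNP_ID: str
    ref_allele: str
    alt_allele: str
    binding_site_locus: str  # "start-end", 1-based closed, transcript space
    binding_region_locus: str
    delta_delta_G: float
    transcript_ids: str = ""


def export_candidates(
    rows: Sequence[CandidateRow],
    path,
    threshold: float = KT_KCAL_MOL,
    metadata: Optional[Dict[str, object]] = None,
) -> pd.DataFrame:
    """Write the candidate table, keeping only rows with |ddG| strictly
    above the thermal-energy threshold, sorted by (transcript, coordinate).
    Returns the exported frame."""
    df = pd.DataFrame([r.__dict__ for r in rows], columns=CANDIDATE_COLUMNS)
    df = df[df["delta_delta_G"].abs() > threshold]
    df = df.sort_values(["transcript", "indel_coordinate"]).reset_index(drop=True)
    _write_tsv_with_metadata(df, path, metadata)
    logger.info(
        "export_candidates: %d of %d rows exceed |ddG| > %.3f kcal/mol",
        len(df),
        len(rows),
        threshold,
    )
    return df


def _write_tsv_with_metadata(
    df: pd.DataFrame, path, metadata: Optional[Dict[str, object]]
) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_curves_tsv(
    points: Sequence[CurvePoint], path, metadata: Optional[Dict[str, object]] = None
) -> None:
    """Serialize curve points (group key, n, mean, sd, ci_low, ci_high) with
    run metadata as '#' header comments so a run can be replicated."""
    _write_tsv_with_metadata(curve_frame(points), path, metadata)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
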