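"""The binding-preference statistic ddG and site sweeps.

For an allele pair and a binding site present on both alleles,

    ddG = dG_l - dG_s,

where dG is the cost of forcing the site single-stranded on the respective
allele. Positive ddG means the protein prefers the shorter allele. Because
the site sequence itself is identical on both alleles, direct protein-RNA
contact energies cancel and ddG isolates the structural (accessibility)
effect of the indel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .alleles import (
    ABSENT,
    AllelePair,
    SiteWindow,
    indel_site_distance,
)
from .errors import BoundsError, OverlapError
from .folding import binding_delta_g, get_engine

logger = logging.getLogger(__name__)

CATEGORIES = (
    "synthetic_random",
    "synthetic_human",
    "synthetic_near_natural",
    "natural",
)
DOWNSTREAM = "downstream_3p"
UPSTREAM = "upstream_5p"
SIDES = (DOWNSTREAM, UPSTREAM)

#: Default sweep-window length (nt) and binding-site length (nt).
WINDOW_LEN = 50
SITE_LEN = 7


@dataclass(frozen=True)
class BindingPreference:
    """One ddG observation: the atomic datum of the analysis."""

    ddg: float
    dg_l: float
    dg_s: float
    distance: int
    indel_size: int
    site_l_start: int
    category: str = "synthetic_random"
    site_side: str = DOWNSTREAM


def binding_preference(
    pair: AllelePair,
    site: SiteWindow,
    engine="toy",
    category: str = "synthetic_random",
    site_side: Optional[str] = None,
    g_none: Optional[Tuple[float, float]] = None,
) -> BindingPreference:
    """Compute ddG for one allele pair at one site.

    ``g_none`` optionally carries precomputed unconstrained free energies
    (l-allele, s-allele) so sweeps fold each allele once.
    """
    if site.s_start is ABSENT:
        raise OverlapError(
            "site overlaps the deleted interval; no s-allele counterpart"
        )
    eng = get_engine(engine)
    g_none_l, g_none_s = g_none if g_none is not None else (None, None)
    dg_l = binding_delta_g(
        pair.l_seq, site.l_start, site.length, eng, g_none=g_none_l
    )
    dg_s = binding_delta_g(
        pair.s_seq, site.s_start, site.length, eng, g_none=g_none_s
    )
    distance = indel_site_distance(pair.indel, site.l_start, site.length)
    if site_side is None:
        site_side = (
            DOWNSTREAM if site.l_start >= pair.indel.junction else UPSTREAM
        )
    return BindingPreference(
        ddg=dg_l - dg_s,
        dg_l=dg_l,
        dg_s=dg_s,
        distance=distance,
        indel_size=pair.indel.size,
        site_l_start=site.l_start,
        category=category,
        site_side=site_side,
    )


def default_window(
    pair: AllelePair,
    side: str = DOWNSTREAM,
    window_len: int = WINDOW_LEN,
    end_margin: int = 0,
) -> Tuple[int, int]:
    """Sweep window adjacent to the indel on the requested side.

    Downstream: ``[junction, junction + window_len)`` clipped so it ends at
    least ``end_margin`` nt before the fragment end (natural-indel runs use
    end_margin=20). Upstream: the mirrored ``[l_start - window_len,
    l_start)`` clipped at the fragment start.
    """
    n = len(pair.l_seq)
    if side == DOWNSTREAM:
        start = pair.indel.junction
        end = min(start + window_len, n - end_margin)
    elif side == UPSTREAM:
        end = pair.indel.l_start
        start = max(end - window_len, end_margin)
    else:
        raise ValueError(f"side must be one of {SIDES}")
    return start, end


def sweep_sites(
    pair: AllelePair,
    window: Optional[Tuple[int, int]] = None,
    site_len: int = SITE_LEN,
    side: str = DOWNSTREAM,
    engine="toy",
    category: str = "synthetic_random",
) -> List[BindingPreference]:
    """ddG for every sliding ``site_len``-mer whose start lies in ``window``
    (0-based half-open on the l-allele); a 50-nt window yields 44 sites at
    distances 0..43 from the indel.

    The unconstrained free energy of each allele is folded once and shared
    across all constrained folds of the sweep.
    """
    eng = get_engine(engine)
    if window is None:
        window = default_window(pair, side)
    w_start, w_end = window
    if w_start < 0 or w_end > len(pair.l_seq):
        raise BoundsError(
            f"window [{w_start}, {w_end}) outside l-allele of length "
            f"{len(pair.l_seq)}"
        )
    indel = pair.indel
    if w_start < indel.junction and w_end > indel.l_start:
        raise OverlapError(
            f"window [{w_start}, {w_end}) overlaps deleted interval "
            f"[{indel.l_start}, {indel.junction})"
        )
    g_none = (
        eng.free_energy(pair.l_seq, None),
        eng.free_energy(pair.s_seq, None),
    )
    results: List[BindingPreference] = []
    for l_start in range(w_start, w_end - site_len + 1):
        site = SiteWindow.on_pair(pair, l_start, site_len)
        results.append(
            binding_preference(
                pair,
                site,
                eng,
                category=category,
                site_side=side,
                g_none=g_none,
            )
        )
    return results
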