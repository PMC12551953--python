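"""Aggregation of ddG observations into SD curves with bootstrap CIs.

The selection analysis works on dispersion, not means: an indel's structural
effect is equally likely to help or hurt binding, so the mean ddG is ~0 and
the standard deviation of ddG measures effect magnitude. Curves of SD versus
indel-site distance (or indel size) are compared between cohorts via 95%
percentile-bootstrap confidence intervals; purifying selection shows up as
one cohort's curve sitting below another's with separated CIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preference import BindingPreference

logger = logging.getLogger(__name__)

A_LOWER = "a_lower"
B_LOWER = "b_lower"
OVERLAP = "overlap"


@dataclass(frozen=True)
class BootstrapConfig:
    resamples: int = 5000
    level: float = 0.95
    seed: int = 0
    subsample_cap: int = 20000

    def __post_init__(self) -> None:
        if self.resamples < 1:
            raise ValueError("resamples must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")


@dataclass(frozen=True)
class CurvePoint:
    """Dispersion of ddG in one (group key, category, side) cell."""

    key: int  # distance (nt) or indel size (nt)
    sd: float
    n: int
    mean: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    category: str = ""
    site_side: str = ""


def _to_frame(observations: Iterable[BindingPreference]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "ddg": [o.ddg for o in observations],
            "distance": [o.distance for o in observations],
            "size": [o.indel_size for o in observations],
            "category": [o.category for o in observations],
            "site_side": [o.site_side for o in observations],
        }
    )


def sd_by_group(
    observations: Sequence[BindingPreference],
    group_on: str = "distance",
) -> List[CurvePoint]:
    """Sample standard deviation (n-1 denominator) and mean of ddG per group
    key; groups with fewer than two observations are dropped with a log
    entry."""
    if group_on not in ("distance", "size"):
        raise ValueError("group_on must be 'distance' or 'size'")
    df = _to_frame(observations)
    points: List[CurvePoint] = []
    for key, sub in df.groupby(group_on, sort=True):
        if len(sub) < 2:
            logger.warning(
                "dropping %s=%s group with n=%d < 2", group_on, key, len(sub)
            )
            continue
        points.append(
            CurvePoint(
                key=int(key),
                sd=float(sub["ddg"].std(ddof=1)),
                n=int(len(sub)),
                mean=float(sub["ddg"].mean()),
                category=str(sub["category"].iloc[0]),
                site_side=str(sub["site_side"].iloc[0]),
            )
        )
    return points


def bootstrap_sd_ci(
    values: Sequence[float], cfg: BootstrapConfig
) -> Tuple[float, float]:
    """Percentile bootstrap CI for the sample SD: resample n values with
    replacement ``cfg.resamples`` times and take the (1-level)/2 and
    (1+level)/2 quantiles of the resampled SDs. Deterministic given seed."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("need at least two values for an SD CI")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n, size=(cfg.resamples, n))
    sds = arr[idx].std(axis=1, ddof=1)
    alpha = (1.0 - cfg.level) / 2.0
    lo, hi = np.quantile(sds, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def subsample_cap(
    values: Sequence, cap: int, seed: int = 0
) -> List:
    """Uniform without-replacement subsample to at most ``cap`` items; inputs
    at or under the cap pass through unchanged."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    items = list(values)
    if len(items) <= cap:
        return items
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(items), size=cap, replace=False)
    keep.sort()
    return [items[i] for i in keep]


def build_curve(
    observations: Sequence[BindingPreference],
    group_on: str = "distance",
    cfg: Optional[BootstrapConfig] = None,
) -> List[CurvePoint]:
    """SD-vs-key curve with bootstrap CIs. Each group is capped at
    ``cfg.subsample_cap`` observations before computing the SD and its CI;
    per-group bootstrap seeds are derived from ``cfg.seed`` and the group
    key so adding a group never perturbs another group's resamples."""
    cfg = cfg or BootstrapConfig()
    if group_on not in ("distance", "size"):
        raise ValueError("group_on must be 'distance' or 'size'")
    df = _to_frame(observations)
    points: List[CurvePoint] = []
    for key, sub in df.groupby(group_on, sort=True):
        if len(sub) < 2:
            logger.warning(
                "dropping %s=%s group with n=%d < 2", group_on, key, len(sub)
            )
            continue
        ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(int(key),))
        sub_seed, boot_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)
        )
        # sort before resampling so results are invariant to input order
        vals = subsample_cap(
            np.sort(sub["ddg"].to_numpy()), cfg.subsample_cap, seed=sub_seed
        )
        arr = np.asarray(vals, dtype=float)
        lo, hi = bootstrap_sd_ci(
            arr,
            BootstrapConfig(
                resamples=cfg.resamples,
                level=cfg.level,
                seed=boot_seed,
                subsample_cap=cfg.subsample_cap,
            ),
        )
        points.append(
            CurvePoint(
                key=int(key),
                sd=float(arr.std(ddof=1)),
                n=int(arr.size),
                mean=float(arr.mean()),
                ci_low=lo,
                ci_high=hi,
                category=str(sub["category"].iloc[0]),
                site_side=str(sub["site_side"].iloc[0]),
            )
        )
    return points


def compare_categories(
    curve_a: Sequence[CurvePoint], curve_b: Sequence[CurvePoint]
) -> Dict[int, str]:
    """Per-key verdict comparing two SD curves by CI separation:
    'a_lower' where curve a's CI lies entirely below curve b's, 'b_lower'
    for the reverse, 'overlap' otherwise."""
    a_by_key = {p.key: p for p in curve_a}
    b_by_key = {p.key: p for p in curve_b}
    shared = sorted(set(a_by_key) & set(b_by_key))
    if not shared:
        raise KeyError("curves share no group keys")
    verdicts: Dict[int, str] = {}
    for key in shared:
        a, b = a_by_key[key], b_by_key[key]
        if a.ci_high is None or b.ci_high is None:
            raise ValueError("compare_categories requires CIs on both curves")
        if a.ci_high < b.ci_low:
            verdicts[key] = A_LOWER
        elif b.ci_high < a.ci_low:
            verdicts[key] = B_LOWER
        else:
            verdicts[key] = OVERLAP
    return verdicts


def curve_frame(points: Sequence[CurvePoint]) -> pd.DataFrame:
    """Tabular view of a curve (for TSV serialization and plotting)."""
    return pd.DataFrame(
        {
            "key": [p.key for p in points],
            "category": [p.category for p in points],
            "site_side": [p.site_side for p in points],
            "n": [p.n for p in points],
            "mean": [p.mean for p in points],
            "sd": [p.sd for p in points],
            "ci_low": [p.ci_low for p in points],
            "ci_high": [p.ci_high for p in points],
        }
    )
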