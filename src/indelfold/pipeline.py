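"""Scenario orchestration: generation -> allele pairs -> sweeps/site
identification -> curves -> TSV outputs.

Each scenario reproduces one figure-style analysis on synthetic stand-ins:

* ``fig2_random``   SD of ddG vs indel-site distance, random fragments.
* ``fig2_natural``  the same for a selection-filtered ("natural") cohort
                    with the natural-indel sweep window (ends 20 nt before
                    the fragment end).
* ``fig3_sizes``    SD of ddG vs indel size at fixed distances.
* ``fig5_categories`` synthetic-far vs synthetic-near vs natural cohorts.
* ``fig6_hur``      the same contrast for fragments near binding sites,
                    where purifying selection is emulated as stronger.
* ``fig7_controls`` identified sites in planted binding regions vs sites
                    identified in 300-nt-shifted control regions.
* ``s3_upstream``   upstream (5') vs downstream (3') sweep symmetry.
* ``candidates``    end-to-end file run: fixtures -> readers -> site
                    identification -> ddG -> thermal-energy-filtered
                    candidate table.

Runs are deterministic given the seed; every output TSV carries the seed and
engine in '#' header comments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .alleles import AllelePair, IndelSpec, SiteWindow, TranscriptFragment
from .constants import KT_KCAL_MOL
from .errors import ConfigError, SkipRegion
from .folding import get_engine
from .io import (
    CandidateRow,
    export_candidates,
    read_bed,
    read_fasta,
    read_indels,
    extract_fragment_centered,
    _write_tsv_with_metadata,
)
from .preference import (
    DOWNSTREAM,
    UPSTREAM,
    BindingPreference,
    binding_preference,
    default_window,
    sweep_sites,
)
from .sitefinder import (
    AffinityTable,
    BindingRegion,
    identify_site,
    shift_control_region,
)
from .stats import BootstrapConfig, build_curve, compare_categories, curve_frame
from .synthetic_data import (
    GeneratorConfig,
    SelectionModel,
    _planted_region_sequence,
    _rng_for,
    fig1_junction,
    make_fixtures,
    random_fragments,
    simulate_selection,
    synthetic_indel_fig1,
)

logger = logging.getLogger(__name__)

SCENARIOS = (
    "fig2_random",
    "fig2_natural",
    "fig3_sizes",
    "fig5_categories",
    "fig6_hur",
    "fig7_controls",
    "s3_upstream",
    "candidates",
)

_SIDE_ALIASES = {"3p": DOWNSTREAM, "5p": UPSTREAM, DOWNSTREAM: DOWNSTREAM, UPSTREAM: UPSTREAM}


@dataclass(frozen=True)
class RunConfig:
    scenario: str
    out_dir: Path
    seed: int = 0
    engine: str = "toy"
    n_fragments: int = 200
    fragment_length: int = 150
    indel_sizes: Tuple[int, ...] = (1, 3, 5)
    site_side: str = "3p"
    resamples: int = 1000
    subsample_cap: int = 20000
    near_offset: int = 20
    selection_threshold: float = KT_KCAL_MOL
    selection_retention: float = 0.0
    plots: bool = False


def _sub_seed(cfg: RunConfig, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _gen_cfg(cfg: RunConfig, stream: int) -> GeneratorConfig:
    return GeneratorConfig(
        seed=_sub_seed(cfg, stream),
        n_fragments=cfg.n_fragments,
        fragment_length=cfg.fragment_length,
        indel_sizes=cfg.indel_sizes,
    )


def _boot_cfg(cfg: RunConfig, stream: int) -> BootstrapConfig:
    return BootstrapConfig(
        resamples=cfg.resamples,
        seed=_sub_seed(cfg, stream),
        subsample_cap=cfg.subsample_cap,
    )


def _metadata(cfg: RunConfig) -> Dict[str, object]:
    return {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "engine": cfg.engine,
        "n_fragments": cfg.n_fragments,
        "fragment_length": cfg.fragment_length,
        "indelfold_version": __version__,
    }


def score_at_distance(
    pair: AllelePair,
    distance: int,
    engine="toy",
    category: str = "synthetic_random",
    side: str = DOWNSTREAM,
    g_none: Optional[Tuple[float, float]] = None,
) -> BindingPreference:
    """ddG at the single site located ``distance`` nt from the indel on the
    requested side."""
    if side == DOWNSTREAM:
        l_start = pair.indel.junction + distance
    else:
        l_start = pair.indel.l_start - distance - 7
    site = SiteWindow.on_pair(pair, l_start, 7)
    return binding_preference(
        pair, site, engine, category=category, site_side=side, g_none=g_none
    )


def select_cohort(
    pairs: Sequence[AllelePair],
    model: SelectionModel,
    engine="toy",
    seed: int = 0,
    category: str = "natural",
) -> List[AllelePair]:
    """Score each pair at the model's reference site and apply the
    purifying-selection filter."""
    ddgs = [
        score_at_distance(p, model.reference_distance, engine, category).ddg
        for p in pairs
    ]
    return simulate_selection(list(pairs), ddgs, model, seed=seed)


def _sweep_cohort(
    pairs: Sequence[AllelePair],
    engine,
    category: str,
    side: str = DOWNSTREAM,
    end_margin: int = 0,
) -> List[BindingPreference]:
    obs: List[BindingPreference] = []
    for pair in pairs:
        window = default_window(pair, side, end_margin=end_margin)
        obs.extend(
            sweep_sites(pair, window, side=side, engine=engine, category=category)
        )
    return obs


def _near_natural_pairs(
    fragments: Sequence[TranscriptFragment], size: int, near_offset: int
) -> List[AllelePair]:
    """Synthetic deletion placed ``near_offset`` nt 5' of the documented
    (here: fig-1 style) indel junction."""
    pairs = []
    for frag in fragments:
        junction = fig1_junction(frag.length) - near_offset
        indel = IndelSpec(l_start=junction - size, size=size, provenance="synthetic")
        pairs.append(AllelePair.from_deletion(frag.sequence, indel))
    return pairs


def _write_curgroups(
    frames: List[pd.DataFrame], out_path: Path, cfg: RunConfig
) -> pd.DataFrame:
    df = pd.concat(frames, ignore_index=True)
    _write_tsv_with_metadata(df, out_path, _metadata(cfg))
    return df


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def _scenario_fig2_random(cfg: RunConfig, out: Path) -> Dict[str, pd.DataFrame]:
    eng = get_engine(cfg.engine)
    side = _SIDE_ALIASES[cfg.site_side]
    fragments = random_fragments(_gen_cfg(cfg, 0))
    frames = []
    for size in cfg.indel_sizes:
        pairs = [synthetic_indel_fig1(f, size) for f in fragments]
        obs = _sweep_cohort(pairs, eng, "synthetic_random", side=side)
        curve = build_curve(obs, "distance", _boot_cfg(cfg, 10 + size))
        frame = curve_frame(curve)
        frame.insert(0, "size", size)
        frames.append(frame)
    df = _write_curgroups(frames, out / "curves_fig2_random.tsv", cfg)
    return {"curves": df}


def _scenario_fig2_natural(cfg: RunConfig, out: Path) -> Dict[str, pd.DataFrame]:
    eng = get_engine(cfg.engine)
    fragments = random_fragments(_gen_cfg(cfg, 0), origin="human")
    model = SelectionModel(cfg.selection_threshold, cfg.selection_retention)
    frames = []
    for size in cfg.indel_sizes:
        pairs = [synthetic_indel_fig1(f, size) for f in fragments]
        retained = select_cohort(
            pairs, model, eng, seed=_sub_seed(cfg, 20 + size), category="natural"
        )
        obs = _sweep_cohort(
            retained, eng, "natural", side=_SIDE_ALIASES[cfg.site_side], end_margin=20
        )
        curve = build_curve(obs, "distance", _boot_cfg(cfg, 30 + size))
        frame = curve_frame(curve)
        frame.insert(0, "size", size)
        frames.append(frame)
    df = _write_curgroups(frames, out / "curves_fig2_natural.tsv", cfg)
    return {"curves": df}


def _scenario_fig3_sizes(cfg: RunConfig, out: Path) -> Dict[str, pd.DataFrame]:
    eng = get_engine(cfg.engine)
    fragments = random_fragments(_gen_cfg(cfg, 0))
    sizes = (1, 2, 3, 4, 5)
    distances = (0, 10, 20)
    obs_by_distance: Dict[int, List[BindingPreference]] = {d: [] for d in distances}
    for size in sizes:
        for frag in fragments:
            pair = synthetic_indel_fig1(frag, size)
            g_none = (
                eng.free_energy(pair.l_seq, None),
                eng.free_energy(pair.s_seq, None),
            )
            for d in distances:
                obs_by_distance[d].append(
                    score_at_distance(
                        pair, d, eng, "synthetic_random", g_none=g_none
                    )
                )
    frames = []
    for d in distances:
        curve = build_curve(obs_by_distance[d], "size", _boot_cfg(cfg, 40 + d))
        frame = curve_frame(curve)
        frame.insert(0, "distance", d)
        frames.append(frame)
    df = _write_curgroups(frames, out / "curves_fig3_sizes.tsv", cfg)
    return {"curves": df}


def _three_category_run(
    cfg: RunConfig,
    out: Path,
    origin: str,
    natural_threshold: float,
    tsv_name: str,
) -> Dict[str, pd.DataFrame]:
    eng = get_engine(cfg.engine)
    model = SelectionModel(natural_threshold, cfg.selection_retention)
    curve_frames, verdict_rows = [], []
    for size in cfg.indel_sizes:
        frags_far = random_fragments(_gen_cfg(cfg, 50 + size), origin=origin)
        frags_near = random_fragments(_gen_cfg(cfg, 60 + size), origin=origin)
        frags_nat = random_fragments(_gen_cfg(cfg, 70 + size), origin=origin)
        far = [synthetic_indel_fig1(f, size) for f in frags_far]
        near = _near_natural_pairs(frags_near, size, cfg.near_offset)
        nat_all = [synthetic_indel_fig1(f, size) for f in frags_nat]
        nat = select_cohort(
            nat_all, model, eng, seed=_sub_seed(cfg, 80 + size), category="natural"
        )
        cohorts = {
            "synthetic_human": _sweep_cohort(far, eng, "synthetic_human"),
            "synthetic_near_natural": _sweep_cohort(
                near, eng, "synthetic_near_natural"
            ),
            "natural": _sweep_cohort(nat, eng, "natural"),
        }
        curves = {}
        for j, (cat, obs) in enumerate(cohorts.items()):
            curves[cat] = build_curve(
                obs, "distance", _boot_cfg(cfg, 90 + 10 * size + j)
            )
            frame = curve_frame(curves[cat])
            frame.insert(0, "size", size)
            curve_frames.append(frame)
        verdicts = compare_categories(curves["natural"], curves["synthetic_human"])
        verdict_rows.extend(
            {"size": size, "distance": k, "natural_vs_synthetic": v}
            for k, v in verdicts.items()
        )
    df = _write_curgroups(curve_frames, out / tsv_name, cfg)
    vdf = pd.DataFrame(verdict_rows)
    _write_tsv_with_metadata(vdf, out / tsv_name.replace("curves", "verdicts"), _metadata(cfg))
    return {"curves": df, "verdicts": vdf}


def _scenario_fig5_categories(cfg: RunConfig, out: Path):
    return _three_category_run(
        cfg, out, "human", cfg.selection_threshold, "curves_fig5_categories.tsv"
    )


def _scenario_fig6_hur(cfg: RunConfig, out: Path):
    # Stronger purifying selection emulates the context of functional
    # binding sites, where disruptive indels carry the largest fitness cost.
    return _three_category_run(
        cfg,
        out,
        "human_near_site",
        cfg.selection_threshold / 2.0,
        "curves_fig6_hur.tsv",
    )


def _scenario_fig7_controls(cfg: RunConfig, out: Path) -> Dict[str, pd.DataFrame]:
    eng = get_engine(cfg.engine)
    from .synthetic_data import synthetic_affinity_table

    aff = synthetic_affinity_table(beta=1.0, seed=_sub_seed(cfg, 100))
    model = SelectionModel(cfg.selection_threshold, cfg.selection_retention)
    sizes = cfg.indel_sizes
    transcript_len, region_start, junction = 600, 400, 375
    natural_obs: List[BindingPreference] = []
    control_obs: List[BindingPreference] = []
    rng_sel = np.random.default_rng(_sub_seed(cfg, 101))
    n_skipped = 0
    for i in range(cfg.n_fragments):
        rng = _rng_for(_sub_seed(cfg, 102), i)
        offset = int(rng.integers(0, 25 - 7 + 1))
        seq = _planted_region_sequence(rng, transcript_len, region_start, offset)
        size = sizes[i % len(sizes)]
        region = BindingRegion("tx", region_start, region_start + 25)
        # --- natural arm: indel centered, planted region downstream ---
        frag_start = junction - 75
        frag = seq[frag_start : frag_start + 150]
        indel = IndelSpec(l_start=75 - size, size=size, provenance="natural")
        pair = AllelePair.from_deletion(frag, indel)
        local = BindingRegion(
            "tx", region.start - frag_start, region.end - frag_start
        )
        site = identify_site(pair, local, aff, eng)
        bp = binding_preference(pair, site, eng, category="natural")
        if abs(bp.ddg) <= model.threshold or rng_sel.random() < model.retention:
            natural_obs.append(bp)
        # --- control arm: region shifted 300 nt 5'-ward, fresh indel near it
        try:
            ctrl = shift_control_region(region)
        except SkipRegion:
            n_skipped += 1
            continue
        ctrl_junction = ctrl.start - 25  # same indel-region spacing as natural
        cfrag_start = ctrl_junction - 75
        cfrag = seq[cfrag_start : cfrag_start + 150]
        cindel = IndelSpec(l_start=75 - size, size=size, provenance="natural")
        cpair = AllelePair.from_deletion(cfrag, cindel)
        clocal = BindingRegion(
            "tx", ctrl.start - cfrag_start, ctrl.end - cfrag_start
        )
        csite = identify_site(cpair, clocal, aff, eng)
        control_obs.append(
            binding_preference(cpair, csite, eng, category="synthetic_human")
        )
    nat_curve = build_curve(natural_obs, "distance", _boot_cfg(cfg, 110))
    ctrl_curve = build_curve(control_obs, "distance", _boot_cfg(cfg, 111))
    frames = []
    for label, curve in (("natural_site", nat_curve), ("shifted_control", ctrl_curve)):
        frame = curve_frame(curve)
        frame.insert(0, "site_type", label)
        frames.append(frame)
    df = _write_curgroups(frames, out / "curves_fig7_controls.tsv", cfg)
    return {"curves": df}


def _scenario_s3_upstream(cfg: RunConfig, out: Path) -> Dict[str, pd.DataFrame]:
    eng = get_engine(cfg.engine)
    fragments = random_fragments(_gen_cfg(cfg, 0))
    frames = []
    for size in cfg.indel_sizes:
        pairs = [synthetic_indel_fig1(f, size) for f in fragments]
        for j, side in enumerate((DOWNSTREAM, UPSTREAM)):
            obs = _sweep_cohort(pairs, eng, "synthetic_random", side=side)
            curve = build_curve(obs, "distance", _boot_cfg(cfg, 120 + 10 * size + j))
            frame = curve_frame(curve)
            frame.insert(0, "size", size)
            frames.append(frame)
    df = _write_curgroups(frames, out / "curves_s3_upstream.tsv", cfg)
    return {"curves": df}


def _scenario_candidates(cfg: RunConfig, out: Path) -> Dict[str, pd.DataFrame]:
    eng = get_engine(cfg.engine)
    fixture_dir = out / "fixtures"
    paths = make_fixtures(fixture_dir, _gen_cfg(cfg, 0))
    transcripts = read_fasta(paths["fasta"])
    variants = read_indels(paths["vcf"])
    regions = {r.transcript_id: r for r in read_bed(paths["bed"])}
    table = AffinityTable.from_tsv(paths["affinity"])
    rows: List[CandidateRow] = []
    n_skipped = 0
    for variant in variants:
        transcript = transcripts[variant.transcript_id]
        region = regions[variant.transcript_id]
        try:
            fragment, indel = extract_fragment_centered(transcript, variant)
        except SkipRegion as exc:
            logger.info("skipping %s: %s", variant.variant_id, exc)
            n_skipped += 1
            continue
        offset = _fragment_offset(variant, indel)
        local = BindingRegion(
            variant.transcript_id,
            region.start - offset,
            region.end - offset,
            region.name,
        )
        pair = AllelePair.from_deletion(fragment.sequence, indel)
        try:
            site = identify_site(pair, local, table, eng)
        except SkipRegion as exc:
            logger.info("skipping %s: %s", variant.variant_id, exc)
            n_skipped += 1
            continue
        bp = binding_preference(pair, site, eng, category="natural")
        rows.append(
            CandidateRow(
                transcript=variant.transcript_id,
                indel_coordinate=variant.pos + 1,
                dbSNP_ID=variant.variant_id,
                ref_allele=variant.ref,
                alt_allele=variant.alt,
                binding_site_locus=(
                    f"{offset + site.l_start + 1}-{offset + site.l_start + site.length}"
                ),
                binding_region_locus=f"{region.start + 1}-{region.end}",
                delta_delta_G=bp.ddg,
                transcript_ids=variant.transcript_id,
            )
        )
    df = export_candidates(rows, out / "candidates.tsv", metadata=_metadata(cfg))
    logger.info("candidates: %d scored, %d skipped", len(rows), n_skipped)
    return {"candidates": df}


def _fragment_offset(variant, indel: IndelSpec, length: int = 150) -> int:
    """Transcript coordinate of the extracted fragment's first nucleotide,
    reconstructed from the centering rule of extract_fragment_centered."""
    junction_on_transcript = (variant.pos - 1) + len(variant.alt) + indel.size
    return junction_on_transcript - length // 2


_SCENARIO_FUNCS = {
    "fig2_random": _scenario_fig2_random,
    "fig2_natural": _scenario_fig2_natural,
    "fig3_sizes": _scenario_fig3_sizes,
    "fig5_categories": _scenario_fig5_categories,
    "fig6_hur": _scenario_fig6_hur,
    "fig7_controls": _scenario_fig7_controls,
    "s3_upstream": _scenario_s3_upstream,
    "candidates": _scenario_candidates,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute one scenario; writes TSVs plus run metadata into
    ``cfg.out_dir`` and returns that directory. Idempotent given the seed."""
    if cfg.scenario not in _SCENARIO_FUNCS:
        raise ConfigError(
            f"unknown scenario {cfg.scenario!r}; expected one of {SCENARIOS}"
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = _SCENARIO_FUNCS[cfg.scenario](cfg, out)
    meta = _metadata(cfg)
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    if cfg.plots and "curves" in results:
        from .plotting import plot_sd_curves

        plot_sd_curves(results["curves"], out / f"{cfg.scenario}.png")
    return out
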