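"""Partition-function RNA folding with single-strandedness constraints.

Two engines sit behind one contract (sequence, optional constrained
interval, temperature -> ensemble free energy in kcal/mol):

* ``nearest_neighbor`` — the ViennaRNA thermodynamic engine (Turner 2004
  parameters, 37 degC defaults) through its Python bindings, with hard
  "must be unpaired" constraints on the binding site.
* ``toy`` — a built-in simplified model: every canonical pair (AU, UA, GC,
  CG, GU, UG) contributes a fixed energy eps, hairpin loops must enclose at
  least ``min_hairpin`` unpaired nucleotides, and the partition function is
  computed exactly by the standard O(n^3) recursion
  ``Z(i,j) = Z(i+1,j) + sum_k w * Z(i+1,k-1) * Z(k+1,j)``.

The toy engine exists so that every energy in the test suite can be checked
against an independent brute-force enumeration of all pseudoknot-free
structures (:func:`enumerate_structures`), which is exponential and guarded
to short sequences.

Protein binding is modelled as forcing the binding site single-stranded;
its energetic cost is ``delta_G = G_constraint - G_none >= 0``
(:func:`binding_delta_g`), since constraining can only shrink the ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, List, Optional, Tuple

import numpy as np
from numba import njit

from .alleles import validate_rna
from .constants import BODY_TEMPERATURE_K, thermal_energy
from .errors import (
    BoundsError,
    ConfigError,
    EngineUnavailableError,
    GuardError,
)

ENGINE_NAMES = ("toy", "nearest_neighbor")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
# With this encoding a pair is allowed iff the codes sum to 3 (AU/UA, GC/CG)
# or 5 (GU/UG).
_ALLOWED_CODE_SUMS = (3, 5)


@dataclass(frozen=True)
class FoldConstraint:
    """Force ``ss_length`` nucleotides starting at ``ss_start`` (0-based) to
    stay single-stranded (participate in no base pair)."""

    ss_start: int
    ss_length: int

    def __post_init__(self) -> None:
        if self.ss_start < 0 or self.ss_length < 0:
            raise BoundsError("constraint interval must be non-negative")

    def check_within(self, seq: str) -> None:
        if self.ss_start + self.ss_length > len(seq):
            raise BoundsError(
                f"constraint [{self.ss_start}, "
                f"{self.ss_start + self.ss_length}) outside sequence of "
                f"length {len(seq)}"
            )


@dataclass(frozen=True)
class FoldEnergy:
    """Ensemble (partition-function) free energy, kcal/mol."""

    g: float
    engine: str
    temperature: float = BODY_TEMPERATURE_K


@dataclass(frozen=True)
class ToyModelParams:
    """Parameters of the built-in simplified folding model."""

    pair_energy: float = -1.0  # kcal/mol per pair; must be stabilizing
    min_hairpin: int = 3  # minimum unpaired nucleotides in a hairpin loop
    kT: float = thermal_energy()  # kcal/mol

    def __post_init__(self) -> None:
        if self.pair_energy >= 0:
            raise ValueError("pair_energy must be negative")
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")


def encode(seq: str) -> np.ndarray:
    validate_rna(seq)
    return np.fromiter((_BASE_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def _pairable_mask(n: int, constraint: Optional[FoldConstraint]) -> np.ndarray:
    mask = np.ones(n, dtype=np.bool_)
    if constraint is not None:
        mask[constraint.ss_start : constraint.ss_start + constraint.ss_length] = False
    return mask


@njit(cache=True)
def _toy_partition(code, pairable, eps, kT, min_hairpin):  # pragma: no cover
    n = code.shape[0]
    # Z[i, j]: partition function of the half-open subsequence [i, j).
    Z = np.ones((n + 1, n + 1))
    w = np.exp(-eps / kT)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            acc = Z[i + 1, j]  # i unpaired
            if pairable[i]:
                si = code[i]
                for k in range(i + min_hairpin + 1, j):
                    if pairable[k]:
                        s = si + code[k]
                        if s == 3 or s == 5:
                            acc += w * Z[i + 1, k] * Z[k + 1, j]
            Z[i, j] = acc
    return Z[0, n]


class ToyEngine:
    """Exact partition function under the simplified per-pair energy model."""

    name = "toy"

    def __init__(self, params: Optional[ToyModelParams] = None):
        self.params = params or ToyModelParams()
        self.temperature = BODY_TEMPERATURE_K

    def free_energy(
        self, seq: str, constraint: Optional[FoldConstraint] = None
    ) -> float:
        if not seq:
            raise ValueError("empty sequence")
        if constraint is not None:
            constraint.check_within(seq)
        code = encode(seq)
        mask = _pairable_mask(len(seq), constraint)
        p = self.params
        z = _toy_partition(code, mask, p.pair_energy, p.kT, p.min_hairpin)
        return -p.kT * math.log(z)


class ViennaEngine:
    """Nearest-neighbor thermodynamic engine (ViennaRNA, Turner 2004
    defaults). Constrained positions are forced unpaired with hard
    constraints before computing the partition function."""

    name = "nearest_neighbor"

    def __init__(self, temperature_c: float = 37.0):
        try:
            import RNA  # noqa: F401  (ViennaRNA python bindings)
        except ImportError as exc:  # pragma: no cover - env-dependent
            raise EngineUnavailableError(
                "ViennaRNA python bindings are not importable; use the "
                "'toy' engine instead"
            ) from exc
        self._RNA = RNA
        self.temperature_c = temperature_c
        self.temperature = temperature_c + 273.15

    def free_energy(
        self, seq: str, constraint: Optional[FoldConstraint] = None
    ) -> float:
        if not seq:
            raise ValueError("empty sequence")
        validate_rna(seq)
        if constraint is not None:
            constraint.check_within(seq)
        RNA = self._RNA
        md = RNA.md()
        md.temperature = self.temperature_c
        fc = RNA.fold_compound(seq, md)
        if constraint is not None:
            for pos in range(
                constraint.ss_start + 1,
                constraint.ss_start + constraint.ss_length + 1,
            ):  # hc_add_up takes 1-based positions
                fc.hc_add_up(pos)
        _, g = fc.pf()
        return float(g)


class CountingEngine:
    """Wrapper that counts ``free_energy`` calls; used to verify that
    G_none is computed once per allele and reused across site sweeps."""

    def __init__(self, inner):
        self.inner = inner
        self.name = inner.name
        self.temperature = inner.temperature
        self.calls = 0

    def free_energy(self, seq, constraint=None):
        self.calls += 1
        return self.inner.free_energy(seq, constraint)


def get_engine(engine="toy", **kwargs):
    """Resolve an engine name ('toy' or 'nearest_neighbor') to an engine
    instance; an engine object passes through unchanged."""
    if hasattr(engine, "free_energy"):
        return engine
    if engine == "toy":
        return ToyEngine(**kwargs)
    if engine == "nearest_neighbor":
        return ViennaEngine(**kwargs)
    raise ConfigError(
        f"unknown engine {engine!r}; expected one of {ENGINE_NAMES}"
    )


def partition_free_energy(
    seq: str,
    constraint: Optional[FoldConstraint] = None,
    engine="toy",
    **engine_kwargs,
) -> FoldEnergy:
    """Ensemble free energy -kT ln Z over all pseudoknot-free structures,
    with constrained positions excluded from pairing."""
    eng = get_engine(engine, **engine_kwargs)
    return FoldEnergy(
        g=eng.free_energy(seq, constraint),
        engine=eng.name,
        temperature=eng.temperature,
    )


def binding_delta_g(
    seq: str,
    site_start: int,
    site_len: int = 7,
    engine="toy",
    g_none: Optional[float] = None,
) -> float:
    """Energetic cost of making a binding site accessible:
    ``G_constraint - G_none`` (>= 0 up to engine round-off).

    ``g_none`` may carry a precomputed unconstrained free energy so a sweep
    over many sites folds the unconstrained sequence only once.
    """
    eng = get_engine(engine)
    constraint = FoldConstraint(site_start, site_len)
    constraint.check_within(seq)
    if g_none is None:
        g_none = eng.free_energy(seq, None)
    g_con = eng.free_energy(seq, constraint)
    return g_con - g_none


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle (exponential; short sequences only)
# ---------------------------------------------------------------------------

_ENUM_MAX_LEN = 20


def _enumerate_pairsets(
    code: np.ndarray,
    pairable: np.ndarray,
    i: int,
    j: int,
    min_hairpin: int,
) -> Iterator[Tuple[Tuple[int, int], ...]]:
    """All non-crossing sets of allowed pairs on the half-open interval
    [i, j), honouring the hairpin minimum and the unpaired mask."""
    if j - i <= 0:
        yield ()
        return
    # Case 1: position i unpaired.
    yield from _enumerate_pairsets(code, pairable, i + 1, j, min_hairpin)
    # Case 2: i paired with some k.
    if pairable[i]:
        for k in range(i + min_hairpin + 1, j):
            if pairable[k] and (code[i] + code[k]) in _ALLOWED_CODE_SUMS:
                for inner in _enumerate_pairsets(
                    code, pairable, i + 1, k, min_hairpin
                ):
                    for outer in _enumerate_pairsets(
                        code, pairable, k + 1, j, min_hairpin
                    ):
                        yield ((i, k),) + inner + outer


def enumerate_structures(
    seq: str,
    constraint: Optional[FoldConstraint] = None,
    params: Optional[ToyModelParams] = None,
) -> List[Tuple[Tuple[Tuple[int, int], ...], float]]:
    """Every pseudoknot-free structure with its Boltzmann weight under the
    toy model. The sum of the weights equals the toy partition function;
    this is the independent oracle for :class:`ToyEngine`."""
    if len(seq) > _ENUM_MAX_LEN:
        raise GuardError(
            f"enumeration limited to sequences of length <= {_ENUM_MAX_LEN}"
        )
    params = params or ToyModelParams()
    if constraint is not None:
        constraint.check_within(seq)
    code = encode(seq)
    mask = _pairable_mask(len(seq), constraint)
    w = math.exp(-params.pair_energy / params.kT)
    return [
        (pairs, w ** len(pairs))
        for pairs in _enumerate_pairsets(
            code, mask, 0, len(seq), params.min_hairpin
        )
    ]


def enumeration_free_energy(
    seq: str,
    constraint: Optional[FoldConstraint] = None,
    params: Optional[ToyModelParams] = None,
) -> float:
    """-kT ln(sum of enumerated Boltzmann weights)."""
    params = params or ToyModelParams()
    z = sum(wt for _, wt in enumerate_structures(seq, constraint, params))
    return -params.kT * math.log(z)
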