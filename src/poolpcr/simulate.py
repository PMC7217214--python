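"""Cycle-by-cycle PCR simulation on heterogeneous template pools.

Each cycle is melt -> anneal -> extend.  After melting, every sense strand
competes for a partner: primer B' versus an antisense strand, chosen with
probability proportional to their concentrations (and symmetrically for
antisense strands and primer A).  A strand-strand pairing is perfectly
matched with probability ``p0 + eps`` where ``p0`` is the reciprocal of the
effective number of species in the pool (a random partner is the exact
complement) and ``eps`` is a small thermodynamic re-equilibration bias;
otherwise its mismatch count is distributed over the pool's pairwise
mismatch law.  Primer-template hybrids are extended by polymerase into
perfectly matched duplexes, consuming primer.  Fluorescence per cycle sums
duplex concentrations weighted by the mismatch-dependent dye-signal factor,
normalized to the plateau of a single-sequence reference run.

The pool is tracked as a mismatch-count histogram, not per sequence: a
20-position fully degenerate library has ~10^12 members, but under
exchangeability only the pairing statistics matter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .duplex import (
    DuplexClass,
    DuplexKind,
    FFunction,
    ThermalParams,
    dye_signal_factor,
    functional_factor,
)
from .library import CodeSet, LibrarySpec, diversity, hamming, mismatch_distribution

__all__ = [
    "MismatchComponent",
    "PairingModel",
    "SimConfig",
    "PoolState",
    "Trajectory",
    "pairing_from_library",
    "pairing_from_code_set",
    "restriction_mixture_pairing",
    "reference_pairing",
    "anneal_step",
    "extend_step",
    "simulate",
    "detect_turning_point",
    "ct_shift_series",
]

_MAX_NETWORK_LENGTH = 64  # strand-length histogram cap (units of one amplicon)


@dataclass(frozen=True)
class MismatchComponent:
    """One labeled component of the mismatched-pairing law.

    ``weight`` is the probability that a mismatched strand-strand pairing
    belongs to this component; ``m_values``/``probs`` give the conditional
    mismatch-count pmf.  Labels carry bookkeeping such as which restriction
    site both strands share (``site:EcoRV``) or that the strands come from
    different sublibraries (``cross``).
    """

    label: str
    weight: float
    m_values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if abs(math.fsum(self.probs) - 1.0) > 1e-9:
            raise ValueError("component pmf must sum to 1")


@dataclass(frozen=True)
class PairingModel:
    """Reannealing statistics of a template pool.

    ``effective_species`` sets the perfect-match probability ``p0`` of a
    random strand-strand pairing (diversity for degenerate libraries, member
    count for uniform code sets, inverse Simpson index for weighted pools).
    ``matched_labels`` distributes matched/extended duplexes over bookkeeping
    labels; ``default_bias`` is the re-equilibration bias used when the
    config leaves it unset.
    """

    name: str
    effective_species: float
    components: tuple[MismatchComponent, ...]
    matched_labels: tuple[tuple[str, float], ...] = (("", 1.0),)
    default_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.effective_species < 1:
            raise ValueError("effective_species must be >= 1")
        weights = math.fsum(c.weight for c in self.components)
        if self.components and abs(weights - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")


def reference_pairing() -> PairingModel:
    """A diversity-1 pool: every strand-strand pairing is perfectly matched."""
    return PairingModel("reference", 1.0, ())


def pairing_from_library(spec: LibrarySpec) -> PairingModel:
    """Pairing statistics of a degenerate library with uniform composition."""
    d = diversity(spec)
    if d == 1:
        return PairingModel(spec.name, 1.0, ())
    dist = mismatch_distribution(spec, distinct_members=True)
    m, p = dist.as_arrays()
    keep = p > 0
    component = MismatchComponent("", 1.0, tuple(int(x) for x in m[keep]), tuple(p[keep]))
    return PairingModel(spec.name, float(d), (component,))


def pairing_from_code_set(
    code_set: CodeSet,
    abundances: Sequence[float] | None = None,
    name: str | None = None,
) -> PairingModel:
    """Pairing statistics of a finite code set, optionally abundance-weighted.

    ``p0`` uses the inverse Simpson index; the mismatch pmf is the pairwise
    distance histogram over distinct member pairs weighted by abundance.
    A positive re-equilibration bias (default 0.2) is the default for code
    sets: annealing of a few discrete species partially re-equilibrates
    toward the thermodynamically favored perfect duplexes — enough to lift
    the curve visibly above a fully degenerate pool of the same pairwise
    distances, far too little to approach perfect matching.
    """
    k = len(code_set.members)
    if abundances is None:
        a = np.full(k, 1.0 / k)
    else:
        a = np.asarray(abundances, dtype=float)
        if a.size != k or np.any(a < 0) or a.sum() <= 0:
            raise ValueError("abundances must be non-negative, one per member, not all zero")
        a = a / a.sum()
    n_eff = 1.0 / float(np.sum(a**2))
    if k == 1:
        return PairingModel(name or "code_set", 1.0, ())
    dist_weights: dict[int, float] = {}
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            d = hamming(code_set.members[i], code_set.members[j])
            dist_weights[d] = dist_weights.get(d, 0.0) + float(a[i] * a[j])
    total = math.fsum(dist_weights.values())
    if total <= 0:  # a single member carries all abundance
        return PairingModel(name or "code_set", n_eff, ())
    ms = tuple(sorted(dist_weights))
    probs = tuple(dist_weights[m] / total for m in ms)
    component = MismatchComponent("", 1.0, ms, probs)
    return PairingModel(name or "code_set", n_eff, (component,), default_bias=0.2)


def restriction_mixture_pairing(
    n_random: int = 14,
    site_a: str = "GATATC",
    site_b: str = "CCCGGG",
    names: tuple[str, str] = ("EcoRV", "SmaI"),
) -> PairingModel:
    """Pairing statistics of an equal mixture of two sublibraries, each with a
    fixed 6-nt restriction site embedded in an otherwise degenerate region.

    Same-sublibrary pairings share the site as a perfect homoduplex (and are
    labeled cuttable by that enzyme); cross-sublibrary pairings carry a
    site/site heteroduplex, adding the inter-site distance to the mismatch
    count and protecting the site from either enzyme.
    """
    site_m = hamming(site_a, site_b)
    random_spec = LibrarySpec(
        "random_core", "A" * 20, "A" * 20, tuple([frozenset("ACGT")] * n_random)
    )
    dist = mismatch_distribution(random_spec, distinct_members=True)
    m, p = dist.as_arrays()
    keep = p > 0
    same_m = tuple(int(x) for x in m[keep])
    same_p = tuple(p[keep])
    dist_all = mismatch_distribution(random_spec, distinct_members=False)
    m2, p2 = dist_all.as_arrays()
    cross_m = tuple(int(x) + site_m for x in m2)
    cross_p = tuple(p2)
    components = (
        MismatchComponent(f"site:{names[0]}", 0.25, same_m, same_p),
        MismatchComponent(f"site:{names[1]}", 0.25, same_m, same_p),
        MismatchComponent("cross", 0.5, cross_m, cross_p),
    )
    return PairingModel(
        name=f"mixture_{names[0]}_{names[1]}",
        effective_species=2.0 * 4.0**n_random,
        components=components,
        matched_labels=((f"site:{names[0]}", 0.5), (f"site:{names[1]}", 0.5)),
    )


@dataclass
class SimConfig:
    """Run conditions for a simulated amplification.

    Defaults are the standard bench condition: 45 cycles, 50 nM primers,
    100 pM template, extension efficiency 0.95, readout at the configured
    elongation temperature.  ``reequilibration_bias`` of ``None`` defers to
    the pairing model's own default (0.05 for code sets, 0 otherwise).
    ``initial_copies`` sets the template copy number in finite-copy mode.
    """

    cycles: int = 45
    extension_efficiency: float = 0.95
    reequilibration_bias: float | None = None
    thermal: ThermalParams = field(default_factory=ThermalParams)
    f_function: FFunction = field(default_factory=FFunction)
    initial_template_conc: float = 100e-12
    primer_conc: float = 50e-9
    mode: str = "deterministic"
    network_extension: bool = False
    network_rate: float = 0.02
    seed: int | None = None
    initial_copies: int = 100_000
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not 0.0 <= self.extension_efficiency <= 1.0:
            raise ValueError("extension_efficiency must be a probability")
        if self.reequilibration_bias is not None and not 0.0 <= self.reequilibration_bias <= 1.0:
            raise ValueError("reequilibration_bias must be a probability")
        if self.initial_template_conc <= 0 or self.primer_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.mode not in ("deterministic", "finite_copy"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "finite_copy" and self.seed is None:
            raise ValueError("finite_copy mode requires a seed")
        if self.network_extension and self.mode != "deterministic":
            raise ValueError("network_extension is modeled in deterministic mode only")


@dataclass
class PoolState:
    """Snapshot of the pool at one cycle.

    ``duplex_classes`` maps ``(kind, label, m)`` to concentration for the
    duplexes present at readout.  Annealing only re-partners strands; strand
    totals change only by extension.
    """

    cycle: int
    primer_a_conc: float
    primer_b_conc: float
    sense_strand_conc: float
    antisense_strand_conc: float
    duplex_classes: dict[tuple[DuplexKind, str, int], float]
    aggregate_mass: float = 0.0
    length_pmf: np.ndarray | None = None

    def full_duplex_classes(self) -> list[DuplexClass]:
        return [
            DuplexClass(kind, m, conc, label)
            for (kind, label, m), conc in self.duplex_classes.items()
            if kind in (DuplexKind.MATCHED_FULL, DuplexKind.MISMATCHED_FULL)
            and conc > 0
        ]


@dataclass
class Trajectory:
    """Per-cycle record of a simulated amplification (cycle 0 = input pool)."""

    cycle: np.ndarray
    fluorescence: np.ndarray
    pool_f: np.ndarray
    primer_a: np.ndarray
    primer_b: np.ndarray
    matched_conc: np.ndarray
    mismatched_conc: np.ndarray
    aggregate_mass: np.ndarray
    name: str = ""
    final_state: PoolState | None = None

    def __post_init__(self) -> None:
        n = self.cycle.size
        for attr in ("fluorescence", "pool_f", "primer_a", "primer_b",
                     "matched_conc", "mismatched_conc", "aggregate_mass"):
            if getattr(self, attr).size != n:
                raise ValueError("trajectory columns must have equal length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "fluorescence": self.fluorescence,
                "pool_F": self.pool_f,
                "primer_a": self.primer_a,
                "primer_b": self.primer_b,
                "matched_conc": self.matched_conc,
                "mismatched_conc": self.mismatched_conc,
                "aggregate_mass": self.aggregate_mass,
            }
        )


def _resolve_pairing(library) -> PairingModel:
    if isinstance(library, PairingModel):
        return library
    if isinstance(library, LibrarySpec):
        return pairing_from_library(library)
    if isinstance(library, CodeSet):
        return pairing_from_code_set(library)
    raise TypeError(
        "library must be a LibrarySpec, CodeSet, or PairingModel, "
        f"got {type(library).__name__}"
    )


def anneal_step(
    state: PoolState, library, config: SimConfig
) -> PoolState:
    """Re-partner all strands of a post-melt pool (deterministic expectation).

    Each sense strand pairs with primer B' versus an antisense strand in
    proportion to their concentrations; strand-strand pairings split into a
    matched fraction ``min(1, p0 + eps)`` and labeled mismatched components.
    Strand and primer totals are unchanged — annealing creates nothing.
    """
    model = _resolve_pairing(library)
    s, t = state.sense_strand_conc, state.antisense_strand_conc
    pa, pb = state.primer_a_conc, state.primer_b_conc
    if s + t <= 0:
        raise ValueError("empty pool: no strands to anneal")
    eps = config.reequilibration_bias
    if eps is None:
        eps = model.default_bias
    p_match = min(1.0, 1.0 / model.effective_species + eps)
    h_s = s * pb / (pb + t) if pb + t > 0 else 0.0
    h_t = t * pa / (pa + s) if pa + s > 0 else 0.0
    duplex = s * t / (pb + t) if pb + t > 0 else 0.0
    classes: dict[tuple[DuplexKind, str, int], float] = {
        (DuplexKind.PRIMER_TEMPLATE_SENSE, "", 0): h_s,
        (DuplexKind.PRIMER_TEMPLATE_ANTISENSE, "", 0): h_t,
    }
    for label, w in model.matched_labels:
        classes[(DuplexKind.MATCHED_FULL, label, 0)] = duplex * p_match * w
    mismatched = duplex * (1.0 - p_match)
    for comp in model.components:
        for m, p in zip(comp.m_values, comp.probs):
            key = (DuplexKind.MISMATCHED_FULL, comp.label, m)
            classes[key] = classes.get(key, 0.0) + mismatched * comp.weight * p
    if not model.components:
        # diversity-1 pool: every strand-strand pairing is matched
        for label, w in model.matched_labels:
            classes[(DuplexKind.MATCHED_FULL, label, 0)] = duplex * w
    return PoolState(
        cycle=state.cycle,
        primer_a_conc=pa,
        primer_b_conc=pb,
        sense_strand_conc=s,
        antisense_strand_conc=t,
        duplex_classes=classes,
        aggregate_mass=state.aggregate_mass,
        length_pmf=state.length_pmf,
    )


def extend_step(state: PoolState, config: SimConfig) -> PoolState:
    """Extend primer-template hybrids into matched full duplexes.

    Each hybrid converts with probability ``extension_efficiency``, consuming
    one primer and creating one full-length strand; primers never go
    negative (a hybrid cannot outnumber its primer by construction).
    """
    eff = config.extension_efficiency
    classes = dict(state.duplex_classes)
    h_s = classes.pop((DuplexKind.PRIMER_TEMPLATE_SENSE, "", 0), 0.0)
    h_t = classes.pop((DuplexKind.PRIMER_TEMPLATE_ANTISENSE, "", 0), 0.0)
    new_t = min(eff * h_s, state.primer_b_conc)
    new_s = min(eff * h_t, state.primer_a_conc)
    matched_labels = [
        (label, conc) for (kind, label, _m), conc in classes.items()
        if kind is DuplexKind.MATCHED_FULL
    ]
    total_matched = sum(c for _, c in matched_labels)
    # extended products inherit the matched-label split of the pool
    # (same sublibrary bookkeeping as their templates)
    for label, conc in matched_labels:
        w = conc / total_matched if total_matched > 0 else 1.0 / len(matched_labels)
        key = (DuplexKind.MATCHED_FULL, label, 0)
        classes[key] = classes.get(key, 0.0) + (new_s + new_t) * w
    if not matched_labels:
        classes[(DuplexKind.MATCHED_FULL, "", 0)] = new_s + new_t
    return PoolState(
        cycle=state.cycle + 1,
        primer_a_conc=state.primer_a_conc - new_s,
        primer_b_conc=state.primer_b_conc - new_t,
        sense_strand_conc=state.sense_strand_conc + new_s,
        antisense_strand_conc=state.antisense_strand_conc + new_t,
        duplex_classes=classes,
        aggregate_mass=state.aggregate_mass,
        length_pmf=state.length_pmf,
    )


def _readout(
    state: PoolState, config: SimConfig
) -> tuple[float, float, float, float]:
    """(raw fluorescence, pool F, matched conc, mismatched conc) of a state."""
    thermal = config.thermal
    fluor = 0.0
    f_mass = 0.0
    duplex_total = 0.0
    matched = 0.0
    mismatched = 0.0
    for (kind, _label, m), conc in state.duplex_classes.items():
        if conc <= 0:
            continue
        if kind is DuplexKind.MATCHED_FULL:
            matched += conc
        elif kind is DuplexKind.MISMATCHED_FULL:
            mismatched += conc
        else:
            continue  # unextended primer hybrids: 20-bp stubs, negligible dye
        fluor += conc * dye_signal_factor(m, thermal)
        f_mass += conc * functional_factor(m, config.f_function)
        duplex_total += conc
    # interwoven multi-strand networks bind dye strongly: unit factor per mass
    fluor += state.aggregate_mass
    pool_f = f_mass / duplex_total if duplex_total > 0 else 1.0
    return fluor, pool_f, matched, mismatched


def _network_step(
    state: PoolState, model: PairingModel, config: SimConfig
) -> PoolState:
    """Extend a fraction of mismatched pairings with 3'-recessed overlaps into
    longer strands; tracks the strand-length histogram and aggregate mass."""
    pmf = state.length_pmf
    if pmf is None:
        pmf = np.zeros(_MAX_NETWORK_LENGTH + 1)
        pmf[1] = 1.0
    mismatched = sum(
        conc for (kind, _l, _m), conc in state.duplex_classes.items()
        if kind is DuplexKind.MISMATCHED_FULL
    )
    strands = state.sense_strand_conc + state.antisense_strand_conc
    t = state.antisense_strand_conc
    pb = state.primer_b_conc
    q = config.network_rate * (1.0 - 1.0 / model.effective_species)
    q *= t / (pb + t) if pb + t > 0 else 0.0
    phi = min(1.0, q * 2.0 * mismatched / strands) if strands > 0 else 0.0
    if phi > 0:
        joined = np.convolve(pmf, pmf)[: pmf.size]
        joined[-1] += 1.0 - joined.sum()  # lump lengths beyond the cap
        pmf = (1.0 - phi) * pmf + phi * joined
    mean_len = float(np.dot(np.arange(pmf.size), pmf))
    aggregate = (mean_len - 1.0) * strands
    return replace(state, length_pmf=pmf, aggregate_mass=aggregate)


def _simulate_deterministic(model: PairingModel, config: SimConfig) -> Trajectory:
    s0 = config.initial_template_conc
    state = PoolState(
        cycle=0,
        primer_a_conc=config.primer_conc,
        primer_b_conc=config.primer_conc,
        sense_strand_conc=s0,
        antisense_strand_conc=s0,
        duplex_classes={
            (DuplexKind.MATCHED_FULL, label, 0): s0 * w
            for label, w in model.matched_labels
        },
    )
    rows = [_record(state, config)]
    for _ in range(config.cycles):
        state = anneal_step(state, model, config)
        state = extend_step(state, config)
        if config.network_extension:
            state = _network_step(state, model, config)
        rows.append(_record(state, config))
    return _assemble(rows, model.name, state)


def _record(state: PoolState, config: SimConfig) -> tuple:
    fluor, pool_f, matched, mismatched = _readout(state, config)
    return (
        state.cycle, fluor, pool_f, state.primer_a_conc, state.primer_b_conc,
        matched, mismatched, state.aggregate_mass,
    )


def _assemble(rows: list[tuple], name: str, final_state: PoolState) -> Trajectory:
    arr = np.array(rows, dtype=float)
    return Trajectory(
        cycle=arr[:, 0],
        fluorescence=arr[:, 1],
        pool_f=arr[:, 2],
        primer_a=arr[:, 3],
        primer_b=arr[:, 4],
        matched_conc=arr[:, 5],
        mismatched_conc=arr[:, 6],
        aggregate_mass=arr[:, 7],
        name=name,
        final_state=final_state,
    )


def _simulate_finite(model: PairingModel, config: SimConfig) -> Trajectory:
    """Stochastic simulation with integer molecule counts (law of small
    numbers matters when few copies per member are present)."""
    rng = np.random.default_rng(config.seed)
    scale = config.initial_copies / config.initial_template_conc  # copies per molar
    s = t = int(config.initial_copies)
    pa = pb = int(round(config.primer_conc * scale))
    eps = config.reequilibration_bias
    if eps is None:
        eps = model.default_bias
    p_match = min(1.0, 1.0 / model.effective_species + eps)
    flat: list[tuple[str, int, float]] = []
    for comp in model.components:
        for m, p in zip(comp.m_values, comp.probs):
            flat.append((comp.label, m, comp.weight * p))
    probs = np.array([p for _, _, p in flat]) if flat else np.empty(0)

    def snapshot(cycle, classes, aggregate=0.0) -> PoolState:
        return PoolState(cycle, pa / scale, pb / scale, s / scale, t / scale,
                         classes, aggregate)

    state0 = snapshot(0, {
        (DuplexKind.MATCHED_FULL, label, 0): s / scale * w
        for label, w in model.matched_labels
    })
    rows = [_record(state0, config)]
    state = state0
    for cycle in range(1, config.cycles + 1):
        h_s = min(rng.binomial(s, pb / (pb + t)) if pb + t > 0 else 0, pb)
        h_t = min(rng.binomial(t, pa / (pa + s)) if pa + s > 0 else 0, pa)
        pairs = min(s - h_s, t - h_t)
        matched = rng.binomial(pairs, p_match) if pairs > 0 else 0
        mismatched = pairs - matched
        classes: dict[tuple[DuplexKind, str, int], float] = {}
        for label, w in model.matched_labels:
            classes[(DuplexKind.MATCHED_FULL, label, 0)] = matched / scale * w
        if mismatched > 0 and flat:
            counts = rng.multinomial(mismatched, probs)
            for (label, m, _p), c in zip(flat, counts):
                if c:
                    key = (DuplexKind.MISMATCHED_FULL, label, m)
                    classes[key] = classes.get(key, 0.0) + c / scale
        elif mismatched > 0:
            for label, w in model.matched_labels:
                classes[(DuplexKind.MATCHED_FULL, label, 0)] += mismatched / scale * w
        new_t = min(rng.binomial(h_s, config.extension_efficiency), pb)
        new_s = min(rng.binomial(h_t, config.extension_efficiency), pa)
        pb -= new_t
        pa -= new_s
        t += new_t
        s += new_s
        for label, w in model.matched_labels:
            key = (DuplexKind.MATCHED_FULL, label, 0)
            classes[key] = classes.get(key, 0.0) + (new_s + new_t) / scale * w
        state = snapshot(cycle, classes)
        rows.append(_record(state, config))
    return _assemble(rows, model.name, state)


def simulate(library, config: SimConfig | None = None) -> Trajectory:
    """Run a full amplification and return its trajectory.

    ``library`` may be a :class:`LibrarySpec`, a :class:`CodeSet`, or a
    prebuilt :class:`PairingModel`.  In deterministic mode the run is
    bit-for-bit reproducible; finite-copy mode is reproducible by seed.
    Fluorescence is normalized so the plateau of a diversity-1 reference run
    under the same conditions equals 1.
    """
    if config is None:
        config = SimConfig()
    model = _resolve_pairing(library)
    if config.mode == "finite_copy":
        traj = _simulate_finite(model, config)
    else:
        traj = _simulate_deterministic(model, config)
    if config.normalize:
        ref_config = replace(
            config, normalize=False, mode="deterministic",
            network_extension=False, reequilibration_bias=0.0,
        )
        ref = _simulate_deterministic(reference_pairing(), ref_config)
        norm = ref.fluorescence.max()
        traj.fluorescence = traj.fluorescence / norm
        traj.aggregate_mass = traj.aggregate_mass / norm
    return traj


def detect_turning_point(traj: Trajectory, sensitivity: float = 0.02) -> int | None:
    """First cycle at which pool F materially declines, or ``None``.

    In a diverse pool, F stays near 1 while newly synthesized perfect
    duplexes outweigh reshuffled mismatched pairs, then falls as primers run
    out.  The decline rate grows smoothly from numerically tiny values, so
    the turning point is located where the per-cycle drop first exceeds
    ``sensitivity`` (F units per cycle).
    """
    drops = np.diff(traj.pool_f)
    below = np.nonzero(drops < -sensitivity)[0]
    if below.size == 0:
        return None
    return int(traj.cycle[below[0] + 1])


def ct_shift_series(
    library,
    concentrations: Sequence[float],
    config: SimConfig | None = None,
    threshold: float = 0.1,
) -> list[tuple[float, float | None]]:
    """Simulate a dilution series and extract the threshold cycle per level."""
    from .curves import extract_features  # local import to avoid a cycle

    if len(concentrations) < 2:
        raise ValueError("need at least two concentrations")
    if config is None:
        config = SimConfig()
    out = []
    for conc in concentrations:
        traj = simulate(library, replace(config, initial_template_conc=conc))
        out.append((conc, extract_features(traj, threshold).ct))
    return out
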