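"""Selection experiments on heterogeneous pools.

Two selection mechanisms are modeled.  First, restriction digestion: a
perfectly matched duplex carrying an enzyme's recognition site is an optimal
substrate, while flanking mismatches in a reshuffled heteroduplex protect
the duplex — cut probability decays as ``exp(-m / kappa)`` in the mismatch
count, and a site/site heteroduplex (strands from different sublibraries) is
not cut at all.  Second, DECL-style streptavidin capture: code-tagged
members carrying a strong ligand (biotin), a weak ligand (iminobiotin), or
no ligand are captured and washed with tag-dependent efficiencies, and the
eluted pool's abundance profile is summarized by evenness metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .duplex import DuplexKind
from .library import CodeSet, design_code_set
from .simulate import (
    PairingModel,
    PoolState,
    SimConfig,
    pairing_from_code_set,
    restriction_mixture_pairing,
    simulate,
)

__all__ = [
    "RestrictionSite",
    "TaggedMember",
    "SelectionOutcome",
    "ECORV",
    "SMAI",
    "DEFAULT_CAPTURE",
    "DEFAULT_RETENTION",
    "digest",
    "amplifiable_template",
    "restriction_protection_profile",
    "decl_select",
    "library_fixtures_decl",
    "eluted_pairing",
]

TAGS = ("strong_binder", "weak_binder", "none")

# Capture / per-wash retention probabilities by tag.  Chosen so that one
# wash ranks total capture Lib-D > (A, C) > Lib-B and a second wash leaves
# Lib-A and Lib-D essentially monocomponent while Lib-C stays a uniform
# ten-member mixture; these are phenomenological, not measured affinities.
DEFAULT_CAPTURE: dict[str, float] = {
    "strong_binder": 0.95,
    "weak_binder": 0.5,
    "none": 0.08,
}
DEFAULT_RETENTION: dict[str, float] = {
    "strong_binder": 0.95,
    "weak_binder": 0.15,
    "none": 0.05,
}


@dataclass(frozen=True)
class RestrictionSite:
    """A blunt-cutting endonuclease site and its digestion parameters.

    ``cut_probability_matched`` applies to a perfect duplex; flanking
    mismatches protect with scale ``protection_scale`` (mismatches per
    e-fold reduction in cut probability).
    """

    name: str
    recognition_sequence: str
    cut_probability_matched: float = 0.9
    protection_scale: float = 3.0

    def __post_init__(self) -> None:
        if len(self.recognition_sequence) < 4:
            raise ValueError("recognition sequence must be at least 4 nt")
        if not 0.0 <= self.cut_probability_matched <= 1.0:
            raise ValueError("cut_probability_matched must be a probability")
        if self.protection_scale <= 0:
            raise ValueError("protection_scale must be positive")


ECORV = RestrictionSite("EcoRV", "GATATC")
SMAI = RestrictionSite("SmaI", "CCCGGG")


@dataclass(frozen=True)
class TaggedMember:
    """A code-set member with its ligand tag and input abundance."""

    code: str
    tag: str
    abundance: float

    def __post_init__(self) -> None:
        if self.tag not in TAGS:
            raise ValueError(f"tag must be one of {TAGS}, got {self.tag!r}")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


@dataclass(frozen=True)
class SelectionOutcome:
    """Post-capture composition of a tagged library.

    ``abundances`` is renormalized over the eluted pool; ``total_captured``
    is the fraction of input DNA retained; ``effective_species`` is the
    inverse Simpson index (1 for a pure sample, the member count for a
    uniform mixture); ``shannon_evenness`` is Shannon entropy over
    ``ln(member count)``.
    """

    abundances: dict[str, float]
    total_captured: float
    effective_species: float
    shannon_evenness: float


def digest(
    state: PoolState,
    sites: Sequence[RestrictionSite],
    enzymes_present: Iterable[str],
) -> PoolState:
    """Apply endonuclease digestion to a pool's duplex classes.

    A duplex class is cut only if both strands carry the same active
    enzyme's site (label ``site:<name>``); the cut probability is
    ``cut_probability_matched * exp(-m / protection_scale)``.  Cut duplexes
    are removed from the amplifiable template.  With no enzymes present the
    pool is returned unchanged.
    """
    by_name = {site.name.lower(): site for site in sites}
    active = set()
    for enzyme in enzymes_present:
        if enzyme.lower() not in by_name:
            raise ValueError(f"unknown enzyme {enzyme!r}; known: {sorted(by_name)}")
        active.add(enzyme.lower())
    classes: dict = {}
    for (kind, label, m), conc in state.duplex_classes.items():
        survival = 1.0
        if label.startswith("site:") and label[5:].lower() in active:
            site = by_name[label[5:].lower()]
            survival = 1.0 - site.cut_probability_matched * math.exp(
                -m / site.protection_scale
            )
        classes[(kind, label, m)] = conc * survival
    return replace(state, duplex_classes=classes)


def amplifiable_template(state: PoolState) -> float:
    """Total concentration of full-length duplexes still amplifiable."""
    return sum(
        conc
        for (kind, _label, _m), conc in state.duplex_classes.items()
        if kind in (DuplexKind.MATCHED_FULL, DuplexKind.MISMATCHED_FULL)
    )


def restriction_protection_profile(
    pretreat_cycles: int,
    config: SimConfig | None = None,
    sites: Sequence[RestrictionSite] = (ECORV, SMAI),
    n_random: int = 14,
) -> pd.DataFrame:
    """Digestion survival of a two-sublibrary mixture after PCR pretreatment.

    Simulates an equal mixture of two sublibraries, each with one site
    embedded in a degenerate region, for ``pretreat_cycles`` cycles, then
    digests the final pool with no enzyme, each enzyme alone, and both.
    Returns a frame with the remaining amplifiable template per treatment and
    its fraction of the untreated value.
    """
    if config is None:
        config = SimConfig()
    config = replace(config, cycles=pretreat_cycles, normalize=False)
    model = restriction_mixture_pairing(
        n_random=n_random,
        site_a=sites[0].recognition_sequence,
        site_b=sites[1].recognition_sequence,
        names=(sites[0].name, sites[1].name),
    )
    final = simulate(model, config).final_state
    treatments = {
        "untreated": (),
        sites[0].name: (sites[0].name,),
        sites[1].name: (sites[1].name,),
        "both": (sites[0].name, sites[1].name),
    }
    rows = []
    for treatment, enzymes in treatments.items():
        remaining = amplifiable_template(digest(final, sites, enzymes))
        rows.append({"treatment": treatment, "remaining_template": remaining})
    frame = pd.DataFrame(rows)
    untreated = frame.loc[frame.treatment == "untreated", "remaining_template"].iloc[0]
    frame["fraction_of_untreated"] = frame.remaining_template / untreated
    return frame


def _evenness_metrics(p: np.ndarray) -> tuple[float, float]:
    effective = 1.0 / float(np.sum(p**2))
    if p.size == 1:
        return effective, 1.0
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return effective, entropy / math.log(p.size)


def decl_select(
    library: Sequence[TaggedMember],
    capture: Mapping[str, float] | None = None,
    wash_retention: Mapping[str, float] | None = None,
    washes: int = 1,
    seed: int | None = None,
) -> SelectionOutcome:
    """Streptavidin-bead capture of a tagged library followed by washes.

    Each member is retained with probability
    ``capture(tag) * wash_retention(tag) ** washes``; the output abundances
    are the renormalized retained fractions.  The model is an expectation
    model and deterministic; ``seed`` is accepted for interface symmetry
    with the stochastic simulator.
    """
    if washes < 0:
        raise ValueError("washes must be >= 0")
    if not library:
        raise ValueError("library is empty")
    capture = dict(DEFAULT_CAPTURE if capture is None else capture)
    wash_retention = dict(DEFAULT_RETENTION if wash_retention is None else wash_retention)
    a = np.array([m.abundance for m in library], dtype=float)
    if a.sum() <= 0:
        raise ValueError("library abundances are all zero")
    a = a / a.sum()
    factors = np.array(
        [capture[m.tag] * wash_retention[m.tag] ** washes for m in library]
    )
    if np.all(factors == 0):
        raise ValueError("all capture probabilities are zero")
    retained = a * factors
    total = float(retained.sum())
    p = retained / total
    effective, evenness = _evenness_metrics(p)
    return SelectionOutcome(
        abundances={m.code: float(x) for m, x in zip(library, p)},
        total_captured=total,
        effective_species=effective,
        shannon_evenness=evenness,
    )


def library_fixtures_decl(
    seed: int = 20200107,
) -> tuple[CodeSet, dict[str, list[TaggedMember]]]:
    """The four DECL selection scenarios over a shared ten-member code set.

    Lib-A: one potent binder, no weak binders.  Lib-B: one weak binder.
    Lib-C: ten weak binders.  Lib-D: one potent binder plus nine weak
    binders.  All members start at uniform abundance.  Deterministic for a
    given seed; the code set has minimum pairwise distance >= 16.
    """
    codes = design_code_set(n=10, length=20, min_distance=16, seed=seed)
    tag_plans = {
        "Lib-A": ["strong_binder"] + ["none"] * 9,
        "Lib-B": ["weak_binder"] + ["none"] * 9,
        "Lib-C": ["weak_binder"] * 10,
        "Lib-D": ["strong_binder"] + ["weak_binder"] * 9,
    }
    libraries = {
        name: [
            TaggedMember(code, tag, 0.1)
            for code, tag in zip(codes.members, tags)
        ]
        for name, tags in tag_plans.items()
    }
    return codes, libraries


def eluted_pairing(outcome: SelectionOutcome, code_set: CodeSet, name: str = "eluate") -> PairingModel:
    """Pairing model of the eluted pool, for feeding back into the simulator
    (the post-selection amplification curve: Ct from total capture, endpoint
    from evenness)."""
    abundances = [outcome.abundances.get(m, 0.0) for m in code_set.members]
    return pairing_from_code_set(code_set, abundances, name=name)
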