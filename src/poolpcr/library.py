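"""Degenerate DNA libraries, code sets, and their combinatorics.

A library is specified positionally: two fixed flanking primer regions and a
variable region in which every position carries a non-empty subset of
``{A, C, G, T}``.  The number of distinct realizable members (the *diversity*)
is the exact product of the per-position alphabet sizes and is kept as a
Python big integer throughout — a 20-position fully degenerate region already
exceeds ``10^12`` members, well past what a float or int64 can count exactly.

The module also provides the Hamming-mismatch distribution of a random pair
of library members (a Poisson-binomial over positions), biased-primer
subsetting, expected per-member copy numbers at bench concentrations, and a
seeded minimum-distance code-set designer with a Plotkin-bound feasibility
check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "AVOGADRO",
    "BASES",
    "LibrarySpec",
    "CodeSet",
    "PrimerSpec",
    "MismatchDistribution",
    "InfeasibleCodeError",
    "CodeSearchBudgetError",
    "parse_variable_region",
    "variable_region_to_iupac",
    "diversity",
    "mismatch_distribution",
    "primer_subset",
    "copies_per_member",
    "design_code_set",
    "hamming",
    "sample_members",
    "enumerate_members",
]

AVOGADRO = 6.02214076e23
BASES = "ACGT"

# IUPAC degeneracy codes <-> base subsets.  Biopython's table contains the
# legacy alias "X" for "any base"; we canonicalize on "N".
IUPAC_TO_SET: dict[str, frozenset[str]] = {
    code: frozenset(values)
    for code, values in ambiguous_dna_values.items()
    if code != "X"
}
SET_TO_IUPAC: dict[frozenset[str], str] = {s: c for c, s in IUPAC_TO_SET.items()}


class InfeasibleCodeError(ValueError):
    """Requested code parameters violate a combinatorial bound."""


class CodeSearchBudgetError(RuntimeError):
    """Randomized search exhausted its retry budget; retry with a larger
    budget or another seed — the request is not provably infeasible."""


def parse_variable_region(text: str) -> tuple[frozenset[str], ...]:
    """Parse an IUPAC-degenerate string into per-position base subsets."""
    region = []
    for symbol in text.upper():
        try:
            region.append(IUPAC_TO_SET[symbol])
        except KeyError:
            raise ValueError(f"not an IUPAC DNA symbol: {symbol!r}") from None
    return tuple(region)


def variable_region_to_iupac(region: Sequence[frozenset[str]]) -> str:
    """Serialize per-position base subsets to an IUPAC-degenerate string."""
    return "".join(SET_TO_IUPAC[frozenset(a)] for a in region)


def _validate_fixed(seq: str, what: str) -> str:
    seq = seq.upper()
    if any(b not in BASES for b in seq):
        raise ValueError(f"{what} must be plain ACGT, got {seq!r}")
    return seq


@dataclass(frozen=True)
class LibrarySpec:
    """A degenerate library: fixed primers flanking a positional variable region.

    Parameters
    ----------
    name:
        Identifier used as the FASTA record id.
    primer_a, primer_b:
        Fixed flanking primer-binding regions (plain ACGT).
    variable_region:
        One base subset per variable position; each subset has 1-4 bases.
    """

    name: str
    primer_a: str
    primer_b: str
    variable_region: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "primer_a", _validate_fixed(self.primer_a, "primer_a"))
        object.__setattr__(self, "primer_b", _validate_fixed(self.primer_b, "primer_b"))
        region = tuple(frozenset(a) for a in self.variable_region)
        for i, alphabet in enumerate(region):
            if not 1 <= len(alphabet) <= 4 or not alphabet <= set(BASES):
                raise ValueError(
                    f"position {i}: alphabet must be a non-empty subset of ACGT"
                )
        object.__setattr__(self, "variable_region", region)

    @property
    def diversity(self) -> int:
        return diversity(self)

    @property
    def degenerate_sequence(self) -> str:
        """IUPAC string of the variable region only."""
        return variable_region_to_iupac(self.variable_region)

    @property
    def full_sequence(self) -> str:
        """primer A + IUPAC variable region + primer B."""
        return self.primer_a + self.degenerate_sequence + self.primer_b

    @classmethod
    def from_iupac(
        cls, name: str, primer_a: str, variable: str, primer_b: str
    ) -> "LibrarySpec":
        return cls(name, primer_a, primer_b, parse_variable_region(variable))


@dataclass(frozen=True)
class PrimerSpec:
    """A base primer optionally extended by ``k`` fixed bases that reach into
    the variable region and thereby select a sub-population of templates."""

    base_primer: str
    extension: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "base_primer", _validate_fixed(self.base_primer, "base_primer")
        )
        object.__setattr__(
            self, "extension", _validate_fixed(self.extension, "extension")
        )

    def __len__(self) -> int:
        return len(self.base_primer) + len(self.extension)


@dataclass(frozen=True)
class CodeSet:
    """A finite set of fixed equal-length sequences with a verified minimum
    pairwise Hamming distance.

    ``min_pairwise_distance`` is always recomputed from the members, never
    taken on trust from a caller or a file.
    """

    members: tuple[str, ...]
    min_pairwise_distance: int = -1  # recomputed in __post_init__

    def __post_init__(self) -> None:
        members = tuple(_validate_fixed(m, "code member") for m in self.members)
        if not members:
            raise ValueError("a code set needs at least one member")
        lengths = {len(m) for m in members}
        if len(lengths) != 1:
            raise ValueError("code members must have equal length")
        if len(set(members)) != len(members):
            raise ValueError("code members must be distinct")
        object.__setattr__(self, "members", members)
        object.__setattr__(
            self, "min_pairwise_distance", _min_pairwise_distance(members)
        )

    @property
    def length(self) -> int:
        return len(self.members[0])

    def pairwise_distances(self) -> list[tuple[int, int, int]]:
        """All (i, j, distance) with i < j."""
        return [
            (i, j, hamming(a, b))
            for (i, a), (j, b) in itertools.combinations(enumerate(self.members), 2)
        ]


def _min_pairwise_distance(members: Sequence[str]) -> int:
    if len(members) < 2:
        return 0
    return min(hamming(a, b) for a, b in itertools.combinations(members, 2))


@dataclass(frozen=True)
class MismatchDistribution:
    """Probability mass function of the Hamming mismatch count ``m`` between
    two independently drawn library members (variable region only)."""

    pmf: dict[int, float]
    mean: float

    def __post_init__(self) -> None:
        total = math.fsum(self.pmf.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pmf sums to {total}, not 1")
        mean = math.fsum(m * p for m, p in self.pmf.items())
        if abs(mean - self.mean) > 1e-9:
            raise ValueError("stored mean inconsistent with pmf")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        m = np.array(sorted(self.pmf), dtype=int)
        p = np.array([self.pmf[k] for k in m], dtype=float)
        return m, p


def diversity(spec: LibrarySpec) -> int:
    """Exact number of distinct members (big integer, never floats)."""
    return math.prod(len(a) for a in spec.variable_region)


def mismatch_distribution(
    spec: LibrarySpec, distinct_members: bool = False
) -> MismatchDistribution:
    """Distribution of the mismatch count between two random members.

    Two members drawn uniformly and independently disagree at position ``i``
    with probability ``1 - 1/|alphabet_i|``; positions are independent, so the
    total count is Poisson-binomial.  With ``distinct_members`` the two draws
    are conditioned on not being identical (identical draws are exactly the
    ``m = 0`` event), which is the relevant law for *mismatched* heteroduplex
    pairings.
    """
    if distinct_members and diversity(spec) == 1:
        raise ValueError("cannot condition on distinct members when diversity is 1")
    pmf = np.ones(1)
    for alphabet in spec.variable_region:
        p = 1.0 - 1.0 / len(alphabet)
        pmf = np.convolve(pmf, [1.0 - p, p])
    if distinct_members:
        p0 = pmf[0]
        pmf = pmf / (1.0 - p0)
        pmf[0] = 0.0
    mean = float(np.dot(np.arange(pmf.size), pmf))
    return MismatchDistribution({m: float(p) for m, p in enumerate(pmf)}, mean)


def primer_subset(
    spec: LibrarySpec, primer: PrimerSpec
) -> tuple[Fraction, LibrarySpec | None]:
    """Fraction of the library a k-base-extended primer can amplify, and the
    reduced library it produces.

    The extension aligns to the first ``k`` variable positions adjacent to the
    base primer.  Each position contributes the exact factor
    ``|{base} ∩ alphabet| / |alphabet|``; an extension base absent from a
    position's alphabet makes the fraction 0 (no member amplifiable), in which
    case the reduced library is ``None`` rather than an error.
    """
    k = len(primer.extension)
    if k > len(spec.variable_region):
        raise ValueError("extension longer than the variable region")
    fraction = Fraction(1)
    new_region = list(spec.variable_region)
    for i, base in enumerate(primer.extension):
        alphabet = spec.variable_region[i]
        fraction *= Fraction(int(base in alphabet), len(alphabet))
        new_region[i] = frozenset(base)
    if fraction == 0:
        return fraction, None
    reduced = replace(
        spec, name=f"{spec.name}+{k}", variable_region=tuple(new_region)
    )
    return fraction, reduced


def copies_per_member(concentration: float, volume: float, diversity: int) -> float:
    """Expected molecule count per distinct member in a sample.

    ``concentration`` in mol/L, ``volume`` in liters.  At 1 nM in 10 uL a
    diversity of ``4^20`` leaves statistically under one copy per member.
    """
    if concentration <= 0 or volume <= 0:
        raise ValueError("concentration and volume must be positive")
    if diversity <= 0:
        raise ValueError("diversity must be a positive count")
    return AVOGADRO * concentration * volume / diversity


def hamming(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def design_code_set(
    n: int,
    length: int,
    min_distance: int,
    seed: int,
    max_tries: int = 500_000,
) -> CodeSet:
    """Design ``n`` sequences of ``length`` nt with pairwise Hamming distance
    at least ``min_distance``, reproducibly from ``seed``.

    Feasibility is screened first: the distance cannot exceed the length, and
    over a quaternary alphabet the Plotkin bound caps the code size at
    ``floor(d / (d - 3L/4))`` whenever ``d > 3L/4``.  Construction is a
    randomized greedy accumulation with targeted repair: propose a uniform
    random sequence and, while it sits too close to an accepted codeword,
    re-randomize one of the agreeing positions.  Plain accept/reject stalls
    near the Plotkin cap (at d = 16, L = 20 the cap is 16 words); the repair
    walk reaches 10 words in a few thousand steps for any seed.

    Raises
    ------
    InfeasibleCodeError
        If the request provably cannot be met.
    CodeSearchBudgetError
        If ``max_tries`` proposals were not enough (retryable).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if min_distance > length:
        raise InfeasibleCodeError(
            f"minimum distance {min_distance} exceeds sequence length {length}"
        )
    if min_distance > 0.75 * length:
        plotkin_cap = math.floor(min_distance / (min_distance - 0.75 * length))
        if n > plotkin_cap:
            raise InfeasibleCodeError(
                f"Plotkin bound: at length {length} and distance {min_distance} "
                f"a quaternary code has at most {plotkin_cap} words, requested {n}"
            )
    rng = np.random.default_rng(seed)
    base_array = np.frombuffer(BASES.encode(), dtype=np.uint8)
    accepted: list[np.ndarray] = []
    steps = 0
    while len(accepted) < n:
        candidate = rng.integers(0, 4, size=length)
        repaired = False
        for _ in range(1000):  # repair walk for this candidate
            steps += 1
            if steps > max_tries:
                raise CodeSearchBudgetError(
                    f"placed {len(accepted)}/{n} codewords in {max_tries} steps"
                )
            if not accepted:
                repaired = True
                break
            dists = np.array([(candidate != word).sum() for word in accepted])
            offenders = np.nonzero(dists < min_distance)[0]
            if offenders.size == 0:
                repaired = True
                break
            word = accepted[offenders[rng.integers(offenders.size)]]
            agree = np.nonzero(candidate == word)[0]
            pos = agree[rng.integers(agree.size)]
            candidate[pos] = (candidate[pos] + 1 + rng.integers(3)) % 4
        if repaired:
            accepted.append(candidate.copy())
    members = tuple(
        base_array[word].tobytes().decode() for word in accepted
    )
    return CodeSet(members)


def sample_members(spec: LibrarySpec, n: int, seed: int) -> list[str]:
    """Draw ``n`` members i.i.d. uniformly (per position) from the library."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    columns = []
    for alphabet in spec.variable_region:
        bases = np.array(sorted(alphabet))
        columns.append(bases[rng.integers(0, len(bases), size=n)])
    matrix = np.stack(columns, axis=1)
    return ["".join(row) for row in matrix]


def enumerate_members(spec: LibrarySpec, limit: int | None = 10_000_000) -> Iterator[str]:
    """Enumerate every member of a (small) library in lexicographic order."""
    if limit is not None and diversity(spec) > limit:
        raise ValueError(f"library has {diversity(spec)} members, above limit {limit}")
    alphabets = [sorted(a) for a in spec.variable_region]
    for combo in itertools.product(*alphabets):
        yield "".join(combo)
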