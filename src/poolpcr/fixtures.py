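"""Seeded generators for every library design used across the experiments.

All sequences here are synthetic stand-ins constructed by this package: two
fixed 20-mer primer regions, a fixed 20-mer filler used both for the
non-degenerate part of partially degenerate regions and as the bases of the
extended biased primers, the X_n ladder, equal-diversity layouts, the
restriction-site sublibraries, the ten-member minimum-distance code set, and
the four DECL scenarios.  Everything is deterministic (seeded) so fixture
files regenerate byte-identically.
"""

from __future__ import annotations

from pathlib import Path

from .library import CodeSet, LibrarySpec, PrimerSpec, design_code_set
from .selection import ECORV, SMAI, TaggedMember, library_fixtures_decl

__all__ = [
    "PRIMER_A",
    "PRIMER_B",
    "FIXED_FILL",
    "DEFAULT_CODE_SEED",
    "s1",
    "x_n",
    "x_ladder",
    "equal_diversity_layouts",
    "biased_primer",
    "code_set_sx10",
    "restriction_sublibraries",
    "all_library_specs",
    "generate_fixtures",
]

# Fixed flanking primer regions (synthetic 20-mers, balanced GC).
PRIMER_A = "GCTGAACGGTCACTGCATCC"
PRIMER_B = "GTCAGGTCAGCCTAAGCGTG"
# Fixed filler for non-degenerate variable positions; biased primers extend
# into the variable region with these bases, so they perfectly match any
# library whose leading positions are fixed filler.
FIXED_FILL = "ATCGGATCCGATACGCTAGC"

DEFAULT_CODE_SEED = 20200107


def s1() -> LibrarySpec:
    """The single-sequence reference template (diversity 1)."""
    return LibrarySpec.from_iupac("S_1", PRIMER_A, FIXED_FILL, PRIMER_B)


def x_n(n: int, total: int = 20) -> LibrarySpec:
    """X_n: a 20-base region whose last ``n`` positions are fully degenerate.

    The fixed prefix uses the filler sequence, so the extended biased
    primers enter degenerate positions only on fully degenerate libraries.
    """
    if not 0 <= n <= total:
        raise ValueError(f"n must be in [0, {total}]")
    region = FIXED_FILL[: total - n] + "N" * n
    return LibrarySpec.from_iupac(f"X_{n}" if n else "S_1", PRIMER_A, region, PRIMER_B)


def x_ladder() -> dict[str, LibrarySpec]:
    """The diversity ladder X_2, X_4, ..., X_20."""
    return {f"X_{n}": x_n(n) for n in range(2, 21, 2)}


def equal_diversity_layouts() -> dict[str, LibrarySpec]:
    """Four layouts of identical total diversity 4^10 but different placement
    of the degenerate positions.

    X_10: fixed 10-mer prefix + 10 fully degenerate.  X_10/2: the mirror
    (degenerate block first, so biased primers select subsets).  X_2/10:
    twenty 2-base positions (purine/pyrimidine alternation).  X_4/5: five
    blocks of two degenerate + two fixed positions.
    """
    x10 = LibrarySpec.from_iupac("X_10", PRIMER_A, FIXED_FILL[:10] + "N" * 10, PRIMER_B)
    x10_2 = LibrarySpec.from_iupac("X_10/2", PRIMER_A, "N" * 10 + FIXED_FILL[:10], PRIMER_B)
    x2_10 = LibrarySpec.from_iupac("X_2/10", PRIMER_A, "RY" * 10, PRIMER_B)
    blocks = "".join("NN" + FIXED_FILL[2 * i : 2 * i + 2] for i in range(5))
    x4_5 = LibrarySpec.from_iupac("X_4/5", PRIMER_A, blocks, PRIMER_B)
    return {"X_10": x10, "X_10/2": x10_2, "X_2/10": x2_10, "X_4/5": x4_5}


def biased_primer(k: int) -> PrimerSpec:
    """A_20+k: the 20-mer primer A extended by k filler bases into the
    variable region (k in {1, 5, 10} in the bench designs)."""
    if not 0 <= k <= len(FIXED_FILL):
        raise ValueError(f"extension length must be in [0, {len(FIXED_FILL)}]")
    return PrimerSpec(PRIMER_A, FIXED_FILL[:k])


def code_set_sx10(seed: int = DEFAULT_CODE_SEED) -> CodeSet:
    """S_x-10: ten 20-mers with pairwise Hamming distance >= 16."""
    return design_code_set(n=10, length=20, min_distance=16, seed=seed)


def restriction_sublibraries() -> dict[str, LibrarySpec]:
    """A-X_EcoRV-B and A-X_SmaI-B: 14 degenerate positions around a central
    fixed recognition site."""
    out = {}
    for site in (ECORV, SMAI):
        region = "N" * 7 + site.recognition_sequence + "N" * 7
        out[f"X_{site.name}"] = LibrarySpec.from_iupac(
            f"X_{site.name}", PRIMER_A, region, PRIMER_B
        )
    return out


def all_library_specs() -> dict[str, LibrarySpec]:
    """Every named degenerate library fixture."""
    specs = {"S_1": s1()}
    specs.update(x_ladder())
    specs.update(equal_diversity_layouts())
    specs.update(restriction_sublibraries())
    return specs


def generate_fixtures(outdir, seed: int = DEFAULT_CODE_SEED) -> dict[str, Path]:
    """Write every fixture to ``outdir`` (IUPAC FASTA + tag TSV).

    Returns the mapping of fixture-set name to file path.  Regeneration with
    the same seed is byte-identical.
    """
    from .io import write_code_set_fasta, write_library_fasta, write_tags_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    lib_path = outdir / "libraries.fasta"
    write_library_fasta(list(all_library_specs().values()), lib_path)
    paths["libraries"] = lib_path

    codes = code_set_sx10(seed)
    code_path = outdir / "s_x-10.fasta"
    write_code_set_fasta(codes, code_path, prefix="S_x-10")
    paths["s_x-10"] = code_path

    decl_codes, decl_libs = library_fixtures_decl(seed)
    decl_code_path = outdir / "decl_codes.fasta"
    write_code_set_fasta(decl_codes, decl_code_path, prefix="code")
    paths["decl_codes"] = decl_code_path
    for name, members in decl_libs.items():
        tag_path = outdir / f"{name.replace('-', '_').lower()}_tags.tsv"
        write_tags_tsv(members, tag_path, code_prefix="code")
        paths[name] = tag_path
    return paths
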