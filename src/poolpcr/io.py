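"""File formats: IUPAC FASTA for libraries, plain FASTA for code sets,
TSV for tags and distance reports, CSV for trajectories and outcomes.

A library FASTA record stores primer A + IUPAC variable region + primer B as
one sequence; the primer lengths ride in the record description so parsing
is lossless (``primer_a=20 primer_b=20``).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library import CodeSet, LibrarySpec, parse_variable_region
from .selection import SelectionOutcome, TaggedMember
from .simulate import Trajectory

__all__ = [
    "write_library_fasta",
    "read_library_fasta",
    "write_code_set_fasta",
    "read_code_set_fasta",
    "write_distance_report",
    "write_tags_tsv",
    "read_tagged_library",
    "write_trajectory",
    "read_trajectory",
    "write_outcome",
]

_PRIMER_RE = re.compile(r"primer_a=(\d+)\s+primer_b=(\d+)")


def write_library_fasta(specs: Sequence[LibrarySpec], path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(
            Seq(spec.full_sequence),
            id=spec.name,
            description=f"primer_a={len(spec.primer_a)} primer_b={len(spec.primer_b)}",
        )
        for spec in specs
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_library_fasta(path) -> list[LibrarySpec]:
    specs = []
    for record in SeqIO.parse(str(path), "fasta"):
        match = _PRIMER_RE.search(record.description)
        la, lb = (int(match.group(1)), int(match.group(2))) if match else (20, 20)
        seq = str(record.seq).upper()
        if len(seq) <= la + lb:
            raise ValueError(f"record {record.id}: sequence shorter than its primers")
        specs.append(
            LibrarySpec(
                name=record.id,
                primer_a=seq[:la],
                primer_b=seq[len(seq) - lb :],
                variable_region=parse_variable_region(seq[la : len(seq) - lb]),
            )
        )
    if not specs:
        raise ValueError(f"no FASTA records in {path}")
    return specs


def _member_id(prefix: str, index: int) -> str:
    return f"{prefix}_{index + 1:02d}"


def write_code_set_fasta(code_set: CodeSet, path, prefix: str = "code") -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(member), id=_member_id(prefix, i), description="")
        for i, member in enumerate(code_set.members)
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_code_set_fasta(path) -> CodeSet:
    members = [str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")]
    if not members:
        raise ValueError(f"no FASTA records in {path}")
    return CodeSet(tuple(members))  # min distance recomputed, never trusted


def write_distance_report(code_set: CodeSet, path, prefix: str = "code") -> Path:
    """All-pairs Hamming verification report: pair, distance (TSV)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("member_i\tmember_j\tdistance\n")
        for i, j, d in code_set.pairwise_distances():
            fh.write(f"{_member_id(prefix, i)}\t{_member_id(prefix, j)}\t{d}\n")
    return path


def write_tags_tsv(members: Sequence[TaggedMember], path, code_prefix: str = "code") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("member_id\tcode\ttag\tabundance\n")
        for i, member in enumerate(members):
            fh.write(
                f"{_member_id(code_prefix, i)}\t{member.code}\t{member.tag}"
                f"\t{member.abundance:.10g}\n"
            )
    return path


def read_tagged_library(path) -> list[TaggedMember]:
    frame = pd.read_csv(path, sep="\t")
    required = {"code", "tag", "abundance"}
    if not required <= set(frame.columns):
        raise ValueError(f"tag file must have columns {sorted(required)}")
    return [
        TaggedMember(row.code, row.tag, float(row.abundance))
        for row in frame.itertuples()
    ]


def write_trajectory(traj: Trajectory, path, header_lines: Iterable[str] = ()) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# poolpcr trajectory: {traj.name}\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        traj.to_frame().to_csv(fh, index=False)
    return path


def read_trajectory(path) -> Trajectory:
    import numpy as np

    frame = pd.read_csv(path, comment="#")
    return Trajectory(
        cycle=frame["cycle"].to_numpy(float),
        fluorescence=frame["fluorescence"].to_numpy(float),
        pool_f=frame["pool_F"].to_numpy(float),
        primer_a=frame["primer_a"].to_numpy(float),
        primer_b=frame["primer_b"].to_numpy(float),
        matched_conc=frame["matched_conc"].to_numpy(float),
        mismatched_conc=frame["mismatched_conc"].to_numpy(float),
        aggregate_mass=frame["aggregate_mass"].to_numpy(float),
        name=str(Path(path).stem),
    )


def write_outcome(outcome: SelectionOutcome, path, header_lines: Iterable[str] = ()) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# poolpcr selection outcome\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(f"# total_captured={outcome.total_captured:.6g}\n")
        fh.write(f"# effective_species={outcome.effective_species:.6g}\n")
        fh.write(f"# shannon_evenness={outcome.shannon_evenness:.6g}\n")
        fh.write("code,abundance\n")
        for code, abundance in outcome.abundances.items():
            fh.write(f"{code},{abundance:.10g}\n")
    return path
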