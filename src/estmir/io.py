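"""Sequence and structure I/O.

All sequences are normalized to an uppercase DNA alphabet on ingest
(U -> T); RNA is produced only on export.  The module also parses
miRBase-style identifiers into (species prefix, family) and reads the
Vienna-style three-line structure dialect (sequence / dot-bracket /
energy in parentheses) emitted by common RNA folding tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ReferenceMiRNA",
    "StructureRecord",
    "normalize_seq",
    "read_fasta",
    "write_fasta",
    "parse_mirna_family",
    "load_reference_mirnas",
    "read_structure",
    "revcomp",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# family is the maximal miR+digits token; letter variants ("a"), arm
# suffixes ("-5p") and ".1" variant suffixes are not part of the family
_FAMILY_RE = re.compile(r"(miR\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (EST, transcript or mature miRNA)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(
                f"record {self.id!r} contains unsupported characters "
                f"{sorted(bad)}; allowed alphabet is A,C,G,T,U,N"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReferenceMiRNA:
    """A mature miRNA with family parsed from its miRBase-style name."""

    id: str
    seq: str
    species_prefix: str = field(default="", compare=False)
    family: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (16 <= len(self.seq) <= 30):
            raise ValueError(
                f"mature {self.id!r}: length {len(self.seq)} outside [16, 30]"
            )
        if not self.family:
            prefix, family = parse_mirna_family(self.id)
            object.__setattr__(self, "species_prefix", prefix)
            object.__setattr__(self, "family", family)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class StructureRecord:
    """A sequence with a pseudoknot-free secondary structure and its ΔG."""

    seq: str
    dotbracket: str
    energy_kcal_mol: float
    source: str = "bundled_fold"  # or "external_file"

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.seq):
            raise ValueError(
                f"structure length {len(self.dotbracket)} != sequence "
                f"length {len(self.seq)}"
            )
        depth = 0
        for c in self.dotbracket:
            if c == "(":
                depth += 1
            elif c == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError("unbalanced brackets in structure")
            elif c != ".":
                raise ValueError(f"invalid structure character {c!r}")
        if depth != 0:
            raise ValueError("unbalanced brackets in structure")
        if self.n_pairs > 0 and self.energy_kcal_mol > 0:
            raise ValueError("paired structure must have energy <= 0")

    @property
    def n_pairs(self) -> int:
        return self.dotbracket.count("(")

    def pair_table(self) -> list[int]:
        """Partner index per position, -1 when unpaired."""
        table = [-1] * len(self.dotbracket)
        stack: list[int] = []
        for i, c in enumerate(self.dotbracket):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                table[i], table[j] = j, i
        return table


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to the internal DNA alphabet (U -> T)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"sequence contains unsupported characters {sorted(bad)}; "
            "ambiguity codes other than N are not accepted"
        )
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_fasta_shape(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed header at line {lineno}: "
                        "FASTA must start with '>'"
                    )
                return
    raise ValueError(f"{path}: no records")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Order is preserved; sequences are uppercased with U converted to T.
    An empty file raises ``ValueError("... no records")``.
    """
    path = Path(path)
    _check_fasta_shape(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=normalize_seq(str(rec.seq)),
                description=rec.description[len(rec.id) :].strip(),
            )
        )
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, rna: bool = False
) -> None:
    """Write records as FASTA; with ``rna=True`` T is shown as U."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            seq = rec.seq.replace("T", "U") if rna else rec.seq
            fh.write(f">{header}\n{seq}\n")


def parse_mirna_family(identifier: str) -> tuple[str, str]:
    """Split a miRBase-style name into (species_prefix, family).

    ``"zma-miR528a-5p"`` -> ``("zma", "miR528")``.  Leading ``>``
    characters are tolerated (they occur in published table cells) and
    letter/arm/".1" suffixes are not part of the family.
    """
    if not identifier:
        raise ValueError("empty miRNA identifier")
    name = identifier.lstrip(">").strip()
    m = _FAMILY_RE.search(name)
    if m is None:
        raise ValueError(f"{identifier!r} is not a miRNA identifier")
    family = "miR" + m.group(1)[3:]
    prefix = name[: name.index("-")] if "-" in name else ""
    return prefix, family


def load_reference_mirnas(path: str | Path) -> list[ReferenceMiRNA]:
    """Read a mature-miRNA FASTA into :class:`ReferenceMiRNA` records."""
    return [ReferenceMiRNA(id=r.id, seq=r.seq) for r in read_fasta(path)]


_ENERGY_RE = re.compile(r"\((\s*-?\d+(?:\.\d+)?)\s*\)\s*$")


def read_structure(path: str | Path) -> StructureRecord:
    """Read a Vienna-style three-line structure file.

    Expected layout: a sequence line (an optional ``>`` header before it
    is tolerated), a dot-bracket line with the energy in trailing
    parentheses, e.g. ``((((...)))) (-35.50)``, or the energy on its own
    line.
    """
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected sequence and structure lines")
    seq = normalize_seq(lines[0])
    m = _ENERGY_RE.search(lines[1])
    if m:
        dotbracket = lines[1][: m.start()].strip()
        energy = float(m.group(1))
    elif len(lines) >= 3:
        dotbracket = lines[1]
        m = _ENERGY_RE.search(lines[2])
        if not m:
            raise ValueError(f"{path}: no parenthesized energy found")
        energy = float(m.group(1))
    else:
        raise ValueError(f"{path}: no parenthesized energy found")
    return StructureRecord(
        seq=seq, dotbracket=dotbracket, energy_kcal_mol=energy, source="external_file"
    )
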