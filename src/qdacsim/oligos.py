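"""Sequence-level toolkit for the assay's oligonucleotide designs.

The assay uses a small panel of synthetic oligos: a biotinylated 69-mer
reporter with its primer/probe set, two proximity-ligation half-templates
(C1, C2) with their connector and primers, and the full-length ligation
product C1C2. This module represents those designs, validates their
geometry (primer siting, probe complementarity, in-silico ligation) and
round-trips them through FASTA.

Coordinates are 0-based, half-open. Matching is exact string matching:
no thermodynamics, no mismatch tolerance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "OligoRecord",
    "AmpliconHit",
    "OligoError",
    "AmpliconNotFoundError",
    "reverse_complement",
    "ligate",
    "find_amplicon",
    "read_oligos",
    "write_oligos",
    "table1_path",
    "load_table1",
]

MOD5_TAGS = frozenset({"none", "biotin", "phosphate", "rox", "fam"})
MOD3_TAGS = frozenset({"none", "biotin", "mgb"})

_DNA_RE = re.compile(r"^[ACGT]+$")


class OligoError(ValueError):
    """Invalid oligo record or sequence operation."""


class AmpliconNotFoundError(OligoError):
    """No amplicon could be located; ``reason`` is 'primer_absent' or 'wrong_orientation'."""

    def __init__(self, message: str, reason: str):
        super().__init__(message)
        self.reason = reason


def _validate_sequence(seq: str) -> str:
    if not seq:
        raise OligoError("sequence must be non-empty")
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise OligoError(
                f"invalid base {base!r} at position {i}: sequence must be upper-case ACGT"
            )
    return seq


@dataclass(frozen=True)
class OligoRecord:
    """A named DNA oligo, written 5'→3', with terminal chemical modifications.

    Modifications (biotin, 5'-phosphate, fluorophores, MGB quencher) are
    metadata tags, never part of the sequence alphabet.
    """

    name: str
    sequence: str
    mod5: str = "none"
    mod3: str = "none"

    def __post_init__(self) -> None:
        if not self.name:
            raise OligoError("oligo name must be non-empty")
        _validate_sequence(self.sequence)
        m5, m3 = self.mod5.lower(), self.mod3.lower()
        if m5 not in MOD5_TAGS:
            raise OligoError(f"unknown 5' modification {self.mod5!r}; allowed: {sorted(MOD5_TAGS)}")
        if m3 not in MOD3_TAGS:
            raise OligoError(f"unknown 3' modification {self.mod3!r}; allowed: {sorted(MOD3_TAGS)}")
        object.__setattr__(self, "mod5", m5)
        object.__setattr__(self, "mod3", m3)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconHit:
    """Location of a primer-pair product on a template (0-based, half-open)."""

    template_name: str
    start: int
    end: int
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise OligoError(f"invalid amplicon coordinates [{self.start}, {self.end})")
        object.__setattr__(self, "length", self.end - self.start)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of an ACGT string."""
    _validate_sequence(seq)
    return str(Seq(seq).reverse_complement())


def ligate(
    upstream: OligoRecord,
    downstream: OligoRecord,
    connector: OligoRecord | None = None,
) -> OligoRecord:
    """Join two oligos end-to-end as a DNA ligase would.

    Ligation chemistry requires a 5'-phosphate on the downstream strand; a
    record lacking one is refused. The connector (splint) is accepted for
    record-keeping only — its bridging geometry is not sequence-verified.
    """
    if downstream.mod5 != "phosphate":
        raise OligoError(
            f"cannot ligate: downstream oligo {downstream.name!r} lacks a 5'-phosphate "
            f"(mod5={downstream.mod5!r}); ligase requires a phosphorylated 5' end"
        )
    return OligoRecord(
        name=f"{upstream.name}+{downstream.name}",
        sequence=upstream.sequence + downstream.sequence,
        mod5=upstream.mod5,
        mod3=downstream.mod3,
    )


def find_amplicon(template: OligoRecord, fwd: OligoRecord, rev: OligoRecord) -> AmpliconHit:
    """Locate the product a primer pair would amplify from a template.

    The forward primer must occur verbatim in the template; the reverse
    primer binds the bottom strand, so its reverse complement must occur
    downstream of the forward site. Exact matching only.
    """
    for primer in (fwd, rev):
        if len(primer) < 15:
            raise OligoError(f"primer {primer.name!r} is {len(primer)} nt; minimum is 15")
    f_pos = template.sequence.find(fwd.sequence)
    if f_pos < 0:
        raise AmpliconNotFoundError(
            f"no amplicon: forward primer {fwd.name!r} not found in {template.name!r}",
            reason="primer_absent",
        )
    rev_site = reverse_complement(rev.sequence)
    r_pos = template.sequence.find(rev_site, f_pos)
    if r_pos < 0:
        if rev_site in template.sequence:
            raise AmpliconNotFoundError(
                f"no amplicon: reverse-primer site for {rev.name!r} lies upstream of "
                f"forward primer {fwd.name!r} on {template.name!r}",
                reason="wrong_orientation",
            )
        raise AmpliconNotFoundError(
            f"no amplicon: reverse-primer site (rc of {rev.name!r}) not found in {template.name!r}",
            reason="primer_absent",
        )
    return AmpliconHit(template_name=template.name, start=f_pos, end=r_pos + len(rev))


def read_oligos(path: str | Path) -> dict[str, OligoRecord]:
    """Read an oligo collection from FASTA.

    Modifications are encoded as ``mod5=``/``mod3=`` tokens on the
    description line. Names must be unique. An empty file yields an empty
    collection.
    """
    records: dict[str, OligoRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        mods = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        if rec.id in records:
            raise OligoError(f"duplicate oligo name {rec.id!r} in {path}")
        records[rec.id] = OligoRecord(
            name=rec.id,
            sequence=str(rec.seq).upper(),
            mod5=mods.get("mod5", "none"),
            mod3=mods.get("mod3", "none"),
        )
    return records


def write_oligos(oligos: Iterable[OligoRecord] | dict[str, OligoRecord], path: str | Path) -> None:
    """Write an oligo collection to FASTA (inverse of :func:`read_oligos`)."""
    if isinstance(oligos, dict):
        oligos = list(oligos.values())
    seq_records = [
        SeqRecord(
            Seq(o.sequence),
            id=o.name,
            description=f"mod5={o.mod5} mod3={o.mod3}",
        )
        for o in oligos
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def table1_path() -> Path:
    """Path of the packaged oligo-panel fixture."""
    return Path(str(resources.files("qdacsim").joinpath("data/table1.fasta")))


def load_table1() -> dict[str, OligoRecord]:
    """Load the packaged oligo panel (13 records) keyed by name."""
    return read_oligos(table1_path())
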