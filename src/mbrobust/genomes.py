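"""Nucleotide sequence containers and FASTA input/output.

A :class:`GenomeSet` is the in-memory form of both the contaminant reference
(e.g. a host genome) and the microbial database being cleaned.  Sequences are
uppercased on ingest and restricted to the alphabet ``{A, C, G, T, N}``; any
other character is a hard format error rather than being silently coerced,
because a masked database must stay byte-predictable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractError, FormatError

VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence (already validated/uppercased)."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(contig_id: str, sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - VALID_ALPHABET
    if bad:
        offset = next(i for i, c in enumerate(seq) if c in bad)
        raise FormatError(
            f"contig {contig_id!r}: invalid character {seq[offset]!r} "
            f"at offset {offset} (allowed: A,C,G,T,N)"
        )
    return seq


class GenomeSet:
    """An ordered collection of contigs with a contig -> genome mapping.

    The genome mapping supports per-genome reporting (a genome may comprise
    several contigs).  When no mapping is given each contig is its own genome.
    """

    def __init__(
        self,
        contigs: Iterable[Contig | tuple[str, str]],
        genome_of_contig: Mapping[str, str] | None = None,
    ):
        self._contigs: dict[str, Contig] = {}
        for item in contigs:
            if not isinstance(item, Contig):
                item = Contig(*item)
            if not item.id:
                raise FormatError("contig with empty id")
            if item.id in self._contigs:
                raise FormatError(f"duplicate contig id {item.id!r}")
            self._contigs[item.id] = Contig(item.id, _validate_sequence(item.id, item.sequence))
        if genome_of_contig is None:
            self._genome_of = {cid: cid for cid in self._contigs}
        else:
            missing = set(self._contigs) - set(genome_of_contig)
            if missing:
                raise ContractError(
                    f"genome_of_contig missing entries for contigs: {sorted(missing)}"
                )
            self._genome_of = {cid: genome_of_contig[cid] for cid in self._contigs}

    # -- container protocol -------------------------------------------------
    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contigs

    def get(self, contig_id: str) -> Contig:
        try:
            return self._contigs[contig_id]
        except KeyError:
            raise ContractError(f"unknown contig id {contig_id!r}") from None

    @property
    def contig_ids(self) -> list[str]:
        return list(self._contigs)

    def length_of(self, contig_id: str) -> int:
        return len(self.get(contig_id))

    def genome_of(self, contig_id: str) -> str:
        self.get(contig_id)
        return self._genome_of[contig_id]

    @property
    def genome_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid in self._contigs:
            seen.setdefault(self._genome_of[cid], None)
        return list(seen)

    @property
    def genome_map(self) -> dict[str, str]:
        return dict(self._genome_of)

    def total_length(self) -> int:
        return sum(len(c) for c in self)

    def with_sequences(self, new_sequences: Mapping[str, str]) -> "GenomeSet":
        """Copy of this set with some contig sequences replaced (lengths kept)."""
        contigs = []
        for contig in self:
            seq = new_sequences.get(contig.id, contig.sequence)
            if len(seq) != len(contig.sequence):
                raise ContractError(
                    f"replacement for contig {contig.id!r} changes length "
                    f"({len(contig.sequence)} -> {len(seq)})"
                )
            contigs.append(Contig(contig.id, seq))
        return GenomeSet(contigs, self._genome_of)

    # -- FASTA --------------------------------------------------------------
    @classmethod
    def from_fasta(
        cls, path, genome_of_contig: Mapping[str, str] | None = None
    ) -> "GenomeSet":
        records = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))
        return cls(records, genome_of_contig)

    def to_fasta(self, path, width: int = 60) -> None:
        records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in self]
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
            writer.write_file(records)
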