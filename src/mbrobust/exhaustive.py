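"""Exhaustive window-based masking of host sequence in microbial databases.

The procedure tiles a contaminant reference (typically one or more human
genome assemblies) into overlapping fixed-length windows (150 bp, 75 bp
stride), locates every placement of those windows in a target microbial
database, converts the placements to reference intervals, merges overlapping
and book-ended intervals, and replaces the merged spans with ``N`` so that a
read aligner can no longer match them.  Because every position of the
reference is covered by two windows, a shared segment that is at least one
window long and aligned to the stride grid is recovered exactly.

Alignments may come from any external aligner as SAM, or from the built-in
exact matcher (deterministic, both strands, all occurrences, no hit cap).
Interval extraction reproduces the field-standard stream pipeline: the end
coordinate is ``pos + len(SEQ)`` from the SAM columns (CIGAR-agnostic by
default), ends are clipped to the contig, records are sorted and
line-deduplicated, and merging uses distance 0 with a support count — the
same semantics as ``bedtools merge -c 5 -o count``.

Coordinates are 0-based half-open internally and in BED output; SAM ``POS``
is converted by ``-1``.  The historical stream pipeline printed the 1-based
SAM position directly into BED context; ``awk_compat=True`` reproduces that
literal behaviour (every interval shifted +1 before clipping).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

from .errors import ContractError, FormatError
from .genomes import GenomeSet, revcomp

__all__ = [
    "Window",
    "AlignmentHit",
    "IntervalPrecursor",
    "Interval",
    "MaskReport",
    "ExhaustiveParams",
    "generate_windows",
    "find_exact_matches",
    "read_sam_hits",
    "hits_to_intervals",
    "merge_intervals",
    "mask_database",
    "run_exhaustive",
    "write_bed",
    "read_bed",
]


@dataclass(frozen=True)
class Window:
    """A reference sub-sequence with provenance coordinates (0-based, half-open)."""

    source_contig: str
    start: int
    end: int
    sequence: str

    @property
    def id(self) -> str:
        # Encodes (contig, start) so dedup and provenance are stable across runs.
        return f"{self.source_contig}:{self.start}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment record reduced to the fields the interval stage consults.

    ``pos`` is the 1-based leftmost reference position (SAM convention);
    ``seq_len`` is the length of the record's sequence field.  Coordinates are
    always forward-strand; ``strand`` only records the query orientation.
    """

    query_id: str
    ref_contig: str
    pos: int
    seq_len: int
    strand: str = "+"

    def __post_init__(self):
        if self.pos < 1:
            raise ContractError(f"alignment pos must be >= 1, got {self.pos}")
        if self.seq_len < 1:
            raise ContractError(f"alignment seq_len must be >= 1, got {self.seq_len}")


class IntervalPrecursor(NamedTuple):
    """Per-record reference span prior to merging (0-based half-open)."""

    contig: str
    start: int
    end: int
    query_id: str


@dataclass(frozen=True)
class Interval:
    """A merged, contig-anchored span with the count of constituent records."""

    contig: str
    start: int
    end: int
    support: int = 1

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ContractError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig!r}"
            )
        if self.support < 1:
            raise ContractError("interval support must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MaskReport:
    """Result of masking a database: the masked sequences plus accounting."""

    masked_db: GenomeSet
    intervals: list[Interval]
    genomes_affected: int
    masked_bases_per_genome: dict[str, int]
    total_masked_bases: int


def generate_windows(
    ref: GenomeSet,
    window_len: int = 150,
    step: int = 75,
    max_n: int = 100,
    min_len: int = 75,
) -> Iterator[Window]:
    """Tile every contig of *ref* into overlapping windows.

    Windows start at 0, step, 2*step, ...; each is the slice
    ``[p, min(p + window_len, contig_len))``.  Windows shorter than *min_len*
    (trailing stubs) or containing at least *max_n* ``N`` characters are
    omitted.  An empty reference yields an empty stream.
    """
    if not (1 <= step <= window_len):
        raise ContractError(f"require window_len >= step >= 1, got {window_len}, {step}")
    if min_len > window_len:
        raise ContractError(f"min_len {min_len} exceeds window_len {window_len}")
    for contig in ref:
        seq = contig.sequence
        for start in range(0, len(seq), step):
            end = min(start + window_len, len(seq))
            if end - start < min_len:
                continue
            sub = seq[start:end]
            if sub.count("N") >= max_n:
                continue
            yield Window(contig.id, start, end, sub)


def _occurrences(needle: str, haystack: str) -> Iterator[int]:
    """All (possibly overlapping) 0-based occurrences of needle in haystack."""
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def find_exact_matches(
    query: str, db: GenomeSet, query_id: str = "query"
) -> list[AlignmentHit]:
    """Locate every exact occurrence of *query* (either strand) in *db*.

    Deterministic stand-in for an external aligner: reports all overlapping
    occurrences with no hit cap.  Coordinates are forward-strand; ``pos`` is
    the 1-based leftmost position; output is ordered by (contig id, pos).
    A palindromic query is reported once per position, on the '+' strand.
    """
    if not query:
        raise ContractError("empty query")
    query = query.upper()
    rc = revcomp(query)
    hits: list[AlignmentHit] = []
    for contig_id in sorted(db.contig_ids):
        seq = db.get(contig_id).sequence
        found: dict[int, str] = {}
        for pos0 in _occurrences(query, seq):
            found[pos0] = "+"
        if rc != query:
            for pos0 in _occurrences(rc, seq):
                found.setdefault(pos0, "-")
        for pos0 in sorted(found):
            hits.append(
                AlignmentHit(query_id, contig_id, pos0 + 1, len(query), found[pos0])
            )
    return hits


def read_sam_hits(
    source, exclude_secondary: bool = False
) -> Iterator[AlignmentHit]:
    """Parse alignment hits from SAM text (path or iterable of lines).

    Only columns 1 (QNAME), 2 (FLAG), 3 (RNAME), 4 (POS) and 10 (SEQ) are
    consulted; header lines are skipped; unmapped records (flag 0x4, or
    ``RNAME='*'``/``POS=0``) are dropped.  Secondary alignments (flag 0x100)
    are kept by default, matching the historical stream pipeline which did
    not filter them; pass ``exclude_secondary=True`` to drop them.
    """

    def _parse(lines: Iterable[str]) -> Iterator[AlignmentHit]:
        for lineno, line in enumerate(lines, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(f"SAM line {lineno}: expected >= 10 fields, got {len(fields)}")
            qname, flag_s, rname, pos_s, seq = (
                fields[0], fields[1], fields[2], fields[3], fields[9],
            )
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"SAM line {lineno}: non-integer FLAG/POS") from None
            if flag & 0x4 or rname == "*" or pos == 0:
                continue
            if exclude_secondary and flag & 0x100:
                continue
            if seq == "*":
                raise FormatError(
                    f"SAM line {lineno}: SEQ is '*'; the interval stage needs the "
                    "sequence field length (re-run the aligner without SEQ omission "
                    "or drop secondary records)"
                )
            strand = "-" if flag & 0x10 else "+"
            yield AlignmentHit(qname, rname, pos, len(seq), strand)

    if hasattr(source, "__fspath__") or isinstance(source, str):
        with open(source) as handle:
            yield from _parse(handle)
    else:
        yield from _parse(source)


def hits_to_intervals(
    hits: Iterable[AlignmentHit], db: GenomeSet, awk_compat: bool = False
) -> list[IntervalPrecursor]:
    """Convert alignment hits to sorted, deduplicated interval precursors.

    Standard mode converts the 1-based SAM position: ``start0 = pos - 1``,
    ``end0 = pos - 1 + seq_len``.  ``awk_compat`` reproduces the literal
    historical stream output (``start0 = pos``, ``end0 = pos + seq_len``, a
    +1 shift).  In both modes the end is clipped to the contig length.
    Records are sorted by (contig, start, end, query) and exact duplicates
    removed, mirroring line-based deduplication of a sorted stream.
    """
    precursors: list[IntervalPrecursor] = []
    for hit in hits:
        length = db.length_of(hit.ref_contig)  # raises on unknown contig
        if hit.pos > length:
            raise ContractError(
                f"hit {hit.query_id!r}: pos {hit.pos} beyond contig "
                f"{hit.ref_contig!r} length {length}"
            )
        if awk_compat:
            start0, end0 = hit.pos, hit.pos + hit.seq_len
        else:
            start0, end0 = hit.pos - 1, hit.pos - 1 + hit.seq_len
        end0 = min(end0, length)
        precursors.append(IntervalPrecursor(hit.ref_contig, start0, end0, hit.query_id))
    precursors.sort()
    deduped: list[IntervalPrecursor] = []
    for p in precursors:
        if not deduped or p != deduped[-1]:
            deduped.append(p)
    return deduped


def merge_intervals(precursors: Sequence[IntervalPrecursor]) -> list[Interval]:
    """Merge overlapping and book-ended precursors into supported intervals.

    Input must already be sorted by (contig, start); unsorted input is an
    error rather than being silently re-sorted (sorting is the caller's
    declared responsibility, as in the stream pipeline).  Book-ended spans
    (end == next start) merge, matching merge distance 0; output intervals
    are disjoint with gaps of at least one base per contig.
    """
    merged: list[Interval] = []
    prev_key: tuple[str, int] | None = None
    cur: list | None = None  # [contig, start, end, support]
    for p in precursors:
        key = (p.contig, p.start)
        if prev_key is not None and key < prev_key:
            raise ContractError(
                f"unsorted precursor stream at {p.contig}:{p.start} (previous "
                f"{prev_key[0]}:{prev_key[1]}); sort by (contig, start) first"
            )
        prev_key = key
        if cur is not None and p.contig == cur[0] and p.start <= cur[2]:
            cur[2] = max(cur[2], p.end)
            cur[3] += 1
        else:
            if cur is not None:
                merged.append(Interval(*cur))
            cur = [p.contig, p.start, p.end, 1]
    if cur is not None:
        merged.append(Interval(*cur))
    return merged


def _union_per_contig(intervals: Iterable[Interval]) -> dict[str, list[tuple[int, int]]]:
    spans: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        spans.setdefault(iv.contig, []).append((iv.start, iv.end))
    union: dict[str, list[tuple[int, int]]] = {}
    for contig, ivs in spans.items():
        ivs.sort()
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        union[contig] = [(s, e) for s, e in out]
    return union


def mask_database(db: GenomeSet, intervals: Sequence[Interval]) -> MaskReport:
    """Replace every base inside the intervals with ``N``.

    All other bases are byte-identical to the input; masking is idempotent.
    Out-of-bounds intervals are an error — clipping is the previous stage's
    job.  Accounting (per-genome cumulative masked length, genomes affected,
    total masked bases) is computed on the union of the intervals.
    """
    union = {}
    for iv in intervals:
        length = db.length_of(iv.contig)
        if iv.end > length:
            raise ContractError(
                f"interval [{iv.start}, {iv.end}) exceeds contig "
                f"{iv.contig!r} length {length}"
            )
    union = _union_per_contig(intervals)
    new_seqs: dict[str, str] = {}
    per_genome: dict[str, int] = {}
    for contig_id, spans in union.items():
        seq = bytearray(db.get(contig_id).sequence, "ascii")
        masked = 0
        for s, e in spans:
            seq[s:e] = b"N" * (e - s)
            masked += e - s
        new_seqs[contig_id] = seq.decode("ascii")
        genome = db.genome_of(contig_id)
        per_genome[genome] = per_genome.get(genome, 0) + masked
    total = sum(per_genome.values())
    return MaskReport(
        masked_db=db.with_sequences(new_seqs),
        intervals=list(intervals),
        genomes_affected=len(per_genome),
        masked_bases_per_genome=per_genome,
        total_masked_bases=total,
    )


@dataclass(frozen=True)
class ExhaustiveParams:
    """Tunable parameters for the end-to-end masking run."""

    window_len: int = 150
    step: int = 75
    max_n: int = 100
    min_len: int = 75
    awk_compat: bool = False
    exclude_secondary: bool = False


def run_exhaustive(
    refs: GenomeSet,
    db: GenomeSet,
    params: ExhaustiveParams = ExhaustiveParams(),
    sam: Iterable[AlignmentHit] | str | None = None,
) -> MaskReport:
    """End-to-end: windows -> matches -> intervals -> merge -> mask.

    If *sam* is given (a path to SAM text, or an iterable of hits already
    parsed), those alignments are consumed instead of running the built-in
    exact matcher — this is how externally aligned window sets are ingested.
    Stage errors propagate annotated with the stage name.
    """

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ContractError, FormatError) as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    if sam is None:
        def _hit_stream() -> Iterator[AlignmentHit]:
            for window in generate_windows(
                refs, params.window_len, params.step, params.max_n, params.min_len
            ):
                yield from find_exact_matches(window.sequence, db, query_id=window.id)

        hits: Iterable[AlignmentHit] = _stage("match", lambda: list(_hit_stream()))
    elif isinstance(sam, (str,)) or hasattr(sam, "__fspath__"):
        hits = _stage("sam", lambda: list(read_sam_hits(sam, params.exclude_secondary)))
    else:
        hits = list(sam)
    precursors = _stage("intervals", hits_to_intervals, hits, db, params.awk_compat)
    merged = _stage("merge", merge_intervals, precursors)
    return _stage("mask", mask_database, db, merged)


# -- BED -------------------------------------------------------------------

def write_bed(intervals: Iterable[Interval], path) -> None:
    """Write intervals as 4-column BED (contig, start, end, support)."""
    with open(path, "w") as handle:
        for iv in intervals:
            handle.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.support}\n")


def read_bed(path) -> list[Interval]:
    intervals = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"BED line {lineno}: expected >= 3 columns")
            support = int(fields[3]) if len(fields) > 3 else 1
            intervals.append(Interval(fields[0], int(fields[1]), int(fields[2]), support))
    return intervals
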