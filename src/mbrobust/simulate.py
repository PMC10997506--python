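"""Host-read simulation and false-positive leakage estimation.

Models the experiment in which paired-end reads are simulated from a host
genome only, pushed through a sequential host-depletion filter, and the
survivors mapped against a microbial database: every database hit is by
construction a false positive.  The estimate of interest is the fraction of
host read pairs that leak through (and how many distinct taxa they light up).

The read simulator is a deliberately simple, fully deterministic model of a
2x150 bp Illumina paired-end run: fragment lengths are normal(270, 27)
rounded and clamped, one pair is emitted per 2*read_len bases of genome per
unit of fold coverage, and the only error process is an optional uniform
per-base substitution (default off).  Quality-profile machinery and indels
are intentionally absent; determinism from the seed is the requirement.
Replicate seeds follow the published schedule: 42, incremented by 1 per
sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ContractError
from .genomes import GenomeSet, revcomp

__all__ = [
    "ReadSimConfig",
    "ReadPair",
    "FPEstimate",
    "ExactReadMatcher",
    "simulate_read_pairs",
    "subsample_reads",
    "host_deplete",
    "estimate_fp_rate",
    "run_fp_experiment",
    "write_fastq_pairs",
    "read_fastq_pairs",
]


@dataclass(frozen=True)
class ReadSimConfig:
    """Paired-end simulation parameters (defaults mirror a 2x150 HiSeq run).

    ``fold_coverage`` sets the pair count per contig as
    ``floor(fold_coverage * contig_len / (2 * read_len))``.
    """

    read_len: int = 150
    frag_mean: float = 270.0
    frag_sd: float = 27.0
    fold_coverage: float = 1.0
    base_error_rate: float = 0.0
    seed: int = 42

    def __post_init__(self):
        if self.read_len < 1:
            raise ContractError("read_len must be >= 1")
        if self.frag_sd < 0:
            raise ContractError("frag_sd must be >= 0")
        if not (0 <= self.base_error_rate < 1):
            raise ContractError("base_error_rate must be in [0, 1)")
        if self.read_len > self.frag_mean:
            warnings.warn(
                "read_len exceeds mean fragment length; fragments are clamped "
                "up to read_len and mates will largely overlap",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ReadPair:
    """One simulated pair: r1 is the fragment prefix on the forward strand,
    r2 the reverse complement of the fragment suffix.  ``origin`` records the
    ground-truth fragment placement (contig, start, end)."""

    id: str
    r1: str
    r2: str
    origin: tuple[str, int, int]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        # Uniform alternative base: draw from the 3 bases differing from the original.
        orig = arr[hit]
        offsets = rng.integers(1, 4, size=n)
        idx = (np.searchsorted(_BASES, orig) + offsets) % 4
        arr[hit] = _BASES[idx]
    return arr.tobytes().decode("ascii")


def simulate_read_pairs(genome: GenomeSet, cfg: ReadSimConfig) -> list[ReadPair]:
    """Simulate error-prone paired reads from every eligible contig.

    Fragment starts are uniform over valid positions; fragment lengths are
    drawn from normal(frag_mean, frag_sd), rounded, and clamped to
    ``[read_len, contig_len - start]``.  Contigs shorter than read_len are
    skipped with a warning; zero eligible contigs is an error.  Output is
    fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs: list[ReadPair] = []
    eligible = 0
    for contig in genome:
        L = len(contig)
        if L < cfg.read_len:
            warnings.warn(
                f"contig {contig.id!r} (length {L}) shorter than read_len "
                f"{cfg.read_len}; skipped",
                stacklevel=2,
            )
            continue
        eligible += 1
        n = int(cfg.fold_coverage * L // (2 * cfg.read_len))
        if n == 0:
            continue
        starts = rng.integers(0, L - cfg.read_len + 1, size=n)
        frags = np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, size=n)).astype(np.int64)
        frags = np.clip(frags, cfg.read_len, L - starts)
        seq = contig.sequence
        for i in range(n):
            s = int(starts[i])
            e = s + int(frags[i])
            r1 = seq[s : s + cfg.read_len]
            r2 = revcomp(seq[e - cfg.read_len : e])
            if cfg.base_error_rate > 0:
                r1 = _apply_errors(r1, cfg.base_error_rate, rng)
                r2 = _apply_errors(r2, cfg.base_error_rate, rng)
            pairs.append(ReadPair(f"sim:{contig.id}:{i}", r1, r2, (contig.id, s, e)))
    if eligible == 0:
        raise ContractError("no contig is long enough to simulate reads from")
    return pairs


def subsample_reads(
    pairs: Sequence[ReadPair], n: int, seed: int
) -> list[ReadPair]:
    """Uniform sample of min(n, total) pairs without replacement.

    Mates are never split; selection is deterministic given the seed and
    preserves the original relative order of the selected pairs.
    """
    if n < 0:
        raise ContractError("subsample size must be >= 0")
    if n >= len(pairs):
        return list(pairs)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    return [pairs[i] for i in np.sort(idx)]


class ExactReadMatcher:
    """Exact full-length substring matcher over a genome set.

    Indexes all substrings of the query length (built lazily per length) so
    that matching a read is a hash lookup.  A read matches if it or its
    reverse complement occurs in any contig; :meth:`genomes_hit` reports
    which genomes contain it.
    """

    def __init__(self, genome: GenomeSet):
        self._genome = genome
        self._index: dict[int, dict[str, frozenset[str]]] = {}

    def _index_for(self, length: int) -> dict[str, frozenset[str]]:
        if length not in self._index:
            table: dict[str, set[str]] = {}
            for contig in self._genome:
                gid = self._genome.genome_of(contig.id)
                seq = contig.sequence
                for i in range(len(seq) - length + 1):
                    table.setdefault(seq[i : i + length], set()).add(gid)
            self._index[length] = {k: frozenset(v) for k, v in table.items()}
        return self._index[length]

    def genomes_hit(self, read: str) -> frozenset[str]:
        index = self._index_for(len(read))
        hits = index.get(read, frozenset()) | index.get(revcomp(read), frozenset())
        return hits

    def matches(self, read: str) -> bool:
        return bool(self.genomes_hit(read))


def host_deplete(
    pairs: Sequence[ReadPair],
    host_refs: Sequence[GenomeSet],
    matchers: Sequence[ExactReadMatcher] | None = None,
) -> list[ReadPair]:
    """Sequentially filter pairs against each host reference.

    After each reference a pair survives only if *neither* mate matches it
    (the both-mates-unmapped retention rule).  Output order is stable.
    Pre-built matchers may be supplied to amortize indexing across calls.
    """
    if not host_refs:
        warnings.warn("host_deplete called with no host references; no-op", stacklevel=2)
        return list(pairs)
    if matchers is None:
        matchers = [ExactReadMatcher(ref) for ref in host_refs]
    surviving = list(pairs)
    for matcher in matchers:
        surviving = [
            p for p in surviving
            if not (matcher.matches(p.r1) or matcher.matches(p.r2))
        ]
    return surviving


@dataclass
class FPEstimate:
    """False-positive leakage summary, pooled and per replicate."""

    n_total: int
    n_mapped: int
    frac_mapped: float
    taxa_hit: frozenset[str]
    n_taxa: int
    per_replicate: list[tuple[float, int]]
    mean_frac: float
    sd_frac: float
    mean_taxa: float
    sd_taxa: float


def estimate_fp_rate(
    surviving: Sequence[ReadPair] | Sequence[Sequence[ReadPair]],
    db: GenomeSet,
    taxon_of_genome: dict[str, str],
    matcher: ExactReadMatcher | None = None,
    per_read: bool = False,
) -> FPEstimate:
    """Map surviving host reads against the database and summarize leakage.

    *surviving* is either one collection of pairs or a list of per-replicate
    collections.  A pair counts as mapped if either mate matches any database
    contig (``per_read=True`` switches to counting mates individually, with
    denominator 2n).  Every database genome must have a taxon label.
    """
    missing = set(db.genome_ids) - set(taxon_of_genome)
    if missing:
        raise ContractError(f"taxon_of_genome missing genomes: {sorted(missing)}")
    if matcher is None:
        matcher = ExactReadMatcher(db)

    replicates: list[Sequence[ReadPair]]
    if len(surviving) > 0 and isinstance(surviving[0], ReadPair):
        replicates = [surviving]  # type: ignore[list-item]
    else:
        replicates = list(surviving)  # type: ignore[arg-type]

    total = mapped = 0
    taxa_all: set[str] = set()
    per_rep: list[tuple[float, int]] = []
    for rep in replicates:
        if len(rep) == 0:
            raise ContractError("replicate with zero reads")
        rep_total = 2 * len(rep) if per_read else len(rep)
        rep_mapped = 0
        rep_taxa: set[str] = set()
        for pair in rep:
            g1 = matcher.genomes_hit(pair.r1)
            g2 = matcher.genomes_hit(pair.r2)
            for gid in g1 | g2:
                rep_taxa.add(taxon_of_genome[gid])
            if per_read:
                rep_mapped += bool(g1) + bool(g2)
            elif g1 or g2:
                rep_mapped += 1
        total += rep_total
        mapped += rep_mapped
        taxa_all |= rep_taxa
        per_rep.append((rep_mapped / rep_total, len(rep_taxa)))

    fracs = np.array([f for f, _ in per_rep])
    taxa_counts = np.array([t for _, t in per_rep], dtype=float)
    sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    return FPEstimate(
        n_total=total,
        n_mapped=mapped,
        frac_mapped=mapped / total,
        taxa_hit=frozenset(taxa_all),
        n_taxa=len(taxa_all),
        per_replicate=per_rep,
        mean_frac=float(fracs.mean()),
        sd_frac=sd(fracs),
        mean_taxa=float(taxa_counts.mean()),
        sd_taxa=sd(taxa_counts),
    )


def run_fp_experiment(
    host: GenomeSet,
    db: GenomeSet,
    taxon_of_genome: dict[str, str],
    cfg: ReadSimConfig = ReadSimConfig(),
    n_replicates: int = 10,
    subsample_n: int = 1_000_000,
    seed_start: int = 42,
    host_refs: Sequence[GenomeSet] = (),
    per_read: bool = False,
) -> FPEstimate:
    """Full pipeline per replicate: simulate -> subsample -> deplete -> map.

    Defaults mirror the published design: 10 replicate samples, one million
    pairs subsampled per replicate, seeds starting at 42 and incremented by
    one per sample (both for simulation and subsampling).
    """
    matchers = [ExactReadMatcher(ref) for ref in host_refs]
    db_matcher = ExactReadMatcher(db)
    surviving: list[list[ReadPair]] = []
    for i in range(n_replicates):
        seed = seed_start + i
        pairs = simulate_read_pairs(host, replace(cfg, seed=seed))
        pairs = subsample_reads(pairs, subsample_n, seed)
        if host_refs:
            pairs = host_deplete(pairs, host_refs, matchers)
        surviving.append(pairs)
    return estimate_fp_rate(surviving, db, taxon_of_genome, db_matcher, per_read)


# -- FASTQ -----------------------------------------------------------------

def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    """Write mates as two 4-line-record FASTQ files with constant quality."""
    with open(r1_path, "w") as h1, open(r2_path, "w") as h2:
        for p in pairs:
            h1.write(f"@{p.id}/1\n{p.r1}\n+\n{'I' * len(p.r1)}\n")
            h2.write(f"@{p.id}/2\n{p.r2}\n+\n{'I' * len(p.r2)}\n")


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    def _records(path):
        with open(path) as handle:
            lines = [line.rstrip("\n") for line in handle]
        if len(lines) % 4:
            raise ContractError(f"{path}: FASTQ record count not a multiple of 4")
        for i in range(0, len(lines), 4):
            name = lines[i].lstrip("@").rsplit("/", 1)[0]
            yield name, lines[i + 1]

    recs1, recs2 = list(_records(r1_path)), list(_records(r2_path))
    if len(recs1) != len(recs2):
        raise ContractError("R1/R2 FASTQ files have different record counts")
    pairs = []
    for (n1, s1), (n2, s2) in zip(recs1, recs2):
        if n1 != n2:
            raise ContractError(f"unpaired records {n1!r} vs {n2!r}")
        pairs.append(ReadPair(n1, s1, s2, (n1, -1, -1)))
    return pairs
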