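"""Synthetic fixtures with known ground truth for every other module.

Fixtures are uniform-random by design — they do not emulate real genome
composition (GC skew, repeats).  What they guarantee instead is the property
the oracle tests need: in a planted database, the only sequence shared
between host and database (at the window minimum length of 75 bp, either
strand) is the planted segments themselves, verified by substring check at
generation time and regenerated on collision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .concordance import ImportanceVector
from .errors import ContractError
from .exhaustive import Interval
from .genomes import Contig, GenomeSet, revcomp

__all__ = [
    "PlantedDatabaseSpec",
    "PlantedDatabase",
    "make_planted_database",
    "ImportancePairSpec",
    "make_importance_pair",
    "TaxonTableSpec",
    "TaxonTableFixture",
    "make_taxon_table",
]

_ALPHA = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _ALPHA[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


# -- planted database ------------------------------------------------------

@dataclass(frozen=True)
class PlantedDatabaseSpec:
    """Parameters of a host + database pair with planted shared segments.

    With ``grid_aligned=True`` the host-side source positions are multiples
    of *step* and segment lengths are multiples of *step* and at least
    *window_len*, which guarantees that overlapping windows tile each planted
    segment completely (full-recovery ground truth).
    """

    n_genomes: int = 3
    genome_length: int = 3000
    host_length: int = 2000
    n_segments: int = 1
    segment_length: int = 300
    grid_aligned: bool = True
    window_len: int = 150
    step: int = 75
    seed: int = 0
    max_tries: int = 20


@dataclass
class PlantedDatabase:
    """Database + host + truth intervals (database coordinates)."""

    db: GenomeSet
    host: GenomeSet
    truth: list[Interval]
    spec: PlantedDatabaseSpec


def _host_kmers(host: GenomeSet, k: int) -> set[str]:
    kmers: set[str] = set()
    for contig in host:
        seq = contig.sequence
        rc = revcomp(seq)
        for s in (seq, rc):
            for i in range(len(s) - k + 1):
                kmers.add(s[i : i + k])
    return kmers


def _clean_of_host(db: GenomeSet, host: GenomeSet, truth: Sequence[Interval], k: int) -> bool:
    """True iff every db k-mer not wholly inside a truth interval is absent
    from the host (either strand).  This covers matches straddling a planted
    segment boundary as well as spurious matches in random sequence."""
    host_kmers = _host_kmers(host, k)
    truth_by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in truth:
        truth_by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    for contig in db:
        spans = sorted(truth_by_contig.get(contig.id, []))
        seq = contig.sequence
        for i in range(len(seq) - k + 1):
            inside = any(s <= i and i + k <= e for s, e in spans)
            if not inside and seq[i : i + k] in host_kmers:
                return False
    return True


def make_planted_database(spec: PlantedDatabaseSpec) -> PlantedDatabase:
    """Generate a random host and database with exact planted segments.

    Segments are copied from the host into database genomes at recorded
    positions (pairwise target gaps of at least one window length, so
    distinct truth intervals never merge).  Reproducible from the seed.
    """
    if spec.segment_length < 1 or spec.genome_length < spec.segment_length:
        raise ContractError("segment length must be in [1, genome_length]")
    if spec.grid_aligned:
        if spec.segment_length % spec.step or spec.segment_length < spec.window_len:
            raise ContractError(
                "grid-aligned segments must have length a multiple of step "
                "and >= window_len"
            )
    if spec.n_segments and spec.host_length < spec.segment_length:
        raise ContractError("host shorter than segment length")
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_tries):
        host = GenomeSet([Contig("host", _random_seq(rng, spec.host_length))])
        db_seqs = {
            f"g{i}": bytearray(_random_seq(rng, spec.genome_length), "ascii")
            for i in range(spec.n_genomes)
        }
        truth: list[Interval] = []
        host_seq = host.get("host").sequence
        ok = True
        # Track occupied target spans per genome to keep >= window_len gaps.
        occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in db_seqs}
        for _seg in range(spec.n_segments):
            if spec.grid_aligned:
                max_src = (spec.host_length - spec.segment_length) // spec.step
                src = int(rng.integers(0, max_src + 1)) * spec.step
            else:
                src = int(rng.integers(0, spec.host_length - spec.segment_length + 1))
            genome = f"g{int(rng.integers(0, spec.n_genomes))}"
            placed = False
            for _try in range(50):
                tgt = int(rng.integers(0, spec.genome_length - spec.segment_length + 1))
                span = (tgt - spec.window_len, tgt + spec.segment_length + spec.window_len)
                if all(e <= span[0] or s >= span[1] for s, e in occupied[genome]):
                    occupied[genome].append((tgt, tgt + spec.segment_length))
                    placed = True
                    break
            if not placed:
                ok = False
                break
            segment = host_seq[src : src + spec.segment_length]
            db_seqs[genome][tgt : tgt + spec.segment_length] = segment.encode("ascii")
            # Sanitize the planted-segment flanks: a database base adjacent to
            # the segment that happens to equal the host base adjacent to the
            # source would extend the shared substring past the truth span.
            buf = db_seqs[genome]
            for db_pos, host_pos in (
                (tgt - 1, src - 1),
                (tgt + spec.segment_length, src + spec.segment_length),
            ):
                if 0 <= db_pos < len(buf) and 0 <= host_pos < len(host_seq):
                    if buf[db_pos] == ord(host_seq[host_pos]):
                        choices = [b for b in b"ACGT" if b != buf[db_pos]]
                        buf[db_pos] = choices[int(rng.integers(0, 3))]
            truth.append(Interval(genome, tgt, tgt + spec.segment_length, 1))
        if not ok:
            continue
        db = GenomeSet(
            [Contig(g, s.decode("ascii")) for g, s in db_seqs.items()]
        )
        truth.sort(key=lambda iv: (iv.contig, iv.start))
        if _clean_of_host(db, host, truth, k=min(spec.step, spec.window_len // 2)):
            return PlantedDatabase(db, host, truth, spec)
    raise ContractError(
        f"could not generate a collision-free planted database in "
        f"{spec.max_tries} tries at the requested sizes"
    )


# -- importance-vector pairs ----------------------------------------------

@dataclass(frozen=True)
class ImportancePairSpec:
    """Two importance vectors with controlled usage overlap and rank noise.

    ``overlap=None`` draws model B's used set uniformly at random,
    independent of model A (the null for the binary-overlap test).  With an
    integer overlap, exactly that many used features are shared, and B's
    ranking of the shared features is A's order perturbed by adjacent swaps
    at probability ``rank_noise``.
    """

    n_features: int = 1240
    k_a: int = 100
    k_b: int = 100
    overlap: int | None = None
    rank_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if max(self.k_a, self.k_b) > self.n_features:
            raise ContractError("k_used exceeds universe size")
        if self.overlap is not None and self.overlap > min(self.k_a, self.k_b):
            raise ContractError("overlap exceeds min(k_a, k_b)")


def make_importance_pair(
    spec: ImportancePairSpec,
) -> tuple[ImportanceVector, ImportanceVector]:
    rng = np.random.default_rng(spec.seed)
    features = [f"f{i:05d}" for i in range(spec.n_features)]
    universe = frozenset(features)
    a_idx = rng.choice(spec.n_features, size=spec.k_a, replace=False)
    a_order = [features[i] for i in a_idx]  # rank 1 first
    scores_a = {f: float(spec.k_a - r) for r, f in enumerate(a_order)}

    if spec.overlap is None:
        b_idx = rng.choice(spec.n_features, size=spec.k_b, replace=False)
        b_order = [features[i] for i in b_idx]
        rng.shuffle(b_order)
    else:
        shared_pos = sorted(rng.choice(spec.k_a, size=spec.overlap, replace=False))
        shared = [a_order[i] for i in shared_pos]  # keeps A's relative order
        pool = [f for f in features if f not in set(a_order)]
        fresh_idx = rng.choice(len(pool), size=spec.k_b - spec.overlap, replace=False)
        fresh = [pool[i] for i in fresh_idx]
        order = list(shared)
        for i in range(len(order) - 1):  # one pass of adjacent swaps
            if rng.random() < spec.rank_noise:
                order[i], order[i + 1] = order[i + 1], order[i]
        b_order = list(order)
        for f in fresh:
            b_order.insert(int(rng.integers(0, len(b_order) + 1)), f)
    scores_b = {f: float(spec.k_b - r) for r, f in enumerate(b_order)}
    return (
        ImportanceVector(scores_a, universe),
        ImportanceVector(scores_b, universe),
    )


# -- taxon tables ----------------------------------------------------------

@dataclass(frozen=True)
class TaxonTableSpec:
    """Taxon count table + coverage intervals straddling the filter
    thresholds, with the expected pass sets recorded."""

    n_random_taxa: int = 6
    read_min: int = 10
    kmer_min: int = 1000
    coverage_threshold: float = 0.50
    genome_length: int = 1000
    seed: int = 0


@dataclass
class TaxonTableFixture:
    counts: pd.DataFrame
    expected_taxa: set[str]
    coverage: pd.DataFrame
    genome_lengths: dict[str, int]
    expected_genomes: set[str]
    spec: TaxonTableSpec


def make_taxon_table(spec: TaxonTableSpec) -> TaxonTableFixture:
    """Deterministic boundary cases plus seeded random clear-cut taxa."""
    rng = np.random.default_rng(spec.seed)
    rows = [
        # taxon, sample, reads, kmers  — fixed boundary probes
        ("t_boundary", "s1", spec.read_min, spec.kmer_min),          # pass (>=)
        ("t_low_reads", "s1", spec.read_min - 1, spec.kmer_min * 10),  # fail
        ("t_low_kmers", "s1", spec.read_min * 10, spec.kmer_min - 1),  # fail
        ("t_split", "s1", spec.read_min * 5, spec.kmer_min - 1),       # fail: never
        ("t_split", "s2", spec.read_min - 1, spec.kmer_min * 5),       # both in one sample
    ]
    expected = {"t_boundary"}
    for i in range(spec.n_random_taxa):
        passes = bool(rng.integers(0, 2))
        if passes:
            reads = int(rng.integers(spec.read_min, spec.read_min * 10))
            kmers = int(rng.integers(spec.kmer_min, spec.kmer_min * 10))
            expected.add(f"t_rand{i}")
        else:
            reads = int(rng.integers(0, spec.read_min))
            kmers = int(rng.integers(0, spec.kmer_min))
        rows.append((f"t_rand{i}", "s1", reads, kmers))
    counts = pd.DataFrame(rows, columns=["taxon", "sample", "reads", "unique_kmers"])

    # Coverage genomes with exactly known union fractions around the threshold.
    L = spec.genome_length
    boundary = int(round(spec.coverage_threshold * L))
    cov_rows = []
    fractions = {
        "g_zero": 0,
        "g_below": boundary - 1,
        "g_boundary": boundary,
        "g_above": min(L, boundary + L // 4),
        "g_full": L,
    }
    for genome, covered in fractions.items():
        if covered == 0:
            continue
        # split the covered prefix into two overlapping per-sample intervals
        half = covered // 2
        if half:
            cov_rows.append((genome, 0, half + min(10, covered - half), "sA"))
            cov_rows.append((genome, half, covered, "sB"))
        else:
            cov_rows.append((genome, 0, covered, "sA"))
    coverage = pd.DataFrame(cov_rows, columns=["genome", "start", "end", "sample"])
    genome_lengths = {g: L for g in fractions}
    expected_genomes = {g for g, c in fractions.items() if c / L >= spec.coverage_threshold}
    return TaxonTableFixture(
        counts, expected, coverage, genome_lengths, expected_genomes, spec
    )
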