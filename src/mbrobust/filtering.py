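"""Conservative two-step taxonomic filtering.

Step (i) restricts candidate taxa to a human-association whitelist (curated
body-site assemblies, decontaminated cohorts, pathogen lists — user-supplied
files); viruses and phages, which such catalogs omit, may be exempted and
left to step (ii).  Step (ii) removes residual false positives either with
classifier confidence thresholds (read count >= 10 AND unique k-mer count >=
1000, boundary inclusive) or with aggregate genome coverage: the fraction of
a genome's positions covered by at least one aligned read across a *set* of
samples, thresholded at >= 50% (75% and 90% are the stricter published
alternates).  A species with several database genomes is kept when any one
of its genomes passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .errors import ContractError, FormatError

__all__ = [
    "normalize_label",
    "Whitelist",
    "intersect_whitelist",
    "filter_krakenuniq",
    "CoverageRecord",
    "aggregate_coverage",
    "CoverageFilterResult",
    "filter_by_coverage",
]


def normalize_label(label: str) -> str:
    """Case- and whitespace-insensitive canonical form for taxon labels."""
    return " ".join(str(label).split()).casefold()


@dataclass
class Whitelist:
    """Human-associated taxa with per-taxon source tags.

    Labels are normalized before membership tests.
    """

    taxa: set[str]
    sources: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.taxa = {normalize_label(t) for t in self.taxa}
        self.sources = {normalize_label(t): set(v) for t, v in self.sources.items()}

    def __contains__(self, taxon: str) -> bool:
        return normalize_label(taxon) in self.taxa

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Whitelist":
        """Build from a table with a ``taxon`` column and optional ``source``."""
        if "taxon" not in frame.columns:
            raise FormatError("whitelist table must have a 'taxon' column")
        sources: dict[str, set[str]] = {}
        if "source" in frame.columns:
            for taxon, src in zip(frame["taxon"], frame["source"]):
                sources.setdefault(normalize_label(taxon), set()).add(str(src))
        return cls(set(frame["taxon"].astype(str)), sources)

    @classmethod
    def from_tsv(cls, path) -> "Whitelist":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def intersect_whitelist(
    taxa: Iterable[str],
    whitelist: Whitelist,
    exempt: Iterable[str] = (),
) -> tuple[set[str], pd.DataFrame]:
    """Keep taxa present in the whitelist (or explicitly exempted).

    *exempt* taxa (typically viruses/phages, absent from association
    catalogs) bypass the whitelist and are retained for downstream
    coverage/threshold filtering only.  Returns the kept set (original
    spellings) and a per-taxon report with the drop reason.
    """
    exempt_norm = {normalize_label(t) for t in exempt}
    kept: set[str] = set()
    rows = []
    for taxon in taxa:
        norm = normalize_label(taxon)
        if norm in whitelist.taxa:
            kept.add(taxon)
            rows.append((taxon, True, "whitelisted"))
        elif norm in exempt_norm:
            kept.add(taxon)
            rows.append((taxon, True, "exempt (deferred to coverage/threshold filtering)"))
        else:
            rows.append((taxon, False, "not human-associated"))
    report = pd.DataFrame(rows, columns=["taxon", "kept", "reason"])
    return kept, report


def filter_krakenuniq(
    records: pd.DataFrame,
    read_min: int = 10,
    kmer_min: int = 1000,
    aggregate: str = "any-sample",
) -> set[str]:
    """Taxa passing the read-count AND unique-k-mer thresholds.

    *records* has columns ``taxon, sample, reads, unique_kmers``.  Under
    ``any-sample`` aggregation a taxon passes if any single sample meets both
    thresholds simultaneously; under ``summed`` the counts are summed across
    samples first.  Boundary values pass (>= semantics).
    """
    required = {"taxon", "reads", "unique_kmers"}
    missing = required - set(records.columns)
    if missing:
        raise FormatError(f"taxon count table missing columns: {sorted(missing)}")
    if len(records) == 0:
        raise ContractError("taxon count table is empty")
    if (records["reads"] < 0).any() or (records["unique_kmers"] < 0).any():
        raise ContractError("negative read or k-mer counts")
    if aggregate == "any-sample":
        both = records[
            (records["reads"] >= read_min) & (records["unique_kmers"] >= kmer_min)
        ]
        return set(both["taxon"])
    if aggregate == "summed":
        sums = records.groupby("taxon")[["reads", "unique_kmers"]].sum()
        passing = sums[(sums["reads"] >= read_min) & (sums["unique_kmers"] >= kmer_min)]
        return set(passing.index)
    raise ContractError(f"unknown aggregation mode {aggregate!r}")


@dataclass
class CoverageRecord:
    """Union of covered intervals for one genome across a sample set."""

    genome_id: str
    genome_length: int
    covered: list[tuple[int, int]]
    aggregate_fraction: float


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    intervals = sorted(intervals)
    out: list[list[int]] = []
    for s, e in intervals:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def aggregate_coverage(
    hits: pd.DataFrame,
    genome_lengths: Mapping[str, int],
    samples: Sequence[str] | None = None,
) -> dict[str, CoverageRecord]:
    """Per-genome coverage union across a (sub)set of samples.

    *hits* has columns ``genome, start, end`` and optionally ``sample``;
    restricting to a sample subset recomputes the union from the cached
    per-sample intervals without re-reading alignments.  Every genome in
    *genome_lengths* gets a record (0.0 with no hits).
    """
    required = {"genome", "start", "end"}
    missing = required - set(hits.columns)
    if missing:
        raise FormatError(f"coverage table missing columns: {sorted(missing)}")
    if samples is not None:
        if "sample" not in hits.columns:
            raise FormatError("sample subset requested but no 'sample' column present")
        hits = hits[hits["sample"].isin(set(samples))]
    by_genome: dict[str, list[tuple[int, int]]] = {g: [] for g in genome_lengths}
    for genome, start, end in zip(hits["genome"], hits["start"], hits["end"]):
        if genome not in genome_lengths:
            raise ContractError(f"coverage interval for unknown genome {genome!r}")
        length = genome_lengths[genome]
        if not (0 <= start < end <= length):
            raise ContractError(
                f"interval [{start}, {end}) out of bounds for genome "
                f"{genome!r} (length {length})"
            )
        by_genome[genome].append((int(start), int(end)))
    records = {}
    for genome, intervals in by_genome.items():
        union = _union(intervals)
        covered = sum(e - s for s, e in union)
        records[genome] = CoverageRecord(
            genome_id=genome,
            genome_length=int(genome_lengths[genome]),
            covered=union,
            aggregate_fraction=covered / genome_lengths[genome],
        )
    return records


class CoverageFilterResult(NamedTuple):
    kept_genomes: set[str]
    kept_species: set[str]


def filter_by_coverage(
    coverages: Mapping[str, CoverageRecord] | Mapping[str, float],
    threshold: float = 0.50,
    species_of_genome: Mapping[str, str] | None = None,
    exclude: Iterable[str] = (),
) -> CoverageFilterResult:
    """Genomes/species passing the aggregate-coverage threshold.

    A genome is kept iff its aggregate fraction is >= *threshold* (boundary
    passes).  A species is kept when any constituent genome passes.  The
    *exclude* list (e.g. manually curated removals) is applied after
    filtering, at the species level, with normalized labels.
    """
    if not (0 < threshold <= 1):
        raise ContractError("coverage threshold must be in (0, 1]")
    fractions = {
        g: (r.aggregate_fraction if isinstance(r, CoverageRecord) else float(r))
        for g, r in coverages.items()
    }
    kept_genomes = {g for g, f in fractions.items() if f >= threshold}
    if species_of_genome is None:
        species_of_genome = {g: g for g in fractions}
    kept_species = {species_of_genome[g] for g in kept_genomes}
    excluded = {normalize_label(t) for t in exclude}
    kept_species = {s for s in kept_species if normalize_label(s) not in excluded}
    kept_genomes = {
        g for g in kept_genomes
        if normalize_label(species_of_genome[g]) not in excluded
    }
    return CoverageFilterResult(kept_genomes, kept_species)
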