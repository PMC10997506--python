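"""Run manifests and mask-report comparison.

A manifest records everything needed to reproduce a CLI invocation —
subcommand, parameters, seeds, and SHA-256 digests of inputs and outputs —
so any run can be replayed (`mbrobust rerun`) and checked byte-for-byte.

Mask-report comparison mirrors how two database-cleaning methods are
benchmarked: per-genome cumulative masked lengths, counts of genomes flagged
by one method or both, and an optional Wilcoxon signed-rank test on the
paired lengths of genomes flagged by both.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field

import pandas as pd
from scipy import stats

from .errors import ContractError
from .exhaustive import MaskReport

__all__ = ["RunManifest", "file_digest", "MaskComparison", "compare_mask_reports"]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record for one CLI invocation."""

    subcommand: str
    argv: list[str]
    params: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    def record_input(self, path) -> None:
        self.inputs[str(path)] = file_digest(path)

    def record_output(self, path) -> None:
        self.outputs[str(path)] = file_digest(path)

    def write(self, path) -> None:
        self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as handle:
            data = json.load(handle)
        return cls(**data)


@dataclass
class MaskComparison:
    """Per-genome comparison of two mask reports over the same database."""

    per_genome: pd.DataFrame  # genome, masked_a, masked_b, flagged_a, flagged_b
    n_both: int
    n_a_only: int
    n_b_only: int
    paired: pd.DataFrame  # restricted to genomes flagged by both
    wilcoxon_p: float | None = None


def compare_mask_reports(
    report_a: MaskReport, report_b: MaskReport, wilcoxon: bool = False
) -> MaskComparison:
    """Compare cumulative masked lengths per genome between two reports.

    Both reports must cover the same database genome set.  The paired table
    is restricted to genomes flagged (>= 1 masked base) by both methods;
    the optional Wilcoxon signed-rank test runs on those paired lengths.
    """
    genomes_a = set(report_a.masked_db.genome_ids)
    genomes_b = set(report_b.masked_db.genome_ids)
    if genomes_a != genomes_b:
        raise ContractError(
            f"genome sets differ: only-in-A={sorted(genomes_a - genomes_b)[:5]} "
            f"only-in-B={sorted(genomes_b - genomes_a)[:5]}"
        )
    rows = []
    for genome in sorted(genomes_a):
        ma = report_a.masked_bases_per_genome.get(genome, 0)
        mb = report_b.masked_bases_per_genome.get(genome, 0)
        rows.append((genome, ma, mb, ma > 0, mb > 0))
    frame = pd.DataFrame(
        rows, columns=["genome", "masked_a", "masked_b", "flagged_a", "flagged_b"]
    )
    both = frame[frame["flagged_a"] & frame["flagged_b"]]
    n_a_only = int((frame["flagged_a"] & ~frame["flagged_b"]).sum())
    n_b_only = int((frame["flagged_b"] & ~frame["flagged_a"]).sum())
    p = None
    if wilcoxon and len(both):
        diffs = both["masked_a"] - both["masked_b"]
        if (diffs != 0).any():
            p = float(stats.wilcoxon(both["masked_a"], both["masked_b"]).pvalue)
        else:
            p = 1.0
    return MaskComparison(
        per_genome=frame,
        n_both=int(len(both)),
        n_a_only=n_a_only,
        n_b_only=n_b_only,
        paired=both.reset_index(drop=True),
        wilcoxon_p=p,
    )
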