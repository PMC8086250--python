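"""Genotype acceptance, sample-level coverage QC and duplicate concordance.

Amplicon-panel and exome sequencing of rare variants produces candidate
genotype calls that need filtering before any association analysis.  The
acceptance rule used here combines four sources of support for a call:

1. an orthogonal chip genotype for the same sample,
2. the variant being observed on more than one amplicon,
3. read depth >= 15 with alternate allele fraction >= 40%,
4. read depth >= 100 with alternate allele fraction >= 25%,

accepted if ANY clause holds.  Samples are retained only if at least 80% of
the target footprint is covered at 15x.  Duplicate concordance is reported as
concordant calls over the union of calls within each duplicate pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError, QCError

#: default sample-retention threshold: fraction of target bases at >=15x
COVERAGE_THRESHOLD = 0.80


@dataclass
class GenotypeEvidence:
    """Read support for one candidate genotype call (one sample x one variant)."""

    sample_id: str
    variant_id: str
    depth: int
    alt_reads: int
    n_amplicons: int = 1
    chip_genotype_available: bool = False

    @property
    def alt_fraction(self) -> float:
        if self.depth == 0:
            if self.alt_reads > 0:
                raise DataError(
                    f"{self.sample_id}/{self.variant_id}: alt reads with zero depth"
                )
            return 0.0
        return self.alt_reads / self.depth


@dataclass
class SampleRecord:
    """One study subject with phenotype, stratum and coverage QC metric."""

    sample_id: str
    status: str  # "case" | "control"
    histotype: str = "NA"  # "HGSOC" | "other-EOC" | "NA"
    stratum: str = "NA"
    platform: str = "TS"  # "TS" | "ES" | "CHIP"
    frac_target_at_15x: float | None = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise DataError(f"{self.sample_id}: unknown status {self.status!r}")
        if self.frac_target_at_15x is not None and not (
            0.0 <= self.frac_target_at_15x <= 1.0
        ):
            raise DataError(f"{self.sample_id}: coverage fraction outside [0,1]")


def call_variant(evidence: GenotypeEvidence) -> bool:
    """Apply the four-clause genotype acceptance rule (inclusive disjunction).

    Boundary comparisons are inclusive (>=) on both depth and alternate
    allele fraction.  Raises :class:`DataError` for alt reads at zero depth.
    """
    if evidence.depth == 0 and evidence.alt_reads > 0:
        raise DataError(
            f"{evidence.sample_id}/{evidence.variant_id}: alt reads with zero depth"
        )
    if evidence.chip_genotype_available:
        return True
    if evidence.n_amplicons > 1:
        return True
    aaf = evidence.alt_fraction
    if evidence.depth >= 15 and aaf >= 0.40:
        return True
    if evidence.depth >= 100 and aaf >= 0.25:
        return True
    return False


def acceptance_clause(evidence: GenotypeEvidence) -> int:
    """Return the first satisfied clause number (1-4), or 0 if rejected."""
    if evidence.depth == 0 and evidence.alt_reads > 0:
        raise DataError(
            f"{evidence.sample_id}/{evidence.variant_id}: alt reads with zero depth"
        )
    if evidence.chip_genotype_available:
        return 1
    if evidence.n_amplicons > 1:
        return 2
    aaf = evidence.alt_fraction
    if evidence.depth >= 15 and aaf >= 0.40:
        return 3
    if evidence.depth >= 100 and aaf >= 0.25:
        return 4
    return 0


def sample_qc(sample: SampleRecord, threshold: float = COVERAGE_THRESHOLD) -> bool:
    """Retain a sample iff its 15x target coverage fraction is >= threshold.

    Samples strictly below the threshold are excluded; a missing metric is a
    :class:`QCError`.
    """
    if sample.frac_target_at_15x is None:
        raise QCError(f"{sample.sample_id}: missing coverage metric")
    return sample.frac_target_at_15x >= threshold


@dataclass
class ConcordanceResult:
    n_concordant: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_total


def duplicate_concordance(
    pairs: Sequence[tuple[Iterable[str], Iterable[str]]],
) -> ConcordanceResult:
    """Aggregate call concordance over duplicate-sequenced subject pairs.

    For each pair the denominator is the union of variants called in either
    member and the numerator the intersection; counts are summed over pairs
    before dividing.
    """
    if len(pairs) == 0:
        raise DataError("duplicate_concordance: empty pair list")
    n_conc = 0
    n_tot = 0
    for calls_a, calls_b in pairs:
        sa, sb = set(calls_a), set(calls_b)
        n_conc += len(sa & sb)
        n_tot += len(sa | sb)
    if n_tot == 0:
        raise DataError("duplicate_concordance: no calls in any pair")
    return ConcordanceResult(n_conc, n_tot)


# ---------------------------------------------------------------------------
# DataFrame-level stage functions used by the pipeline
# ---------------------------------------------------------------------------

EVIDENCE_COLUMNS = [
    "sample_id",
    "variant_id",
    "depth",
    "alt_reads",
    "n_amplicons",
    "chip_genotype_available",
]


def apply_genotype_acceptance(evidence: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Vectorised acceptance rule over an evidence table.

    Returns the accepted subset (with an ``accepted_clause`` column) and a
    tally report ``{clause: n}`` plus counts in/out.  Chip genotypes win over
    conflicting read evidence (clause 1 is unconditional); the report records
    how many calls were accepted on the chip clause alone.
    """
    ev = evidence.copy()
    bad = (ev["depth"] == 0) & (ev["alt_reads"] > 0)
    if bad.any():
        first = ev.loc[bad].iloc[0]
        raise DataError(
            f"{first['sample_id']}/{first['variant_id']}: alt reads with zero depth"
        )
    aaf = ev["alt_reads"] / ev["depth"].where(ev["depth"] > 0, other=1)
    chip = ev["chip_genotype_available"].astype(bool)
    multi_amp = ev["n_amplicons"] > 1
    rule3 = (ev["depth"] >= 15) & (aaf >= 0.40)
    rule4 = (ev["depth"] >= 100) & (aaf >= 0.25)

    clause = pd.Series(0, index=ev.index)
    clause[rule4] = 4
    clause[rule3] = 3
    clause[multi_amp] = 2
    clause[chip] = 1
    ev["accepted_clause"] = clause
    accepted = ev[clause > 0].copy()
    report = {
        "n_in": int(len(ev)),
        "n_accepted": int(len(accepted)),
        "n_rejected": int((clause == 0).sum()),
        "by_clause": {int(k): int(v) for k, v in clause[clause > 0].value_counts().items()},
        "chip_overrides_reads": int((chip & ~(multi_amp | rule3 | rule4)).sum()),
    }
    return accepted, report


def apply_sample_qc(
    manifest: pd.DataFrame, threshold: float = COVERAGE_THRESHOLD
) -> tuple[pd.DataFrame, dict]:
    """Drop samples with <threshold of target bases at 15x; report exclusions."""
    if "frac_target_at_15x" not in manifest.columns:
        raise QCError("manifest lacks frac_target_at_15x column")
    if manifest["frac_target_at_15x"].isna().any():
        bad = manifest.loc[manifest["frac_target_at_15x"].isna(), "sample_id"].iloc[0]
        raise QCError(f"{bad}: missing coverage metric")
    keep = manifest["frac_target_at_15x"] >= threshold
    retained = manifest[keep].copy()
    excl = manifest[~keep]
    report = {
        "n_in": int(len(manifest)),
        "n_retained": int(len(retained)),
        "n_excluded": int(len(excl)),
        "excluded_cases": int((excl["status"] == "case").sum()),
        "excluded_controls": int((excl["status"] == "control").sum()),
        "threshold": threshold,
    }
    return retained, report
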