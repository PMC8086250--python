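"""Deleterious-variant classification and rare-missense filtering.

A variant is classified *deleterious* if any of three independent clauses
holds:

* **truncation** — the annotated consequence predicts protein truncation
  (frameshift indel, nonsense, canonical splice site, start loss);
* **clinvar** — ClinVar classifies it pathogenic or likely pathogenic;
* **splice** — it lies in the splice-candidate window around an exon-intron
  boundary and its MaxEntScan score drops by more than 40% from a reference
  score of at least 3.

Rare missense variants (MAF < 1%) that are NOT deleterious form a separate
analysis set; each is labelled damaging when at least two of SIFT
(score < 0.05), PolyPhen-2 (probably damaging/damaging) and PROVEAN
(score <= -2.5) agree.  Standard genotype-level QC (call-rate and exact
Hardy-Weinberg filters) is applied before any missense association test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ClassificationError, DataError

TRUNCATING_CONSEQUENCES = frozenset(
    {"frameshift_indel", "nonsense", "canonical_splice_site", "start_loss"}
)
CONSEQUENCE_VOCAB = TRUNCATING_CONSEQUENCES | {"missense", "synonymous", "other"}
CLINVAR_VOCAB = frozenset({"pathogenic", "likely_pathogenic", "benign", "VUS", "absent"})
CLINVAR_PATHOGENIC = frozenset({"pathogenic", "likely_pathogenic"})
POLYPHEN_DAMAGING = frozenset({"probably_damaging", "damaging"})

#: splice-candidate window sizes (bp from the exon-intron boundary)
EXONIC_WINDOW = 3
ACCEPTOR_INTRONIC_WINDOW = 20
DONOR_INTRONIC_WINDOW = 6

#: MaxEntScan decision rule
MES_MIN_REF = 3.0
MES_MIN_RELATIVE_DROP = 0.40


@dataclass
class VariantAnnotation:
    """Functional annotation of one variant.

    ``distance_to_boundary`` is signed: non-negative for exonic positions,
    negative for intronic positions, measured in bp from the nearest
    exon-intron boundary.  ``boundary_side`` names the splice site the
    boundary belongs to ("acceptor" or "donor").  MaxEntScan scores and the
    three in-silico missense predictions may be missing (None/NaN).
    """

    variant_id: str
    gene: str
    consequence: str
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "T"
    clinvar_class: str = "absent"
    mes_ref: float | None = None
    mes_alt: float | None = None
    distance_to_boundary: float | None = None
    boundary_side: str | None = None
    maf: float = 0.0
    sift: float | None = None
    polyphen: str | None = None
    provean: float | None = None
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCE_VOCAB:
            raise ClassificationError(
                f"{self.variant_id}: unknown consequence {self.consequence!r}"
            )
        if self.clinvar_class not in CLINVAR_VOCAB:
            raise ClassificationError(
                f"{self.variant_id}: unknown ClinVar class {self.clinvar_class!r}"
            )
        if not (0.0 <= self.maf <= 0.5):
            raise ClassificationError(f"{self.variant_id}: MAF outside [0, 0.5]")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def _present(x) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))


def splice_candidate(variant: VariantAnnotation) -> bool:
    """Is the variant inside the splice-evaluation window?

    Exonic SNVs within 3 bp of the boundary qualify, as do intronic variants
    within 20 bp on the acceptor side or 6 bp on the donor side (matching the
    MaxEntScan 23-mer acceptor / 9-mer donor footprints).
    """
    if not _present(variant.distance_to_boundary) or not _present(variant.boundary_side):
        raise ClassificationError(f"{variant.variant_id}: missing boundary annotation")
    d = variant.distance_to_boundary
    if d >= 0:  # exonic
        return variant.is_snv and d <= EXONIC_WINDOW
    window = (
        ACCEPTOR_INTRONIC_WINDOW
        if variant.boundary_side == "acceptor"
        else DONOR_INTRONIC_WINDOW
    )
    return -d <= window


def splice_disrupting(mes_ref: float, mes_alt: float) -> bool:
    """MaxEntScan decision rule: ref score >= 3 and a relative drop > 40%."""
    if mes_ref <= 0:
        warnings.warn(
            "splice_disrupting: non-positive reference score, relative decrease "
            "undefined; returning False",
            stacklevel=2,
        )
        return False
    return mes_ref >= MES_MIN_REF and (mes_ref - mes_alt) / mes_ref > MES_MIN_RELATIVE_DROP


def classify_deleterious(variant: VariantAnnotation) -> tuple[str, str | None]:
    """Classify one variant; returns ``(label, triggering_clause)``.

    ``label`` is ``"deleterious"`` or ``"not_deleterious"``; the clause is
    ``"truncation"``, ``"clinvar"`` or ``"splice"`` (first satisfied, though
    the three clauses form an order-independent disjunction), else None.
    """
    if variant.consequence in TRUNCATING_CONSEQUENCES:
        return "deleterious", "truncation"
    if variant.clinvar_class in CLINVAR_PATHOGENIC:
        return "deleterious", "clinvar"
    if (
        _present(variant.distance_to_boundary)
        and _present(variant.boundary_side)
        and _present(variant.mes_ref)
        and _present(variant.mes_alt)
        and splice_candidate(variant)
        and splice_disrupting(variant.mes_ref, variant.mes_alt)
    ):
        return "deleterious", "splice"
    return "not_deleterious", None


def missense_damaging(
    sift: float | None, polyphen: str | None, provean: float | None
) -> bool | None:
    """Two-of-three in-silico consensus for missense variants.

    Votes: SIFT < 0.05, PolyPhen-2 in {probably_damaging, damaging},
    PROVEAN <= -2.5.  Returns None (indeterminate) when fewer than two
    predictions are available; such variants are excluded from the damaging
    set rather than guessed.
    """
    votes = []
    if _present(sift):
        votes.append(sift < 0.05)
    if _present(polyphen) and polyphen != "":
        votes.append(polyphen in POLYPHEN_DAMAGING)
    if _present(provean):
        votes.append(provean <= -2.5)
    if len(votes) < 2:
        return None
    return sum(votes) >= 2


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the conditional probabilities (given allele counts) of all
    heterozygote counts whose probability does not exceed that of the
    observed count, using the standard recurrence over heterozygote
    configurations of matching parity.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DataError("hwe_exact_p: negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("hwe_exact_p: all-zero genotype counts")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # minor allele count
    if n_rare == 0:
        return 1.0

    # probabilities over het counts h with h ≡ n_rare (mod 2), 0 <= h <= n_rare
    h_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # recurrence: P(h+2)/P(h) = 4*n_hom_rare(h)*n_hom_common(h) / ((h+2)*(h+1))
    log_probs = np.zeros(len(h_values))
    for i in range(len(h_values) - 1):
        h = h_values[i]
        hom_rare = (n_rare - h) // 2
        hom_common = n - ((n_rare - h) // 2) - h  # = n_AA-equivalent at this h
        log_probs[i + 1] = log_probs[i] + math.log(
            4.0 * hom_rare * hom_common / ((h + 2.0) * (h + 1.0))
        )
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    obs = np.searchsorted(h_values, n_Aa)
    p_obs = probs[obs]
    # tolerance guards float ties in the "as or less probable" comparison
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# DataFrame-level stage functions
# ---------------------------------------------------------------------------

_ANNOT_FIELDS = [
    "variant_id", "gene", "consequence", "chrom", "pos", "ref", "alt",
    "clinvar_class", "mes_ref", "mes_alt", "distance_to_boundary",
    "boundary_side", "maf", "sift", "polyphen", "provean", "call_rate",
]


def annotation_from_row(row: pd.Series) -> VariantAnnotation:
    kwargs = {k: row[k] for k in _ANNOT_FIELDS if k in row.index}
    for key in ("mes_ref", "mes_alt", "distance_to_boundary", "sift", "provean"):
        if key in kwargs and pd.isna(kwargs[key]):
            kwargs[key] = None
    for key in ("boundary_side", "polyphen"):
        if key in kwargs and (pd.isna(kwargs[key]) or kwargs[key] == ""):
            kwargs[key] = None
    if "pos" in kwargs:
        kwargs["pos"] = int(kwargs["pos"])
    return VariantAnnotation(**kwargs)


def classify_variants(variants: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of an annotation table.

    Returns a table with ``variant_id, gene, consequence, maf, class, clause``
    plus a ``missense_damaging`` column (True/False/<NA> for indeterminate).
    """
    records = []
    for _, row in variants.iterrows():
        ann = annotation_from_row(row)
        label, clause = classify_deleterious(ann)
        dmg = (
            missense_damaging(ann.sift, ann.polyphen, ann.provean)
            if ann.consequence == "missense"
            else None
        )
        records.append(
            {
                "variant_id": ann.variant_id,
                "gene": ann.gene,
                "consequence": ann.consequence,
                "maf": ann.maf,
                "class": label,
                "clause": clause,
                "missense_damaging": dmg,
            }
        )
    out = pd.DataFrame.from_records(
        records,
        columns=[
            "variant_id", "gene", "consequence", "maf", "class", "clause",
            "missense_damaging",
        ],
    )
    out["missense_damaging"] = out["missense_damaging"].astype("boolean")
    return out


def missense_filters(
    variants: pd.DataFrame,
    genotypes: pd.DataFrame,
    manifest: pd.DataFrame,
    maf_max: float = 0.01,
    call_rate_min: float = 0.80,
    hwe_p_min: float = 1e-5,
) -> tuple[list[str], list[str], dict]:
    """Build the rare-missense analysis set.

    ``genotypes`` is a sample x variant matrix (0/1/2, NaN = missing) whose
    index is sample_id.  Removes deleterious-classified missense variants,
    keeps MAF < ``maf_max``, drops subjects with call rate < ``call_rate_min``
    over the missense variants, then drops variants with call rate <
    ``call_rate_min`` or exact HWE p < ``hwe_p_min`` (computed on controls).

    Returns (retained variant ids, retained sample ids, filter report).
    """
    classified = classify_variants(variants) if "class" not in variants.columns else variants
    mis = classified[
        (classified["consequence"] == "missense")
        & (classified["class"] == "not_deleterious")
    ]
    report: dict = {"n_missense_in": int(len(mis))}

    keep_vars = [v for v in mis["variant_id"] if v in genotypes.columns]
    gt = genotypes[keep_vars]

    sample_cr = 1.0 - gt.isna().mean(axis=1) if len(keep_vars) else pd.Series(1.0, index=gt.index)
    keep_samples = sample_cr[sample_cr >= call_rate_min].index.tolist()
    report["n_samples_dropped_call_rate"] = int(len(gt.index) - len(keep_samples))
    gt = gt.loc[keep_samples]

    controls = manifest.loc[manifest["status"] == "control", "sample_id"]
    controls = [s for s in controls if s in gt.index]

    retained = []
    n_cr = n_maf = n_hwe = 0
    for v in keep_vars:
        col = gt[v]
        if 1.0 - col.isna().mean() < call_rate_min:
            n_cr += 1
            continue
        obs = col.dropna()
        maf = obs.mean() / 2.0 if len(obs) else 0.0
        maf = min(maf, 1.0 - maf)
        if maf >= maf_max:
            n_maf += 1
            continue
        ctrl = col.loc[[s for s in controls if s in col.index]].dropna()
        if len(ctrl):
            counts = ctrl.value_counts()
            n_aa, n_het, n_hom = (
                int(counts.get(0.0, 0)), int(counts.get(1.0, 0)), int(counts.get(2.0, 0)),
            )
            if n_aa + n_het + n_hom > 0 and hwe_exact_p(n_aa, n_het, n_hom) < hwe_p_min:
                n_hwe += 1
                continue
        retained.append(v)
    report.update(
        n_variants_dropped_call_rate=n_cr,
        n_variants_dropped_maf=n_maf,
        n_variants_dropped_hwe=n_hwe,
        n_retained=len(retained),
    )
    return retained, keep_samples, report
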