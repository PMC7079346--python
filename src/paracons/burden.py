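"""Gene-family de novo burden testing.

Observed de novo mutations are filtered against a reference panel, assigned
to paralog-conserved or non-conserved site classes, aggregated over family
members, and compared to expectation with a one-sided (upper tail) Poisson
test under a Bonferroni correction across categories x families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .conservation import ParalogScoreTrack
from .expectation import FamilyExpectation, GeneExpectation

logger = logging.getLogger(__name__)

PTV_CLASSES = ("nonsense", "frameshift", "splice")

DEFAULT_CATEGORIES = (
    "ptv",
    "missense",
    "missense_conserved",
    "missense_nonconserved",
    "missense_plus_ptv_conserved",
)

#: smallest positive double; stands in for p-values that underflow,
#: see ``log10_p`` on BurdenResult for the exact magnitude.
TINY = 5e-324


@dataclass(frozen=True)
class DnmRecord:
    """One de novo variant call in a proband."""

    proband_id: str
    cohort: str
    gene_id: str
    consequence: str  # synonymous|missense|nonsense|frameshift|splice
    protein_position: Optional[int] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None

    def genomic_key(self) -> Optional[tuple]:
        if self.chrom is None or self.pos is None or not self.ref or not self.alt:
            return None
        return (self.chrom, self.pos, self.ref, self.alt)

    def protein_key(self) -> Optional[tuple]:
        if self.protein_position is None:
            return None
        return (self.gene_id, self.aa_ref, self.protein_position, self.aa_alt)


@dataclass
class MultiplicityConfig:
    alpha: float = 0.05
    n_categories: int = 5
    n_families: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_categories < 1 or self.n_families < 1:
            raise ValueError("counts must be positive")

    @property
    def threshold(self) -> float:
        return self.alpha / (self.n_categories * self.n_families)


@dataclass
class BurdenResult:
    subfamily_id: str
    category: str
    observed: int
    expected: float
    p_value: float
    log10_p: float
    significant: bool
    per_gene: dict[str, int] = field(default_factory=dict)
    per_cohort: dict[str, int] = field(default_factory=dict)

    @property
    def fold_enrichment(self) -> float:
        return self.observed / self.expected if self.expected > 0 else math.inf


@dataclass(frozen=True)
class GeneAnnotationRow:
    gene_id: str
    brain_rpkm: Optional[float] = None
    pli: Optional[float] = None
    missense_constraint_z: Optional[float] = None

    def __post_init__(self) -> None:
        if self.brain_rpkm is not None and self.brain_rpkm < 0:
            raise ValueError(f"{self.gene_id}: negative RPKM")
        if self.pli is not None and not 0 <= self.pli <= 1:
            raise ValueError(f"{self.gene_id}: pLI outside [0, 1]")


# ---------------------------------------------------------------------------
# filtering and site classification
# ---------------------------------------------------------------------------

def filter_reference_panel(
    dnms: Sequence[DnmRecord], panel: Iterable[tuple]
) -> list[DnmRecord]:
    """Drop variants present in the reference panel of standing variation.

    Records carrying a genomic key match on (chrom, pos, ref, alt); records
    without one match on (gene, aa_ref, protein_position, aa_alt).  Panel
    keys are assumed normalized (see :mod:`paracons.annotation`).
    """
    panel_set = {tuple(k) for k in panel}
    kept: list[DnmRecord] = []
    removed_per_gene: dict[str, int] = {}
    for rec in dnms:
        key = rec.genomic_key() or rec.protein_key()
        if key is not None and key in panel_set:
            removed_per_gene[rec.gene_id] = removed_per_gene.get(rec.gene_id, 0) + 1
            continue
        kept.append(rec)
    for gene, n in sorted(removed_per_gene.items()):
        logger.info("panel filter removed %d variant(s) in %s", n, gene)
    return kept


def assign_site_class(dnm: DnmRecord, track: ParalogScoreTrack) -> str:
    """'conserved' or 'nonconserved' from the track at the mutated residue.

    The aa_ref guard catches isoform drift between the variant table and the
    sequence set the track was computed on.
    """
    if dnm.protein_position is None:
        raise ValueError(f"{dnm.gene_id}: missense record without protein position")
    pos = dnm.protein_position
    if not 1 <= pos <= len(track):
        raise IndexError(
            f"{dnm.gene_id}: position {pos} outside track of length {len(track)}"
        )
    if dnm.aa_ref and track.residues[pos - 1] not in ("X", dnm.aa_ref):
        raise ValueError(
            f"{dnm.gene_id} p.{pos}: variant reference {dnm.aa_ref} != "
            f"track residue {track.residues[pos - 1]}"
        )
    return "conserved" if track.conserved_at(pos) else "nonconserved"


# ---------------------------------------------------------------------------
# Poisson upper tail in log space
# ---------------------------------------------------------------------------

def log10_poisson_upper_tail(observed: int, expected: float) -> float:
    """log10 of P(X >= observed | X ~ Poisson(expected)).

    Computed by log-sum-exp over the tail terms so that p-values far below
    the double-precision floor (1e-400 and beyond) stay finite on the log
    scale.
    """
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if observed < 0 or observed != int(observed):
        raise ValueError("observed must be a non-negative integer")
    k = int(observed)
    if k == 0:
        return 0.0
    # tail terms decay geometrically once j >> lambda; this many suffice
    n_terms = max(200, 5 * k, int(3 * expected))
    j = np.arange(k, k + n_terms, dtype=float)
    log_terms = -expected + j * math.log(expected) - gammaln(j + 1.0)
    log_p = float(logsumexp(log_terms))
    return min(log_p, 0.0) / math.log(10.0)


def poisson_upper_tail(observed: int, expected: float) -> float:
    """P(X >= observed) as a float in (0, 1].

    Underflowing tails are clamped to the smallest positive double so the
    return value is always finite and nonzero; use
    :func:`log10_poisson_upper_tail` when the magnitude matters.
    """
    p = 10.0 ** log10_poisson_upper_tail(observed, expected)
    return p if p > 0.0 else TINY


# ---------------------------------------------------------------------------
# burden test
# ---------------------------------------------------------------------------

def _category_observed(
    category: str,
    dnms: Sequence[DnmRecord],
    tracks: Mapping[str, ParalogScoreTrack],
) -> list[DnmRecord]:
    out = []
    for rec in dnms:
        if category == "ptv":
            ok = rec.consequence in PTV_CLASSES
        elif category == "missense":
            ok = rec.consequence == "missense"
        elif category == "missense_conserved":
            ok = (
                rec.consequence == "missense"
                and assign_site_class(rec, tracks[rec.gene_id]) == "conserved"
            )
        elif category == "missense_nonconserved":
            ok = (
                rec.consequence == "missense"
                and assign_site_class(rec, tracks[rec.gene_id]) == "nonconserved"
            )
        elif category == "missense_plus_ptv_conserved":
            ok = rec.consequence in PTV_CLASSES or (
                rec.consequence == "missense"
                and assign_site_class(rec, tracks[rec.gene_id]) == "conserved"
            )
        else:
            raise ValueError(f"unknown category {category!r}")
        if ok:
            out.append(rec)
    return out


def _category_expected(category: str, exp: GeneExpectation) -> float:
    if category == "ptv":
        return exp.ptv
    if category == "missense":
        return exp.missense
    if category == "missense_conserved":
        return exp.missense_conserved
    if category == "missense_nonconserved":
        return exp.missense_nonconserved
    if category == "missense_plus_ptv_conserved":
        return exp.missense_conserved + exp.ptv
    raise ValueError(f"unknown category {category!r}")


def family_burden_test(
    expectation: FamilyExpectation,
    dnms: Sequence[DnmRecord],
    tracks: Mapping[str, ParalogScoreTrack],
    config: MultiplicityConfig,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
) -> list[BurdenResult]:
    """Observed-vs-expected Poisson tests for one sub-family.

    ``dnms`` should already be panel-filtered.  Records in genes outside the
    family expectation are skipped with a warning.  Results are sorted by
    p-value.
    """
    member_genes = set(expectation.gene_ids)
    in_family = []
    for rec in dnms:
        if rec.gene_id in member_genes:
            in_family.append(rec)
        else:
            logger.warning(
                "%s: record in %s not covered by family expectations; skipped",
                expectation.subfamily_id, rec.gene_id,
            )

    results = []
    for category in categories:
        hits = _category_observed(category, in_family, tracks)
        expected = _category_expected(category, expectation.total)
        observed = len(hits)
        if expected > 0:
            log10p = log10_poisson_upper_tail(observed, expected)
            p = 10.0 ** log10p
            if p == 0.0:
                p = TINY
        else:
            log10p, p = 0.0, 1.0
        per_gene: dict[str, int] = {}
        per_cohort: dict[str, int] = {}
        for rec in hits:
            per_gene[rec.gene_id] = per_gene.get(rec.gene_id, 0) + 1
            per_cohort[rec.cohort] = per_cohort.get(rec.cohort, 0) + 1
        results.append(
            BurdenResult(
                subfamily_id=expectation.subfamily_id,
                category=category,
                observed=observed,
                expected=expected,
                p_value=p,
                log10_p=log10p,
                significant=p < config.threshold,
                per_gene=per_gene,
                per_cohort=per_cohort,
            )
        )
    results.sort(key=lambda r: (r.log10_p, r.category))
    return results


# ---------------------------------------------------------------------------
# class-wise z-score comparison (rank-sum)
# ---------------------------------------------------------------------------

def class_zscore_comparison(
    za: Sequence[float], zb: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum between two variant classes.

    Exact enumeration when both samples have n <= 8 and no ties; otherwise
    the normal approximation with tie correction (no continuity correction).
    Returns (U statistic for the first sample, p).
    """
    a = np.asarray(za, dtype=float)
    b = np.asarray(zb, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all values identical: statistic sits at the null center
        return a.size * b.size / 2.0, 1.0
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    p = float(res.pvalue)
    return float(res.statistic), min(p, 1.0)


# ---------------------------------------------------------------------------
# candidate gene flagging
# ---------------------------------------------------------------------------

@dataclass
class CandidateCall:
    gene_id: str
    candidate: bool
    evaluable: bool
    reasons: list[str]


def flag_candidate_genes(
    annotation: GeneAnnotationRow,
    in_enriched_family: bool,
    has_dnm: bool,
    rpkm_cutoff: float = 1.0,
    pli_cutoff: float = 0.9,
    mis_z_cutoff: float = 3.09,
) -> CandidateCall:
    """Plausible novel disease gene: in an enriched family, mutated,
    brain-expressed (RPKM strictly > 1) and constrained (pLI >= 0.9 or
    missense z > 3.09)."""
    reasons: list[str] = []
    if annotation.brain_rpkm is None or (
        annotation.pli is None and annotation.missense_constraint_z is None
    ):
        return CandidateCall(annotation.gene_id, False, False, ["missing_annotation"])

    if not in_enriched_family:
        reasons.append("not_in_enriched_family")
    if not has_dnm:
        reasons.append("no_dnm")
    brain = annotation.brain_rpkm > rpkm_cutoff
    if not brain:
        reasons.append("not_brain_expressed")
    pli_ok = annotation.pli is not None and annotation.pli >= pli_cutoff
    z_ok = (
        annotation.missense_constraint_z is not None
        and annotation.missense_constraint_z > mis_z_cutoff
    )
    if not (pli_ok or z_ok):
        reasons.append("not_constrained")
    else:
        reasons.append("pli" if pli_ok else "missense_z")
    candidate = in_enriched_family and has_dnm and brain and (pli_ok or z_ok)
    return CandidateCall(annotation.gene_id, candidate, True, reasons)
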