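"""Per-gene expected de novo mutation counts from coding-sequence context.

Every possible single-nucleotide substitution in a CDS is classified by its
codon consequence and weighted by a trinucleotide-context mutation rate.
Class totals are scaled by twice the number of trios (two parental
haplotypes each).  The missense expectation is additionally partitioned into
paralog-conserved and non-conserved portions, either proportionally to the
site-class sizes or by per-site summation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .conservation import ParalogScoreTrack
from .family_graph import GeneRecord

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP = "*"

CONSEQUENCE_CLASSES = ("synonymous", "missense", "nonsense", "stoploss")

#: indel context is invisible to a CDS-only model; the cited framework's
#: convention scales the nonsense expectation instead.
DEFAULT_FRAMESHIFT_MULTIPLIER = 1.25

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = STOP


def translate_codon(codon: str) -> str:
    try:
        return _CODON_TO_AA[codon.upper()]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None


class MutationRateTable:
    """Map (trinucleotide context, alternate center base) -> per-site rate.

    A complete table has 64 contexts x 3 alternates.  Incomplete tables are
    rejected unless ``default_rate`` is given, in which case missing entries
    fall back to it.  The fallback is also used for terminal CDS positions
    that lack flanking context.
    """

    def __init__(
        self,
        rates: Mapping[tuple[str, str], float],
        default_rate: Optional[float] = None,
    ):
        clean: dict[tuple[str, str], float] = {}
        for (context, alt), rate in rates.items():
            context, alt = context.upper(), alt.upper()
            if len(context) != 3 or any(b not in BASES for b in context):
                raise ValueError(f"invalid context {context!r}")
            if alt not in BASES or alt == context[1]:
                raise ValueError(f"invalid alternate {alt!r} for context {context!r}")
            if rate < 0:
                raise ValueError(f"negative rate for ({context}, {alt})")
            clean[(context, alt)] = float(rate)
        if len(clean) < 64 * 3 and default_rate is None:
            raise ValueError(
                f"incomplete rate table ({len(clean)}/192 entries) "
                "and no default rate configured"
            )
        if default_rate is not None and default_rate < 0:
            raise ValueError("default rate must be >= 0")
        self._rates = clean
        self.default_rate = default_rate
        self._fallback = (
            default_rate
            if default_rate is not None
            else float(np.mean(list(clean.values())))
        )

    @classmethod
    def uniform(cls, rate: float) -> "MutationRateTable":
        rates = {}
        for context in ("".join(t) for t in itertools.product(BASES, repeat=3)):
            for alt in BASES:
                if alt != context[1]:
                    rates[(context, alt)] = rate
        return cls(rates)

    def rate(self, context: Optional[str], alt: str) -> float:
        """Rate for a context/alt pair; ``context=None`` means unavailable
        (terminal position without flank) and uses the fallback mean."""
        if context is None:
            return self._fallback
        key = (context.upper(), alt.upper())
        if key in self._rates:
            return self._rates[key]
        if self.default_rate is not None:
            return self.default_rate
        raise KeyError(f"no rate for {key}")

    def scaled(self, s: float) -> "MutationRateTable":
        return MutationRateTable(
            {k: v * s for k, v in self._rates.items()},
            None if self.default_rate is None else self.default_rate * s,
        )

    def items(self):
        return self._rates.items()


@dataclass(frozen=True)
class CohortSpec:
    name: str
    n_trios: int

    def __post_init__(self) -> None:
        if self.n_trios <= 0:
            raise ValueError("n_trios must be positive")


@dataclass
class GeneExpectation:
    """Expected de novo counts for one gene, by consequence class."""

    gene_id: str
    synonymous: float = 0.0
    missense: float = 0.0
    nonsense: float = 0.0
    frameshift: float = 0.0
    stoploss: float = 0.0
    missense_conserved: float = 0.0
    missense_nonconserved: float = 0.0
    n_conserved_sites: int = 0
    n_nonconserved_sites: int = 0

    @property
    def ptv(self) -> float:
        return self.nonsense + self.frameshift

    def validate(self) -> None:
        for cls in ("synonymous", "missense", "nonsense", "frameshift", "stoploss"):
            if getattr(self, cls) < 0:
                raise ValueError(f"{self.gene_id}: negative {cls} expectation")
        if abs(self.missense_conserved + self.missense_nonconserved - self.missense) > 1e-9:
            raise ValueError(f"{self.gene_id}: missense split does not sum")


def classify_substitution(cds: str, position: int, alt: str) -> str:
    """Consequence of substituting ``alt`` at 1-based CDS ``position``.

    Returns one of synonymous/missense/nonsense/stoploss.  Changes inside a
    reference stop codon that leave a stop are synonymous; those that remove
    it are stoploss.
    """
    cds = cds.upper()
    alt = alt.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    if not 1 <= position <= len(cds):
        raise ValueError(f"position {position} out of range 1..{len(cds)}")
    if alt not in BASES:
        raise ValueError(f"invalid base {alt!r}")
    ref = cds[position - 1]
    if ref not in BASES:
        raise ValueError(f"reference base {ref!r} at position {position} not ACGT")
    if alt == ref:
        raise ValueError(f"alt equals reference base {ref!r} at position {position}")

    codon_start = (position - 1) // 3 * 3
    codon = cds[codon_start : codon_start + 3]
    offset = position - 1 - codon_start
    new_codon = codon[:offset] + alt + codon[offset + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(new_codon)

    if aa_ref == STOP:
        return "synonymous" if aa_alt == STOP else "stoploss"
    if aa_alt == STOP:
        return "nonsense"
    return "synonymous" if aa_alt == aa_ref else "missense"


def _context(cds: str, position: int, flank5: Optional[str], flank3: Optional[str]) -> Optional[str]:
    i = position - 1
    left = cds[i - 1] if i >= 1 else flank5
    right = cds[i + 1] if i <= len(cds) - 2 else flank3
    if left is None or right is None:
        return None
    return left + cds[i] + right


def gene_expectation(
    gene: GeneRecord,
    rates: MutationRateTable,
    cohort: CohortSpec,
    track: Optional[ParalogScoreTrack] = None,
    flank5: Optional[str] = None,
    flank3: Optional[str] = None,
    split_mode: str = "proportional",
    frameshift_multiplier: float = DEFAULT_FRAMESHIFT_MULTIPLIER,
) -> GeneExpectation:
    """Expected de novo counts for one gene: lambda = 2 x n_trios x sum(rates).

    The reference stop codon contributes only to the stoploss bucket.  The
    missense expectation is split by paralog-conservation site class when a
    track is supplied: ``proportional`` scales by site-class size,
    ``per_site`` sums missense rate mass over conserved codons only.
    """
    if gene.cds_seq is None:
        raise ValueError(f"{gene.gene_id}: expectation model needs a CDS")
    if split_mode not in ("proportional", "per_site"):
        raise ValueError(f"unknown split mode {split_mode!r}")
    cds = gene.cds_seq.upper()
    n_res = len(gene.protein_seq)
    if track is not None and len(track) != n_res:
        raise ValueError(
            f"{gene.gene_id}: track length {len(track)} != protein length {n_res}"
        )

    sums = {cls: 0.0 for cls in CONSEQUENCE_CLASSES}
    missense_by_residue = np.zeros(n_res)
    n_fallback = 0
    for pos in range(1, len(cds) + 1):
        ref = cds[pos - 1]
        context = _context(cds, pos, flank5, flank3)
        if context is None:
            n_fallback += 1
        for alt in BASES:
            if alt == ref:
                continue
            cls = classify_substitution(cds, pos, alt)
            r = rates.rate(context, alt)
            sums[cls] += r
            if cls == "missense":
                residue_idx = (pos - 1) // 3  # 0-based; never the stop codon
                missense_by_residue[residue_idx] += r
    if n_fallback:
        logger.info(
            "%s: %d terminal position(s) used the fallback context rate",
            gene.gene_id, n_fallback,
        )

    scale = 2.0 * cohort.n_trios
    exp = GeneExpectation(
        gene_id=gene.gene_id,
        synonymous=scale * sums["synonymous"],
        missense=scale * sums["missense"],
        nonsense=scale * sums["nonsense"],
        stoploss=scale * sums["stoploss"],
    )
    exp.frameshift = frameshift_multiplier * exp.nonsense

    if track is not None:
        conserved = np.asarray(track.conserved, dtype=bool)
        n_cons = int(conserved.sum())
        exp.n_conserved_sites = n_cons
        exp.n_nonconserved_sites = n_res - n_cons
        if split_mode == "proportional":
            frac = n_cons / n_res
            exp.missense_conserved = exp.missense * frac
        else:
            exp.missense_conserved = scale * float(missense_by_residue[conserved].sum())
        exp.missense_nonconserved = exp.missense - exp.missense_conserved
    else:
        exp.n_nonconserved_sites = n_res
        exp.missense_nonconserved = exp.missense
    exp.validate()
    return exp


@dataclass
class FamilyExpectation:
    """Component-wise sum of member expectations, keeping the breakdown."""

    subfamily_id: str
    members: list[GeneExpectation]
    total: GeneExpectation = field(init=False)

    def __post_init__(self) -> None:
        self.total = family_expectation(self.members, label=self.subfamily_id)

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]


def family_expectation(
    members: Iterable[GeneExpectation], label: str = "family"
) -> GeneExpectation:
    members = list(members)
    if not members:
        raise ValueError("need >= 1 member expectation")
    ids = [m.gene_id for m in members]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene expectation(s): {dupes}")
    total = GeneExpectation(gene_id=label)
    for m in members:
        total.synonymous += m.synonymous
        total.missense += m.missense
        total.nonsense += m.nonsense
        total.frameshift += m.frameshift
        total.stoploss += m.stoploss
        total.missense_conserved += m.missense_conserved
        total.missense_nonconserved += m.missense_nonconserved
        total.n_conserved_sites += m.n_conserved_sites
        total.n_nonconserved_sites += m.n_nonconserved_sites
    return total
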