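"""Synthetic gene families and de novo variant sets.

Families are generated by mutating a random ancestor protein block-wise, so
low-divergence blocks become paralog-conserved cores and high-divergence
blocks become variable linkers; a matching CDS is drawn by random synonymous
codon choice.  De novo variants are drawn per gene and consequence class
from Poisson counts, with an optional enrichment multiplier at conserved
sites.  All randomness flows through one explicitly passed seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .burden import DnmRecord
from .conservation import Msa, ParalogScoreTrack
from .expectation import GeneExpectation
from .family_graph import GeneFamily, GeneRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_BY_AA:
    _CODONS_BY_AA[_aa].sort()
_STOP_CODONS = sorted(standard_dna_table.stop_codons)


@dataclass
class FamilySimConfig:
    """Block-structured paralog family simulation settings.

    ``blocks`` is a list of (length, divergence) pairs; divergence is the
    per-site probability that a descendant differs from the ancestor in that
    block.  When ``blocks`` is empty, a single block of ``protein_length``
    at ``divergence`` is used.
    """

    n_genes: int = 4
    protein_length: int = 100
    divergence: float = 0.2
    blocks: list[tuple[int, float]] = field(default_factory=list)
    family_id: str = "simfam"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        effective = self.blocks or [(self.protein_length, self.divergence)]
        for length, div in effective:
            if length < 1:
                raise ValueError("block lengths must be >= 1")
            if not 0.0 <= div <= 1.0:
                raise ValueError(f"divergence {div} outside [0, 1]")

    @property
    def effective_blocks(self) -> list[tuple[int, float]]:
        return list(self.blocks) or [(self.protein_length, self.divergence)]


@dataclass
class SimulatedFamily:
    family: GeneFamily
    ancestor: str
    block_labels: np.ndarray  # per-residue block index
    block_divergence: np.ndarray  # per-residue divergence used


@dataclass
class DnmSimConfig:
    """De novo variant simulation settings.

    ``rho`` multiplies the conserved-site missense mean; ``rho = 1`` is the
    null.  Class means come from the supplied expectations.
    """

    cohort: str = "SIM"
    rho: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _mutate(rng: np.random.Generator, residue: str) -> str:
    choices = [a for a in AA_ALPHABET if a != residue]
    return choices[rng.integers(len(choices))]


def _random_cds(rng: np.random.Generator, protein: str) -> str:
    codons = [
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein
    ]
    codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
    return "".join(codons)


def simulate_family(
    config: FamilySimConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedFamily:
    """Simulate one gene family with known conserved-block structure.

    All descendants have the ancestor's length (no indels), so stacking the
    sequences is already a valid alignment (see :func:`trivial_msa`).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    blocks = config.effective_blocks
    length = sum(b[0] for b in blocks)
    ancestor = _random_protein(rng, length)
    labels = np.concatenate(
        [np.full(b[0], i, dtype=int) for i, b in enumerate(blocks)]
    )
    divergence = np.concatenate([np.full(b[0], b[1]) for b in blocks])

    members = []
    for g in range(config.n_genes):
        hits = rng.random(length) < divergence
        protein = "".join(
            _mutate(rng, a) if hit else a for a, hit in zip(ancestor, hits)
        )
        members.append(
            GeneRecord(
                gene_id=f"{config.family_id}_G{g + 1}",
                protein_seq=protein,
                cds_seq=_random_cds(rng, protein),
            )
        )
    family = GeneFamily(config.family_id, members)
    return SimulatedFamily(family, ancestor, labels, divergence)


def trivial_msa(family: GeneFamily) -> Msa:
    """Stack equal-length member proteins as an alignment (no gaps)."""
    lengths = {len(m.protein_seq) for m in family.members}
    if len(lengths) != 1:
        raise ValueError("members differ in length; needs a real aligner")
    return Msa([(m.gene_id, m.protein_seq) for m in family.members])


def simulate_dnms(
    expectations: Sequence[GeneExpectation],
    config: DnmSimConfig,
    tracks: Optional[dict[str, ParalogScoreTrack]] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[DnmRecord]:
    """Draw de novo variants matching the expectation model.

    Per gene: synonymous/nonsense counts ~ Poisson(lambda); missense counts
    ~ Poisson(rho x lambda_cons) at conserved sites plus
    Poisson(lambda_noncons) at non-conserved sites, positions uniform within
    the site class.  Genes without a track draw all missense uniformly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[DnmRecord] = []
    proband = 0

    def _emit(gene_id: str, consequence: str, position: Optional[int], track):
        nonlocal proband
        proband += 1
        aa_ref = None
        if position is not None and track is not None:
            aa_ref = track.residues[position - 1]
        aa_alt = None
        if consequence == "missense" and aa_ref is not None:
            aa_alt = _mutate(rng, aa_ref)
        records.append(
            DnmRecord(
                proband_id=f"P{proband:06d}",
                cohort=config.cohort,
                gene_id=gene_id,
                consequence=consequence,
                protein_position=position,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
            )
        )

    for exp in expectations:
        track = (tracks or {}).get(exp.gene_id)
        for consequence, lam in (
            ("synonymous", exp.synonymous),
            ("nonsense", exp.nonsense),
            ("frameshift", exp.frameshift),
        ):
            for _ in range(rng.poisson(lam)):
                position = None
                if track is not None and consequence != "frameshift":
                    position = int(rng.integers(1, len(track) + 1))
                _emit(exp.gene_id, consequence, position, track)

        if track is not None and (exp.n_conserved_sites + exp.n_nonconserved_sites):
            cons_positions = np.flatnonzero(track.conserved) + 1
            noncons_positions = np.flatnonzero(~track.conserved) + 1
            n_cons = rng.poisson(config.rho * exp.missense_conserved)
            n_noncons = rng.poisson(exp.missense_nonconserved)
            for pool, n in ((cons_positions, n_cons), (noncons_positions, n_noncons)):
                if n > 0 and pool.size == 0:
                    raise ValueError(
                        f"{exp.gene_id}: positive mean but empty site class"
                    )
                for _ in range(n):
                    _emit(
                        exp.gene_id,
                        "missense",
                        int(pool[rng.integers(pool.size)]),
                        track,
                    )
        else:
            for _ in range(rng.poisson(config.rho * exp.missense_conserved
                                       + exp.missense_nonconserved)):
                _emit(exp.gene_id, "missense", None, None)
    return records
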