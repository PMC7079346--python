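"""Gene-family assembly and sub-family clustering.

Families are connected components of a paralog-pair graph.  Each family is
then split into sub-families: genes are connected when their pairwise global
alignment covers more than ``aligned_fraction_cutoff`` of the longer
sequence, and sub-families are the connected components of that similarity
graph.  Only clusters with at least two members survive at either level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: Canonical amino acids plus X (unknown residue).
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

GAP = "-"


@dataclass(frozen=True)
class GeneRecord:
    """One gene: symbol, protein sequence, optional coding sequence.

    If ``cds_seq`` is present it must translate (standard code, stop
    stripped) to ``protein_seq``.
    """

    gene_id: str
    protein_seq: str
    cds_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.protein_seq) < 1:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        bad = set(self.protein_seq) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.gene_id}: invalid residues {sorted(bad)} in protein sequence"
            )
        if self.cds_seq is not None:
            if len(self.cds_seq) % 3 != 0:
                raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
            prot = str(Seq(self.cds_seq).translate())
            if prot.endswith("*"):
                prot = prot[:-1]
            if prot != self.protein_seq:
                raise ValueError(
                    f"{self.gene_id}: CDS does not translate to protein sequence"
                )


@dataclass
class GeneFamily:
    family_id: str
    members: list[GeneRecord]

    def __post_init__(self) -> None:
        ids = [m.gene_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError(f"family {self.family_id}: duplicate gene ids")
        if len(self.members) < 2:
            raise ValueError(f"family {self.family_id}: needs >= 2 members")
        self.members = sorted(self.members, key=lambda m: m.gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]


@dataclass
class ClusteringParams:
    """Thresholds and aligner settings for sub-family clustering.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    aligned_fraction_cutoff: float = 0.8
    substitution_matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.aligned_fraction_cutoff <= 1.0):
            raise ValueError("aligned_fraction_cutoff must be in (0, 1]")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are non-negative magnitudes")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix_name)


@dataclass
class SubFamily:
    """A connected cluster (>= 2 proteins) of paralogs; the unit of
    conservation scoring and burden testing."""

    subfamily_id: str
    members: list[GeneRecord]
    alignment: Optional[object] = None  # paracons.conservation.Msa once aligned

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"subfamily {self.subfamily_id}: needs >= 2 members")
        self.members = sorted(self.members, key=lambda m: m.gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]


# ---------------------------------------------------------------------------
# family assembly
# ---------------------------------------------------------------------------

def build_families(
    pair_table: Iterable[tuple],
    sequences: Mapping[str, GeneRecord],
) -> list[GeneFamily]:
    """Assemble gene families as connected components of the paralog-pair graph.

    ``pair_table`` rows are ``(gene_id_a, gene_id_b)`` or
    ``(gene_id_a, gene_id_b, family_id)``.  Genes missing from ``sequences``
    are dropped with a warning; components of size 1 are discarded.  The same
    pair annotated with two different family ids is an error.

    Returns families sorted by family_id, members sorted by gene_id.
    """
    pair_family: dict[frozenset, str] = {}
    graph = nx.Graph()
    for row in pair_table:
        a, b = row[0], row[1]
        annotated = row[2] if len(row) > 2 and row[2] else None
        key = frozenset((a, b))
        if annotated is not None:
            prev = pair_family.get(key)
            if prev is not None and prev != annotated:
                raise ValueError(
                    f"contradictory family ids for pair ({a}, {b}): "
                    f"{prev!r} vs {annotated!r}"
                )
            pair_family[key] = annotated
        dropped = [g for g in (a, b) if g not in sequences]
        if dropped:
            logger.warning("dropping pair (%s, %s): unresolved id(s) %s", a, b, dropped)
            for g in (a, b):
                if g in sequences:
                    graph.add_node(g)
            continue
        graph.add_edge(a, b)

    families = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        annotated_ids = sorted(
            {
                pair_family[key]
                for key in pair_family
                if key <= set(comp)
            }
        )
        if len(annotated_ids) == 1:
            fid = annotated_ids[0]
        else:
            if len(annotated_ids) > 1:
                logger.warning(
                    "component %s carries multiple family ids %s; synthesizing",
                    members[0], annotated_ids,
                )
            fid = f"fam-{members[0]}"
        families.append(GeneFamily(fid, [sequences[g] for g in members]))
    families.sort(key=lambda f: f.family_id)
    return families


# ---------------------------------------------------------------------------
# pairwise global alignment (Gotoh, affine gaps)
# ---------------------------------------------------------------------------

_NEG = -1e30


def _score_lookup(matrix, a: str, b: str) -> float:
    alphabet = matrix.alphabet
    ai = alphabet.index(a) if a in alphabet else alphabet.index("X")
    bi = alphabet.index(b) if b in alphabet else alphabet.index("X")
    return float(matrix[ai, bi])


def global_align(
    a: str, b: str, params: Optional[ClusteringParams] = None
) -> tuple[str, str, float]:
    """Needleman-Wunsch global alignment with affine gap penalties.

    Returns ``(gapped_a, gapped_b, score)``.  Ties during traceback prefer
    diagonal over up (gap in ``b``) over left (gap in ``a``), so output is
    deterministic.  Removing gaps recovers the inputs.
    """
    if params is None:
        params = ClusteringParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for seq, name in ((a, "a"), (b, "b")):
        bad = set(seq) - VALID_RESIDUES
        if bad:
            raise ValueError(f"sequence {name}: invalid characters {sorted(bad)}")

    matrix = params.matrix()
    alphabet = matrix.alphabet
    idx_a = np.array([alphabet.index(c) for c in a])
    idx_b = np.array([alphabet.index(c) for c in b])
    sub = np.asarray(matrix)  # (n_alpha, n_alpha)

    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend

    # M: a[i] aligned to b[j]; Ix: gap in b (consumes a, "up");
    # Iy: gap in a (consumes b, "left").  1-based DP over (n+1)x(m+1).
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Iy[0, j] = -(go + (j - 1) * ge)

    for i in range(1, n + 1):
        srow = sub[idx_a[i - 1], idx_b]  # score of a[i-1] vs each b[j-1]
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + srow
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) - go, Ix[i - 1, 1:] - ge
        )
        # Iy depends on the current row left neighbour: sequential scan.
        row_m, row_ix, row_iy = M[i], Ix[i], Iy[i]
        for j in range(1, m + 1):
            row_iy[j] = max(
                row_m[j - 1] - go, row_ix[j - 1] - go, row_iy[j - 1] - ge
            )

    score = max(M[n, m], Ix[n, m], Iy[n, m])

    # Traceback with diagonal > up > left preference.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    eps = 1e-9
    if M[n, m] >= score - eps:
        state = "M"
    elif Ix[n, m] >= score - eps:
        state = "Ix"
    else:
        state = "Iy"
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[idx_a[i - 1], idx_b[j - 1]]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if M[i, j] >= target - eps:
                state = "M"
            elif Ix[i, j] >= target - eps:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            out_a.append(a[i - 1])
            out_b.append(GAP)
            val = Ix[i, j]
            i -= 1
            if M[i, j] - go >= val - eps:
                state = "M"
            elif Iy[i, j] - go >= val - eps:
                state = "Iy"
            else:
                state = "Ix"
        else:  # Iy
            out_a.append(GAP)
            out_b.append(b[j - 1])
            val = Iy[i, j]
            j -= 1
            if M[i, j] - go >= val - eps:
                state = "M"
            elif Ix[i, j] - go >= val - eps:
                state = "Ix"
            else:
                state = "Iy"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def aligned_fraction(alignment: tuple[str, str] | tuple[str, str, float]) -> float:
    """Fraction of residue-residue columns over the longer unaligned length.

    Symmetric in row order; raises on a zero-length alignment.
    """
    row_a, row_b = alignment[0], alignment[1]
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    if len(row_a) == 0:
        raise ValueError("zero-length alignment")
    both = sum(1 for x, y in zip(row_a, row_b) if x != GAP and y != GAP)
    longer = max(
        len(row_a) - row_a.count(GAP),
        len(row_b) - row_b.count(GAP),
    )
    if longer == 0:
        raise ValueError("alignment contains no residues")
    return both / longer


# ---------------------------------------------------------------------------
# sub-family clustering
# ---------------------------------------------------------------------------

def cluster_subfamilies(
    family: GeneFamily, params: Optional[ClusteringParams] = None
) -> list[SubFamily]:
    """Split a family into sub-families by the >cutoff aligned-fraction graph.

    Edges require strictly more than ``params.aligned_fraction_cutoff`` of the
    longer sequence aligned; connected components of size 1 are discarded.
    Sub-family ids are ``<family_id>.<k>`` with k ordered by each cluster's
    lexicographically smallest member.
    """
    if params is None:
        params = ClusteringParams()
    members = family.members
    graph = nx.Graph()
    graph.add_nodes_from(m.gene_id for m in members)
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            aln = global_align(members[i].protein_seq, members[j].protein_seq, params)
            if aligned_fraction(aln) > params.aligned_fraction_cutoff:
                graph.add_edge(members[i].gene_id, members[j].gene_id)

    by_id = {m.gene_id: m for m in members}
    clusters = [sorted(c) for c in nx.connected_components(graph) if len(c) >= 2]
    clusters.sort(key=lambda c: c[0])
    return [
        SubFamily(f"{family.family_id}.{k + 1}", [by_id[g] for g in cluster])
        for k, cluster in enumerate(clusters)
    ]
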