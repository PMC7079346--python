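"""Physico-chemical column conservation and per-gene z-score tracks.

Each alignment column gets an integer score in [0, 11]: the number of
residue properties that are uniformly present in, or uniformly absent from,
every entry of the column, promoted to 11 for gap-free single-residue
identity.  Per gene, column scores are projected onto ungapped residue
positions and z-normalized (sample sd); residues with z > 0 are called
conserved.  The same operations serve paralog and ortholog alignments.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .family_graph import GAP, VALID_RESIDUES

IDENTITY_SCORE = 11


@dataclass
class Msa:
    """A multiple sequence alignment: ordered (gene_id, gapped seq) rows."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an Msa needs >= 2 rows")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError("Msa rows differ in length")
        ids = [gid for gid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in Msa")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def gene_ids(self) -> list[str]:
        return [gid for gid, _ in self.rows]

    def row(self, gene_id: str) -> str:
        for gid, seq in self.rows:
            if gid == gene_id:
                return seq
        raise KeyError(f"gene {gene_id!r} not in Msa")

    def column(self, j: int) -> list[str]:
        """Column j, 1-based."""
        return [seq[j - 1] for _, seq in self.rows]

    def ungapped(self, gene_id: str) -> str:
        return self.row(gene_id).replace(GAP, "")


class PropertyTable:
    """Ordered residue-property sets used for column scoring.

    The default is the Livingstone & Barton physico-chemical classification;
    it is loaded from a TSV data file and should be serialized alongside any
    results for provenance (see :meth:`to_tsv`).
    """

    def __init__(self, membership: dict[str, frozenset[str]]):
        self._membership = {k: frozenset(v) for k, v in membership.items()}
        self._by_residue: dict[str, frozenset[str]] = {}
        for res in VALID_RESIDUES:
            props = frozenset(
                p for p, residues in self._membership.items() if res in residues
            )
            self._by_residue[res] = props
        # gaps and X carry no properties
        self._by_residue[GAP] = frozenset()
        self._by_residue["X"] = frozenset()

    @property
    def properties(self) -> list[str]:
        return list(self._membership)

    def members(self, prop: str) -> frozenset[str]:
        return self._membership[prop]

    def properties_of(self, char: str) -> frozenset[str]:
        try:
            return self._by_residue[char]
        except KeyError:
            raise ValueError(f"unknown character {char!r}") from None

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        membership: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                prop, residues = line.split("\t")
                membership[prop] = frozenset(residues.split(","))
        return cls(membership)

    @classmethod
    def default(cls) -> "PropertyTable":
        ref = importlib.resources.files("paracons") / "data" / "amas_properties.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("property\tresidues\n")
            for prop, residues in self._membership.items():
                fh.write(f"{prop}\t{','.join(sorted(residues))}\n")


@dataclass
class ConservationProfile:
    subfamily_id: str
    column_scores: np.ndarray  # int, one per alignment column

    def __post_init__(self) -> None:
        self.column_scores = np.asarray(self.column_scores, dtype=int)
        if self.column_scores.size and (
            self.column_scores.min() < 0 or self.column_scores.max() > IDENTITY_SCORE
        ):
            raise ValueError("column scores out of [0, 11]")


@dataclass
class ParalogScoreTrack:
    """Per-residue conservation of one gene: raw scores, z-scores, flags."""

    gene_id: str
    residues: str
    residue_scores: np.ndarray
    mean: float = 0.0
    sd: float = 0.0
    para_zscore: np.ndarray = field(default_factory=lambda: np.array([]))
    conserved: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        self.residue_scores = np.asarray(self.residue_scores, dtype=float)
        if len(self.residues) != self.residue_scores.size:
            raise ValueError(f"{self.gene_id}: residues/scores length mismatch")

    def __len__(self) -> int:
        return self.residue_scores.size

    def score_at(self, position: int) -> float:
        """1-based residue position."""
        if not 1 <= position <= len(self):
            raise IndexError(f"{self.gene_id}: position {position} out of range")
        return float(self.residue_scores[position - 1])

    def zscore_at(self, position: int) -> float:
        if not 1 <= position <= len(self):
            raise IndexError(f"{self.gene_id}: position {position} out of range")
        return float(self.para_zscore[position - 1])

    def conserved_at(self, position: int) -> bool:
        if not 1 <= position <= len(self):
            raise IndexError(f"{self.gene_id}: position {position} out of range")
        return bool(self.conserved[position - 1])

    @property
    def n_conserved(self) -> int:
        return int(self.conserved.sum())


@dataclass
class ConservationComparison:
    gene_id: str
    rand_index: float
    adjusted_rand: float
    pearson_r: float
    pearson_defined: bool
    n_both: int
    n_paralog_only: int
    n_ortholog_only: int
    n_neither: int


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_column(column: Sequence[str], table: Optional[PropertyTable] = None) -> int:
    """AMAS-style score of one alignment column.

    A property counts as conserved when every entry has it or no entry has
    it.  Gaps and X carry no properties, so they break present-in-all
    properties but keep absent-in-all ones.  A gap-free column of one
    repeated residue (not X) is promoted from 10 to 11.
    """
    if table is None:
        table = _default_table()
    if len(column) < 2:
        raise ValueError("a column needs >= 2 entries")
    prop_sets = []
    for k, char in enumerate(column):
        if char not in VALID_RESIDUES and char != GAP:
            raise ValueError(f"unknown character {char!r} at column entry {k + 1}")
        prop_sets.append(table.properties_of(char))

    distinct = set(column)
    if len(distinct) == 1 and GAP not in distinct and distinct != {"X"}:
        return IDENTITY_SCORE

    present_in_all = frozenset.intersection(*prop_sets)
    present_in_any = frozenset.union(*prop_sets)
    absent_in_all = set(table.properties) - set(present_in_any)
    return len(present_in_all) + len(absent_in_all)


_TABLE_CACHE: Optional[PropertyTable] = None


def _default_table() -> PropertyTable:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = PropertyTable.default()
    return _TABLE_CACHE


def score_msa(
    msa: Msa, table: Optional[PropertyTable] = None, subfamily_id: str = ""
) -> ConservationProfile:
    """Score every column of an alignment; invariant under row order."""
    scores = [score_column(msa.column(j), table) for j in range(1, msa.length + 1)]
    return ConservationProfile(subfamily_id, np.array(scores, dtype=int))


def project_to_gene(
    profile: ConservationProfile, msa: Msa, gene_id: str
) -> ParalogScoreTrack:
    """Extract the column scores landing on one gene's residues.

    Residue j of the gene receives the score of the column holding its j-th
    non-gap character.  Returns a track with scores only (no z yet).
    """
    row = msa.row(gene_id)
    if profile.column_scores.size != len(row):
        raise ValueError("profile length does not match Msa length")
    mask = np.frombuffer(row.encode(), dtype=np.uint8) != ord(GAP)
    residues = row.replace(GAP, "")
    return ParalogScoreTrack(gene_id, residues, profile.column_scores[mask])


def zscore_track(track: ParalogScoreTrack) -> ParalogScoreTrack:
    """Fill in per-gene mean/sd, para_zscores and conserved flags.

    Uses the sample standard deviation (n-1).  When sd is 0 (constant track,
    or length-1 track) every z is 0 and nothing is conserved: conservation is
    strictly z > 0.
    """
    scores = track.residue_scores
    if scores.size == 0:
        raise ValueError(f"{track.gene_id}: empty track")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1)) if scores.size > 1 else 0.0
    if sd > 0:
        z = (scores - mean) / sd
    else:
        z = np.zeros_like(scores, dtype=float)
        sd = 0.0
    track.mean = mean
    track.sd = sd
    track.para_zscore = z
    track.conserved = z > 0
    return track


def score_subfamily(
    msa: Msa, table: Optional[PropertyTable] = None, subfamily_id: str = ""
) -> dict[str, ParalogScoreTrack]:
    """Full per-gene workflow for one alignment: score, project, z-normalize."""
    profile = score_msa(msa, table, subfamily_id)
    return {
        gid: zscore_track(project_to_gene(profile, msa, gid))
        for gid in msa.gene_ids
    }


# ---------------------------------------------------------------------------
# paralog vs ortholog comparison
# ---------------------------------------------------------------------------

def rand_index(a: Sequence[bool], b: Sequence[bool]) -> float:
    """Rand index of two binary labelings via the pair-counting closed form."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 positions")
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = int(np.sum(~a & ~b))

    def c2(x: int) -> int:
        return x * (x - 1) // 2

    agree = c2(n11) + c2(n10) + c2(n01) + c2(n00)
    # pairs split by exactly one labeling disagree
    same_a = c2(n11 + n10) + c2(n01 + n00)
    same_b = c2(n11 + n01) + c2(n10 + n00)
    disagree = (same_a - agree) + (same_b - agree)
    return (c2(n) - disagree) / c2(n)


def compare_conservation(
    paralog_flags: Sequence[bool],
    ortholog_flags: Sequence[bool],
    gene_id: str = "",
) -> ConservationComparison:
    """Rand index, adjusted Rand and Pearson r between two conserved/non
    labelings of the same residues, plus the 2x2 overlap counts."""
    p = np.asarray(paralog_flags, dtype=bool)
    o = np.asarray(ortholog_flags, dtype=bool)
    if p.size != o.size:
        raise ValueError("flag vectors differ in length")
    if p.size < 2:
        raise ValueError("need >= 2 positions")

    ri = rand_index(p, o)
    ari = float(adjusted_rand_score(p.astype(int), o.astype(int)))
    if p.var() == 0 or o.var() == 0:
        pearson, defined = float("nan"), False
    else:
        pearson = float(stats.pearsonr(p.astype(float), o.astype(float)).statistic)
        defined = True
    return ConservationComparison(
        gene_id=gene_id,
        rand_index=ri,
        adjusted_rand=ari,
        pearson_r=pearson,
        pearson_defined=defined,
        n_both=int(np.sum(p & o)),
        n_paralog_only=int(np.sum(p & ~o)),
        n_ortholog_only=int(np.sum(~p & o)),
        n_neither=int(np.sum(~p & ~o)),
    )
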