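"""Variant normalization and conservation-track annotation/export.

Variants are reduced to a single minimal, left-aligned representation
(vt-style) before any matching against the reference panel.  Missense
records then pick up the para_zscore and conserved flag of their residue;
per-protein track exports with variant overlays back the conservation
plots.

Coordinates are 1-based for both genomic positions and protein residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .burden import DnmRecord
from .conservation import ParalogScoreTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference_window: str,
    window_start: int = 1,
) -> NormalizedVariant:
    """Minimal left-aligned representation of a variant.

    ``reference_window`` is local reference sequence beginning at 1-based
    coordinate ``window_start``; it must cover the variant and enough
    upstream bases for left-shifting.  The procedure trims shared suffix,
    trims shared prefix (keeping one anchor base when either allele would
    become empty), and left-shifts indels while the trailing base of both
    alleles equals the preceding reference base.  Idempotent.
    """
    ref, alt = ref.upper(), alt.upper()
    window = reference_window.upper()
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    off = pos - window_start
    if off < 0 or off + len(ref) > len(window):
        raise ValueError("reference window does not cover the variant")
    if window[off : off + len(ref)] != ref:
        raise ValueError(
            f"ref {ref!r} at {chrom}:{pos} does not match reference window"
        )

    # iterate shift + trim until fixed point (vt algorithm)
    while True:
        # trim shared suffix, but keep at least one base in each allele
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        # left-extend and retry when both alleles end with the same base and
        # trimming is blocked because one allele is length 1 (pure indel)
        if ref[-1] == alt[-1] and (len(ref) == 1 or len(alt) == 1):
            if pos == window_start:
                raise ValueError(
                    f"window exhausted while left-aligning {chrom}:{pos}"
                )
            prev = window[pos - 1 - window_start]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
            continue
        break
    # trim shared prefix, keeping an anchor base when an allele would empty
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return NormalizedVariant(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedDnm:
    record: DnmRecord
    para_zscore: Optional[float] = None
    conserved: Optional[bool] = None
    flag: str = "ok"  # ok | no_track | no_position


def annotate_variants(
    dnms: Sequence[DnmRecord],
    tracks: Mapping[str, ParalogScoreTrack],
) -> list[AnnotatedDnm]:
    """Attach para_zscore and conserved flag to each record.

    Missense, PTV and synonymous records all pick up the z-score at their
    protein position when a track exists (class-wise score comparisons need
    all three).  Rows are flagged, never dropped: output length equals input
    length.
    """
    out: list[AnnotatedDnm] = []
    for rec in dnms:
        track = tracks.get(rec.gene_id)
        if track is None:
            out.append(AnnotatedDnm(rec, flag="no_track"))
            continue
        if rec.protein_position is None:
            out.append(AnnotatedDnm(rec, flag="no_position"))
            continue
        pos = rec.protein_position
        if not 1 <= pos <= len(track):
            raise IndexError(
                f"{rec.gene_id}: position {pos} outside track of length {len(track)}"
            )
        if (
            rec.consequence == "missense"
            and rec.aa_ref
            and track.residues[pos - 1] not in ("X", rec.aa_ref)
        ):
            raise ValueError(
                f"{rec.gene_id} p.{pos}: variant reference {rec.aa_ref} != "
                f"track residue {track.residues[pos - 1]}"
            )
        out.append(
            AnnotatedDnm(
                rec,
                para_zscore=track.zscore_at(pos),
                conserved=track.conserved_at(pos),
            )
        )
    return out


# ---------------------------------------------------------------------------
# track export
# ---------------------------------------------------------------------------

OVERLAY_CLASSES = ("missense", "ptv", "synonymous")
_PTV = {"nonsense", "frameshift", "splice"}


@dataclass
class TrackExport:
    """Row-per-residue export of one gene's conservation with variant
    overlays, ordered by position."""

    gene_id: str
    positions: list[int]
    residues: list[str]
    para_zscores: list[float]
    overlays: dict[str, list[int]]  # class -> sorted positions

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.residues) == len(self.para_zscores) == n):
            raise ValueError("export columns differ in length")
        for cls, positions in self.overlays.items():
            for p in positions:
                if not 1 <= p <= n:
                    raise ValueError(f"overlay {cls} position {p} out of range")


def export_track(
    gene_id: str,
    track: ParalogScoreTrack,
    variants: Sequence[DnmRecord] = (),
) -> TrackExport:
    """Build the plot-ready per-residue table (mean reference line is z=0)."""
    overlays: dict[str, set[int]] = {cls: set() for cls in OVERLAY_CLASSES}
    for rec in variants:
        if rec.gene_id != gene_id or rec.protein_position is None:
            continue
        if rec.consequence == "missense":
            cls = "missense"
        elif rec.consequence in _PTV:
            cls = "ptv"
        elif rec.consequence == "synonymous":
            cls = "synonymous"
        else:
            continue
        if 1 <= rec.protein_position <= len(track):
            overlays[cls].add(rec.protein_position)
        else:
            logger.warning(
                "%s: overlay position %d outside track; skipped",
                gene_id, rec.protein_position,
            )
    return TrackExport(
        gene_id=gene_id,
        positions=list(range(1, len(track) + 1)),
        residues=list(track.residues),
        para_zscores=[float(z) for z in track.para_zscore],
        overlays={cls: sorted(v) for cls, v in overlays.items()},
    )


def plot_track(export: TrackExport, path) -> None:
    """Optional bar plot of a track export (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"missense": "tab:blue", "ptv": "tab:pink", "synonymous": "tab:orange"}
    pos_to_cls = {}
    for cls in ("synonymous", "ptv", "missense"):  # missense wins overlaps
        for p in export.overlays[cls]:
            pos_to_cls[p] = cls
    bar_colors = [
        colors.get(pos_to_cls.get(p), "lightgray") for p in export.positions
    ]
    fig, ax = plt.subplots(figsize=(max(6, len(export.positions) / 50), 3))
    ax.bar(export.positions, export.para_zscores, color=bar_colors, width=1.0)
    ax.axhline(0.0, color="red", linestyle=":")
    ax.set_xlabel("residue (1-based)")
    ax.set_ylabel("para_zscore")
    ax.set_title(export.gene_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
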