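"""Readers and writers for the pipeline's tabular and sequence formats.

All tables are TSV with a header row; sequences are FASTA keyed by gene id.
Genomic coordinates are 1-based, protein residues 1-based; output headers
state this.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotatedDnm, TrackExport
from .burden import BurdenResult, DnmRecord, GeneAnnotationRow
from .conservation import Msa, ParalogScoreTrack, zscore_track
from .expectation import GeneExpectation, MutationRateTable
from .family_graph import GeneRecord, SubFamily

logger = logging.getLogger(__name__)

COORDINATE_NOTE = "# coordinates: genomic 1-based; protein residues 1-based"


# -- sequences ---------------------------------------------------------------

def read_protein_fasta(path) -> dict[str, GeneRecord]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = GeneRecord(gene_id=rec.id, protein_seq=str(rec.seq).upper())
    return records


def read_cds_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[GeneRecord], path, cds: bool = False) -> None:
    seqs = [
        SeqRecord(Seq(r.cds_seq if cds else r.protein_seq), id=r.gene_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_msa(path, fmt: str = "fasta") -> Msa:
    """Read an aligned FASTA (or Clustal) file into an Msa."""
    rows = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "clustal" if fmt == "clustal" else "fasta")
    ]
    return Msa(rows)


def write_msa(msa: Msa, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in msa.rows],
        str(path),
        "fasta",
    )


# -- pair table and sub-family membership ------------------------------------

def read_pair_table(path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("pair table needs >= 2 columns")
    out = []
    for row in df.itertuples(index=False):
        vals = list(row)[:3]
        fam = vals[2] if len(vals) > 2 and pd.notna(vals[2]) else None
        out.append((vals[0], vals[1], fam) if fam else (vals[0], vals[1]))
    return out


def write_subfamilies(subfamilies: Sequence[SubFamily], path) -> None:
    with open(path, "w") as fh:
        fh.write("subfamily_id\tgene_id\n")
        for sf in subfamilies:
            for gid in sf.gene_ids:
                fh.write(f"{sf.subfamily_id}\t{gid}\n")


def read_subfamilies(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.subfamily_id, []).append(row.gene_id)
    return out


# -- score tracks ------------------------------------------------------------

def write_tracks(tracks: Mapping[str, ParalogScoreTrack], path) -> None:
    """The distributable per-gene conservation annotation table."""
    with open(path, "w") as fh:
        fh.write(COORDINATE_NOTE + "\n")
        fh.write("gene_id\tposition\tresidue\traw_score\tpara_zscore\tconserved\n")
        for gid in sorted(tracks):
            t = tracks[gid]
            for i in range(len(t)):
                fh.write(
                    f"{gid}\t{i + 1}\t{t.residues[i]}\t{t.residue_scores[i]:g}"
                    f"\t{t.para_zscore[i]:.6f}\t{int(t.conserved[i])}\n"
                )


def read_tracks(path) -> dict[str, ParalogScoreTrack]:
    df = pd.read_csv(path, sep="\t", comment="#")
    tracks = {}
    for gid, grp in df.groupby("gene_id", sort=True):
        grp = grp.sort_values("position")
        t = ParalogScoreTrack(
            gene_id=str(gid),
            residues="".join(grp["residue"]),
            residue_scores=grp["raw_score"].to_numpy(dtype=float),
        )
        t.para_zscore = grp["para_zscore"].to_numpy(dtype=float)
        t.conserved = t.para_zscore > 0
        t.mean = float(t.residue_scores.mean())
        sd = float(t.residue_scores.std(ddof=1)) if len(t) > 1 else 0.0
        t.sd = sd
        tracks[str(gid)] = t
    return tracks


# -- mutation rates ----------------------------------------------------------

def read_rate_table(path, default_rate: Optional[float] = None) -> MutationRateTable:
    df = pd.read_csv(path, sep="\t", dtype={"context": str, "alt": str, "rate": float})
    rates = {
        (row.context, row.alt): row.rate for row in df.itertuples(index=False)
    }
    return MutationRateTable(rates, default_rate=default_rate)


def write_rate_table(table: MutationRateTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("context\talt\trate\n")
        for (context, alt), rate in sorted(table.items()):
            fh.write(f"{context}\t{alt}\t{rate:.6e}\n")


# -- expectations ------------------------------------------------------------

_EXPECTATION_COLUMNS = [
    "gene_id", "synonymous", "missense", "nonsense", "frameshift", "stoploss",
    "missense_conserved", "missense_nonconserved",
    "n_conserved_sites", "n_nonconserved_sites",
]


def write_expectations(expectations: Iterable[GeneExpectation], path) -> None:
    rows = [
        {c: getattr(e, c) for c in _EXPECTATION_COLUMNS} for e in expectations
    ]
    pd.DataFrame(rows, columns=_EXPECTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_expectations(path) -> dict[str, GeneExpectation]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        kwargs = {c: getattr(row, c) for c in _EXPECTATION_COLUMNS}
        kwargs["gene_id"] = str(kwargs["gene_id"])
        kwargs["n_conserved_sites"] = int(kwargs["n_conserved_sites"])
        kwargs["n_nonconserved_sites"] = int(kwargs["n_nonconserved_sites"])
        out[kwargs["gene_id"]] = GeneExpectation(**kwargs)
    return out


# -- de novo variants and panel ----------------------------------------------

_DNM_COLUMNS = [
    "proband_id", "cohort", "gene_id", "consequence",
    "protein_position", "aa_ref", "aa_alt", "chrom", "pos", "ref", "alt",
]


def read_dnms(path) -> list[DnmRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    out = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c, None) for c in _DNM_COLUMNS if hasattr(row, c)}
        d = {k: (None if pd.isna(v) else v) for k, v in d.items()}
        if d.get("protein_position") is not None:
            d["protein_position"] = int(float(d["protein_position"]))
        if d.get("pos") is not None:
            d["pos"] = int(float(d["pos"]))
        out.append(DnmRecord(**d))
    return out


def write_dnms(dnms: Iterable[DnmRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(COORDINATE_NOTE + "\n")
        fh.write("\t".join(_DNM_COLUMNS) + "\n")
        for d in dnms:
            vals = [getattr(d, c) for c in _DNM_COLUMNS]
            fh.write("\t".join("" if v is None else str(v) for v in vals) + "\n")


def read_panel(path) -> set[tuple]:
    """Panel of normalized variant keys; genomic when chrom/pos present,
    protein-level (gene, aa_ref, protein_position, aa_alt) otherwise."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    keys = set()
    for row in df.itertuples(index=False):
        if hasattr(row, "chrom") and pd.notna(getattr(row, "chrom", None)):
            keys.add((row.chrom, int(float(row.pos)), row.ref, row.alt))
        else:
            keys.add(
                (
                    row.gene_id,
                    getattr(row, "aa_ref", None),
                    int(float(row.protein_position)),
                    getattr(row, "aa_alt", None),
                )
            )
    return keys


def read_gene_annotations(path) -> dict[str, GeneAnnotationRow]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.gene_id)] = GeneAnnotationRow(
            gene_id=str(row.gene_id),
            brain_rpkm=None if pd.isna(row.brain_rpkm) else float(row.brain_rpkm),
            pli=None if pd.isna(row.pli) else float(row.pli),
            missense_constraint_z=None
            if pd.isna(row.missense_constraint_z)
            else float(row.missense_constraint_z),
        )
    return out


# -- results -----------------------------------------------------------------

def write_burden_results(results: Sequence[BurdenResult], path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "subfamily_id": r.subfamily_id,
                "category": r.category,
                "observed": r.observed,
                "expected": r.expected,
                "p_value": r.p_value,
                "log10_p": r.log10_p,
                "significant": int(r.significant),
                "per_gene": json.dumps(r.per_gene, sort_keys=True),
                "per_cohort": json.dumps(r.per_cohort, sort_keys=True),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_annotated(annotated: Sequence[AnnotatedDnm], path) -> None:
    with open(path, "w") as fh:
        fh.write(COORDINATE_NOTE + "\n")
        fh.write("\t".join(_DNM_COLUMNS) + "\tpara_zscore\tconserved\tflag\n")
        for a in annotated:
            vals = [getattr(a.record, c) for c in _DNM_COLUMNS]
            z = "" if a.para_zscore is None else f"{a.para_zscore:.6f}"
            c = "" if a.conserved is None else str(int(a.conserved))
            fh.write(
                "\t".join("" if v is None else str(v) for v in vals)
                + f"\t{z}\t{c}\t{a.flag}\n"
            )


def write_track_export(export: TrackExport, path) -> None:
    overlay_lookup = {
        cls: set(positions) for cls, positions in export.overlays.items()
    }
    with open(path, "w") as fh:
        fh.write(COORDINATE_NOTE + "\n")
        fh.write("# mean reference line: para_zscore = 0\n")
        fh.write("gene_id\tposition\tresidue\tpara_zscore\toverlay\n")
        for i, pos in enumerate(export.positions):
            overlay = ""
            for cls in ("missense", "ptv", "synonymous"):
                if pos in overlay_lookup.get(cls, ()):
                    overlay = cls
                    break
            fh.write(
                f"{export.gene_id}\t{pos}\t{export.residues[i]}"
                f"\t{export.para_zscores[i]:.6f}\t{overlay}\n"
            )


def read_track_export(path) -> TrackExport:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    overlays: dict[str, list[int]] = {"missense": [], "ptv": [], "synonymous": []}
    for row in df.itertuples(index=False):
        if row.overlay:
            overlays[row.overlay].append(int(row.position))
    return TrackExport(
        gene_id=str(df["gene_id"].iloc[0]),
        positions=[int(p) for p in df["position"]],
        residues=[str(r) for r in df["residue"]],
        para_zscores=[float(z) for z in df["para_zscore"]],
        overlays={cls: sorted(v) for cls, v in overlays.items()},
    )
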