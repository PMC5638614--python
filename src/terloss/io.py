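"""File formats: bedGraph, counts TSV, lineage TSV, map config, FASTA.

All writers round-trip losslessly through their readers.  bedGraph is
0-based half-open with no track line; TSV schemas are versioned by a
leading comment line and unknown columns are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import ChromosomeMap, Rearrangement, TerSite
from .lineage import CELL_COLUMNS, DIVISION_COLUMNS, LineageTable
from .mfa import COUNTS, MfaProfile

LINEAGE_SCHEMA = "# terloss lineage v1"
CELLS_SCHEMA = "# terloss cells v1"
COUNTS_SCHEMA = "# terloss counts v1"


# --- windowed profiles ----------------------------------------------------

def write_bedgraph(profile: MfaProfile, path, length_bp: int | None = None) -> None:
    """0-based half-open bedGraph; masked windows are omitted."""
    starts = profile.starts()
    ends = starts + profile.window_bp
    if length_bp is not None:
        ends = np.minimum(ends, length_bp)
    with open(path, "w") as fh:
        for s, e, v, ok in zip(starts, ends, profile.values, profile.mask):
            if ok:
                fh.write(f"{profile.chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(path, kind: str = COUNTS) -> MfaProfile:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="t",  # skips optional track lines
        names=["chrom", "start", "end", "value"],
    )
    if df.empty:
        raise ValueError(f"empty bedGraph {path}")
    window = int(df["end"].iloc[0] - df["start"].iloc[0])
    n = int(df["start"].max()) // window + 1
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    idx = (df["start"] // window).to_numpy()
    values[idx] = df["value"].to_numpy()
    mask[idx] = True
    return MfaProfile(
        window_bp=window, values=values, kind=kind, mask=mask,
        chrom=str(df["chrom"].iloc[0]),
    )


def write_counts_tsv(profile: MfaProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(COUNTS_SCHEMA + "\n")
        fh.write("window_start\tcount\n")
        for s, v, ok in zip(profile.starts(), profile.values, profile.mask):
            if ok:
                fh.write(f"{s}\t{v:.10g}\n")


def read_counts_tsv(path, kind: str = COUNTS, chrom: str = "chr") -> MfaProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"empty counts table {path}")
    starts = df["window_start"].to_numpy()
    window = int(np.diff(np.sort(np.unique(starts))).min()) if len(starts) > 1 else int(starts[0] or 1000)
    n = int(starts.max()) // window + 1
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    idx = starts // window
    values[idx] = df["count"].to_numpy()
    mask[idx] = True
    return MfaProfile(window_bp=window, values=values, kind=kind, mask=mask, chrom=chrom)


def write_series_tsv(profile: MfaProfile, path) -> None:
    """Per-window series (position, value, valid) for external viewers."""
    pd.DataFrame(
        {
            "position": profile.starts(),
            "value": profile.values,
            "valid": profile.mask.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


# --- lineage tables -------------------------------------------------------

def write_lineage_tsv(table: LineageTable, divisions_path, cells_path=None) -> None:
    with open(divisions_path, "w") as fh:
        fh.write(LINEAGE_SCHEMA + "\n")
        df = table.divisions.copy()
        df["daughter1_focus"] = df["daughter1_focus"].astype(int)
        df["daughter2_focus"] = df["daughter2_focus"].astype(int)
        df.to_csv(fh, sep="\t", index=False)
    if cells_path is not None and table.cells is not None:
        with open(cells_path, "w") as fh:
            fh.write(CELLS_SCHEMA + "\n")
            table.cells.to_csv(fh, sep="\t", index=False)


def read_lineage_tsv(divisions_path, cells_path=None) -> LineageTable:
    df = pd.read_csv(divisions_path, sep="\t", comment="#")
    missing = [c for c in DIVISION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"lineage table missing columns {missing}")
    df["daughter1_focus"] = df["daughter1_focus"].astype(bool)
    df["daughter2_focus"] = df["daughter2_focus"].astype(bool)
    cells = None
    if cells_path is not None and Path(cells_path).exists():
        cells = pd.read_csv(cells_path, sep="\t", comment="#")
    return LineageTable(divisions=df, cells=cells)


# --- chromosome map config ------------------------------------------------

def map_to_dict(chrom: ChromosomeMap) -> dict:
    return {
        "name": chrom.name,
        "length_bp": chrom.length_bp,
        "oriC": chrom.oriC,
        "loci": dict(chrom.loci),
        "ter_sites": [
            {
                "name": t.name, "position": t.position,
                "blocks": t.blocks, "efficiency": t.efficiency,
            }
            for t in chrom.ter_sites
        ],
        "rearrangements": [
            {"kind": r.kind, "start": r.start, "end": r.end, "payload": r.payload}
            for r in chrom.rearrangements
        ],
    }


def map_from_dict(d: dict) -> ChromosomeMap:
    return ChromosomeMap(
        length_bp=int(d["length_bp"]),
        oriC=int(d["oriC"]),
        loci={k: int(v) for k, v in (d.get("loci") or {}).items()},
        ter_sites=tuple(
            TerSite(
                name=t["name"], position=int(t["position"]),
                blocks=t["blocks"], efficiency=float(t.get("efficiency", 1.0)),
            )
            for t in d.get("ter_sites") or []
        ),
        rearrangements=tuple(
            Rearrangement(
                kind=r["kind"], start=int(r["start"]), end=int(r["end"]),
                payload=r.get("payload"),
            )
            for r in d.get("rearrangements") or []
        ),
        name=d.get("name", "chr"),
    )


def write_map_yaml(chrom: ChromosomeMap, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(map_to_dict(chrom), fh, sort_keys=False)


def read_map_yaml(path) -> ChromosomeMap:
    with open(path) as fh:
        return map_from_dict(yaml.safe_load(fh))


# --- FASTA ----------------------------------------------------------------

def read_fasta(path) -> tuple[str, str]:
    """(id, uppercase sequence) of the first record."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def write_fasta(path, seq_id: str, sequence: str, description: str = "") -> None:
    rec = SeqRecord(Seq(sequence), id=seq_id, description=description)
    SeqIO.write([rec], str(path), "fasta")
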