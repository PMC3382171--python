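"""File-format readers and writers.

Standard formats (FASTA, FASTQ) go through Biopython; tabular inputs through
pandas.  The paired-read SAM interchange uses a deliberately minimal dialect:
``@SQ SN: LN:`` header lines followed by six-column records
``QNAME FLAG RNAME POS MAPQ CIGAR`` with only M (match) and S (soft clip)
CIGAR operations — enough to carry the ungapped, clipped placements this
pipeline produces, and strict enough that anything else is rejected with the
file, line and offending field named.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cnv import GeneModel, ProbeTrack
from .doseresponse import PlateReadout
from .mapping import MateAlignment, ReadPairAlignment, TranscriptSet

__all__ = [
    "FormatError",
    "read_fasta", "write_fasta",
    "read_fastq_pair", "write_fastq_pair",
    "read_minimal_sam", "write_minimal_sam",
    "read_plate_csv", "read_combo_csv",
    "read_probe_tsv", "read_bed_genes",
    "write_report_json",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"


class FormatError(ValueError):
    """A malformed record, reported with file, line and field."""

    def __init__(self, path, line: int | None, field: str, message: str):
        loc = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc}: field {field!r}: {message}")


# -- FASTA / FASTQ ----------------------------------------------------------


def read_fasta(path) -> TranscriptSet:
    records = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    if not records:
        raise FormatError(path, None, "records", "no FASTA records found")
    return TranscriptSet(records=records)


def write_fasta(path, records) -> None:
    """``records``: iterable of (id, sequence) or a TranscriptSet."""
    if isinstance(records, TranscriptSet):
        records = records.records
    SeqIO.write(
        (SeqRecord(Seq(seq), id=tid, description="") for tid, seq in records),
        str(path), "fasta",
    )


def read_fastq_pair(path1, path2) -> list[tuple[str, str, str]]:
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1) != len(r2):
        raise FormatError(path2, None, "records",
                          f"mate files differ in length ({len(r1)} vs {len(r2)})")
    pairs = []
    for a, b in zip(r1, r2):
        ida = re.sub(r"/[12]$", "", a.id)
        idb = re.sub(r"/[12]$", "", b.id)
        if ida != idb:
            raise FormatError(path2, None, "id", f"pair ids disagree: {a.id} vs {b.id}")
        pairs.append((ida, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


def write_fastq_pair(path1, path2, pairs) -> None:
    """``pairs``: iterable of (pair_id, seq1, seq2); qualities are constant."""

    def _recs(idx):
        for pid, s1, s2 in pairs:
            seq = s1 if idx == 1 else s2
            rec = SeqRecord(Seq(seq), id=f"{pid}/{idx}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            yield rec

    SeqIO.write(_recs(1), str(path1), "fastq")
    SeqIO.write(_recs(2), str(path2), "fastq")


# -- minimal SAM dialect ----------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_FIRST = 0x40
_FLAG_SECOND = 0x80


def _cigar_parts(cigar: str, path, line: int):
    if cigar == "*":
        return []
    parts = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in parts) != cigar:
        raise FormatError(path, line, "CIGAR", f"unparseable CIGAR {cigar!r}")
    for _, op in parts:
        if op not in ("M", "S"):
            raise FormatError(path, line, "CIGAR",
                              f"unsupported CIGAR op {op!r} (dialect allows M and S only)")
    return [(int(n), op) for n, op in parts]


def _mate_from_fields(fields, path, line) -> MateAlignment:
    flag = int(fields[1])
    if flag & _FLAG_UNMAPPED or fields[2] == "*":
        return MateAlignment(status="unmapped")
    parts = _cigar_parts(fields[5], path, line)
    clip5 = parts[0][0] if parts and parts[0][1] == "S" else 0
    clip3 = parts[-1][0] if parts and parts[-1][1] == "S" else 0
    span = sum(n for n, op in parts if op == "M")
    return MateAlignment(
        status="unique",
        transcript=fields[2],
        start=int(fields[3]),
        strand="-" if flag & _FLAG_REVERSE else "+",
        span=span,
        clip5=clip5,
        clip3=clip3,
    )


def read_minimal_sam(path) -> tuple[list[ReadPairAlignment], dict[str, int]]:
    """Parse the minimal SAM dialect into read-pair alignments.

    Returns (alignments, reference lengths from @SQ lines).  Mates pair by
    QNAME with the FIRST/SECOND flag bits.
    """
    refs: dict[str, int] = {}
    mates: dict[str, dict[int, MateAlignment]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.rstrip("\n")
            if not text:
                continue
            if text.startswith("@"):
                if text.startswith("@SQ"):
                    sn = ln = None
                    for tag in text.split("\t")[1:]:
                        if tag.startswith("SN:"):
                            sn = tag[3:]
                        elif tag.startswith("LN:"):
                            ln = int(tag[3:])
                    if sn is None or ln is None:
                        raise FormatError(path, lineno, "@SQ", "needs SN: and LN: tags")
                    refs[sn] = ln
                continue
            fields = text.split("\t")
            if len(fields) < 6:
                raise FormatError(path, lineno, "columns",
                                  f"expected 6 columns (QNAME FLAG RNAME POS MAPQ CIGAR), got {len(fields)}")
            try:
                flag = int(fields[1])
                int(fields[3])
                int(fields[4])
            except ValueError as exc:
                raise FormatError(path, lineno, "FLAG/POS/MAPQ", str(exc)) from None
            qname = fields[0]
            which = 2 if flag & _FLAG_SECOND else 1
            if qname not in mates:
                mates[qname] = {}
                order.append(qname)
            mates[qname][which] = _mate_from_fields(fields, path, lineno)
    out = []
    unmapped = MateAlignment(status="unmapped")
    for qname in order:
        pair = mates[qname]
        out.append(ReadPairAlignment(qname, pair.get(1, unmapped), pair.get(2, unmapped)))
    return out, refs


def write_minimal_sam(path, alignments: list[ReadPairAlignment], refs: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for name, length in refs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for pair in alignments:
            for which, mate in ((1, pair.mate1), (2, pair.mate2)):
                flag = _FLAG_PAIRED | (_FLAG_FIRST if which == 1 else _FLAG_SECOND)
                if mate.status != "unique":
                    fh.write(f"{pair.pair_id}\t{flag | _FLAG_UNMAPPED}\t*\t0\t0\t*\n")
                    continue
                if mate.strand == "-":
                    flag |= _FLAG_REVERSE
                cigar = ""
                if mate.clip5:
                    cigar += f"{mate.clip5}S"
                cigar += f"{mate.span}M"
                if mate.clip3:
                    cigar += f"{mate.clip3}S"
                fh.write(
                    f"{pair.pair_id}\t{flag}\t{mate.transcript}\t{mate.start}\t60\t{cigar}\n"
                )


# -- tabular inputs ---------------------------------------------------------

_PLATE_COLUMNS = ("well", "drug", "dose_molar", "count", "role")
_ROLES = ("treated", "untreated", "baseline")


def read_plate_csv(path) -> tuple[PlateReadout, pd.DataFrame]:
    """Read a plate CSV; returns (PlateReadout, treated-well table).

    Columns: well, drug, dose_molar, count, role in {treated, untreated,
    baseline}; dose may be empty only for non-treated roles.
    """
    df = pd.read_csv(path)
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(path, None, ",".join(missing),
                          f"plate CSV requires columns {list(_PLATE_COLUMNS)}")
    bad = df[~df["role"].isin(_ROLES)]
    if len(bad):
        raise FormatError(path, int(bad.index[0]) + 2, "role",
                          f"role must be one of {list(_ROLES)}, got {bad['role'].iloc[0]!r}")
    treated = df[df["role"] == "treated"].copy()
    if treated["dose_molar"].isna().any():
        row = treated[treated["dose_molar"].isna()].index[0]
        raise FormatError(path, int(row) + 2, "dose_molar", "treated wells need a dose")
    plate = PlateReadout(
        wells=tuple(
            (r.well, r.drug, float(r.dose_molar), float(r.count))
            for r in treated.itertuples()
        ),
        baseline_wells=tuple(
            (r.well, float(r.count)) for r in df[df["role"] == "baseline"].itertuples()
        ),
        untreated_wells=tuple(
            (r.well, float(r.count)) for r in df[df["role"] == "untreated"].itertuples()
        ),
    )
    return plate, treated


def write_plate_csv(path, plate: PlateReadout) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_PLATE_COLUMNS)
        for well, drug, dose, count in plate.wells:
            w.writerow([well, drug, repr(dose), repr(count), "treated"])
        for well, count in plate.baseline_wells:
            w.writerow([well, "", "", repr(count), "baseline"])
        for well, count in plate.untreated_wells:
            w.writerow([well, "", "", repr(count), "untreated"])


def read_combo_csv(path):
    """Read a combination matrix CSV (dose_a_molar, dose_b_molar, tgi).

    Returns (observed matrix, doses_a, doses_b) with ascending dose axes.
    """
    df = pd.read_csv(path)
    for col in ("dose_a_molar", "dose_b_molar", "tgi"):
        if col not in df.columns:
            raise FormatError(path, None, col, "combination CSV requires "
                              "columns dose_a_molar, dose_b_molar, tgi")
    pivot = df.pivot_table(index="dose_a_molar", columns="dose_b_molar", values="tgi")
    if pivot.isna().any().any():
        raise FormatError(path, None, "tgi", "dose grid is incomplete")
    return pivot.to_numpy(), pivot.index.to_numpy(float), pivot.columns.to_numpy(float)


def write_combo_csv(path, observed, doses_a, doses_b) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dose_a_molar", "dose_b_molar", "tgi"])
        for i, da in enumerate(doses_a):
            for j, db in enumerate(doses_b):
                w.writerow([repr(float(da)), repr(float(db)), repr(float(observed[i][j]))])


def read_probe_tsv(path) -> ProbeTrack:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "log2_ratio"):
        if col not in df.columns:
            raise FormatError(path, None, col,
                              "probe TSV requires columns chrom, pos, log2_ratio")
    return ProbeTrack.from_frame(df)


def write_probe_tsv(path, track: ProbeTrack) -> None:
    pd.DataFrame(
        {"chrom": track.chrom, "pos": track.pos, "log2_ratio": track.log2_ratio}
    ).to_csv(path, sep="\t", index=False)


def read_bed_genes(path) -> list[GeneModel]:
    """Read gene models from BED12 (block-structured) or an exon-per-row TSV.

    The TSV form needs columns gene, chrom, strand, start, end (1-based
    inclusive exons).  BED12 blocks are converted from 0-based half-open.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if "\t" in first and first.split("\t")[0] in ("gene",):
        df = pd.read_csv(path, sep="\t")
        genes = []
        for gid, grp in df.groupby("gene", sort=False):
            genes.append(
                GeneModel(
                    gene_id=str(gid),
                    chrom=str(grp["chrom"].iloc[0]),
                    strand=str(grp["strand"].iloc[0]),
                    exons=tuple(
                        (int(r.start), int(r.end)) for r in grp.itertuples()
                    ),
                )
            )
        return genes
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.rstrip("\n")
            if not text or text.startswith(("track", "browser", "#")):
                continue
            fields = text.split("\t")
            if len(fields) < 12:
                raise FormatError(path, lineno, "columns",
                                  f"BED12 requires 12 columns, got {len(fields)}")
            chrom, chrom_start, _, name = fields[0], int(fields[1]), fields[2], fields[3]
            strand = fields[5]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != int(fields[9]) or len(offsets) != int(fields[9]):
                raise FormatError(path, lineno, "blockSizes/blockStarts",
                                  "block count disagrees with blockCount")
            exons = tuple(
                (chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(offsets, sizes)
            )
            genes.append(GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons))
    return genes


# -- JSON report ------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonify(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report_json(path, payload: dict) -> None:
    """Write a versioned JSON report; concentrations are molar with an
    explicit units field to avoid nM/uM confusion."""
    doc = {"schema_version": REPORT_SCHEMA_VERSION, "concentration_units": "molar"}
    doc.update(_jsonify(payload))
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
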