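"""Readers and writers for every external format the pipeline touches.

Conventions:

* narrowPeak / BED / bedGraph are 0-based half-open and pass through unchanged.
* GTF is 1-based inclusive on disk and converted to 0-based half-open on read;
  the writer applies the inverse conversion, so read∘write is the identity.
* FASTA is uppercased on read (soft-masking is ignored by design).
* Motifs are MEME minimal format; alphabet order A,C,G,T is enforced.

Writers emit one canonical formatting so that byte-level determinism holds for
identical inputs.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import GeneModel, GenomicInterval, Peak, PWMRecord, SignalTrack

__all__ = [
    "ParseError",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gtf_genes",
    "write_gtf_genes",
    "read_bedgraph",
    "write_bedgraph",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_fasta",
    "write_fasta",
    "read_tf_list",
    "write_se_table",
    "read_se_table",
    "write_regions",
    "read_regions",
]

SE_TABLE_COLUMNS = [
    "se_id",
    "chrom",
    "start",
    "end",
    "n_constituents",
    "signal",
    "rank",
    "is_super",
    "assigned_genes",
]


class ParseError(ValueError):
    """Malformed input file; message names the file and line number."""


def _fmt_float(x: float) -> str:
    """Canonical float formatting: up to 6 decimals, trailing zeros trimmed."""
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


# ---------------------------------------------------------------------------
# narrowPeak / BED


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read a narrowPeak (BED6+4) or BED3–6 file into Peak records.

    Missing optional columns take narrowPeak defaults (signalValue 0,
    p/q −1, summit −1). Coordinates are used exactly as in the file.
    """
    peaks: list[Peak] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = int(float(fields[4])) if len(fields) > 4 else 0
                strand = fields[5] if len(fields) > 5 else "."
                signal = float(fields[6]) if len(fields) > 6 else 0.0
                p = float(fields[7]) if len(fields) > 7 else -1.0
                q = float(fields[8]) if len(fields) > 8 else -1.0
                summit = int(fields[9]) if len(fields) > 9 else -1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            try:
                peaks.append(
                    Peak(
                        interval=GenomicInterval(fields[0], start, end, strand),
                        name=name,
                        score=score,
                        signal_value=signal,
                        p_value=p,
                        q_value=q,
                        summit=summit,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        p.interval.strand,
                        _fmt_float(p.signal_value),
                        _fmt_float(p.p_value),
                        _fmt_float(p.q_value),
                        str(p.summit),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Read gene records from a GTF; 1-based inclusive → 0-based half-open."""
    genes: list[GeneModel] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != feature:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            if "gene_id" not in attrs:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            symbol = attrs.get("gene_name", attrs["gene_id"])
            strand = fields[6] if fields[6] in ("+", "-") else "."
            try:
                interval = GenomicInterval(fields[0], start1 - 1, end1, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(attrs["gene_id"], symbol, interval))
    return genes


def write_gtf_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.interval.chrom,
                        "crcpipe",
                        "gene",
                        str(g.interval.start + 1),
                        str(g.interval.end),
                        ".",
                        g.interval.strand,
                        ".",
                        f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";',
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack.

    Steps may arrive unsorted; overlapping steps or negative values are
    rejected rather than resolved by guesswork.
    """
    records: list[tuple[str, int, int, float]] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value")
            records.append((fields[0], start, end, value))
    try:
        return SignalTrack.from_records(records)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt_float(value)}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_motifs(path: str | Path) -> list[PWMRecord]:
    """Read MEME minimal-format motifs into PWMRecords.

    Alphabet must be ACGT. Probability rows off by at most 1e-3 are
    renormalised; larger deviations are an error.
    """
    path = Path(path)
    text = path.read_text()
    if "MEME version" not in text:
        raise ParseError(f"{path}: not a MEME minimal format file")
    alpha_match = re.search(r"^ALPHABET\s*=\s*(\S+)", text, re.MULTILINE)
    if alpha_match and alpha_match.group(1) != "ACGT":
        raise ParseError(f"{path}: unsupported alphabet {alpha_match.group(1)!r}")

    motifs: list[PWMRecord] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{i + 1}: MOTIF line without identifier")
            motif_id = parts[1]
            tf_symbol = parts[2] if len(parts) > 2 else motif_id
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                if lines[j].strip().startswith("MOTIF"):
                    raise ParseError(
                        f"{path}:{i + 1}: motif {motif_id} has no probability matrix"
                    )
                j += 1
            if j >= len(lines):
                raise ParseError(
                    f"{path}:{i + 1}: motif {motif_id} has no probability matrix"
                )
            w_match = re.search(r"w\s*=\s*(\d+)", lines[j])
            rows: list[list[float]] = []
            k = j + 1
            while k < len(lines):
                stripped = lines[k].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                try:
                    row = [float(x) for x in stripped.split()]
                except ValueError as exc:
                    raise ParseError(f"{path}:{k + 1}: malformed matrix row") from exc
                if len(row) != 4:
                    raise ParseError(f"{path}:{k + 1}: expected 4 probabilities")
                total = sum(row)
                if abs(total - 1.0) > 1e-3:
                    raise ParseError(
                        f"{path}:{k + 1}: probability row sums to {total:.6f}"
                    )
                rows.append([x / total for x in row])
                k += 1
            if w_match and int(w_match.group(1)) != len(rows):
                raise ParseError(
                    f"{path}: motif {motif_id}: declared w= {w_match.group(1)} "
                    f"but {len(rows)} rows found"
                )
            try:
                motifs.append(PWMRecord(motif_id, tf_symbol, np.array(rows)))
            except ValueError as exc:
                raise ParseError(f"{path}: motif {motif_id}: {exc}") from exc
            i = k
        else:
            i += 1
    return motifs


def write_meme_motifs(
    motifs: Sequence[PWMRecord],
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {0} C {1} G {2} T {3}\n\n".format(*(f"{b:.5f}" for b in background))
        )
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id} {m.tf_symbol}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {chrom: uppercase sequence}; duplicate names error."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ParseError(f"{path}: duplicate chromosome name {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_tf_list(path: str | Path) -> list[str]:
    """One TF symbol per line; blank lines and # comments ignored."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return symbols


# ---------------------------------------------------------------------------
# SE table (ROSE-like TSV)


def write_se_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the ranked-enhancer table as TSV with a fixed column order."""
    missing = [c for c in SE_TABLE_COLUMNS if c not in rows.columns]
    if missing:
        raise ValueError(f"SE table missing columns: {missing}")
    out = rows[SE_TABLE_COLUMNS].copy()
    out["signal"] = out["signal"].map(_fmt_float)
    out["is_super"] = out["is_super"].map(lambda b: "1" if b else "0")
    out.to_csv(path, sep="\t", index=False)


REGIONS_COLUMNS = [
    "region_id",
    "chrom",
    "start",
    "end",
    "n_constituents",
    "constituent_starts",
    "constituent_ends",
    "signal",
]


def write_regions(regions: Sequence, path: str | Path) -> None:
    """Write stitched (quantified) regions as TSV, constituents inline."""
    rows = []
    for r in regions:
        rows.append(
            {
                "region_id": r.id,
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "n_constituents": r.n_constituents,
                "constituent_starts": ",".join(str(c.start) for c in r.constituents),
                "constituent_ends": ",".join(str(c.end) for c in r.constituents),
                "signal": _fmt_float(r.signal if r.signal is not None else 0.0),
            }
        )
    pd.DataFrame(rows, columns=REGIONS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path):
    """Read a regions TSV back into StitchedRegion objects."""
    from .stitching import StitchedRegion

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    regions = []
    for _, row in df.iterrows():
        starts = [int(x) for x in row["constituent_starts"].split(",") if x]
        ends = [int(x) for x in row["constituent_ends"].split(",") if x]
        constituents = [
            Peak(interval=GenomicInterval(row["chrom"], s, e), name=".")
            for s, e in zip(starts, ends)
        ]
        regions.append(
            StitchedRegion(
                id=row["region_id"],
                interval=GenomicInterval(
                    row["chrom"], int(row["start"]), int(row["end"])
                ),
                constituents=constituents,
                signal=float(row["signal"]),
            )
        )
    return regions


def read_se_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "se_id": str,
            "chrom": str,
            "start": int,
            "end": int,
            "n_constituents": int,
            "signal": float,
            "rank": int,
            "is_super": int,
        },
        keep_default_na=False,
    )
    df["is_super"] = df["is_super"].astype(bool)
    df["assigned_genes"] = df["assigned_genes"].astype(str)
    return df
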