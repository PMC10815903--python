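"""Plain-text readers and writers for the pipeline's file dialects.

* Trace CSV: columns ``time_s, signal_au`` with metadata in ``#``-prefixed
  header comment lines (``# enzyme_uM=``, ``# primer_uM=``,
  ``# nucleotide_uM=``, ``# channel=``).
* Product time-course CSV: ``time_s, product_fraction`` with ``# conc_uM=``.
* Decay CSV: ``bin_ns, counts, irf_counts``.
* Aligned FASTA (gap ``-``) via Biopython.
* Key-value report files and TSV conservation profiles.

All writers are atomic (write to a temp file, then rename).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import AlignedSet, ColumnProfile
from .lifetime import DecayHistogram
from .quench import ProductTimeCourse
from .transient import Trace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_product_csv",
    "read_product_csv",
    "write_decay_csv",
    "read_decay_csv",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_report",
    "read_report",
    "write_profile_tsv",
]


def _atomic_write(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


# -- traces -----------------------------------------------------------------


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    lines = [
        f"# enzyme_uM={trace.conc_enzyme:g}",
        f"# primer_uM={trace.conc_primer:g}",
        f"# nucleotide_uM={trace.conc_nucleotide:g}",
        f"# channel={trace.channel}",
        f"# id={trace.id}",
        "time_s,signal_au",
    ]
    lines += [f"{t:.9g},{s:.9g}" for t, s in zip(trace.times, trace.signal)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_trace_csv(path: str | Path) -> Trace:
    path = Path(path)
    meta = _header_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
        times = df["time_s"].to_numpy(dtype=float)
        signal = df["signal_au"].to_numpy(dtype=float)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed trace CSV {path}: {exc}") from exc
    return Trace(
        times=times,
        signal=signal,
        channel=meta.get("channel", "CPy"),
        conc_enzyme=float(meta.get("enzyme_uM", 0.0)),
        conc_primer=float(meta.get("primer_uM", 0.0)),
        conc_nucleotide=float(meta.get("nucleotide_uM", 0.0)),
        id=meta.get("id", path.stem),
    )


# -- quench product time courses -------------------------------------------


def write_product_csv(tc: ProductTimeCourse, path: str | Path) -> None:
    lines = [
        f"# conc_uM={tc.conc_titrant:g}",
        f"# label={tc.label}",
        "time_s,product_fraction",
    ]
    lines += [f"{t:.9g},{p:.9g}" for t, p in zip(tc.times, tc.product_fraction)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_product_csv(path: str | Path) -> ProductTimeCourse:
    path = Path(path)
    meta = _header_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
        times = df["time_s"].to_numpy(dtype=float)
        frac = df["product_fraction"].to_numpy(dtype=float)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed product CSV {path}: {exc}") from exc
    return ProductTimeCourse(
        times=times,
        product_fraction=frac,
        conc_titrant=float(meta.get("conc_uM", 0.0)),
        label=meta.get("label", path.stem),
    )


# -- TCSPC decays ------------------------------------------------------------


def write_decay_csv(h: DecayHistogram, path: str | Path) -> None:
    lines = ["bin_ns,counts,irf_counts"]
    lines += [
        f"{b:.9g},{int(c)},{int(i)}"
        for b, c, i in zip(h.bin_centers, h.counts, h.irf_counts)
    ]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_decay_csv(path: str | Path) -> DecayHistogram:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
        return DecayHistogram(
            bin_centers=df["bin_ns"].to_numpy(dtype=float),
            counts=df["counts"].to_numpy(dtype=float),
            irf_counts=df["irf_counts"].to_numpy(dtype=float),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed decay CSV {path}: {exc}") from exc


# -- alignments ---------------------------------------------------------------


def read_alignment_fasta(path: str | Path, reference_id: str) -> AlignedSet:
    records: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in records:
            raise ValueError(f"duplicate record id {rec.id!r} at record {i} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return AlignedSet(records=records, reference_id=reference_id)


def write_alignment_fasta(a: AlignedSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in a.records.items()]
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        SeqIO.write(recs, tmp, "fasta")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- reports and profiles -----------------------------------------------------


def write_report(entries: Mapping[str, object], path: str | Path) -> None:
    """Write a flat key: value report (floats at full precision)."""
    lines = []
    for key, val in entries.items():
        if isinstance(val, float):
            lines.append(f"{key}: {val:.10g}")
        else:
            lines.append(f"{key}: {val}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_report(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(":")
            out[key.strip()] = val.strip()
    return out


def write_profile_tsv(profiles: Sequence[ColumnProfile], path: str | Path) -> None:
    rows = []
    for prof in profiles:
        for res in sorted(prof.percents, key=lambda r: -prof.percents[r]):
            rows.append(
                {
                    "position": prof.ref_position,
                    "residue": res,
                    "percent": round(prof.percents[res], 4),
                    "count": prof.counts[res],
                }
            )
    df = pd.DataFrame(rows, columns=["position", "residue", "percent", "count"])
    _atomic_write(path, df.to_csv(sep="\t", index=False))
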