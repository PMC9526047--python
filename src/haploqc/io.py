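"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; gzipped inputs are handled transparently
by extension. Histograms and spectra use simple TSV dialects, model fits and
reports use versioned JSON.
"""

from __future__ import annotations

import gzip
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import IO, Iterable

import numpy as np
from Bio import SeqIO

from .errors import InputError
from .kmers import KmerHistogram, SpectraCN
from .simdata import AssemblyTruth, Contig, DiploidTruth, Read
from .specmodel import ComponentCurves, ModelFit

SCHEMA_VERSION = 1


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if "r" in mode and not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    return dict(read_fasta(path))


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Reads from FASTA or FASTQ (gzip transparent), format by extension."""
    name = Path(path).name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fq", ".fastq")) else "fasta"
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]


def write_fasta(records: Iterable[tuple[str, str] | Contig], path: str | Path,
                width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.seq) if isinstance(rec, Contig) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: Iterable[Read | tuple[str, str]], path: str | Path) -> None:
    """Phred+33 FASTQ with constant quality 'I' (Q40)."""
    with _open_text(path, "wt") as fh:
        for rec in reads:
            rid, seq = (rec.id, rec.seq) if isinstance(rec, Read) else rec
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# histograms and spectra

def write_histogram(hist: KmerHistogram, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(f"#k={hist.k}\n")
        for x, n in hist.items():
            fh.write(f"{x}\t{n}\n")


def read_histogram(path: str | Path) -> KmerHistogram:
    k = None
    counts: dict[int, int] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#k="):
                k = int(line[3:])
                continue
            if line.startswith("#"):
                continue
            x, n = line.split("\t")
            counts[int(x)] = int(n)
    if k is None:
        raise InputError("histogram TSV lacks the #k= header")
    return KmerHistogram(k=k, counts=counts)


def write_spectra(spectra: SpectraCN, path: str | Path) -> None:
    """Spectra TSV: a header, one row per multiplicity with one column per
    copy class, then an ``assembly_exclusive`` section."""
    labels = spectra.class_labels
    cols = [f"cn{label.replace('+', 'plus')}" for label in labels]
    x_max = spectra.max_multiplicity
    with _open_text(path, "wt") as fh:
        fh.write(f"#k={spectra.k}\n#cmax={spectra.cmax}\n")
        fh.write("multiplicity\t" + "\t".join(cols) + "\n")
        for x in range(1, x_max + 1):
            row = [str(spectra.table.get(c, {}).get(x, 0)) for c in range(spectra.cmax + 1)]
            if any(v != "0" for v in row):
                fh.write(f"{x}\t" + "\t".join(row) + "\n")
        fh.write("#assembly_exclusive\nassembly_multiplicity\tcount\n")
        for a in sorted(spectra.assembly_exclusive):
            fh.write(f"{a}\t{spectra.assembly_exclusive[a]}\n")


def read_spectra(path: str | Path) -> SpectraCN:
    k = cmax = None
    table: dict[int, dict[int, int]] = {}
    exclusive: dict[int, int] = {}
    section = "spectra"
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#k="):
                k = int(line[3:])
                continue
            if line.startswith("#cmax="):
                cmax = int(line[6:])
                table = {c: {} for c in range(cmax + 1)}
                continue
            if line == "#assembly_exclusive":
                section = "exclusive"
                continue
            if line.startswith(("multiplicity", "assembly_multiplicity")):
                continue
            fields = line.split("\t")
            if section == "spectra":
                if cmax is None:
                    raise InputError("spectra TSV lacks the #cmax= header")
                x = int(fields[0])
                for c, val in enumerate(fields[1:]):
                    if int(val):
                        table[c][x] = int(val)
            else:
                exclusive[int(fields[0])] = int(fields[1])
    if k is None or cmax is None:
        raise InputError("spectra TSV lacks required headers")
    return SpectraCN(k=k, cmax=cmax, table=table, assembly_exclusive=exclusive)


# ---------------------------------------------------------------------------
# model fits and reports

def model_to_json(fit: ModelFit, curves: ComponentCurves | None = None) -> dict:
    doc = {"schema_version": SCHEMA_VERSION, "model": asdict(fit)}
    doc["model"]["fit_range"] = list(fit.fit_range)
    if curves is not None:
        doc["curves"] = {
            "x": curves.x.tolist(),
            "error": curves.error.tolist(),
            "het": curves.het.tolist(),
            "hom": curves.hom.tolist(),
        }
    return doc


def write_model(fit: ModelFit, path: str | Path,
                curves: ComponentCurves | None = None) -> None:
    with _open_text(path, "wt") as fh:
        json.dump(model_to_json(fit, curves), fh, indent=2)
        fh.write("\n")


def read_model(path: str | Path) -> ModelFit:
    with _open_text(path) as fh:
        doc = json.load(fh)
    m = doc["model"]
    m["fit_range"] = tuple(m["fit_range"])
    return ModelFit(**m)


def write_json(doc: dict, path: str | Path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **doc}
    with _open_text(path, "wt") as fh:
        json.dump(doc, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# simulation truth

def write_truth_json(diploid: DiploidTruth, assembly: AssemblyTruth | None,
                     path: str | Path) -> None:
    doc = {
        "n_het_sites": diploid.n_het_sites,
        "variant_positions": diploid.variant_positions,
    }
    if assembly is not None:
        doc["realized_f"] = assembly.realized_f
        doc["primary_breakpoints"] = assembly.primary_breakpoints
        doc["redundant_blocks"] = [
            {"contig_id": cid, "hap2_start": s, "hap2_end": e}
            for cid, s, e in assembly.redundant_blocks
        ]
    write_json(doc, path)


def write_truth_bed(assembly: AssemblyTruth, path: str | Path,
                    source_name: str = "hap2") -> None:
    """Redundant blocks as 0-based half-open BED in hap2 coordinates."""
    with _open_text(path, "wt") as fh:
        for cid, start, end in assembly.redundant_blocks:
            fh.write(f"{source_name}\t{start}\t{end}\t{cid}\n")


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
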