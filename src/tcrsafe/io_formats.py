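"""Readers and writers for every file the pipeline touches.

Fixed dialects:

* FASTA -- wrapped sequences, ``>`` headers; UniProt ``sp|ACC|NAME`` headers
  are unwrapped to the bare accession.
* Positional-scan matrix -- one TSV per replicate: two ``#`` metadata lines
  (cognate peptide, cognate response in pg/ml), then a ``residue`` header row
  and 20 rows (canonical residues, alphabetical) by L position columns.
  Empty cells are read as missing (NaN), never as zero.
* NetMHC-4.0 tabular output -- header detected by column names, one binding
  prediction per data row, affinity kept in nM.
* PROSITE pattern syntax -- ``S-L-[FY]-x-...`` for export/round-trip.
* Candidate report -- TSV plus JSON with identical records, 1-based inclusive
  protein coordinates.

Parsers validate; they never aggregate (replicate averaging happens in the
fingerprint stage) and never silently fill missing values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AMINO_ACIDS, AMINO_ACID_SET
from .proteome_scan import CandidatePeptide, DegeneratePattern

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA


@dataclass(frozen=True)
class ProteomeRecord:
    """One protein from a FASTA file.

    ``accession`` is the first whitespace-delimited header token, with
    UniProt-style ``db|ACC|NAME`` identifiers unwrapped to ``ACC``.  The
    sequence may contain non-canonical letters; the scanner treats those as
    never-matching.
    """

    accession: str
    description: str
    sequence: str


def _unwrap_accession(token: str) -> str:
    parts = token.split("|")
    if len(parts) >= 2 and parts[1]:
        return parts[1]
    return token


def read_fasta(path: "str | Path") -> list[ProteomeRecord]:
    """Read a FASTA file into :class:`ProteomeRecord` objects.

    Wrapped sequence lines are concatenated, sequences upper-cased and a
    trailing ``*`` (stop) stripped.  Duplicate accessions keep the first
    record with a logged warning.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records: list[ProteomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id
        accession = _unwrap_accession(token)
        seq = str(rec.seq).upper().rstrip("*")
        if accession in seen:
            logger.warning("duplicate accession %s in %s: keeping first", accession, path)
            continue
        seen.add(accession)
        records.append(ProteomeRecord(accession, rec.description, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteomeRecord], path: "str | Path") -> None:
    """Write records as wrapped FASTA (60 columns)."""
    out = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="")
        for r in records
    ]
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Positional-scan matrix


@dataclass
class RawScanData:
    """Replicate-resolved raw positional-scan responses (pg/ml).

    ``responses`` has shape (n_replicates, 20, L) with rows in the fixed
    alphabetical residue order; missing cells are NaN.  ``cognate_responses``
    holds each replicate's response to the unmodified cognate peptide.
    """

    cognate: str
    responses: np.ndarray
    cognate_responses: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[0]

    @property
    def length(self) -> int:
        return self.responses.shape[2]


def read_scan_matrix(paths: "str | Path | Sequence[str | Path]") -> RawScanData:
    """Read one or more replicate scan-matrix TSV files.

    Each file carries one replicate; replicates must agree on the cognate
    peptide and the matrix dimensions.  Non-numeric cells and missing
    residues are hard errors; empty cells become NaN (flagged missing).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("no scan-matrix files given")
    cognate: str | None = None
    mats: list[np.ndarray] = []
    cog_resp: list[float] = []
    for path in paths:
        path = Path(path)
        meta: dict[str, str] = {}
        rows: dict[str, list[float]] = {}
        header: list[str] | None = None
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#"):
                    key, _, value = line.lstrip("#").partition(":")
                    meta[key.strip()] = value.strip()
                    continue
                fields = line.split("\t")
                if header is None:
                    if fields[0] != "residue":
                        raise ValueError(
                            f"{path}:{lineno}: expected 'residue' header row, got {fields[0]!r}"
                        )
                    header = fields[1:]
                    continue
                residue = fields[0].strip().upper()
                if residue not in AMINO_ACID_SET:
                    raise ValueError(f"{path}:{lineno}: unknown residue row {residue!r}")
                if len(fields) - 1 != len(header):
                    raise ValueError(
                        f"{path}:{lineno}: row {residue} has {len(fields) - 1} cells, "
                        f"expected {len(header)}"
                    )
                values = []
                for col, cell in zip(header, fields[1:]):
                    cell = cell.strip()
                    if cell == "" or cell.upper() in {"NA", "NAN"}:
                        values.append(math.nan)
                        continue
                    try:
                        values.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} at "
                            f"residue {residue}, position {col}"
                        ) from None
                if residue in rows:
                    raise ValueError(f"{path}:{lineno}: duplicate residue row {residue}")
                rows[residue] = values
        if header is None:
            raise ValueError(f"{path}: no matrix found")
        missing = sorted(AMINO_ACID_SET - rows.keys())
        if missing:
            raise ValueError(f"{path}: missing residue row(s): {', '.join(missing)}")
        if "cognate" not in meta:
            raise ValueError(f"{path}: missing '# cognate:' metadata line")
        if "cognate_response" not in meta:
            raise ValueError(f"{path}: missing '# cognate_response:' metadata line")
        this_cognate = meta["cognate"].upper()
        if cognate is None:
            cognate = this_cognate
        elif this_cognate != cognate:
            raise ValueError(
                f"{path}: cognate {this_cognate} differs from {cognate} in earlier replicate"
            )
        L = len(header)
        if L != len(this_cognate):
            raise ValueError(
                f"{path}: {L} position columns but cognate of length {len(this_cognate)}"
            )
        if mats and mats[0].shape[1] != L:
            raise ValueError(f"{path}: inconsistent matrix width across replicates")
        mat = np.array([rows[aa] for aa in AMINO_ACIDS], dtype=float)
        mats.append(mat)
        cog_resp.append(float(meta["cognate_response"]))
    assert cognate is not None
    return RawScanData(
        cognate=cognate,
        responses=np.stack(mats),
        cognate_responses=np.array(cog_resp, dtype=float),
    )


def write_scan_matrix(raw: RawScanData, directory: "str | Path", prefix: str = "scan") -> list[Path]:
    """Write one TSV per replicate; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    L = raw.length
    for r in range(raw.n_replicates):
        path = directory / f"{prefix}_rep{r + 1}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# cognate: {raw.cognate}\n")
            fh.write(f"# cognate_response: {float(raw.cognate_responses[r])!r}\n")
            fh.write("residue\t" + "\t".join(str(p) for p in range(1, L + 1)) + "\n")
            for i, aa in enumerate(AMINO_ACIDS):
                cells = [
                    "" if math.isnan(v) else repr(float(v)) for v in raw.responses[r, i]
                ]
                fh.write(aa + "\t" + "\t".join(cells) + "\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# NetMHC-4.0 tabular output


@dataclass(frozen=True)
class BindingPrediction:
    """One peptide/allele binding prediction (affinity in nM, %rank)."""

    peptide: str
    allele: str
    affinity_nM: float
    percent_rank: float

    def __post_init__(self) -> None:
        if self.affinity_nM <= 0:
            raise ValueError(f"affinity must be positive, got {self.affinity_nM}")
        if self.percent_rank <= 0:
            raise ValueError(f"%rank must be positive, got {self.percent_rank}")


_NETMHC_COLS = {"peptide", "affinity", "%rank", "allele"}


def parse_binding_predictions(path: "str | Path") -> list[BindingPrediction]:
    """Parse NetMHC-4.0 tabular output.

    The header row is located by its column names ('peptide', 'Affinity(nM)',
    '%Rank', and an allele column named 'HLA' or 'allele'); comment, rule and
    repeated-header lines are skipped.  Duplicate (peptide, allele) rows keep
    the last occurrence with a logged warning.
    """
    path = Path(path)
    idx: dict[str, int] | None = None
    out: dict[tuple[str, str], BindingPrediction] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or set(line) <= {"-", " "}:
                continue
            tokens = line.split()
            lowered = [t.lower() for t in tokens]
            if "peptide" in lowered:
                idx = {}
                for i, t in enumerate(lowered):
                    if t == "peptide":
                        idx["peptide"] = i
                    elif t.startswith("affinity"):
                        idx["affinity"] = i
                    elif t == "%rank":
                        idx["%rank"] = i
                    elif t in {"hla", "allele", "mhc"}:
                        idx["allele"] = i
                missing = _NETMHC_COLS - idx.keys()
                if missing:
                    raise ValueError(
                        f"{path}: unrecognized header; missing column(s) "
                        f"{', '.join(sorted(missing))} in {line!r}"
                    )
                continue
            if idx is None:
                continue
            if len(tokens) <= max(idx.values()):
                continue
            try:
                pred = BindingPrediction(
                    peptide=tokens[idx["peptide"]].upper(),
                    allele=tokens[idx["allele"]],
                    affinity_nM=float(tokens[idx["affinity"]]),
                    percent_rank=float(tokens[idx["%rank"]]),
                )
            except ValueError:
                continue  # summary/footer line
            key = (pred.peptide, pred.allele)
            if key in out:
                logger.warning(
                    "duplicate prediction for %s / %s in %s: keeping last",
                    pred.peptide, pred.allele, path,
                )
            out[key] = pred
    if idx is None:
        raise ValueError(
            f"{path}: no NetMHC header row found (expected columns "
            "'peptide', 'Affinity(nM)', '%Rank', 'HLA')"
        )
    return list(out.values())


# ---------------------------------------------------------------------------
# PROSITE patterns


def write_prosite_pattern(pattern: DegeneratePattern) -> str:
    """Render a degenerate pattern in PROSITE syntax.

    Singleton sets become bare letters, larger sets bracketed classes, the
    full 20-letter alphabet the wildcard ``x``; positions are joined by
    dashes.  The string can be pasted into an external motif-scanning tool to
    reproduce the proteome query.
    """
    parts = []
    for s in pattern.position_sets:
        if len(s) == 1:
            parts.append(next(iter(s)))
        elif s == AMINO_ACID_SET:
            parts.append("x")
        else:
            parts.append("[" + "".join(sorted(s)) + "]")
    return "-".join(parts)


def parse_prosite_pattern(text: str) -> DegeneratePattern:
    """Inverse of :func:`write_prosite_pattern`."""
    sets = []
    for i, token in enumerate(text.strip().split("-"), start=1):
        token = token.strip()
        if token == "x":
            sets.append(frozenset(AMINO_ACID_SET))
        elif token.startswith("[") and token.endswith("]"):
            sets.append(frozenset(token[1:-1].upper()))
        elif len(token) == 1:
            sets.append(frozenset(token.upper()))
        else:
            raise ValueError(f"position {i}: cannot parse PROSITE token {token!r}")
    return DegeneratePattern(tuple(sets))


# ---------------------------------------------------------------------------
# Candidate report

REPORT_COLUMNS = [
    "peptide",
    "edit_distance",
    "n_sources",
    "sources",
    "predicted_affinity_nM",
    "percent_rank",
    "binder_class",
    "activation",
]


def _candidate_record(c: CandidatePeptide) -> dict:
    return {
        "peptide": str(c.sequence),
        "edit_distance": c.edit_distance,
        "n_sources": len(c.sources),
        # 1-based inclusive coordinates for human consumption
        "sources": [
            {"accession": acc, "start": off + 1, "end": off + len(c.sequence)}
            for acc, off in c.sources
        ],
        "predicted_affinity_nM": c.predicted_affinity_nM,
        "percent_rank": c.percent_rank,
        "binder_class": c.binder_class,
        "activation": c.activation,
    }


def write_candidate_report(
    candidates: Sequence[CandidatePeptide], path: "str | Path"
) -> tuple[Path, Path]:
    """Write candidates as a TSV and a JSON file with identical records.

    ``path`` is the TSV path; the JSON sits next to it with a ``.json``
    suffix.  Protein coordinates are 1-based inclusive in both.
    """
    tsv_path = Path(path)
    json_path = tsv_path.with_suffix(".json")
    records = [_candidate_record(c) for c in candidates]
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for rec in records:
            srcs = ";".join(
                f"{s['accession']}:{s['start']}-{s['end']}" for s in rec["sources"]
            )
            cells = [
                rec["peptide"],
                str(rec["edit_distance"]),
                str(rec["n_sources"]),
                srcs,
                "" if rec["predicted_affinity_nM"] is None else repr(rec["predicted_affinity_nM"]),
                "" if rec["percent_rank"] is None else repr(rec["percent_rank"]),
                rec["binder_class"] or "",
                rec["activation"],
            ]
            fh.write("\t".join(cells) + "\n")
    with open(json_path, "w") as fh:
        json.dump(records, fh, indent=2)
        fh.write("\n")
    return tsv_path, json_path


def read_candidate_report_json(path: "str | Path") -> list[dict]:
    """Load the JSON half of a candidate report."""
    with open(path) as fh:
        return json.load(fh)
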