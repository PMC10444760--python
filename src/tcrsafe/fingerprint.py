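"""TCR fingerprinting from a positional-scanning activation matrix.

A positional scan loads antigen-presenting cells with every single-residue
variant of the cognate epitope (19 substitutions per position plus the
original: 19L+1 peptides for an L-mer) and measures T-cell activation,
typically IFN-gamma release.  Responses are normalized per replicate to that
replicate's cognate-peptide response and averaged across replicates.  The
fingerprint is the per-position set of residues whose normalized activation
clears a cut-off: >=10% of the cognate response for the primary (confident)
set, with residues between 5% and 10% kept in a separate extended set.  Both
boundaries are inclusive at the lower edge.

The fingerprint can be rendered as a Shannon information-content sequence
logo: per position, activities are renormalized to a probability vector q,
the information content is I = log2(20) - H(q), and each residue's letter
height is q(a) * I.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AA_INDEX, AMINO_ACIDS, EpitopeContext, Peptide, as_peptide
from .io_formats import RawScanData

logger = logging.getLogger(__name__)


@dataclass
class FingerprintConfig:
    """Thresholds and aggregation policy for fingerprint construction.

    ``primary_cutoff`` (default 0.10) is the fraction of the cognate response
    at or above which a substitution counts as cross-recognized;
    ``extended_cutoff`` (default 0.05) admits borderline residues into a
    separate lower-confidence set.  ``include_extended_in_query`` controls
    whether the proteome query uses the union of both sets.
    """

    primary_cutoff: float = 0.10
    extended_cutoff: float = 0.05
    replicate_aggregation: str = "mean"
    include_extended_in_query: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.extended_cutoff < self.primary_cutoff < 1:
            raise ValueError(
                "cut-offs must satisfy 0 < extended < primary < 1, got "
                f"extended={self.extended_cutoff}, primary={self.primary_cutoff}"
            )
        if self.replicate_aggregation not in {"mean", "median"}:
            raise ValueError(
                f"unknown replicate aggregation {self.replicate_aggregation!r}"
            )


@dataclass
class PositionalScanMatrix:
    """Raw and cognate-normalized activation responses for one epitope.

    ``normalized`` is a 20 x L DataFrame (rows: residues in alphabetical
    order, columns: 1-based positions) of fraction-of-cognate values; the
    cell of the cognate residue at each position is exactly 1.0 by
    construction.
    """

    cognate: Peptide
    raw: np.ndarray
    cognate_response: np.ndarray
    normalized: pd.DataFrame

    @property
    def length(self) -> int:
        return len(self.cognate)


@dataclass
class Fingerprint:
    """Per-position tolerated-residue sets at primary and extended cut-offs.

    ``primary_sets[p]`` holds residues at or above the primary cut-off (the
    cognate residue is always a member); ``extended_sets[p]`` holds residues
    in [extended, primary), disjoint from the primary set.
    """

    cognate: Peptide
    primary_sets: tuple[frozenset[str], ...]
    extended_sets: tuple[frozenset[str], ...]
    primary_cutoff: float
    extended_cutoff: float

    def __post_init__(self) -> None:
        for p, aa in enumerate(str(self.cognate)):
            if aa not in self.primary_sets[p]:
                raise ValueError(
                    f"cognate residue {aa} missing from primary set at position {p + 1}"
                )
            if self.primary_sets[p] & self.extended_sets[p]:
                raise ValueError(f"primary and extended sets overlap at position {p + 1}")

    def to_json(self, path: "str | Path") -> None:
        doc = {
            "cognate": str(self.cognate),
            "primary_cutoff": self.primary_cutoff,
            "extended_cutoff": self.extended_cutoff,
            "primary_sets": ["".join(sorted(s)) for s in self.primary_sets],
            "extended_sets": ["".join(sorted(s)) for s in self.extended_sets],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: "str | Path") -> "Fingerprint":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            cognate=Peptide(doc["cognate"]),
            primary_sets=tuple(frozenset(s) for s in doc["primary_sets"]),
            extended_sets=tuple(frozenset(s) for s in doc["extended_sets"]),
            primary_cutoff=doc["primary_cutoff"],
            extended_cutoff=doc["extended_cutoff"],
        )


def make_positional_library(cognate: "Peptide | str") -> list[Peptide]:
    """All single-residue variants of the cognate peptide, plus the original.

    For an L-mer this is 19L + 1 unique peptides (e.g. 172 for a 9-mer):
    the scanning library synthesized for the activation matrix.  Order is
    deterministic: cognate first, then position-major with substituting
    residues alphabetical.
    """
    cognate = as_peptide(cognate)
    seq = str(cognate)
    library = [cognate]
    for p in range(len(seq)):
        for aa in AMINO_ACIDS:
            if aa == seq[p]:
                continue
            library.append(Peptide(seq[:p] + aa + seq[p + 1 :]))
    return library


def make_length_frame_variants(
    context: EpitopeContext,
    min_len: int = 8,
    max_len: int = 10,
    max_shift: int = 1,
) -> list[Peptide]:
    """Frame-shifted and length variants of an epitope in its natural context.

    Produces (a) same-length windows shifted up/downstream by 1..max_shift
    residues, (b) truncations of the epitope down to ``min_len`` dropping
    residues from either end, and (c) extensions up to ``max_len`` adding
    natural flanking residues on either end.  Variants that would require
    sequence beyond the protein termini are omitted, never padded.  These
    peptides probe whether recognition genuinely requires the exact epitope
    register.
    """
    prot = context.protein_sequence
    L = len(context.epitope)
    off = context.epitope_offset
    variants: list[Peptide] = []
    seen: set[str] = {str(context.epitope)}

    def _add(start: int, length: int) -> None:
        if start < 0 or start + length > len(prot):
            return
        window = prot[start : start + length]
        if window in seen:
            return
        try:
            pep = Peptide(window)
        except ValueError:
            return  # non-canonical flank residue
        seen.add(window)
        variants.append(pep)

    for k in range(1, max_shift + 1):
        _add(off - k, L)
        _add(off + k, L)
    for length in range(min_len, max_len + 1):
        if length == L:
            continue
        if length < L:
            _add(off, length)              # drop from C-terminus
            _add(off + (L - length), length)  # drop from N-terminus
        else:
            _add(off - (length - L), length)  # extend N-terminally
            _add(off, length)                 # extend C-terminally
    return variants


def normalize_scan(
    raw: RawScanData,
    aggregation: str = "mean",
    blank: "np.ndarray | float | None" = None,
) -> PositionalScanMatrix:
    """Normalize raw responses to fraction-of-cognate and aggregate replicates.

    Each replicate is divided by its own cognate-peptide response before
    aggregation (default: mean of replicate-level normalized values), so
    inter-experiment scale differences cancel.  An optional ``blank``
    (per-replicate or scalar background, pg/ml) is subtracted from both the
    matrix and the cognate response first; negative values arising from
    blank subtraction are clamped to zero with a warning.  The cognate cell
    at each position is forced to exactly 1.0.
    """
    responses = raw.responses.astype(float).copy()
    cog = raw.cognate_responses.astype(float).copy()
    if blank is not None:
        blank_arr = np.broadcast_to(np.asarray(blank, dtype=float), cog.shape)
        responses = responses - blank_arr[:, None, None]
        cog = cog - blank_arr
    if np.any(cog <= 0):
        raise ValueError(
            f"cognate response must be positive in every replicate, got {cog.tolist()}"
        )
    if np.any(responses < 0):
        logger.warning("negative responses after blank subtraction clamped to 0")
        responses = np.clip(responses, 0.0, None)
    per_rep = responses / cog[:, None, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells handled below
        if aggregation == "mean":
            agg = np.nanmean(per_rep, axis=0)
        elif aggregation == "median":
            agg = np.nanmedian(per_rep, axis=0)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    if np.isnan(agg).any():
        n_missing = int(np.isnan(agg).sum())
        raise ValueError(f"{n_missing} matrix cell(s) missing in every replicate")
    L = raw.length
    norm = pd.DataFrame(agg, index=list(AMINO_ACIDS), columns=range(1, L + 1))
    cognate = Peptide(raw.cognate)
    for p, aa in enumerate(str(cognate), start=1):
        norm.loc[aa, p] = 1.0
    return PositionalScanMatrix(
        cognate=cognate,
        raw=raw.responses,
        cognate_response=raw.cognate_responses,
        normalized=norm,
    )


def build_fingerprint(
    matrix: PositionalScanMatrix, config: FingerprintConfig | None = None
) -> Fingerprint:
    """Threshold the normalized matrix into tolerated-residue sets.

    Residues with normalized response >= ``primary_cutoff`` enter the primary
    set; residues in [``extended_cutoff``, ``primary_cutoff``) the extended
    set.  Both thresholds are inclusive at their lower edge ("10% or more" is
    positive).  The cognate residue, normalized to 1.0, is always primary.
    """
    config = config or FingerprintConfig()
    primary, extended = [], []
    for p in range(1, matrix.length + 1):
        col = matrix.normalized[p]
        prim = frozenset(col.index[col >= config.primary_cutoff])
        ext = frozenset(
            col.index[(col >= config.extended_cutoff) & (col < config.primary_cutoff)]
        )
        primary.append(prim)
        extended.append(ext)
    return Fingerprint(
        cognate=matrix.cognate,
        primary_sets=tuple(primary),
        extended_sets=tuple(extended),
        primary_cutoff=config.primary_cutoff,
        extended_cutoff=config.extended_cutoff,
    )


def pattern_space_size(fingerprint: Fingerprint, include_extended: bool = False) -> int:
    """Number of distinct peptides matching the fingerprint's tolerated sets."""
    n = 1
    for p in range(len(fingerprint.cognate)):
        size = len(fingerprint.primary_sets[p])
        if include_extended:
            size += len(fingerprint.extended_sets[p])
        n *= size
    return n


def logo_weights(matrix: PositionalScanMatrix) -> pd.DataFrame:
    """Shannon information-content letter heights (bits) for a sequence logo.

    Per position p the normalized activities are renormalized to
    probabilities q(a); the information content is I(p) = log2(20) - H(q),
    and each residue's height is q(a) * I(p).  A position tolerating a single
    residue scores log2(20) ~ 4.32 bits on that residue; uniform tolerance
    scores zero everywhere.

    Raises
    ------
    ValueError
        If any position has no positive activity at all.
    """
    values = matrix.normalized.to_numpy(dtype=float)
    col_sums = values.sum(axis=0)
    if np.any(col_sums <= 0):
        dead = [int(p) for p, s in zip(matrix.normalized.columns, col_sums) if s <= 0]
        raise ValueError(f"position(s) {dead} have no positive activity")
    q = values / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(q > 0, q * np.log2(q), 0.0)
    entropy = -plogp.sum(axis=0)
    info = np.log2(20.0) - entropy
    heights = q * info
    return pd.DataFrame(
        heights, index=matrix.normalized.index, columns=matrix.normalized.columns
    )
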