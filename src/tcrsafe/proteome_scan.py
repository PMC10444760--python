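"""Degenerate-pattern proteome scanning.

A TCR fingerprint compiles to a degenerate pattern: one set of tolerated
residues per epitope position.  Scanning slides a window of the pattern
length over every protein and reports each window whose residue at every
position lies in that position's set -- the candidate cross-reactive
peptides.  Matching is exact set membership (a character-class regular
expression); windows containing non-canonical letters (X, U, B, Z, J, O)
never match, mirroring conservative motif-scanner behaviour.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .core import AMINO_ACID_SET, AMINO_ACIDS, Peptide, as_peptide, hamming_distance


@dataclass(frozen=True)
class DegeneratePattern:
    """An ordered list of non-empty tolerated-residue sets, one per position."""

    position_sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        sets = tuple(frozenset(s) for s in self.position_sets)
        if not sets:
            raise ValueError("pattern must have at least one position")
        for i, s in enumerate(sets):
            if not s:
                raise ValueError(f"position {i + 1}: empty residue set")
            bad = sorted(s - AMINO_ACID_SET)
            if bad:
                raise ValueError(
                    f"position {i + 1}: non-canonical residue(s) {', '.join(bad)}"
                )
        object.__setattr__(self, "position_sets", sets)

    def __len__(self) -> int:
        return len(self.position_sets)

    def matches(self, window: str) -> bool:
        """True if ``window`` (same length as the pattern) matches positionwise."""
        if len(window) != len(self):
            return False
        return all(c in s for c, s in zip(window.upper(), self.position_sets))

    @property
    def space_size(self) -> int:
        """Number of distinct peptides the pattern matches."""
        n = 1
        for s in self.position_sets:
            n *= len(s)
        return n


@dataclass
class CandidatePeptide:
    """A unique proteome peptide matching a TCR fingerprint.

    One candidate per distinct sequence; all source locations are aggregated
    in ``sources`` as (accession, 0-based offset) pairs.  Annotation fields
    are filled in downstream from predictor output and activation screens.
    """

    sequence: Peptide
    sources: list[tuple[str, int]]
    edit_distance: int
    predicted_affinity_nM: float | None = None
    percent_rank: float | None = None
    binder_class: str | None = None
    activation: str = "untested"


def fingerprint_to_pattern(fingerprint, include_extended: bool = False) -> DegeneratePattern:
    """Compile a fingerprint's tolerated sets into a degenerate pattern.

    With ``include_extended`` the lower-confidence (extended cut-off) residues
    are unioned in at every position, giving a strictly-not-smaller search
    space.
    """
    sets = []
    for p in range(len(fingerprint.cognate)):
        s = set(fingerprint.primary_sets[p])
        if include_extended:
            s |= set(fingerprint.extended_sets[p])
        sets.append(frozenset(s))
    return DegeneratePattern(tuple(sets))


def _compile(pattern: DegeneratePattern) -> re.Pattern:
    # capture inside a lookahead so overlapping matches are all found
    parts = []
    for s in pattern.position_sets:
        if len(s) == 1:
            parts.append(next(iter(s)))
        else:
            parts.append("[" + "".join(sorted(s)) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_proteome(
    pattern: DegeneratePattern,
    proteome: Sequence,
    cognate: "Peptide | str",
    exclude_cognate_protein: str | None = None,
) -> list[CandidatePeptide]:
    """Find every pattern-matching peptide in a proteome.

    Parameters
    ----------
    pattern : DegeneratePattern
        Compiled tolerated-residue sets.
    proteome : sequence of records
        Anything with ``accession`` and ``sequence`` attributes
        (:class:`tcrsafe.io_formats.ProteomeRecord`).
    cognate : Peptide or str
        The on-target epitope; its exact sequence is always excluded from
        the candidate list, and candidate edit distances are computed
        against it.
    exclude_cognate_protein : str, optional
        Accession whose windows are skipped entirely (the source antigen
        would otherwise trivially match its own fingerprint).

    Returns
    -------
    list of CandidatePeptide
        De-duplicated by sequence, sources aggregated, in order of first
        occurrence in the proteome.  Overlapping matches are all found.
    """
    if not proteome:
        raise ValueError("empty proteome")
    cognate = as_peptide(cognate)
    if len(cognate) != len(pattern):
        raise ValueError(
            f"cognate length {len(cognate)} does not match pattern length {len(pattern)}"
        )
    rx = _compile(pattern)
    hits: dict[str, CandidatePeptide] = {}
    for rec in proteome:
        if exclude_cognate_protein is not None and rec.accession == exclude_cognate_protein:
            continue
        seq = rec.sequence.upper()
        for m in rx.finditer(seq):
            window = m.group(1)
            if window == str(cognate):
                continue
            cand = hits.get(window)
            if cand is None:
                hits[window] = CandidatePeptide(
                    sequence=Peptide(window),
                    sources=[(rec.accession, m.start())],
                    edit_distance=hamming_distance(window, cognate),
                )
            else:
                cand.sources.append((rec.accession, m.start()))
    return list(hits.values())


class CrossSpeciesMatch(NamedTuple):
    """Closest equal-length window to a peptide in another proteome."""

    distance: int
    window: str
    accession: str
    offset: int


def cross_species_min_distance(
    candidate: "CandidatePeptide | Peptide | str", other_proteome: Sequence
) -> CrossSpeciesMatch:
    """Minimum Hamming distance from a peptide to any window of another proteome.

    Used to ask whether a candidate off-target has a close homologue in a
    second species (e.g. mouse), which determines whether an animal model can
    report on that cross-reactivity at all.  Ties are broken by first
    occurrence in file order.  Non-canonical letters in the proteome count as
    mismatches.
    """
    seq = str(candidate.sequence if isinstance(candidate, CandidatePeptide) else candidate).upper()
    L = len(seq)
    best: CrossSpeciesMatch | None = None
    for rec in other_proteome:
        prot = rec.sequence.upper()
        for off in range(len(prot) - L + 1):
            window = prot[off : off + L]
            d = sum(x != y for x, y in zip(window, seq))
            if best is None or d < best.distance:
                best = CrossSpeciesMatch(d, window, rec.accession, off)
                if d == 0:
                    return best
    if best is None:
        raise ValueError(f"no window of length {L} in the comparison proteome")
    return best
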