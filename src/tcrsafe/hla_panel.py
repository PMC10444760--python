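"""Unintended-HLA screening: allele implication and population prevalence.

A TCR restricted to one HLA allele may react to structurally similar alleles
presenting irrelevant peptides (allo-reactivity).  Screening against a panel
of HLA-typed lymphoblastoid cell lines implicates alleles by set arithmetic:
an allele is implicated when it appears in a reactive line and in no
non-reactive line.  This is a presence/absence argument -- an allele carried
by any non-reactive line is exonerated, which can mask alleles whose response
falls below the reactive-call threshold.

Population impact of implicated alleles is computed under Hardy-Weinberg
equilibrium: the probability of carrying at least one copy of an allele with
frequency f is 1 - (1 - f)^2, a set of alleles at one locus covers
1 - (1 - sum f)^2 of the population, and loci combine by independence
(linkage disequilibrium is ignored, as in standard carrier calculators).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_ALLELE_RE = re.compile(r"^([A-Z]+[0-9]*)\*(\d+):(\d+)$")


def normalize_allele(name: str) -> str:
    """Canonicalize an HLA class-I allele name to e.g. 'A*02:06'.

    Accepts 'HLA-A*02:06', 'a*2:6' and similar variants; the optional
    'HLA-' prefix is stripped, the locus upper-cased and the two numeric
    fields zero-padded to two digits.
    """
    s = name.strip().upper()
    if s.startswith("HLA-"):
        s = s[4:]
    m = _ALLELE_RE.match(s)
    if not m:
        raise ValueError(f"cannot parse HLA allele name {name!r}")
    locus, f1, f2 = m.groups()
    return f"{locus}*{int(f1):02d}:{int(f2):02d}"


def allele_locus(allele: str) -> str:
    """Locus of a (normalized) allele name, e.g. 'A' for 'A*02:06'."""
    return normalize_allele(allele).split("*", 1)[0]


@dataclass
class PanelLine:
    """One HLA-typed cell line of the screening panel.

    ``reactive`` is the qualitative reactivity call (user-supplied or derived
    from the 10%-of-positive-control rule); ``killing_survival`` is the
    optional fraction of target cells surviving relative to mock effectors;
    ``antigen_positive`` marks lines expressing the TCR's target antigen, in
    which case cognate-peptide presentation on an implicated allele cannot be
    excluded as the cause of reactivity.
    """

    line_id: str
    alleles: frozenset[str]
    response: float
    reactive: bool
    killing_survival: float | None = None
    antigen_positive: bool = False

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"line {self.line_id}: empty allele set")
        self.alleles = frozenset(normalize_allele(a) for a in self.alleles)


def implicate_alleles(
    panel: Sequence[PanelLine],
) -> tuple[set[str], pd.DataFrame]:
    """Implicate cross-reactive alleles from panel reactivity.

    Implicated alleles are those carried by at least one reactive line and by
    no non-reactive line.  Returns the implicated set and an evidence table
    with, per implicated allele, the supporting reactive lines and whether
    every supporting line also expresses the target antigen (confounded: the
    reactivity could be cognate peptide on that allele rather than true
    allo-reactivity).

    An empty implicated set (no reactive lines) is a valid result, not an
    error.
    """
    if not panel:
        raise ValueError("empty panel")
    reactive = [ln for ln in panel if ln.reactive]
    nonreactive = [ln for ln in panel if not ln.reactive]
    candidate = set().union(*(ln.alleles for ln in reactive)) if reactive else set()
    exonerated = set().union(*(ln.alleles for ln in nonreactive)) if nonreactive else set()
    implicated = candidate - exonerated
    rows = []
    for allele in sorted(implicated):
        supporting = [ln for ln in reactive if allele in ln.alleles]
        rows.append(
            {
                "allele": allele,
                "locus": allele_locus(allele),
                "supporting_lines": ";".join(ln.line_id for ln in supporting),
                "n_supporting": len(supporting),
                "max_response": max(ln.response for ln in supporting),
                "confounded": all(ln.antigen_positive for ln in supporting),
            }
        )
    evidence = pd.DataFrame(
        rows,
        columns=[
            "allele",
            "locus",
            "supporting_lines",
            "n_supporting",
            "max_response",
            "confounded",
        ],
    )
    return implicated, evidence


def normalize_killing(
    target_counts: Sequence[float], mock_counts: Sequence[float]
) -> np.ndarray:
    """Survival fractions: per-well target counts over the mean mock count.

    Killing is 1 - survival; survival > 1 (more targets than mock) is left
    as-is, it simply means no killing.
    """
    mock = np.asarray(mock_counts, dtype=float)
    if mock.size == 0 or mock.mean() <= 0:
        raise ValueError("mean mock count must be positive")
    return np.asarray(target_counts, dtype=float) / mock.mean()


def hw_carrier_prevalence(freq: "float | Iterable[float]") -> float:
    """Hardy-Weinberg carrier prevalence of one allele or an allele set.

    For a single allele frequency f the probability that a random diploid
    individual carries at least one copy is 1 - (1 - f)^2 = 2f - f^2.  For a
    set of mutually exclusive alleles at one locus, f is replaced by the sum
    of their frequencies.
    """
    if isinstance(freq, (int, float)):
        total = float(freq)
    else:
        fs = [float(f) for f in freq]
        for f in fs:
            if not 0 <= f <= 1:
                raise ValueError(f"frequency {f} outside [0, 1]")
        total = sum(fs)
    if not -1e-9 <= total <= 1 + 1e-9:
        raise ValueError(f"summed allele frequency {total} outside [0, 1]")
    total = min(max(total, 0.0), 1.0)
    return 1.0 - (1.0 - total) ** 2


def combined_carrier_prevalence(per_locus_freq_sums: Mapping[str, float]) -> float:
    """Probability of carrying at least one implicated allele at any locus.

    Loci are combined by independence: 1 - prod over loci of (1 - sum f)^2.
    """
    p_none = 1.0
    for locus, total in per_locus_freq_sums.items():
        if not 0 <= total <= 1 + 1e-9:
            raise ValueError(f"locus {locus}: summed frequency {total} outside [0, 1]")
        p_none *= (1.0 - min(total, 1.0)) ** 2
    return 1.0 - p_none


class AlleleFrequencyTable:
    """Per-population HLA allele frequencies.

    Backed by a long-format table (population, allele, frequency); reads the
    TSV dialect ``population<TAB>allele<TAB>frequency``.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"population", "allele", "frequency"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"frequency table missing column(s): {sorted(missing)}")
        frame = frame.copy()
        frame["allele"] = frame["allele"].map(normalize_allele)
        bad = frame[(frame["frequency"] < 0) | (frame["frequency"] > 1)]
        if len(bad):
            raise ValueError(f"frequencies outside [0, 1]:\n{bad}")
        self.frame = frame

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "AlleleFrequencyTable":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population"].unique())

    def frequencies(self, population: str) -> dict[str, float]:
        sub = self.frame[self.frame["population"] == population]
        if sub.empty:
            raise KeyError(
                f"unknown population {population!r}; available: {self.populations}"
            )
        return dict(zip(sub["allele"], sub["frequency"]))

    def prevalence(self, alleles: Iterable[str], population: str) -> dict:
        """Carrier prevalence of an allele set: per allele, per locus, combined.

        Alleles absent from the table contribute zero frequency (and are
        listed under 'missing').
        """
        freqs = self.frequencies(population)
        alleles = [normalize_allele(a) for a in alleles]
        per_allele = {a: hw_carrier_prevalence(freqs.get(a, 0.0)) for a in alleles}
        per_locus_sum: dict[str, float] = {}
        for a in alleles:
            per_locus_sum.setdefault(allele_locus(a), 0.0)
            per_locus_sum[allele_locus(a)] += freqs.get(a, 0.0)
        per_locus = {
            locus: hw_carrier_prevalence(total)
            for locus, total in per_locus_sum.items()
        }
        return {
            "population": population,
            "per_allele": per_allele,
            "per_locus": per_locus,
            "combined": combined_carrier_prevalence(per_locus_sum),
            "missing": sorted(a for a in alleles if a not in freqs),
        }


def panel_coverage(
    panel: Sequence[PanelLine],
    freq_table: AlleleFrequencyTable,
    population: str,
) -> dict:
    """Fraction of a population carrying at least one allele of the panel.

    Per locus this is the Hardy-Weinberg carrier prevalence of the union of
    panel alleles at that locus; the combined value treats loci as
    independent.  Quantifies how much of the population the screening panel
    can speak for.
    """
    freqs = freq_table.frequencies(population)
    panel_alleles = set().union(*(ln.alleles for ln in panel)) if panel else set()
    per_locus_sum: dict[str, float] = {}
    for allele in panel_alleles:
        locus = allele_locus(allele)
        per_locus_sum[locus] = per_locus_sum.get(locus, 0.0) + freqs.get(allele, 0.0)
    per_locus = {
        locus: hw_carrier_prevalence(min(total, 1.0))
        for locus, total in per_locus_sum.items()
    }
    combined = combined_carrier_prevalence(
        {locus: min(total, 1.0) for locus, total in per_locus_sum.items()}
    )
    return {"population": population, "per_locus": per_locus, "combined": combined}


# ---------------------------------------------------------------------------
# Supertypes

_SUPERTYPES: dict[str, str] | None = None


def _load_bundled_supertypes() -> dict[str, str]:
    global _SUPERTYPES
    if _SUPERTYPES is None:
        table = {}
        text = (
            resources.files("tcrsafe").joinpath("data/hla_supertypes.tsv").read_text()
        )
        reader = csv.DictReader(text.splitlines(), delimiter="\t")
        for row in reader:
            table[normalize_allele(row["allele"])] = row["supertype"]
        _SUPERTYPES = table
    return _SUPERTYPES


def supertype_lookup(
    allele: str, supertype_table: Mapping[str, str] | None = None
) -> str:
    """Supertype label of an HLA class-I allele, or 'unassigned'.

    Uses the bundled functional-supertype mapping by default; pass a custom
    allele -> supertype mapping to replace it.  Lookup is format-normalized,
    so 'HLA-A*02:06' and 'A*02:06' resolve identically.
    """
    table = (
        {normalize_allele(k): v for k, v in supertype_table.items()}
        if supertype_table is not None
        else _load_bundled_supertypes()
    )
    return table.get(normalize_allele(allele), "unassigned")


# ---------------------------------------------------------------------------
# Panel TSV I/O

PANEL_COLUMNS = ["line_id", "A1", "A2", "B1", "B2", "C1", "C2",
                 "response", "reactive", "antigen_positive"]


def read_panel(path: "str | Path") -> list[PanelLine]:
    """Read a panel TSV (line_id, A1..C2, response, reactive, antigen_positive).

    Empty allele cells are allowed (homozygous or untyped loci); the
    ``killing_survival`` column is optional.
    """
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing column(s): {sorted(missing)}")
    lines = []
    for _, row in df.iterrows():
        alleles = frozenset(
            str(row[c])
            for c in ["A1", "A2", "B1", "B2", "C1", "C2"]
            if isinstance(row[c], str) and row[c].strip()
        )
        killing = None
        if "killing_survival" in df.columns and pd.notna(row["killing_survival"]):
            killing = float(row["killing_survival"])
        lines.append(
            PanelLine(
                line_id=str(row["line_id"]),
                alleles=alleles,
                response=float(row["response"]),
                reactive=bool(row["reactive"]),
                killing_survival=killing,
                antigen_positive=bool(row["antigen_positive"]),
            )
        )
    return lines


def write_panel(lines: Sequence[PanelLine], path: "str | Path") -> None:
    """Write panel lines in the TSV dialect read by :func:`read_panel`."""
    rows = []
    for ln in lines:
        by_locus: dict[str, list[str]] = {"A": [], "B": [], "C": []}
        for a in sorted(ln.alleles):
            by_locus.setdefault(allele_locus(a), []).append(a)
        row = {"line_id": ln.line_id}
        for locus in ["A", "B", "C"]:
            alleles = by_locus.get(locus, [])
            row[f"{locus}1"] = alleles[0] if len(alleles) > 0 else ""
            row[f"{locus}2"] = alleles[1] if len(alleles) > 1 else ""
        row["response"] = ln.response
        row["reactive"] = ln.reactive
        row["antigen_positive"] = ln.antigen_positive
        if ln.killing_survival is not None:
            row["killing_survival"] = ln.killing_survival
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
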