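"""Synthetic data with ground truth for every pipeline stage.

Generators emulate the study conditions the pipeline is built for: a noisy
ELISA positional-scan matrix over a planted tolerance profile (three
replicates, multiplicative lognormal noise), random proteomes with candidate
off-target peptides spliced in at known coordinates, and HLA-typed panels
with one planted cross-reactive allele.  Every generator is a pure function
of its parameters and seed, and returns the planted truth alongside the
data so recovery can be asserted exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import AA_INDEX, AMINO_ACIDS, Peptide, as_peptide
from .hla_panel import PanelLine, allele_locus, normalize_allele
from .io_formats import ProteomeRecord, RawScanData

#: Approximate residue frequencies of a vertebrate proteome (sums to 1).
HUMAN_LIKE_FREQUENCIES: dict[str, float] = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset.

    ``true_activity`` is a 20 x L array of noiseless fraction-of-cognate
    activities (cognate residues exactly 1); ``tolerated_sets`` the residue
    sets at the 10% cut-off that a perfect fingerprint should recover.
    """

    cognate: Peptide
    true_activity: np.ndarray
    tolerated_sets: tuple[frozenset[str], ...]
    planted_offtargets: list[tuple[str, str, int]] = field(default_factory=list)
    planted_allele: str | None = None
    seed: int = 0


def random_tolerance_profile(
    cognate: "Peptide | str",
    seed: int,
    extra_tolerated_range: tuple[int, int] = (0, 3),
    high_activity_range: tuple[float, float] = (0.2, 1.0),
    low_activity_max: float = 0.02,
) -> SyntheticTruth:
    """Draw a ground-truth activity profile with well-separated classes.

    Cognate residues have activity 1.  Each position additionally tolerates
    0-3 random residues with activity in [0.2, 1.0]; all other residues get
    activity in [0, 0.02].  Both classes sit far from the 5% and 10%
    cut-offs, so a correct fingerprint under moderate noise must recover the
    planted sets exactly.
    """
    cognate = as_peptide(cognate)
    rng = np.random.default_rng(seed)
    L = len(cognate)
    activity = np.empty((20, L))
    tolerated: list[frozenset[str]] = []
    for p in range(L):
        activity[:, p] = rng.uniform(0.0, low_activity_max, size=20)
        cog_aa = cognate[p]
        others = [aa for aa in AMINO_ACIDS if aa != cog_aa]
        n_extra = int(rng.integers(extra_tolerated_range[0], extra_tolerated_range[1] + 1))
        extra = list(rng.choice(others, size=n_extra, replace=False)) if n_extra else []
        for aa in extra:
            activity[AA_INDEX[aa], p] = rng.uniform(*high_activity_range)
        activity[AA_INDEX[cog_aa], p] = 1.0
        tolerated.append(frozenset([cog_aa, *extra]))
    return SyntheticTruth(
        cognate=cognate,
        true_activity=activity,
        tolerated_sets=tuple(tolerated),
        seed=seed,
    )


def simulate_scan_matrix(
    truth: SyntheticTruth,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    cognate_level_pg_ml: float = 2690.0,
    seed: int | None = None,
) -> RawScanData:
    """Simulate replicate ELISA readouts of a positional scan.

    Raw responses are cognate_level * true_activity * eps, where eps is
    lognormal with mean 1 and coefficient of variation ``noise_cv``
    (multiplicative, ELISA-like heteroscedastic noise).  The per-replicate
    cognate response receives independent noise of the same kind.  With
    ``noise_cv = 0`` normalization recovers the true activities exactly.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    if cognate_level_pg_ml <= 0:
        raise ValueError(f"cognate level must be positive, got {cognate_level_pg_ml}")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    L = len(truth.cognate)

    def _noise(size) -> np.ndarray:
        if noise_cv == 0:
            return np.ones(size)
        sigma2 = math.log(1.0 + noise_cv**2)
        mu = -sigma2 / 2.0  # mean-1 lognormal
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)

    responses = (
        cognate_level_pg_ml
        * truth.true_activity[None, :, :]
        * _noise((n_replicates, 20, L))
    )
    cognate_responses = cognate_level_pg_ml * _noise(n_replicates)
    return RawScanData(
        cognate=str(truth.cognate),
        responses=responses,
        cognate_responses=cognate_responses,
    )


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    planted: Sequence[tuple["Peptide | str", int, int]] = (),
    background_frequencies: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[ProteomeRecord], list[tuple[str, str, int]]]:
    """Random proteome with peptides planted at exact coordinates.

    Background residues are i.i.d. from ``background_frequencies`` (uniform
    1/20 by default; :data:`HUMAN_LIKE_FREQUENCIES` is a bundled preset).
    ``planted`` lists (peptide, protein_index, offset) triples; plants must
    fit inside their protein and not overlap one another.  Returns the
    records plus the planted truth as (peptide, accession, offset).
    """
    rng = np.random.default_rng(seed)
    if background_frequencies is None:
        probs = np.full(20, 1.0 / 20.0)
    else:
        probs = np.array([background_frequencies[aa] for aa in AMINO_ACIDS])
        probs = probs / probs.sum()
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    alphabet = np.array(list(AMINO_ACIDS))
    seqs = ["".join(rng.choice(alphabet, size=n, p=probs)) for n in lengths]
    occupied: dict[int, list[tuple[int, int]]] = {}
    truth: list[tuple[str, str, int]] = []
    for pep, prot_idx, offset in planted:
        pep = str(as_peptide(pep))
        if not 0 <= prot_idx < n_proteins:
            raise ValueError(f"protein index {prot_idx} out of range")
        if offset < 0 or offset + len(pep) > lengths[prot_idx]:
            raise ValueError(
                f"plant {pep} at offset {offset} exceeds protein {prot_idx} "
                f"of length {lengths[prot_idx]}"
            )
        for start, end in occupied.get(prot_idx, []):
            if offset < end and start < offset + len(pep):
                raise ValueError(
                    f"plant {pep} at offset {offset} overlaps an earlier plant"
                )
        occupied.setdefault(prot_idx, []).append((offset, offset + len(pep)))
        seq = seqs[prot_idx]
        seqs[prot_idx] = seq[:offset] + pep + seq[offset + len(pep) :]
        truth.append((pep, f"SYN{prot_idx + 1:04d}", offset))
    records = [
        ProteomeRecord(f"SYN{i + 1:04d}", f"synthetic protein {i + 1}", seq)
        for i, seq in enumerate(seqs)
    ]
    return records, truth


DEFAULT_ALLELE_POOL: tuple[str, ...] = (
    "A*01:01", "A*02:01", "A*02:03", "A*02:06", "A*03:01", "A*11:01",
    "A*24:02", "A*26:01", "A*32:01", "A*68:01",
    "B*07:02", "B*08:01", "B*15:01", "B*18:01", "B*27:05", "B*35:01",
    "B*40:01", "B*44:02", "B*51:01", "B*57:01",
    "C*01:02", "C*03:04", "C*04:01", "C*05:01", "C*06:02", "C*07:01",
    "C*07:02", "C*08:02", "C*12:03", "C*16:01",
)


def simulate_panel(
    n_lines: int,
    planted_allele: str,
    allele_pool: Sequence[str] = DEFAULT_ALLELE_POOL,
    seed: int = 0,
    carrier_fraction: float = 0.25,
    reactive_level_pg_ml: float = 2000.0,
    baseline_level_pg_ml: float = 20.0,
    noise_cv: float = 0.2,
) -> tuple[list[PanelLine], SyntheticTruth]:
    """Simulate an HLA-typed cell-line panel with one cross-reactive allele.

    Each line draws two alleles per locus (A, B, C) from the pool.  Lines
    carrying the planted allele respond at ``reactive_level_pg_ml`` (times
    lognormal noise) and are called reactive; all other lines sit at
    baseline.  At least one carrier and one non-carrier are guaranteed, so
    implication always has both positive and negative evidence.
    """
    if n_lines < 3:
        raise ValueError(f"need at least 3 lines, got {n_lines}")
    planted_allele = normalize_allele(planted_allele)
    pool = [normalize_allele(a) for a in allele_pool]
    if planted_allele not in pool:
        raise ValueError(f"planted allele {planted_allele} not in pool")
    by_locus: dict[str, list[str]] = {}
    for a in pool:
        by_locus.setdefault(allele_locus(a), []).append(a)
    for locus, alleles in by_locus.items():
        if len(alleles) < 2:
            raise ValueError(f"pool has fewer than 2 alleles at locus {locus}")
    planted_locus = allele_locus(planted_allele)
    rng = np.random.default_rng(seed)
    carriers = rng.random(n_lines) < carrier_fraction
    if not carriers.any():
        carriers[int(rng.integers(n_lines))] = True
    if carriers.all():
        carriers[int(rng.integers(n_lines))] = False

    sigma2 = math.log(1.0 + noise_cv**2)
    mu_shift = -sigma2 / 2.0

    lines: list[PanelLine] = []
    for i in range(n_lines):
        alleles: set[str] = set()
        for locus, pool_here in by_locus.items():
            if locus == planted_locus:
                others = [a for a in pool_here if a != planted_allele]
                if carriers[i]:
                    picked = [planted_allele, str(rng.choice(others))]
                else:
                    picked = list(rng.choice(others, size=2, replace=False))
            else:
                picked = list(rng.choice(pool_here, size=2, replace=False))
            alleles.update(picked)
        level = reactive_level_pg_ml if carriers[i] else baseline_level_pg_ml
        noise = rng.lognormal(mean=mu_shift, sigma=math.sqrt(sigma2))
        lines.append(
            PanelLine(
                line_id=f"LCL{i + 1:03d}",
                alleles=frozenset(alleles),
                response=level * noise,
                reactive=bool(carriers[i]),
            )
        )
    truth = SyntheticTruth(
        cognate=Peptide("SLLMWITQC"),
        true_activity=np.zeros((20, 9)),
        tolerated_sets=tuple(),
        planted_allele=planted_allele,
        seed=seed,
    )
    return lines, truth
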