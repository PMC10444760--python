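"""Candidate annotation: binder classes, activation calls, statistics, constructs.

Predicted MHC-I binding is classified from the predictor's %rank with the
conventional strict thresholds (<0.5 strong, <2 weak).  Measured activation
uses the same inclusive 10%-of-cognate rule as fingerprinting.  Group
comparisons (e.g. edit distance of activating vs non-activating candidates)
use a two-sided Mann-Whitney U test with an exact small-sample path.
Validation constructs -- a 30-residue minigene with the epitope embedded in
natural flanking sequence, and an epitope-linker trimer cassette -- are
designed from the epitope's source-protein context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .core import EpitopeContext, Peptide, as_peptide
from .io_formats import BindingPrediction


@dataclass
class BinderClassConfig:
    """%rank thresholds for strong/weak binder classification (both strict <)."""

    strong_rank_cutoff: float = 0.5
    weak_rank_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.strong_rank_cutoff < self.weak_rank_cutoff:
            raise ValueError(
                "need 0 < strong < weak, got "
                f"strong={self.strong_rank_cutoff}, weak={self.weak_rank_cutoff}"
            )


def classify_binder(
    prediction: BindingPrediction, config: BinderClassConfig | None = None
) -> str:
    """Classify a prediction as 'strong', 'weak' or 'none' by %rank.

    Strict inequalities: rank < 0.5 is strong, 0.5 <= rank < 2 is weak,
    rank >= 2 is a non-binder.
    """
    config = config or BinderClassConfig()
    rank = prediction.percent_rank
    if rank < config.strong_rank_cutoff:
        return "strong"
    if rank < config.weak_rank_cutoff:
        return "weak"
    return "none"


def classify_activation(normalized_response: float, cutoff: float = 0.10) -> str:
    """Call a peptide activating iff its response reaches ``cutoff`` of cognate.

    The boundary is inclusive: a response of exactly 10% of the cognate
    response counts as activating/cross-recognized.
    """
    if normalized_response < 0:
        raise ValueError(f"normalized response must be >= 0, got {normalized_response}")
    return "activating" if normalized_response >= cutoff else "non_activating"


@dataclass
class DoseResponse:
    """Normalized activation of one peptide across a concentration titration."""

    peptide: Peptide
    points: list[tuple[float, float]]  # (concentration in M, fraction-of-cognate)

    def __post_init__(self) -> None:
        self.peptide = as_peptide(self.peptide)
        for conc, resp in self.points:
            if conc <= 0:
                raise ValueError(f"concentration must be positive, got {conc}")
            if resp < 0:
                raise ValueError(f"response must be >= 0, got {resp}")


def screen_dose_response(
    dr: DoseResponse,
    screen_concentration: float = 1e-7,
    cutoff: float = 0.10,
) -> tuple[list[tuple[float, str]], str]:
    """Per-concentration activation calls plus the overall screening call.

    The overall call is taken at ``screen_concentration`` (nearest tested
    concentration within 1% relative tolerance).  Candidates are screened at
    a deliberately high concentration so weak cross-reactivities are not
    missed.
    """
    calls = [(conc, classify_activation(resp, cutoff)) for conc, resp in dr.points]
    best = None
    for conc, call in calls:
        if math.isclose(conc, screen_concentration, rel_tol=0.01):
            best = call
            break
    if best is None:
        available = sorted({c for c, _ in dr.points})
        raise ValueError(
            f"screen concentration {screen_concentration:g} M not among tested "
            f"concentrations {[f'{c:g}' for c in available]}"
        )
    return calls, best


# ---------------------------------------------------------------------------
# Statistics


@dataclass(frozen=True)
class GroupTestResult:
    """Two-sided Mann-Whitney U result with the method actually used."""

    U: float
    p_two_sided: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approximation"


def _pair_count_u(a: Sequence[float], b: Sequence[float]) -> float:
    """U statistic for group a: pairs (x, y) with x > y, ties counting 1/2."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], method: str = "auto"
) -> GroupTestResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    For untied pooled samples with n1 + n2 <= 20 the p-value is exact: all
    C(n1+n2, n1) group labelings are enumerated and the two-sided p is the
    fraction of labelings with |U - n1*n2/2| at least as large as observed.
    Otherwise a mid-rank normal approximation with tie correction and
    continuity correction is used and flagged in ``method``.  Degenerate
    pooled data with zero rank variance yields p = 1.  ``method`` may force
    either path ('exact' requires untied data and n1 + n2 <= 20).
    """
    if method not in {"auto", "exact", "normal_approximation"}:
        raise ValueError(f"unknown method {method!r}")
    a = [float(x) for x in values_a]
    b = [float(x) for x in values_b]
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError(f"both groups must be non-empty, got sizes {n1} and {n2}")
    pooled = a + b
    u_obs = _pair_count_u(a, b)
    untied = len(set(pooled)) == len(pooled)
    exact_ok = untied and n1 + n2 <= 20
    if method == "exact" and not exact_ok:
        raise ValueError(
            "exact method requires untied pooled data with n1 + n2 <= 20"
        )
    if exact_ok and method in {"auto", "exact"}:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        total = math.comb(n, n1)
        extreme = 0
        dev_obs = abs(u_obs - mu)
        for idx_a in combinations(range(n), n1):
            set_a = set(idx_a)
            u = 0
            for i in idx_a:
                for j in range(n):
                    if j not in set_a and pooled[i] > pooled[j]:
                        u += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                extreme += 1
        return GroupTestResult(
            U=u_obs, p_two_sided=extreme / total, n1=n1, n2=n2, method="exact"
        )
    # mid-rank normal approximation with tie and continuity corrections
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return GroupTestResult(
            U=u_obs, p_two_sided=1.0, n1=n1, n2=n2, method="normal_approximation"
        )
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return GroupTestResult(
        U=u_obs, p_two_sided=p, n1=n1, n2=n2, method="normal_approximation"
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> float:
    """Correlation between two equal-length response vectors.

    Pearson product-moment by default (the readouts being correlated --
    IFN-gamma and activation-marker levels -- are continuous measurements on
    a common scale); Spearman rank correlation available via ``method``.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.var(xa) == 0 or np.var(ya) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        return float(stats.pearsonr(xa, ya).statistic)
    if method == "spearman":
        return float(stats.spearmanr(xa, ya).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


# ---------------------------------------------------------------------------
# Validation constructs


@dataclass
class MinigeneConstruct:
    """A short coding construct embedding an epitope in natural flanks.

    ``aa_sequence`` is the amino-acid window taken verbatim from the source
    protein; a reporter tag (e.g. GFP) is metadata only and never enters the
    window.  ``truncated`` flags proteins too short for the requested length.
    """

    aa_sequence: str
    total_length: int
    epitope_start: int
    source: EpitopeContext
    tag: str | None = None
    truncated: bool = False


def design_minigene(
    context: EpitopeContext,
    total_length: int = 30,
    upstream_flank: int = 10,
    tag: str | None = None,
) -> MinigeneConstruct:
    """Design a minigene placing the epitope near the middle of a 30-mer.

    Default layout for a 9-mer epitope: 10 natural upstream residues, the
    epitope, then natural downstream residues to fill ``total_length`` (11
    for the default 30).  Near a protein terminus the deficit on one side is
    taken from the other so the total length is preserved; if the whole
    protein is shorter than ``total_length`` the construct is the maximal
    window and flagged ``truncated``.
    """
    prot = context.protein_sequence
    L = len(context.epitope)
    off = context.epitope_offset
    if total_length < L:
        raise ValueError(
            f"total_length {total_length} shorter than epitope length {L}"
        )
    avail_up = off
    avail_down = len(prot) - off - L
    up = min(upstream_flank, avail_up)
    down = total_length - L - up
    if down > avail_down:
        deficit = down - avail_down
        down = avail_down
        up = min(up + deficit, avail_up)
    start = off - up
    window = prot[start : start + up + L + down]
    truncated = len(window) < total_length
    return MinigeneConstruct(
        aa_sequence=window,
        total_length=len(window),
        epitope_start=up,
        source=context,
        tag=tag,
        truncated=truncated,
    )


def design_trimer_minigene(epitope: "Peptide | str", linker: str = "AAY") -> str:
    """Epitope followed by a proteasomal-liberation linker (default AAY).

    The AAY linker promotes cleavage at the epitope's C-terminus when the
    cassette is expressed as a polypeptide, e.g. 'SLFLGILSV' -> 'SLFLGILSVAAY'.
    """
    return str(as_peptide(epitope)) + linker.upper()


def tumor_volume(a: float, b: float, c: float) -> float:
    """Ellipsoid tumor volume pi/6 * a * b * c from three caliper diameters (mm)."""
    if a < 0 or b < 0 or c < 0:
        raise ValueError(f"dimensions must be non-negative, got {(a, b, c)}")
    return math.pi / 6.0 * a * b * c


def annotate_candidates(
    candidates,
    predictions: Sequence[BindingPrediction] = (),
    activation_responses: "dict[str, float] | None" = None,
    binder_config: BinderClassConfig | None = None,
    activation_cutoff: float = 0.10,
):
    """Fill binder class and activation status on candidates in place.

    ``predictions`` are matched to candidates by peptide sequence (any
    allele); ``activation_responses`` maps peptide -> normalized response.
    Returns the candidate list for chaining.
    """
    by_pep = {p.peptide: p for p in predictions}
    for cand in candidates:
        pred = by_pep.get(str(cand.sequence))
        if pred is not None:
            cand.predicted_affinity_nM = pred.affinity_nM
            cand.percent_rank = pred.percent_rank
            cand.binder_class = classify_binder(pred, binder_config)
        if activation_responses and str(cand.sequence) in activation_responses:
            cand.activation = classify_activation(
                activation_responses[str(cand.sequence)], activation_cutoff
            )
    return candidates
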