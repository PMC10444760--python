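import numpy as np
import pytest

from tcrsafe.core import AMINO_ACIDS
from tcrsafe.io_formats import ProteomeRecord, RawScanData
from tcrsafe.proteome_scan import DegeneratePattern


@pytest.fixture
def rng():
    return np.random.default_rng(20230822)


@pytest.fixture
def random_peptide(rng):
    def make(length=9):
        return "".join(rng.choice(list(AMINO_ACIDS), size=length))

    return make


@pytest.fixture
def random_pattern(rng):
    """Random degenerate pattern with position-set sizes mostly 1-4."""

    def make(length=9, max_set_size=4):
        sets = []
        for _ in range(length):
            k = int(rng.integers(1, max_set_size + 1))
            sets.append(frozenset(rng.choice(list(AMINO_ACIDS), size=k, replace=False)))
        return DegeneratePattern(tuple(sets))

    return make


@pytest.fixture
def random_proteome(rng):
    """Random proteome as ProteomeRecord list, possibly with rare 'X' letters."""

    def make(n_proteins=8, min_len=50, max_len=200, x_rate=0.0):
        letters = list(AMINO_ACIDS)
        records = []
        for i in range(n_proteins):
            n = int(rng.integers(min_len, max_len + 1))
            seq = list(rng.choice(letters, size=n))
            if x_rate:
                mask = rng.random(n) < x_rate
                for j in np.flatnonzero(mask):
                    seq[j] = "X"
            records.append(ProteomeRecord(f"P{i:03d}", f"random {i}", "".join(seq)))
        return records

    return make


def naive_scan(pattern, proteome, cognate=None, exclude_accession=None):
    """Independent double-loop membership oracle for proteome scanning."""
    hits = {}
    L = len(pattern.position_sets)
    for rec in proteome:
        if exclude_accession is not None and rec.accession == exclude_accession:
            continue
        seq = rec.sequence.upper()
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            ok = True
            for c, allowed in zip(window, pattern.position_sets):
                if c not in allowed:
                    ok = False
                    break
            if not ok:
                continue
            if cognate is not None and window == str(cognate):
                continue
            hits.setdefault(window, []).append((rec.accession, off))
    return hits


@pytest.fixture
def make_scan_data():
    """Assemble a RawScanData directly from a normalized-activity array."""

    def make(cognate, activity, cognate_level=1000.0, n_replicates=1):
        activity = np.asarray(activity, dtype=float)
        responses = np.repeat(
            (cognate_level * activity)[None, :, :], n_replicates, axis=0
        )
        return RawScanData(
            cognate=cognate,
            responses=responses,
            cognate_responses=np.full(n_replicates, cognate_level),
        )

    return make
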