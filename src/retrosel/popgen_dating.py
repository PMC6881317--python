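"""Neutrality testing, pairwise Ka/Ks, and synonymous-clock dating.

Tajima's D contrasts mean pairwise nucleotide diversity with the
segregating-sites estimator (Watterson's theta = ps/a1) after complete
deletion of gapped columns.  Ka and Ks come from the Nei-Gojobori (1986)
pathway-counting method with Jukes-Cantor correction; ages follow the
synonymous molecular clock T = Ks / (2r) with the rice rate
r = 6.5e-9 substitutions per site per year.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .genetic_code import STOP_CODONS, translate_codon
from .seq_tree_io import CodonAlignment

RICE_SYNONYMOUS_RATE = 6.5e-9  # substitutions / synonymous site / year
_DNA = set("ACGT")


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


@dataclass
class TajimaResult:
    m: int  # number of sequences
    n_sites: int  # nucleotide sites compared (complete deletion)
    S: int  # segregating sites
    ps: float  # S / n_sites
    a1: float  # sum_{i<m} 1/i
    theta: float  # Watterson estimator per site, ps / a1
    pi: float  # mean pairwise diversity per site
    D: float | None  # Tajima statistic; None when S == 0
    note: str = ""


def harmonic_a1(m: int) -> float:
    """a1 = sum of 1/i for i = 1 .. m-1."""
    if m < 2:
        raise ValueError("need at least 2 sequences")
    return float(sum(1.0 / i for i in range(1, m)))


def watterson_theta(ps: float, m: int) -> float:
    """Watterson's estimator per site from the segregating-site fraction."""
    return ps / harmonic_a1(m)


def _as_nucleotide_rows(aln) -> list[str]:
    if isinstance(aln, CodonAlignment):
        return aln.nucleotide_rows()
    rows = [str(s).upper() for s in aln]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("sequences must share one length")
    return rows


def tajima_d(aln) -> TajimaResult:
    """Tajima's neutrality test on a nucleotide alignment.

    Accepts a CodonAlignment or an iterable of equal-length nucleotide
    strings.  Columns holding anything other than A/C/G/T in any sequence
    are excluded (complete deletion).  With no segregating sites the
    statistic is undefined and returned as None with a note.
    """
    rows = _as_nucleotide_rows(aln)
    m = len(rows)
    if m < 4:
        raise ValueError("Tajima's D needs at least 4 sequences")
    cols = [
        col
        for col in zip(*rows)
        if all(c in _DNA for c in col)
    ]
    n_sites = len(cols)
    if n_sites == 0:
        raise ValueError("no comparable sites after complete deletion")

    S = sum(1 for col in cols if len(set(col)) > 1)
    total_pairs = m * (m - 1) // 2
    # mean pairwise difference count over all sequence pairs
    diff_total = 0
    for col in cols:
        counts = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        same = sum(k * (k - 1) // 2 for k in counts.values())
        diff_total += total_pairs - same
    k_bar = diff_total / total_pairs

    a1 = harmonic_a1(m)
    ps = S / n_sites
    theta = ps / a1
    pi = k_bar / n_sites

    if S == 0:
        return TajimaResult(m, n_sites, S, ps, a1, theta, pi, None,
                            note="no segregating sites: D undefined")

    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (k_bar - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return TajimaResult(m, n_sites, S, ps, a1, theta, pi, float(D))


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks
# ---------------------------------------------------------------------------


class SaturationError(ValueError):
    """Proportion of differences too high for the Jukes-Cantor correction."""


@functools.lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon.

    Each position contributes the fraction of its three possible
    nucleotide changes that are synonymous; changes creating a stop codon
    count as non-synonymous.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@functools.lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons.

    Averages over all minimal substitution pathways with equal weight;
    pathways passing through a stop codon are discarded unless every
    pathway does.
    """
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        cur = c1
        steps = []
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((through_stop, steps))
    usable = [steps for stop, steps in pathways if not stop] or [
        steps for _, steps in pathways
    ]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if translate_codon(a) == translate_codon(b) and "*" not in (
                translate_codon(a),
                translate_codon(b),
            ):
                syn += 1
            else:
                nonsyn += 1
    n = len(usable)
    return syn / n, nonsyn / n


def jukes_cantor(p: float) -> float:
    """d = -3/4 ln(1 - 4p/3); raises SaturationError at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise SaturationError(f"p = {p:.4f} >= 0.75: correction undefined")
    return -0.75 * math.log(arg)


def ng86(seq_a: str, seq_b: str, correction: bool = True) -> tuple[float, float, float]:
    """Nei-Gojobori Ka, Ks and their ratio for two in-frame sequences.

    Site counts are averaged between the two sequences; differences are
    averaged over all minimal substitution pathways per codon.  Both
    proportions receive the Jukes-Cantor correction unless ``correction``
    is off.  Returns (Ka, Ks, Ka/Ks) with the ratio as NaN when Ks = 0.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (set(ca) <= _DNA and set(cb) <= _DNA):
            continue  # gap or ambiguity: skip the codon pair
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        ds, dn = _codon_differences(ca, cb)
        s_diff += ds
        n_diff += dn
    if s_sites == 0 or n_sites == 0:
        raise ValueError("no comparable codons")
    p_s = s_diff / s_sites
    p_n = n_diff / n_sites
    ks = jukes_cantor(p_s) if correction else p_s
    ka = jukes_cantor(p_n) if correction else p_n
    ratio = ka / ks if ks > 0 else float("nan")
    return ka, ks, ratio


# ---------------------------------------------------------------------------
# Ks dating
# ---------------------------------------------------------------------------


@dataclass
class AgeEstimate:
    ks: float
    ks_ci: float  # half-width of the 95% interval
    rate: float  # substitutions / site / year
    age_my: float
    age_ci_my: float


def age_from_ks(ks: float, rate: float = RICE_SYNONYMOUS_RATE) -> float:
    """Divergence time in million years under a synonymous clock."""
    if ks < 0 or rate <= 0:
        raise ValueError("ks must be >= 0 and rate > 0")
    return ks / (2.0 * rate) / 1e6


def ks_confidence(
    seq_a: str,
    seq_b: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float, dict]:
    """Codon-bootstrap mean Ks and 95% half-width (1.96 x bootstrap SE).

    Returns (ks, ci_half_width, info); info carries the point estimate and
    a saturation warning when more than 5% of replicates hit the
    Jukes-Cantor domain edge.
    """
    n_codons = len(seq_a) // 3
    if n_codons < 30:
        raise ValueError("need at least 30 codons for a bootstrap interval")
    ka, ks_point, _ = ng86(seq_a, seq_b)
    codons_a = [seq_a[i : i + 3] for i in range(0, n_codons * 3, 3)]
    codons_b = [seq_b[i : i + 3] for i in range(0, n_codons * 3, 3)]
    rng = np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_codons, size=n_codons)
        sa = "".join(codons_a[i] for i in idx)
        sb = "".join(codons_b[i] for i in idx)
        try:
            values.append(ng86(sa, sb)[1])
        except (SaturationError, ValueError):
            failures += 1
    if not values:
        raise SaturationError("every bootstrap replicate saturated")
    se = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    info = {"ks_point": ks_point, "ka": ka, "n_failed": failures}
    if failures > 0.05 * n_boot:
        info["warning"] = f"{failures}/{n_boot} bootstrap replicates saturated"
    return float(np.mean(values)), 1.96 * se, info


def age_estimate(
    seq_a: str,
    seq_b: str,
    rate: float = RICE_SYNONYMOUS_RATE,
    n_boot: int = 1000,
    seed: int = 0,
) -> AgeEstimate:
    """Ks-based age of a duplicate pair with a bootstrap 95% interval."""
    ks, ci, _ = ks_confidence(seq_a, seq_b, n_boot=n_boot, seed=seed)
    return AgeEstimate(
        ks=ks,
        ks_ci=ci,
        rate=rate,
        age_my=age_from_ks(ks, rate),
        age_ci_my=age_from_ks(ci, rate),
    )


# ---------------------------------------------------------------------------
# cohort enrichment
# ---------------------------------------------------------------------------


def enrichment_test(
    hits: int, total: int, baseline_rate: float, baseline_n: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test of a cohort rate against a baseline.

    The 2x2 table contrasts (hits, total - hits) with the rounded count
    expected among ``baseline_n`` genes at ``baseline_rate``.  Returns
    (odds ratio, p); degenerate tables give p = 1 by convention.
    """
    if hits > total:
        raise ValueError("hits cannot exceed total")
    if not (0.0 <= baseline_rate <= 1.0):
        raise ValueError("baseline_rate must be a proportion")
    base_hits = int(round(baseline_rate * baseline_n))
    table = [[hits, total - hits], [base_hits, baseline_n - base_hits]]
    if min(sum(row) for row in table) == 0 or min(
        table[0][j] + table[1][j] for j in range(2)
    ) == 0:
        return float("nan"), 1.0
    res = scipy.stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
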