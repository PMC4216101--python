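"""Nei–Gojobori (1986) synonymous/nonsynonymous analysis.

Implements fractional site counting, minimal-pathway difference averaging,
the Jukes–Cantor multiple-hit correction, pooled alignment-wide dN/dS, and a
sliding-window scan along the coding region.

Conventions pinned for reproducibility:

* single-base mutations into stop codons are excluded both from the site
  denominators (site fractions are renormalized so every codon contributes
  n + s = 3 sites) and from mutational pathways;
* pathways between two codons are the minimal edit orders; pathways passing
  through a stop codon are discarded and the remainder reweighted (if *every*
  pathway passes through a stop, all pathways are used unweighted and a
  warning is logged);
* the ratio is reported as NaN (undefined) when dS = 0, never clamped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from .seq_io import CodingAlignment, GeneticCode, STANDARD_CODE

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

__all__ = [
    "CodonSiteCounts",
    "PairwiseDnDs",
    "SlidingWindowProfile",
    "codon_sites",
    "count_pathway_differences",
    "pairwise_dnds",
    "mean_dnds",
    "sliding_window_dnds",
    "jukes_cantor",
]


@dataclass(frozen=True)
class CodonSiteCounts:
    """Fractional nonsynonymous/synonymous site counts (n + s = 3 per codon)."""

    n_sites: float
    s_sites: float


@dataclass
class PairwiseDnDs:
    """NG86 summary for one sequence pair (or a pooled pair set)."""

    Nd: float
    Sd: float
    N: float
    S: float
    pN: float
    pS: float
    dN: float
    dS: float
    ratio: float  # NaN when undefined (dS = 0)


@dataclass
class SlidingWindowProfile:
    """Per-window dN/dS track along the coding region (codon units)."""

    windows: list[tuple[float, float, float, float]]  # (midpoint, dN, dS, ratio)
    window_len: int
    step: int


def _code_key(code: GeneticCode) -> tuple:
    return tuple(sorted(code.table.items()))


@lru_cache(maxsize=8)
def _sites_table(code_key: tuple, stops: frozenset) -> dict[str, CodonSiteCounts]:
    code = GeneticCode(table=dict(code_key), stops=stops)
    table = {}
    for codon in code.table:
        s_total = 0.0
        for k in range(3):
            syn = 0
            non_stop = 0
            for base in NUCLEOTIDES:
                if base == codon[k]:
                    continue
                mutant = codon[:k] + base + codon[k + 1 :]
                if code.is_stop(mutant):
                    continue
                non_stop += 1
                if code.table[mutant] == code.table[codon]:
                    syn += 1
            if non_stop:
                s_total += syn / non_stop
            # all three mutants are stops: the position is fully nonsynonymous
        table[codon] = CodonSiteCounts(n_sites=3.0 - s_total, s_sites=s_total)
    return table


def codon_sites(codon: str, code: GeneticCode = STANDARD_CODE) -> CodonSiteCounts:
    """NG86 fractional site counts for one sense codon.

    Each of the three positions contributes one site, split between
    synonymous and nonsynonymous in proportion to its single-base mutants
    (stop mutants excluded from the denominator).
    """
    codon = codon.upper()
    if "-" in codon:
        raise ValueError(f"gapped codon {codon!r}")
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    table = _sites_table(_code_key(code), code.stops)
    if codon not in table:
        raise ValueError(f"invalid codon {codon!r}")
    return table[codon]


_PATHWAY_CACHE: dict[tuple, tuple[float, float]] = {}


def count_pathway_differences(
    codon_a: str, codon_b: str, code: GeneticCode = STANDARD_CODE
) -> tuple[float, float]:
    """Average (nonsynonymous, synonymous) step counts over minimal pathways.

    All orderings of the differing positions are considered; orderings whose
    intermediate codons are stops are discarded and the rest averaged with
    equal weight.  If every ordering passes through a stop, all orderings are
    used unweighted (stop steps counted as nonsynonymous) with a warning.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if code.is_stop(c) or "-" in c or any(x not in NUCLEOTIDES for x in c):
            raise ValueError(f"invalid codon {c!r}")
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return (0.0, 0.0)
    cache_key = (_code_key(code), a, b)
    cached = _PATHWAY_CACHE.get(cache_key)
    if cached is not None:
        return cached

    def walk(order: tuple[int, ...]) -> tuple[int, int, bool]:
        nd = sd = 0
        current = a
        hits_stop = False
        for k in order:
            nxt = current[:k] + b[k] + current[k + 1 :]
            if code.is_stop(nxt):
                hits_stop = True
                nd += 1  # only used in the unweighted fallback
            elif code.is_stop(current):
                nd += 1
            elif code.table[nxt] == code.table[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        return nd, sd, hits_stop

    results = [walk(order) for order in permutations(diffs)]
    clean = [(nd, sd) for nd, sd, hit in results if not hit]
    if not clean:
        logger.warning(
            "all minimal pathways %s -> %s pass through stop codons; "
            "using unweighted inclusion", a, b,
        )
        clean = [(nd, sd) for nd, sd, _ in results]
    n = len(clean)
    result = (sum(nd for nd, _ in clean) / n, sum(sd for _, sd in clean) / n)
    _PATHWAY_CACHE[cache_key] = result
    return result


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3); p must be < 3/4."""
    if p < 0:
        raise ValueError(f"proportion {p} < 0")
    if p >= 0.75:
        raise ValueError(
            f"proportion {p:.4f} >= 3/4: Jukes-Cantor correction undefined "
            "(saturated divergence)"
        )
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _accumulate_pair(
    seq_a: str,
    seq_b: str,
    code: GeneticCode,
    codon_range: tuple[int, int] | None = None,
) -> tuple[float, float, float, float]:
    """Pooled (Nd, Sd, N, S) over gap-free codon pairs of two sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    if len(seq_a) % 3:
        raise ValueError("sequence length not a multiple of 3")
    n_codons = len(seq_a) // 3
    lo, hi = (0, n_codons) if codon_range is None else codon_range
    Nd = Sd = N = S = 0.0
    for i in range(lo, hi):
        ca = seq_a[3 * i : 3 * i + 3]
        cb = seq_b[3 * i : 3 * i + 3]
        if "-" in ca or "-" in cb:
            continue
        sa = codon_sites(ca, code)
        sb = codon_sites(cb, code)
        N += 0.5 * (sa.n_sites + sb.n_sites)
        S += 0.5 * (sa.s_sites + sb.s_sites)
        nd, sd = count_pathway_differences(ca, cb, code)
        Nd += nd
        Sd += sd
    return Nd, Sd, N, S


def _finish(Nd: float, Sd: float, N: float, S: float) -> PairwiseDnDs:
    if S <= 0:
        raise ValueError("no synonymous sites (S = 0); dS undefined")
    if N <= 0:
        raise ValueError("no nonsynonymous sites (N = 0); dN undefined")
    pN, pS = Nd / N, Sd / S
    dN, dS = jukes_cantor(pN), jukes_cantor(pS)
    ratio = dN / dS if dS > 0 else math.nan
    return PairwiseDnDs(Nd=Nd, Sd=Sd, N=N, S=S, pN=pN, pS=pS, dN=dN, dS=dS, ratio=ratio)


def pairwise_dnds(
    seq_a: str, seq_b: str, code: GeneticCode = STANDARD_CODE
) -> PairwiseDnDs:
    """NG86 dN/dS for one pair of in-frame sequences (gapped codons skipped)."""
    return _finish(*_accumulate_pair(seq_a.upper(), seq_b.upper(), code))


def _pairs_for(aln: CodingAlignment, taxa: list[str]) -> list[tuple[str, str]]:
    return [(taxa[i], taxa[j]) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]


def mean_dnds(
    aln: CodingAlignment,
    taxa_subset=None,
    code: GeneticCode | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> PairwiseDnDs:
    """Pooled NG86 dN/dS over all unordered pairs of a taxon subset.

    Nd, Sd, N and S are summed over pairs before correction (pooled
    estimate, not a mean of per-pair ratios).  An explicit ``pairs`` list
    overrides the all-pairs default.
    """
    code = code or aln.code
    if pairs is None:
        taxa = list(taxa_subset) if taxa_subset is not None else list(aln.taxa)
        if len(taxa) < 2:
            raise ValueError("need at least 2 taxa")
        pairs = _pairs_for(aln, taxa)
    Nd = Sd = N = S = 0.0
    for a, b in pairs:
        nd, sd, n, s = _accumulate_pair(aln.sequences[a], aln.sequences[b], code)
        Nd += nd
        Sd += sd
        N += n
        S += s
    return _finish(Nd, Sd, N, S)


def sliding_window_dnds(
    aln: CodingAlignment,
    pairs: list[tuple[str, str]] | None = None,
    window_len: int = 50,
    step: int = 10,
    code: GeneticCode | None = None,
    units: str = "codon",
) -> SlidingWindowProfile:
    """Sliding-window NG86 scan along the coding region.

    Per window, Nd/Sd/N/S are pooled over the pair set restricted to the
    window's codons; dN and dS are emitted separately so the dN track is
    available even where the ratio is undefined (window dS = 0 → NaN ratio;
    fully gapped or saturated windows → NaN everywhere).

    The default pair set is every non-reference taxon against the reference.
    ``units="nt"`` interprets window_len/step in nucleotides (multiples of 3).
    """
    code = code or aln.code
    if units == "nt":
        if window_len % 3 or step % 3:
            raise ValueError("nt-unit window_len and step must be multiples of 3")
        window_len //= 3
        step //= 3
    elif units != "codon":
        raise ValueError(f"unknown units {units!r}")
    L = aln.n_codons
    if window_len > L:
        raise ValueError(f"window length {window_len} exceeds alignment ({L} codons)")
    if pairs is None:
        pairs = [(t, aln.reference) for t in aln.taxa if t != aln.reference]

    windows = []
    for start in range(0, L - window_len + 1, step):
        end = start + window_len  # exclusive, 0-based codons
        Nd = Sd = N = S = 0.0
        for a, b in pairs:
            nd, sd, n, s = _accumulate_pair(
                aln.sequences[a], aln.sequences[b], code, codon_range=(start, end)
            )
            Nd += nd
            Sd += sd
            N += n
            S += s
        midpoint = (start + 1 + end) / 2.0  # 1-based codon coordinates
        if N <= 0 or S <= 0:
            windows.append((midpoint, math.nan, math.nan, math.nan))
            continue
        pN, pS = Nd / N, Sd / S
        if pN >= 0.75 or pS >= 0.75:
            windows.append((midpoint, math.nan, math.nan, math.nan))
            continue
        dN, dS = jukes_cantor(pN), jukes_cantor(pS)
        ratio = dN / dS if dS > 0 else math.nan
        windows.append((midpoint, dN, dS, ratio))
    return SlidingWindowProfile(windows=windows, window_len=window_len, step=step)
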