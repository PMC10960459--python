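"""Nei-Gojobori (1986) Ka/Ks estimation and the breakpoint-rate correlation.

The NG86 method counts, for each codon, the fraction of its nine possible
point mutations that are synonymous (synonymous "sites"); differences
between a codon pair are classified along all substitution pathways with
equal weights (2 pathways for two changed positions, 6 for three), excluding
pathways that pass through a stop codon.  Proportions pN = Nd/N and
pS = Sd/S are Jukes-Cantor corrected, K = -(3/4) ln(1 - (4/3) p).  The
default genetic code is the invertebrate mitochondrial code (translation
table 5), appropriate for arthropod mitochondrial protein-coding genes.

Mutations that would create a stop codon count as nonsynonymous in site
counting, so S + N = 3 x (number of codons) always holds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

_NT = "ACGT"


@lru_cache(maxsize=None)
def _code(table_id: int):
    """(forward table incl. stops mapped to '*', stop set) for a code table."""
    from Bio.Data import CodonTable

    tbl = CodonTable.unambiguous_dna_by_id[table_id]
    fwd = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        fwd[stop] = "*"
    return fwd, frozenset(tbl.stop_codons)


@lru_cache(maxsize=None)
def _codon_sites(codon: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon."""
    fwd, _ = _code(table_id)
    aa = fwd[codon]
    syn = 0.0
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1:]
            if fwd[mut] == aa and aa != "*":
                syn += 1.0
    syn /= 3.0
    return syn, 3.0 - syn


def _is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(c in _NT for c in codon.upper())


def _codons(seq: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def count_sites(seq: str, table_id: int = 5) -> tuple[float, float]:
    """Total (S_sites, N_sites) of a codon sequence.

    Codons with gaps/ambiguity are skipped; an internal stop codon raises
    with its codon position named.
    """
    fwd, stops = _code(table_id)
    S = N = 0.0
    for i, codon in enumerate(_codons(seq)):
        if not _is_valid_codon(codon):
            continue
        if codon in stops:
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        s, n = _codon_sites(codon, table_id)
        S += s
        N += n
    return S, N


def _pair_differences(c1: str, c2: str, table_id: int) -> tuple[float, float]:
    """NG86 pathway-averaged (syn, nonsyn) differences for one codon pair."""
    fwd, stops = _code(table_id)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    counted = []
    for perm in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in stops and nxt != c2:
                blocked = True
                break
            if fwd[cur] == fwd[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            counted.append((sd, nd))
    if not counted:  # every pathway passes a stop: fall back to all pathways
        for perm in itertools.permutations(diff):
            cur = c1
            sd = nd = 0.0
            for pos in perm:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if fwd[cur] == fwd[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            counted.append((sd, nd))
    sd = sum(c[0] for c in counted) / len(counted)
    nd = sum(c[1] for c in counted) / len(counted)
    return sd, nd


def count_differences(a: str, b: str, table_id: int = 5) -> tuple[float, float]:
    """Total pathway-averaged (Sd, Nd) between two aligned codon sequences."""
    ca, cb = _codons(a), _codons(b)
    if len(ca) != len(cb):
        raise ValueError("sequences differ in codon count")
    Sd = Nd = 0.0
    for c1, c2 in zip(ca, cb):
        if not (_is_valid_codon(c1) and _is_valid_codon(c2)):
            continue
        sd, nd = _pair_differences(c1, c2, table_id)
        Sd += sd
        Nd += nd
    return Sd, Nd


@dataclass(frozen=True)
class KaKsResult:
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    Ks_saturated: bool
    n_codons: int


def _jc(p: float) -> float:
    return 0.0 if p == 0.0 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks(a: str, b: str, table_id: int = 5) -> KaKsResult:
    """NG86 Ka/Ks for an aligned codon sequence pair.

    Sites are averaged across the two sequences; codons with gaps or
    ambiguity codes in either sequence are excluded pairwise.  ``Ks`` (and
    likewise ``Ka``) is undefined past Jukes-Cantor saturation
    (p >= 3/4); saturation of the synonymous rate sets ``Ks_saturated``.
    """
    ca, cb = _codons(a), _codons(b)
    if len(ca) != len(cb):
        raise ValueError("sequences differ in codon count")
    fwd, stops = _code(table_id)
    keep_a, keep_b = [], []
    for i, (c1, c2) in enumerate(zip(ca, cb)):
        if not (_is_valid_codon(c1) and _is_valid_codon(c2)):
            continue
        for which, c in (("first", c1), ("second", c2)):
            if c in stops:
                raise ValueError(
                    f"internal stop codon {c} at codon {i + 1} ({which} sequence)"
                )
        keep_a.append(c1)
        keep_b.append(c2)
    if not keep_a:
        raise ValueError("no comparable codons")
    sa = "".join(keep_a)
    sb = "".join(keep_b)
    S1, N1 = count_sites(sa, table_id)
    S2, N2 = count_sites(sb, table_id)
    S, N = (S1 + S2) / 2.0, (N1 + N2) / 2.0
    Sd, Nd = count_differences(sa, sb, table_id)
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    saturated = pS >= 0.75
    Ks = float("nan") if saturated else _jc(pS)
    Ka = float("nan") if pN >= 0.75 else _jc(pN)
    return KaKsResult(
        S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        Ks=Ks, Ka=Ka, Ks_saturated=saturated, n_codons=len(keep_a),
    )


def kaks_table(
    sequences: dict[str, str], reference_id: str, table_id: int = 5
):
    """Per-taxon NG86 results versus a reference sequence, as a DataFrame."""
    import pandas as pd

    if reference_id not in sequences:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    ref = sequences[reference_id]
    rows = []
    for taxon, seq in sequences.items():
        if taxon == reference_id:
            continue
        r = kaks(seq, ref, table_id)
        rows.append(
            {
                "taxon": taxon, "S": r.S_sites, "N": r.N_sites,
                "Sd": r.Sd, "Nd": r.Nd, "Ka": r.Ka, "Ks": r.Ks,
                "saturated": r.Ks_saturated,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    df: int
    p_value: float


def correlate_bp_ka(bp: Sequence[float], ka: Sequence[float]) -> CorrelationResult:
    """Pearson correlation between breakpoint counts and Ka, with a
    two-sided p-value from t = r * sqrt(df / (1 - r^2)), df = n - 2."""
    x = np.asarray(bp, dtype=float)
    y = np.asarray(ka, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("bp and ka must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(n=n, r=r, df=df, p_value=float(p))
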