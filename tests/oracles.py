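"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written directly from the operation's definition,
sharing no code path with the package.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}


def orf_bruteforce(seq: str) -> int:
    """Enumerate every ATG and walk in-frame to the next stop."""
    s = seq.upper().replace("U", "T")
    best = 0
    for i in range(len(s) - 2):
        if s[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(s):
            codon = s[j : j + 3]
            if "N" in codon:
                break  # broken frame: no complete ORF from this ATG
            if codon in _STOPS:
                best = max(best, (j - i) // 3)
                break
            j += 3
    return best


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """padj_(i) = min over j >= i of p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    sorted_p = p[order]
    for rank in range(m):
        tail = [sorted_p[j] * m / (j + 1) for j in range(rank, m)]
        out[order[rank]] = min(1.0, min(tail))
    return out


def permutation_pearson_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p over all n! orderings of x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    r_obs = abs((xc * yc).sum() / denom)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(x))):
        r = abs((xc[list(perm)] * yc).sum() / denom)
        count += r >= r_obs - 1e-12
        total += 1
    return count / total


def seed_scan_bruteforce(mirna_rna: str, target: str) -> list[tuple[int, str]]:
    """Sliding-window complementarity check; returns (1-based pos, type)."""
    m = mirna_rna.upper().replace("U", "T")
    t = target.upper().replace("U", "T")
    hits = []
    for i in range(len(t) - 5):
        window = t[i : i + 6]
        # core must be antiparallel-complementary to miRNA positions 2-7
        if all(window[k] == _COMP[m[1 + (5 - k)]] for k in range(6)):
            m8 = i - 1 >= 0 and t[i - 1] == _COMP[m[7]]
            a1 = i + 6 < len(t) and t[i + 6] == "A"
            st = ("8mer" if m8 and a1 else "7mer-m8" if m8
                  else "7mer-A1" if a1 else "6mer")
            hits.append((i + 1, st))
    return hits


def cluster_components_bruteforce(spans, max_gap):
    """O(n^2) connected components of the pairwise <= max_gap relation.

    ``spans`` is a list of (scaffold, start, end).
    """
    n = len(spans)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            si, sj = spans[i], spans[j]
            if si[0] != sj[0]:
                continue
            gap = max(0, max(si[1], sj[1]) - min(si[2], sj[2]))
            if gap <= max_gap:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [sorted(v) for v in comps.values() if len(v) >= 2]


def lnc_class_bruteforce(lnc, genes) -> str:
    """Interval/strand checker applying the category definitions directly."""

    def exons_overlap(a, b):
        return any(
            x.start <= y.end and y.start <= x.end
            for x in a.exons
            for y in b.exons
        )

    anti = sense = intronic = False
    for g in genes:
        if g.scaffold != lnc.scaffold:
            continue
        if exons_overlap(lnc, g):
            if g.strand != lnc.strand:
                anti = True
            else:
                sense = True
        else:
            for k in range(len(g.exons) - 1):
                ia, ib = g.exons[k].end + 1, g.exons[k + 1].start - 1
                if ia <= lnc.start and lnc.end <= ib:
                    intronic = True
    if anti:
        return "antisense"
    if sense:
        return "sense"
    if intronic:
        return "intronic"
    return "lincRNA"


def pearson_twopass(x, y) -> float:
    """Textbook two-pass Pearson formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def read_match_bruteforce(read, references, end_tolerance=3, max_mismatches=1):
    """All-pairs, all-offsets aligner applying the matching rule directly."""
    r = read.upper().replace("T", "U")
    results = []
    for ref_id in references:
        ref = references[ref_id].upper().replace("T", "U")
        for off in range(-end_tolerance, end_tolerance + 1):
            if abs(off + len(r) - len(ref)) > end_tolerance:
                continue
            lo, hi = max(0, off), min(len(ref), off + len(r))
            if hi <= lo:
                continue
            mism = sum(ref[k] != r[k - off] for k in range(lo, hi))
            if mism <= max_mismatches:
                results.append((mism, -(hi - lo), ref_id))
    return min(results) if results else None


def venn_bruteforce(flags: dict[str, np.ndarray]) -> dict[tuple[str, ...], int]:
    """Region counts by enumerating every transcript's exact method set."""
    methods = list(flags)
    n = len(next(iter(flags.values())))
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(methods) + 1):
        for sub in itertools.combinations(methods, r):
            out[sub] = 0
    for i in range(n):
        present = tuple(m for m in methods if flags[m][i])
        if present:
            out[present] += 1
    return out
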