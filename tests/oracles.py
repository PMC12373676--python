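"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — nested loops, explicit dynamic
programming, substring search — and shares no code with the implementation
paths it checks.
"""

from __future__ import annotations

NEG_INF = float("-inf")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def gotoh_global_score(a: str, b: str, match: float = 2.0,
                       mismatch: float = -3.0, open_: float = -5.0,
                       extend: float = -2.0) -> float:
    """Affine-gap global alignment score by explicit Gotoh DP.

    Convention: a gap of length L costs open + (L - 1) * extend, end gaps
    included.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Y[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + extend,
                          Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + extend,
                          X[i][j - 1] + open_)
    return max(M[n][m], X[n][m], Y[n][m])


def naive_kmer_set(seq: str, k: int) -> set[str]:
    """Sliding-window k-mer enumeration, N-containing windows dropped."""
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if all(c in "ACGT" for c in w):
            out.add(w)
    return out


def naive_male_specific(male_seq_sets: list[list[str]],
                        female_seq_sets: list[list[str]], k: int) -> set[str]:
    """Defining predicate evaluated per k-mer by substring search: present
    in some record of every male sample, absent from every record of
    every female sample."""
    universe: set[str] = set()
    for recs in male_seq_sets:
        for s in recs:
            universe |= naive_kmer_set(s, k)
    keep = set()
    for km in universe:
        in_all_males = all(any(km in s for s in recs) for recs in male_seq_sets)
        in_no_female = not any(km in s for recs in female_seq_sets for s in recs)
        if in_all_males and in_no_female:
            keep.add(km)
    return keep


def naive_site_positions(seq: str, recognition: str) -> list[int]:
    """Plus-strand recognition matches by per-base set membership."""
    hits = []
    for i in range(len(seq) - len(recognition) + 1):
        window = seq[i:i + len(recognition)]
        if all(t in "ACGT" and t in IUPAC[p]
               for p, t in zip(recognition, window)):
            hits.append(i)
    return hits


def naive_cut_positions(seq: str, recognition: str, cut_offset: int) -> list[int]:
    """Top-strand cut coordinates, both strands, derived independently by
    scanning the reverse complement and mapping coordinates back."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
            "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
            "B": "V", "D": "H", "H": "D", "V": "B"}
    rc = "".join(comp[c] for c in reversed(seq))
    cuts = {i + cut_offset for i in naive_site_positions(seq, recognition)}
    palindromic = recognition == "".join(comp[c] for c in reversed(recognition))
    if not palindromic:
        for p in naive_site_positions(rc, recognition):
            cuts.add(len(seq) - (p + cut_offset))
    return sorted(c for c in cuts if 0 < c < len(seq))


def benjamini_hochberg(pvals: list[float]) -> list[float]:
    """Hand-applied BH step-up adjustment."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
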