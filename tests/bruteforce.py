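"""Independent brute-force reference for the tandem-repeat scan.

Every candidate (seed, end) substring is re-scored from scratch by
literal comparison against a freshly tiled unit, so no incremental
bookkeeping is shared with the production scanner.
"""

DNA = set("ACGT")


def _primitive(unit: str) -> bool:
    k = len(unit)
    return not any(k % d == 0 and unit == unit[:d] * (k // d) for d in range(1, k))


def bruteforce_repeat_arrays(
    seq,
    unit_sizes,
    min_repeats=6,
    min_purity=0.9,
    match=1,
    penalty=6,
    min_score=8,
    max_drop=30,
):
    """All maximal non-overlapping arrays, by exhaustive substring scoring."""
    cands = []
    n = len(seq)
    for k in sorted(set(unit_sizes)):
        for i in range(n - k + 1):
            unit = seq[i : i + k]
            if not set(unit) <= DNA or not _primitive(unit):
                continue
            if i >= k and seq[i - k : i] == unit:
                continue
            best_score, best_end, best_mm = 0, i + k, 0
            j = i + k
            while j < n:
                if seq[j] not in DNA:
                    break
                sub = seq[i : j + 1]
                tiled = (unit * (len(sub) // k + 1))[: len(sub)]
                mism = sum(x != y for x, y in zip(sub, tiled))
                score = (len(sub) - k - mism) * match - mism * penalty
                j += 1
                if score > best_score or (score == best_score and j > best_end):
                    best_score, best_end, best_mm = score, j, mism
                if score < best_score - max_drop:
                    break
            length = best_end - i
            if length < k * min_repeats or best_score < min_score:
                continue
            purity = (length - best_mm) / length
            if purity < min_purity:
                continue
            cands.append((i, best_end, unit, best_score, purity))
    ranked = sorted(
        set(cands), key=lambda c: (-c[3], -(c[1] - c[0]), c[0], len(c[2]), c[2])
    )
    kept = []
    for c in ranked:
        if all(c[1] <= o[0] or c[0] >= o[1] for o in kept):
            kept.append(c)
    kept.sort(key=lambda c: c[0])
    return kept


def biallelic_hwe_pvalue(n_AA, n_Aa, n_aa):
    """Exact biallelic HWE p value by direct enumeration over het counts."""
    from math import factorial

    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n_aa + n_Aa

    def prob(het):
        if (nA - het) % 2 or het > min(nA, na) or (na - het) % 2:
            return None
        aa_hom = (na - het) // 2
        AA_hom = (nA - het) // 2
        if aa_hom < 0 or AA_hom < 0:
            return None
        return (
            factorial(n)
            / (factorial(AA_hom) * factorial(het) * factorial(aa_hom))
            * 2**het
            * factorial(nA)
            * factorial(na)
            / factorial(2 * n)
        )

    p_obs = prob(n_Aa)
    total = 0.0
    het = nA % 2
    while het <= min(nA, na):
        p = prob(het)
        if p is not None and p <= p_obs * (1 + 1e-9):
            total += p
        het += 2
    return min(total, 1.0)
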