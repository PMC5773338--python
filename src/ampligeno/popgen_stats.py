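"""Per-locus population-genetic summaries of a genotype matrix.

For each locus the module computes the observed allele count (Ao), the
effective allele number Ae = 1/Σp², observed heterozygosity Ho,
expected heterozygosity He = 1 − Σp² (uncorrected; Nei's unbiased
2n/(2n−1) variant is available as an option), Botstein's polymorphism
information content

    PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j²,

and an exact Hardy-Weinberg equilibrium test.  The exact test
conditions on the observed allele counts: the probability of a
genotype table {n_ij} given allele counts {m_i} in n diploids is

    P = n! / Π n_ij! · 2^h · Π m_i! / (2n)! ,

with h the heterozygote count, and the p value sums the probabilities
of all tables no more probable than the observed one.  Tables are
enumerated exhaustively when their number is manageable; otherwise the
null distribution is sampled by random pairing of the observed gene
copies (Monte Carlo, seeded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

DEFAULT_MC_REPS = 100_000
DEFAULT_MAX_TABLES = 1_000_000

Call = tuple[int, int]


class UndefinedLocusError(ValueError):
    """A locus has no non-missing genotype calls."""


def round2(x: float) -> float:
    """Round half-up to 2 decimals (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def allele_frequencies(calls: Sequence[Call]) -> dict[int, float]:
    """Allele frequencies over the 2n gene copies of non-missing calls."""
    if not calls:
        raise UndefinedLocusError("no non-missing calls at locus")
    counts: dict[int, int] = {}
    for a, b in calls:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(calls)
    return {allele: c / total for allele, c in sorted(counts.items())}


def observed_het(calls: Sequence[Call]) -> float:
    """Fraction of non-missing calls that are heterozygous."""
    if not calls:
        raise UndefinedLocusError("no non-missing calls at locus")
    return sum(1 for a, b in calls if a != b) / len(calls)


def expected_het(freqs: Mapping[int, float], n: int | None = None) -> float:
    """He = 1 − Σp²; with ``n`` given, Nei's unbiased 2n/(2n−1) correction."""
    he = 1.0 - sum(p * p for p in freqs.values())
    if n is not None:
        he *= 2 * n / (2 * n - 1)
    return he


def effective_alleles(freqs: Mapping[int, float]) -> float:
    """Ae = 1 / Σp², the effective number of alleles."""
    return 1.0 / sum(p * p for p in freqs.values())


def pic(freqs: Mapping[int, float]) -> float:
    """Botstein's polymorphism information content."""
    ps = list(freqs.values())
    s2 = sum(p * p for p in ps)
    cross = 0.0
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            cross += 2.0 * ps[i] * ps[i] * ps[j] * ps[j]
    return 1.0 - s2 - cross


def _genotype_counts(calls: Sequence[Call]) -> dict[Call, int]:
    counts: dict[Call, int] = {}
    for a, b in calls:
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _log_table_prob(
    geno_counts: Mapping[tuple[int, int], int],
    log_const: float,
) -> float:
    """log P(table | allele counts) up to the shared constant term."""
    h = 0
    s = 0.0
    for (a, b), c in geno_counts.items():
        s += math.lgamma(c + 1)
        if a != b:
            h += c
    return log_const + h * math.log(2.0) - s


def _enumerate_tables(
    allele_counts: Sequence[int], max_tables: int
) -> list[dict[tuple[int, int], int]] | None:
    """All genotype tables with the given allele-count margins.

    Returns None when more than ``max_tables`` tables exist.
    """
    k = len(allele_counts)
    tables: list[dict[tuple[int, int], int]] = []
    # pairs ordered so that (i, k-1) is the last pair touching allele i,
    # which lets the count for that pair be forced rather than searched
    pairs = [(i, j) for i in range(k) for j in range(i, k)]

    def rec(idx: int, remaining: list[int], current: dict) -> bool:
        if idx == len(pairs):
            tables.append(dict(current))
            return len(tables) <= max_tables
        i, j = pairs[idx]
        if i == j:
            if i == k - 1:  # final pair: forced, must consume the rest
                if remaining[i] % 2:
                    return True
                choices = [remaining[i] // 2]
            else:
                choices = range(remaining[i] // 2, -1, -1)
        elif j == k - 1:  # last pair for allele i: forced
            if remaining[i] > remaining[j]:
                return True
            choices = [remaining[i]]
        else:
            choices = range(min(remaining[i], remaining[j]), -1, -1)
        for c in choices:
            current[(i, j)] = c
            if i == j:
                remaining[i] -= 2 * c
            else:
                remaining[i] -= c
                remaining[j] -= c
            proceed = rec(idx + 1, remaining, current)
            if i == j:
                remaining[i] += 2 * c
            else:
                remaining[i] += c
                remaining[j] += c
            if not proceed:
                return False
        current.pop((i, j), None)
        return True

    if not rec(0, list(allele_counts), {}):
        return None
    return tables


def hwe_exact_test(
    calls: Sequence[Call],
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int | None = None,
    max_tables: int = DEFAULT_MAX_TABLES,
) -> float:
    """Exact Hardy-Weinberg test p value for one locus.

    Full enumeration of genotype tables conditional on allele counts
    when at most ``max_tables`` tables exist, otherwise Monte Carlo by
    random pairing of the observed gene copies (``mc_reps`` draws,
    requires ``seed``).  Monomorphic input returns NaN (test
    undefined).
    """
    if not calls:
        raise UndefinedLocusError("no non-missing calls at locus")
    alleles = sorted({x for call in calls for x in call})
    if len(alleles) < 2:
        return float("nan")
    index = {a: i for i, a in enumerate(alleles)}
    n = len(calls)
    geno = {
        (index[min(a, b)], index[max(a, b)]): c
        for (a, b), c in _genotype_counts(calls).items()
    }
    m = [0] * len(alleles)
    for (i, j), c in geno.items():
        # a homozygote (i == j) adds two copies via the two increments
        m[i] += c
        m[j] += c
    # shared constant: log n! + Σ log m_i! − log (2n)!
    log_const = (
        math.lgamma(n + 1)
        + sum(math.lgamma(mi + 1) for mi in m)
        - math.lgamma(2 * n + 1)
    )
    logp_obs = _log_table_prob(geno, log_const)
    tables = _enumerate_tables(m, max_tables)
    tol = 1e-9  # relative tolerance when comparing table probabilities
    if tables is not None:
        p = 0.0
        for table in tables:
            lp = _log_table_prob(table, log_const)
            if lp <= logp_obs + tol:
                p += math.exp(lp)
        return min(p, 1.0)
    if seed is None:
        raise ValueError("Monte Carlo HWE path requires a seed")
    return _hwe_monte_carlo(geno, m, n, logp_obs, log_const, mc_reps, seed, tol)


def _hwe_monte_carlo(
    geno, m, n, logp_obs, log_const, reps, seed, tol
) -> float:
    rng = np.random.default_rng(seed)
    k = len(m)
    copies = np.repeat(np.arange(k), m)
    mat = np.tile(copies, (reps, 1))
    mat = rng.permuted(mat, axis=1)
    a = mat[:, 0::2]
    b = mat[:, 1::2]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    het = (lo != hi).sum(axis=1)
    code = lo * k + hi + np.arange(reps)[:, None] * (k * k)
    counts = np.bincount(code.ravel(), minlength=reps * k * k).reshape(reps, k * k)
    logp = (
        log_const
        + het * math.log(2.0)
        - gammaln(counts + 1).sum(axis=1)
    )
    hits = int(np.count_nonzero(logp <= logp_obs + tol))
    return (hits + 1) / (reps + 1)


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    n: int
    alleles: tuple[int, ...]
    Ao: int
    Ae: float
    Ho: float
    He: float
    PIC: float
    hwe_p: float
    monomorphic: bool


def calls_at_locus(matrix: pd.DataFrame, locus: str) -> list[Call]:
    """Non-missing calls (allele1, allele2) for one locus of a matrix."""
    sub = matrix[(matrix["locus"] == locus) & (matrix["status"] == "called")]
    return [
        (int(r.allele1), int(r.allele2))
        for r in sub.itertuples()
        if pd.notna(r.allele1) and pd.notna(r.allele2)
    ]


def locus_summary(
    matrix: pd.DataFrame,
    locus: str,
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int | None = None,
    unbiased_he: bool = False,
) -> LocusSummary:
    calls = calls_at_locus(matrix, locus)
    if not calls:
        raise UndefinedLocusError(f"locus {locus}: all calls missing")
    freqs = allele_frequencies(calls)
    n = len(calls)
    ao = len(freqs)
    return LocusSummary(
        locus=locus,
        n=n,
        alleles=tuple(sorted(freqs)),
        Ao=ao,
        Ae=effective_alleles(freqs),
        Ho=observed_het(calls),
        He=expected_het(freqs, n=n if unbiased_he else None),
        PIC=pic(freqs),
        hwe_p=hwe_exact_test(calls, mc_reps=mc_reps, seed=seed),
        monomorphic=ao == 1,
    )


def summarize_all(
    matrix: pd.DataFrame,
    mc_reps: int = DEFAULT_MC_REPS,
    seed: int | None = None,
    unbiased_he: bool = False,
) -> pd.DataFrame:
    """Per-locus summary table plus a mean row over polymorphic loci.

    Values are reported both raw and rounded half-up to 2 decimals; a
    monomorphic locus is flagged in the ``note`` column and excluded
    from the mean row.
    """
    rows = []
    summaries: list[LocusSummary] = []
    for locus in sorted(matrix["locus"].unique()):
        try:
            s = locus_summary(
                matrix, locus, mc_reps=mc_reps, seed=seed, unbiased_he=unbiased_he
            )
        except UndefinedLocusError:
            continue
        summaries.append(s)
        rows.append(
            {
                "locus": s.locus,
                "alleles": ", ".join(map(str, s.alleles)),
                "n": s.n,
                "Ao": s.Ao,
                "Ae": round2(s.Ae),
                "Ho": round2(s.Ho),
                "He": round2(s.He),
                "PIC": round2(s.PIC),
                "HWE_p": round2(s.hwe_p) if not math.isnan(s.hwe_p) else float("nan"),
                "note": "Monomorphic" if s.monomorphic else "",
            }
        )
    poly = [s for s in summaries if not s.monomorphic]
    if poly:
        rows.append(
            {
                "locus": "Mean",
                "alleles": "",
                "n": "",
                "Ao": round2(sum(s.Ao for s in poly) / len(poly)),
                "Ae": round2(sum(s.Ae for s in poly) / len(poly)),
                "Ho": round2(sum(s.Ho for s in poly) / len(poly)),
                "He": round2(sum(s.He for s in poly) / len(poly)),
                "PIC": round2(sum(s.PIC for s in poly) / len(poly)),
                "HWE_p": float("nan"),
                "note": f"mean over {len(poly)} polymorphic loci",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus", "alleles", "n", "Ao", "Ae", "Ho", "He", "PIC", "HWE_p", "note"],
    )


def export_genepop(matrix: pd.DataFrame, path, title: str = "ampligeno export") -> None:
    """Write the genotype matrix in GenePop format (3-digit alleles)."""
    loci = sorted(matrix["locus"].unique())
    samples = sorted(matrix["sample"].unique())
    lookup = {
        (r.sample, r.locus): (r.allele1, r.allele2)
        for r in matrix[matrix["status"] == "called"].itertuples()
    }
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in loci:
            fh.write(locus + "\n")
        fh.write("Pop\n")
        for sample in samples:
            fields = []
            for locus in loci:
                call = lookup.get((sample, locus))
                if call is None or pd.isna(call[0]):
                    fields.append("000000")
                else:
                    fields.append(f"{int(call[0]):03d}{int(call[1]):03d}")
            fh.write(f"{sample} , " + " ".join(fields) + "\n")
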