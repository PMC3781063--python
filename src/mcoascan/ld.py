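"""Two-locus linkage disequilibrium in a genotyped cohort.

Validates a candidate SNP pair in a large panel of unphased genotypes:
haplotype frequencies are estimated by EM (the double-heterozygote class is
split by its expected phase), from which D, D' and r^2 follow.  A cohort in
"complete LD" — every individual carrying identical dosage at both loci, as
for the intronic/coding PMEL pair — yields D' = r^2 = 1.

Genotypes are allele dosages in {0, 1, 2} of the focal (minor/disease)
allele at each locus.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class LDError(ValueError):
    pass


@dataclass(frozen=True)
class TwoLocusGenotypeCounts:
    """3x3 table: n[i][j] = individuals with dosage i at locus 1, j at locus 2."""

    n: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.n)
        if arr.shape != (3, 3):
            raise LDError(f"counts must be 3x3, got shape {arr.shape}")
        if (arr < 0).any():
            raise LDError("counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.n, dtype=float)

    @property
    def total(self) -> int:
        return int(np.asarray(self.n).sum())

    @classmethod
    def from_dosages(cls, pairs: Iterable[tuple[int, int]]) -> "TwoLocusGenotypeCounts":
        arr = np.zeros((3, 3), dtype=int)
        for i, j in pairs:
            if i not in (0, 1, 2) or j not in (0, 1, 2):
                raise LDError(f"dosages must be in {{0,1,2}}, got ({i}, {j})")
            arr[i, j] += 1
        return cls(tuple(tuple(int(x) for x in row) for row in arr))


@dataclass(frozen=True)
class LDResult:
    haplotype_freqs: tuple[float, float, float, float]  # (p_AB, p_Ab, p_aB, p_ab)
    D: float
    D_prime: float
    r_squared: float
    log_likelihood: float
    iterations: int
    converged: bool
    degenerate: bool = False  # a locus is monomorphic; statistics reported as 0


def genotype_class_probs(freqs: Sequence[float]) -> np.ndarray:
    """P(dosage pair (i, j)) for haplotype freqs (p_AB, p_Ab, p_aB, p_ab)."""
    fab, fAb, faB, fAB = freqs[3], freqs[1], freqs[2], freqs[0]
    P = np.zeros((3, 3))
    P[2, 2] = fAB ** 2
    P[2, 1] = 2 * fAB * fAb
    P[2, 0] = fAb ** 2
    P[1, 2] = 2 * fAB * faB
    P[1, 1] = 2 * fAB * fab + 2 * fAb * faB
    P[1, 0] = 2 * fAb * fab
    P[0, 2] = faB ** 2
    P[0, 1] = 2 * faB * fab
    P[0, 0] = fab ** 2
    return P


def log_likelihood(counts: TwoLocusGenotypeCounts, freqs: Sequence[float]) -> float:
    """Multinomial log-likelihood of the genotype classes under ``freqs``."""
    n = counts.array
    P = genotype_class_probs(freqs)
    with np.errstate(divide="ignore"):
        logP = np.log(P)
    mask = n > 0
    if np.any(np.isneginf(logP[mask])):
        return -math.inf
    return float((n[mask] * logP[mask]).sum())


def em_haplotype_frequencies(
    counts: TwoLocusGenotypeCounts, tol: float = 1e-10, max_iter: int = 1000
) -> LDResult:
    """Maximum-likelihood haplotype frequencies for unphased two-locus data.

    Initialized at linkage equilibrium (products of observed allele
    frequencies); iterates until the largest absolute frequency change is
    below ``tol`` or ``max_iter`` is reached.  Monomorphic loci short-circuit
    to a flagged degenerate result (all LD statistics 0) instead of raising.
    """
    if tol <= 0:
        raise LDError("tol must be > 0")
    n = counts.array
    N = n.sum()
    if N < 1:
        raise LDError("cohort must contain at least one individual")

    i_idx, j_idx = np.meshgrid([0, 1, 2], [0, 1, 2], indexing="ij")
    pA = float((n * i_idx).sum() / (2 * N))
    pB = float((n * j_idx).sum() / (2 * N))

    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        freqs = (pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB))
        return LDResult(freqs, 0.0, 0.0, 0.0, log_likelihood(counts, freqs),
                        iterations=0, converged=True, degenerate=True)

    fAB, fAb = pA * pB, pA * (1 - pB)
    faB, fab = (1 - pA) * pB, (1 - pA) * (1 - pB)
    n_dh = n[1, 1]  # double heterozygotes: phase unknown

    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        # E: split double hets between coupling (AB/ab) and repulsion (Ab/aB)
        denom = fAB * fab + fAb * faB
        coupling = n_dh * (fAB * fab / denom) if denom > 0 else 0.0
        # M: expected haplotype counts from phase-known classes + split
        cAB = 2 * n[2, 2] + n[2, 1] + n[1, 2] + coupling
        cAb = 2 * n[2, 0] + n[2, 1] + n[1, 0] + (n_dh - coupling)
        caB = 2 * n[0, 2] + n[1, 2] + n[0, 1] + (n_dh - coupling)
        cab = 2 * n[0, 0] + n[1, 0] + n[0, 1] + coupling
        new = np.array([cAB, cAb, caB, cab]) / (2 * N)
        delta = np.max(np.abs(new - np.array([fAB, fAb, faB, fab])))
        fAB, fAb, faB, fab = new
        if delta < tol:
            converged = True
            break

    freqs = (float(fAB), float(fAb), float(faB), float(fab))
    D, D_prime, r_squared = ld_statistics(freqs)
    return LDResult(freqs, D, D_prime, r_squared,
                    log_likelihood(counts, freqs), iterations, converged)


def ld_statistics(freqs: Sequence[float]) -> tuple[float, float, float]:
    """(D, D', r^2) from haplotype frequencies (p_AB, p_Ab, p_aB, p_ab).

    D = p_AB - p_A p_B; D' = |D| / D_max with the usual frequency-dependent
    bound; r^2 = D^2 / (p_A p_a p_B p_b).  Monomorphic loci (an allele
    frequency of 0 or 1) give (0, 0, 0).
    """
    fAB, fAb, faB, fab = freqs
    total = fAB + fAb + faB + fab
    if not math.isclose(total, 1.0, abs_tol=1e-6) or min(freqs) < -1e-12:
        raise LDError(f"invalid haplotype frequencies {freqs}")
    pA = fAB + fAb
    pB = fAB + faB
    qA, qB = 1 - pA, 1 - pB
    if min(pA, qA, pB, qB) <= 0:
        return 0.0, 0.0, 0.0
    D = fAB - pA * pB
    if D > 0:
        d_max = min(pA * qB, qA * pB)
    elif D < 0:
        d_max = min(pA * pB, qA * qB)
    else:
        return 0.0, 0.0, 0.0
    D_prime = abs(D) / d_max
    r_squared = D * D / (pA * qA * pB * qB)
    return float(D), float(D_prime), float(r_squared)


# ---------------------------------------------------------------------------
# cohort-level summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CarrierSummary:
    n_carriers: int
    n_noncarriers: int
    by_label: dict[str, int]  # carrier counts per label (e.g. coat colour)


def carrier_summary(
    dosages: Sequence[int], labels: Sequence[str] | None = None
) -> CarrierSummary:
    """Carrier (dosage >= 1) vs non-carrier partition, optionally by label."""
    by_label: dict[str, int] = {}
    carriers = 0
    for idx, d in enumerate(dosages):
        if d not in (0, 1, 2):
            raise LDError(f"dosage must be in {{0,1,2}}, got {d}")
        if d >= 1:
            carriers += 1
            if labels is not None:
                by_label[labels[idx]] = by_label.get(labels[idx], 0) + 1
    return CarrierSummary(carriers, len(dosages) - carriers, by_label)


def complete_ld_check(pairs: Iterable[tuple[int, int]]) -> bool:
    """True iff every individual has identical dosage at both loci."""
    return all(i == j for i, j in pairs)


# ---------------------------------------------------------------------------
# cohort TSV + report
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["horse_id", "locus1_dosage", "locus2_dosage", "coat_label"]


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise LDError(f"cohort table {path} lacks columns {missing}")
    if "coat_label" not in df.columns:
        df["coat_label"] = "unknown"
    return df


def analyse_cohort(df: pd.DataFrame, tol: float = 1e-10, max_iter: int = 1000) -> dict:
    """EM + LD statistics + carrier summaries for a cohort genotype table."""
    pairs = list(zip(df["locus1_dosage"].astype(int), df["locus2_dosage"].astype(int)))
    counts = TwoLocusGenotypeCounts.from_dosages(pairs)
    result = em_haplotype_frequencies(counts, tol=tol, max_iter=max_iter)
    carriers = carrier_summary(
        [p[0] for p in pairs], list(df["coat_label"].astype(str))
    )
    return {
        "n_individuals": len(pairs),
        "haplotype_freqs": {
            "AB": result.haplotype_freqs[0], "Ab": result.haplotype_freqs[1],
            "aB": result.haplotype_freqs[2], "ab": result.haplotype_freqs[3],
        },
        "D": result.D,
        "D_prime": result.D_prime,
        "r_squared": result.r_squared,
        "log_likelihood": result.log_likelihood,
        "iterations": result.iterations,
        "converged": result.converged,
        "degenerate": result.degenerate,
        "complete_ld": complete_ld_check(pairs),
        "n_carriers": carriers.n_carriers,
        "n_noncarriers": carriers.n_noncarriers,
        "carriers_by_label": carriers.by_label,
    }


def write_ld_report(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


__all__ = [
    "TwoLocusGenotypeCounts", "LDResult", "CarrierSummary", "LDError",
    "em_haplotype_frequencies", "ld_statistics", "log_likelihood",
    "genotype_class_probs", "carrier_summary", "complete_ld_check",
    "read_cohort_tsv", "analyse_cohort", "write_ld_report", "COHORT_COLUMNS",
]
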