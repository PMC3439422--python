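"""Differential association of miRNAs between two libraries.

Counts are normalised to transcripts per million (TPM); a normalised
value of zero is replaced by 0.01 so fold changes stay finite.  The
significance of a count difference is assessed with the Audic-Claverie
exact test: conditional on the counts (x, y) and library sizes (N1, N2),

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

which is the negative-binomial pmf NB(x + 1, 1/(1 + N2/N1)) in y.  Tail
probabilities are therefore regularised incomplete beta functions and are
evaluated through ``scipy.special.betainc`` (log-space internally), exact
for counts far beyond 10^5.  The two-sided p-value doubles the smaller
tail and caps at 1.  Classes follow the scatter convention: ratio
TPM2/TPM1 > 2 is "up", < 1/2 "down", otherwise "unchanged".

Also includes the RT-qPCR ΔΔCT helper (relative quantity 2^-ΔΔCT with
propagated standard error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "normalize_tpm", "audic_claverie_pvalue", "differential_table",
    "frequency_ranges", "delta_delta_ct", "DiffAssocResult",
]

ZERO_SUBSTITUTE = 0.01


@dataclass(frozen=True)
class DiffAssocResult:
    mirna_id: str
    tpm1: float
    tpm2: float
    log2fc: float
    pvalue: float
    klass: str


def normalize_tpm(count: int, library_total: int) -> float:
    """Transcripts per million; zero maps to 0.01."""
    if count < 0:
        raise ValueError("negative count")
    if library_total < 1:
        raise ValueError("library_total must be >= 1")
    level = count * 1e6 / library_total
    return level if level > 0 else ZERO_SUBSTITUTE


def _tails(x: int, y: int, n1: int, n2: int) -> tuple[float, float]:
    """(P(Y <= y | x), P(Y >= y | x)) under the conditional model."""
    p = n1 / (n1 + n2)          # NB success probability 1 / (1 + N2/N1)
    lower = special.betainc(x + 1, y + 1, p)
    upper = 1.0 if y == 0 else special.betainc(y, x + 1, 1.0 - p)
    return float(lower), float(upper)


def audic_claverie_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided exact p-value for observing counts (x, y) in libraries
    of total size (n1, n2) under a common association level.

    Symmetric under (x, n1) <-> (y, n2) exchange; always in (0, 1].
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be >= 1")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    lower, upper = _tails(x, y, n1, n2)
    return min(1.0, 2.0 * min(lower, upper))


def differential_table(inputs, n1: int, n2: int, alpha: float | None = None,
                       fdr: bool = False) -> pd.DataFrame:
    """Per-miRNA TPM, log2 fold change, exact p-value and scatter class.

    ``inputs`` is an iterable of (mirna_id, x, y) with x the count in
    library 1 and y in library 2.  Rows are sorted by descending |log2fc|.
    ``alpha`` adds a boolean ``significant`` column only when supplied (no
    significance threshold is imposed by default); ``fdr`` adds a
    Benjamini-Hochberg adjusted column (off by default).
    """
    rows = list(inputs)
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mirna_id in input")
    out = []
    for mirna_id, x, y in rows:
        if x > n1 or y > n2:
            raise ValueError(f"count exceeds library total for {mirna_id}")
        t1 = normalize_tpm(x, n1)
        t2 = normalize_tpm(y, n2)
        ratio = t2 / t1
        klass = "up" if ratio > 2 else ("down" if ratio < 0.5 else "unchanged")
        out.append((mirna_id, x, y, t1, t2, math.log2(ratio),
                    audic_claverie_pvalue(x, y, n1, n2), klass))
    df = pd.DataFrame(out, columns=["mirna_id", "x", "y", "tpm1", "tpm2",
                                    "log2fc", "pvalue", "class"])
    df = df.reindex(df["log2fc"].abs().sort_values(ascending=False).index)
    df = df.reset_index(drop=True)
    if fdr and len(df):
        from statsmodels.stats.multitest import multipletests
        df["pvalue_bh"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    if alpha is not None:
        df["significant"] = df["pvalue"] < alpha
    return df


def frequency_ranges(counts, bins=(1, 10, 100, 1_000, 10_000, 100_000)) -> pd.DataFrame:
    """Histogram of counts over decade ranges (1-10, 10-100, ... >100000)."""
    edges = list(bins)
    labels = [f"{a}-{b}" for a, b in zip(edges[:-1], edges[1:])] + [f">{edges[-1]}"]
    out = {lab: 0 for lab in labels}
    for c in counts:
        for a, b, lab in zip(edges[:-1], edges[1:], labels):
            if a <= c < b:
                out[lab] += 1
                break
        else:
            if c >= edges[-1]:
                out[labels[-1]] += 1
    return pd.DataFrame({"range": labels, "n": [out[lab] for lab in labels]})


@dataclass(frozen=True)
class RelativeQuantity:
    delta_delta_ct: float
    rq: float          # 2 ** -ΔΔCT
    se: float          # standard error of rq (delta method)


def delta_delta_ct(ct_target, ct_reference) -> RelativeQuantity:
    """Relative quantity by the ΔΔCT method with propagated standard error.

    Each argument is a pair of replicate CT lists: (test condition,
    calibrator condition).  ΔCT = mean(target) - mean(reference) per
    condition; ΔΔCT = ΔCT_test - ΔCT_calibrator; RQ = 2^-ΔΔCT.  Replicate
    SDs propagate through both subtractions; SE(RQ) = ln2 * RQ * SE(ΔΔCT).
    """
    def _cell(values):
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("each condition needs >= 2 replicates")
        if not np.isfinite(v).all():
            raise ValueError("CT values must be finite")
        return v.mean(), v.std(ddof=1) ** 2 / v.size

    (mt_test, vt_test), (mt_cal, vt_cal) = map(_cell, ct_target)
    (mr_test, vr_test), (mr_cal, vr_cal) = map(_cell, ct_reference)
    ddct = (mt_test - mr_test) - (mt_cal - mr_cal)
    var = vt_test + vr_test + vt_cal + vr_cal
    rq = 2.0 ** (-ddct)
    se = math.log(2.0) * rq * math.sqrt(var)
    return RelativeQuantity(ddct, rq, se)
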