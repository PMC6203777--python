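"""Quantification and no-replicate differential expression.

CircRNA abundance is expressed as back-spliced reads per million,
``RPM = 1e6 * C / N``, with C the junction reads uniquely assigned to one
circRNA and N the library's total junction reads; over a complete
catalog the per-library RPM values sum to one million by construction.

With a single library per condition no dispersion can be estimated, so
differential testing fixes the biological coefficient of variation (BCV)
and uses an exact conditional negative-binomial test: the two counts are
rescaled to the geometric-mean library size, and conditional on their
sum s the two-sided p-value aggregates all outcomes whose probability
does not exceed that of the observed split, under two independent
NB(mean s/2, dispersion BCV^2) masses normalized over the s + 1
outcomes. At BCV = 0 this reduces to the conditional binomial test.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CircRecord, DeResult

DEFAULT_BCV = 0.01
DEFAULT_FC = 2.0
DEFAULT_FDR = 0.01
DEFAULT_PSEUDO_RPM = 1.0


def compute_rpm(counts: Mapping[str, int], total: int) -> Dict[str, float]:
    """Back-spliced reads per million: 1e6 * C / N (no pseudocounts)."""
    if total <= 0:
        raise ValueError("total junction reads must be positive for RPM")
    return {circ_id: 1e6 * c / total for circ_id, c in counts.items()}


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi == 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / phi
    return stats.nbinom.logpmf(k, r, r / (r + mean))


def exact_nb_test(y1: int, y2: int, n1: float, n2: float, bcv: float = DEFAULT_BCV) -> float:
    """Two-sided exact conditional NB test for one count per group.

    Counts are equalized to the geometric-mean library size as
    pseudo-counts (rounded half-to-even), so the test reduces to the
    identity when n1 == n2. Two zero counts carry no evidence (p = 1).
    """
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be non-negative")
    if bcv < 0:
        raise ValueError("bcv must be non-negative")
    phi = bcv * bcv
    g = math.sqrt(n1 * n2)
    yt1 = round(y1 * g / n1)
    yt2 = round(y2 * g / n2)
    s = yt1 + yt2
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    logp = _nb_logpmf(k, s / 2, phi) + _nb_logpmf(s - k, s / 2, phi)
    probs = np.exp(logp - logp.max())
    probs /= math.fsum(probs)  # compensated: tails can be ~1e-300
    p_obs = probs[yt1]
    return float(min(1.0, math.fsum(probs[probs <= p_obs * (1 + 1e-12)])))


def bh_adjust(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    if len(pvals) == 0:
        return []
    return list(multipletests(list(pvals), method="fdr_bh")[1])


def call_degs(
    records: Sequence[CircRecord],
    contrast: Tuple[str, str],
    bcv: float = DEFAULT_BCV,
    fc_threshold: float = DEFAULT_FC,
    fdr_threshold: float = DEFAULT_FDR,
    pseudo_rpm: float = DEFAULT_PSEUDO_RPM,
) -> List[DeResult]:
    """Differential calls for one two-library contrast.

    log2FC is computed on RPM with a pseudo-RPM offset (default 1) so
    zero counts stay finite; the p-value comes from the exact NB test on
    the raw counts with the library junction-read totals; q-values are
    BH-adjusted over all tested circRNAs. A circRNA is differentially
    expressed when |log2FC| >= log2(fc_threshold) and q <= fdr_threshold.
    """
    lib1, lib2 = contrast
    results = []
    pvals = []
    for rec in records:
        n1, n2 = rec.N[lib1], rec.N[lib2]
        c1, c2 = rec.C[lib1], rec.C[lib2]
        rpm1 = rec.rpm.get(lib1, 1e6 * c1 / n1 if n1 > 0 else 0.0)
        rpm2 = rec.rpm.get(lib2, 1e6 * c2 / n2 if n2 > 0 else 0.0)
        log2fc = math.log2((rpm2 + pseudo_rpm) / (rpm1 + pseudo_rpm))
        p = exact_nb_test(c1, c2, n1, n2, bcv=bcv)
        pvals.append(p)
        results.append((rec.circ_id, log2fc, p))
    qvals = bh_adjust(pvals)
    lfc_min = math.log2(fc_threshold) if math.isfinite(fc_threshold) else math.inf
    out = []
    for (circ_id, log2fc, p), q in zip(results, qvals):
        is_deg = abs(log2fc) >= lfc_min and q <= fdr_threshold
        out.append(DeResult(circ_id=circ_id, log2fc=log2fc, p=p, q=float(q), is_deg=is_deg))
    return out


def records_from_counts(counts, libraries: Sequence[str] | None = None) -> List[CircRecord]:
    """Build CircRecords from a counts table (circ_id x library).

    Library totals N are the column sums of the catalog (junction reads
    counted after candidate filtering), so RPM sums to 1e6 per library.
    """
    libs = list(libraries) if libraries is not None else list(counts.columns)
    totals = {lib: int(counts[lib].sum()) for lib in libs}
    records = []
    for circ_id, row in counts.iterrows():
        c = {lib: int(row[lib]) for lib in libs}
        rpm = {
            lib: (1e6 * c[lib] / totals[lib]) if totals[lib] > 0 else 0.0
            for lib in libs
        }
        records.append(CircRecord(circ_id=str(circ_id), C=c, N=totals, rpm=rpm))
    return records
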