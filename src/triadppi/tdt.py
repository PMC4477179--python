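"""Reference transmission/discordance tests: TDT, parenTDT, combTDT.

The TDT counts transmissions of the variant allele from heterozygous
parents to the affected child: with ``b`` transmissions and ``c``
non-transmissions the statistic is ``(b - c)^2 / (b + c)`` on 1 df.

The parenTDT (parental discordance test) compares allele counts between
an affected and an unaffected parent within each family.  Families where
both parents are affected — or neither is — are uninformative and
discarded, as are genotype-concordant pairs (their difference is zero).
With per-family differences ``d_i = g_affected - g_unaffected`` the
statistic is ``(sum d_i)^2 / (sum d_i^2)`` on 1 df, a McNemar-style form
using the observed second moment as the variance.

combTDT combines the two at the count level:
``(b - c + sum d_i)^2 / (b + c + sum d_i^2)``.

All three discard families with missing genotypes.  Because every
family's contribution is determined by its cell ``(M, F, C, D_M[, D_F])``,
the counts are computed from a :class:`~triadppi.data.CellCountTable`;
record-level wrappers tabulate first.  One-sex designs treat the father
as unaffected, so "exactly one affected parent" reduces to ``D_M = 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

from .data import CELL_C, CELL_F, CELL_M, CellCountTable, TriadRecord, tabulate
from .results import TestResult, chi2_test

logger = logging.getLogger(__name__)

# deterministic per-cell transmission bookkeeping:
#   heterozygous parents in the cell, and how many of them transmitted
#   the variant (fixed by C minus the homozygous-variant parents' copies)
_HETS = (CELL_M == 1).astype(float) + (CELL_F == 1).astype(float)
_DET = (CELL_M == 2).astype(float) + (CELL_F == 2).astype(float)
_HET_TRANS = CELL_C - _DET
_HET_NONTRANS = _HETS - _HET_TRANS
_MF_DIFF = (CELL_M - CELL_F).astype(float)


@dataclass
class TdtCounts:
    """Sufficient statistics of the TDT family of tests."""

    b: float            # variant transmissions from heterozygous parents
    c: float            # non-transmissions
    d_sum: float        # sum of (affected - unaffected) parent allele counts
    d_sq_sum: float     # sum of squared differences
    n_discarded: float = 0.0


def _as_table(data: Union[CellCountTable, Iterable[TriadRecord]]) -> tuple[CellCountTable, float]:
    if isinstance(data, CellCountTable):
        return data, 0.0
    records = list(data)
    complete = [r for r in records if r.complete]
    n_dropped = len(records) - len(complete)
    if n_dropped:
        logger.info("TDT-family tests discarded %d incomplete families", n_dropped)
    return tabulate(complete), float(n_dropped)


def tdt_counts(data: Union[CellCountTable, Iterable[TriadRecord]]) -> TdtCounts:
    table, n_dropped = _as_table(data)
    margin = table.genotype_margin()
    b = float(margin @ _HET_TRANS)
    c = float(margin @ _HET_NONTRANS)
    if table.design == "one_sex":
        # father implicitly unaffected: informative iff the mother is affected
        aff = table.counts[:, 1]
        d_sum = float(aff @ _MF_DIFF)
        d_sq = float(aff @ _MF_DIFF**2)
    else:
        mother_only = table.counts[:, 1, 0]
        father_only = table.counts[:, 0, 1]
        d_sum = float(mother_only @ _MF_DIFF - father_only @ _MF_DIFF)
        d_sq = float((mother_only + father_only) @ _MF_DIFF**2)
    return TdtCounts(b, c, d_sum, d_sq, n_discarded=n_dropped)


def tdt(data) -> TestResult:
    """Transmission disequilibrium test."""
    k = tdt_counts(data)
    denom = k.b + k.c
    if denom <= 0:
        return TestResult("tdt", np.nan, 1, np.nan,
                          message="no informative transmissions")
    return chi2_test("tdt", (k.b - k.c) ** 2 / denom, 1,
                     sign=1 if k.b >= k.c else -1, n_used=denom)


def paren_tdt(data) -> TestResult:
    """Parental discordance test (phenotype-discordant parents only)."""
    k = tdt_counts(data)
    if k.d_sq_sum <= 0:
        return TestResult("parentdt", np.nan, 1, np.nan,
                          message="no informative discordant parental pairs")
    return chi2_test("parentdt", k.d_sum**2 / k.d_sq_sum, 1,
                     sign=1 if k.d_sum >= 0 else -1, n_used=k.d_sq_sum)


def comb_tdt(data) -> TestResult:
    """Combined TDT: transmission and parental-discordance counts summed."""
    k = tdt_counts(data)
    denom = k.b + k.c + k.d_sq_sum
    if denom <= 0:
        return TestResult("combtdt", np.nan, 1, np.nan,
                          message="no informative families")
    num = k.b - k.c + k.d_sum
    return chi2_test("combtdt", num**2 / denom, 1,
                     sign=1 if num >= 0 else -1, n_used=denom)
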